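# saposim

Why does a sea cucumber not dissolve its own membranes?  Holothuroids produce
saponins — amphiphilic glycosides such as Frondoside A that permeabilize
sterol-containing membranes by clustering the sterol into domains — yet their
own cell membranes are full of sterol.  The twist is *which* sterol: instead
of cholesterol (Δ5), holothuroids use Δ7 sterols (5α-cholest-7-en-3β-ol),
whose 7,8 double bond bends the molecule into an "L".  `saposim` is a
desk-scale modelling pipeline for studying that contrast: it quantifies how a
saponin inserts into a bilayer, how strongly it couples to each membrane
lipid, how those couplings reshape a monolayer into sterol domains, and how
the corresponding wet-lab readouts (calcein leakage, isothermal titration
calorimetry) are computed.

## What's inside

| stage | module | core quantity |
|---|---|---|
| implicit-bilayer insertion | `saposim.impala` | hydration C(z) = 1 − 1/(1+e^{α(\|z\|−z₀)}) and the two-restraint energy profile E(z) |
| interfacial pair docking | `saposim.hypermatrix` | per-heavy-atom interaction energies over an exhaustive interface-preserving pose grid |
| lattice monolayer | `saposim.bigmonolayer` | side×side molecular grid minimized by Kawasaki-exchange Metropolis annealing |
| domain analysis | `saposim.domains` | relative mean sterol-domain size and the Welch two-sample test between systems |
| wet-lab arithmetic | `saposim.invitro` | %Leakage = 100(F_t−F_contr)/(F_tot−F_contr); partition-model fit of (K, ΔH); ΔG = −RT ln(K·c°), TΔS = ΔH − ΔG |
| input generators | `saposim.synthetic_data` | fixture molecules (rod / L / cone / phospholipid), scenario matrices, seeded ITC and leakage traces |
| structures | `saposim.molecules` | PDB/CSV input, per-atom parameters, conformer scans, interface orientation, interfacial areas |

The numbered scripts under `analysis/` run the stages in order and write
tables, grids and figures under `results/`.  See `docs/methods.md` for the
models, parameter defaults and design decisions.

## Worked example

Dock the saponin fixture against each membrane lipid, then run the two
monolayer systems and compare their sterol domains:

```bash
python analysis/03_docking_energies.py
python analysis/04_monolayer_simulation.py
python analysis/05_domain_statistics.py
```

prints

```
saponin vs dmpc_like         :  -3.085 kJ/mol per heavy atom (vdw  -21.21, elec  0.000, pho  -80.59)
saponin vs cholesterol_like  :  -2.486 kJ/mol per heavy atom (vdw   -1.21, elec  0.000, pho  -75.85)
saponin vs delta7_like       :  -2.273 kJ/mol per heavy atom (vdw  -11.04, elec  0.000, pho  -59.43)
...
cholesterol_system:   54.6 domains of mean size   42.2 cells, relative mean size 0.0183
delta7_system:   80.2 domains of mean size   28.8 cells, relative mean size 0.0125
Welch two sample test on log relative mean size: t = 12.115, df = 6.4537, p = 1.119e-05
larger relative mean sterol-domain size: cholesterol_system
```

Reading the numbers: the saponin couples most strongly to the phospholipid and
more strongly to cholesterol than to the bent Δ7 sterol, with the hydrophobic
component dominating every pair — so the interaction is chiefly apolar.
Downstream, the cholesterol monolayer coarsens into few large sterol domains
while the Δ7 monolayer stays scattered into many small clusters
(`results/monolayer/*/rep*.png` shows the grids, one pixel per molecule), and
the Welch test on the log relative mean domain sizes separates the two systems
decisively.  That is the modelled mechanism of selective membranolysis: strong
saponin–cholesterol coupling plus strong cholesterol self-association build
the large domains associated with permeabilization, and the Δ7 geometry breaks
both.

The same library calls are available directly:

```python
from saposim.impala import ImplicitMembrane, insertion_scan
from saposim.molecules import orient_at_interface
from saposim.synthetic_data import fixture_molecule

sap = fixture_molecule("frondoside_like")
sap = sap.transformed(orient_at_interface(sap))
profile = insertion_scan(sap, ImplicitMembrane(), dz=1.0, angular_step=30.0)
print(profile.global_best.z_center)   # -10.0 : optimum near the interface
```

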