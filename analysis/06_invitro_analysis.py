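"""ITC isotherm fitting and calcein-leakage arithmetic on synthetic traces.

Generates a blank-contaminated titration from known parameters, subtracts the
two blanks, refits the partition model, derives the thermodynamic description
(ΔG, TΔS at 26 °C), and recovers leakage percentages from simulated
fluorescence traces.  Also reports the thermodynamics implied by the measured
fish-like-liposome binding constant K = 469.6 mM⁻¹.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from saposim.invitro import (
    derive_thermodynamics,
    fit_binding_isotherm,
    leakage_percent,
    subtract_blanks,
)
from saposim.synthetic_data import (
    plateau_fluorescence,
    simulate_itc_trace,
    simulate_leakage_trace,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/invitro"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    K_true, dH_true = 1.5, -30.0
    clean = simulate_itc_trace(K_true, dH_true, n_inj=30)
    noise = 0.05 * np.abs(clean.heats).max()
    raw = simulate_itc_trace(K_true, dH_true, n_inj=30, noise_sd=noise, seed=args.seed)
    # systematic blanks: lipid-into-buffer runs negative, buffer-into-saponin positive
    blank1 = replace(raw, heats=np.full(30, -0.8))
    blank2 = replace(raw, heats=np.full(30, +0.3))
    contaminated = replace(raw, heats=raw.heats + blank1.heats + blank2.heats)
    corrected = subtract_blanks(contaminated, blank1, blank2)
    corrected.to_csv(args.out / "corrected_titration.csv")
    res = fit_binding_isotherm(corrected)
    print(
        f"partition-model fit: K = {res.K:.3f} ± {res.K_stderr:.3f} mM⁻¹ "
        f"(true {K_true}), ΔH = {res.dH:.2f} ± {res.dH_stderr:.2f} kJ/mol (true {dH_true})"
    )
    print(
        f"derived at {res.temperature:.2f} K: ΔG = {res.dG:.2f} kJ/mol, "
        f"TΔS = {res.TdS:.2f} kJ/mol"
    )
    fish = derive_thermodynamics(K=469.6, dH=-5.0, T=299.15)
    print(
        f"fish-like K = 469.6 mM⁻¹ implies ΔG = {fish.dG:.2f} kJ/mol at 26 °C "
        f"(entropy-dominated: |TΔS| = {abs(fish.TdS):.2f} > |ΔH| = {abs(fish.dH):.2f})"
    )

    rows = []
    for label, level in (("fish_like", 70.0), ("holothuroid_like", 25.0), ("sterol_free", 20.0)):
        tr = simulate_leakage_trace(level, noise_sd=0.5, seed=args.seed)
        tr.to_csv(args.out / f"leakage_{label}.csv", index=False)
        rec = leakage_percent(plateau_fluorescence(tr), 10.0, 100.0)
        rows.append({"system": label, "true_level_pct": level, "recovered_pct": rec})
        print(f"leakage {label:18s}: generated {level:5.1f} %, recovered {rec:5.1f} %")
    pd.DataFrame(rows).to_csv(args.out / "leakage_summary.csv", index=False)


if __name__ == "__main__":
    main()
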