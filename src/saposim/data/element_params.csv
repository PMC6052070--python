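# Default per-element physicochemical parameters for coarse molecular models.
# etr_per_area: atomic transfer-energy scale, kJ mol^-1 A^-2 (negative = apolar,
#   i.e. transfer water->apolar phase is favorable); multiplied by the atom's
#   accessible surface S(i) to give the per-atom transfer energy E_tr(i).
# radius: van der Waals radius, Angstrom.  charge: default partial charge, e.
element,charge,etr_per_area,radius
C,0.0,-0.105,1.8
H,0.0,-0.0175,1.0
O,0.0,0.100,1.5
N,0.0,0.112,1.55
P,0.0,0.100,1.9
S,0.0,-0.100,1.8
NA,0.0,0.100,1.2
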