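"""Formula and ion-mass arithmetic for three library standards.

Computes the theoretical [M-H]-/[M+H]+ m/z (monoisotopic mass with
electron-mass correction) and the mass error of an observed m/z under both
ppm conventions the package exposes.
"""

from dbaffinity import IonSpec, ion_mz, isotope_envelope, parse_formula, \
    ppm_error, truncate

cases = [
    ("liquiritigenin [M-H]-", "C15H11O4", -1, 255.0661),
    ("gallic acid [M-H]-", "C7H5O5", -1, 169.0133),
    ("L-(-)-proline [M+H]+", "C5H10NO2", +1, 116.0708),
]

for name, formula, charge, observed in cases:
    ion = IonSpec(parse_formula(formula), charge)
    theo = round(ion_mz(ion), 4)  # reported at the instrument's 4 decimals
    print(f"{name:26s} theoretical m/z {theo:.4f}  observed {observed:.4f}  "
          f"error {truncate(ppm_error(observed, theo, 'nominal_denominator')):.4f} ppm "
          f"(nominal) / {truncate(ppm_error(observed, theo)):.4f} ppm (exact)")

env = isotope_envelope("C15H11O4", n_peaks=3)
print("\nliquiritigenin ion isotope envelope (A, A+1, A+2):",
      ", ".join(f"{a:.4f}" for _, a in env))
print("Each error is |observed - theoretical| in parts per million; the")
print("envelope gives the relative abundance of the first three isotopologues.")
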