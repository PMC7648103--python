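"""Accurate-mass adduct annotation of observed feature m/z values.

Builds a small candidate list of metabolites, annotates a handful of observed
m/z values against the common positive-mode adducts at 10 ppm, and prints the
matches.  The ppm error column is the signed relative mass error; values well
inside +/-10 ppm support the assignment, and smaller tolerances (5 ppm) can
be used on high-resolution instruments.
"""

from pulsedims import chem

candidates = [
    ("niacinamide", "C6H6N2O"),
    ("hypoxanthine", "C5H4N4O"),
    ("taurine", "C2H7NO3S"),
    ("L-kynurenine", "C10H12N2O3"),
    ("L-tryptophan", "C11H12N2O2"),
    ("5-hydroxy-L-tryptophan", "C11H12N2O3"),
]

observed = [123.0552, 163.9777, 209.0927, 227.0793, 243.0745, 350.0000]
adducts = ["[M+H]+", "[M+Na]+", "[M+K]+", "[M+NH4]+"]

print(f"{'observed':>10} {'candidate':<24} {'adduct':<10} {'theoretical':>12} {'ppm':>7}")
for mz in observed:
    hits = chem.annotate(mz, candidates, adducts, tol_ppm=10.0)
    if not hits:
        print(f"{mz:>10.4f} {'-- no match within 10 ppm --':<24}")
        continue
    for h in hits:
        print(
            f"{mz:>10.4f} {h.candidate_name:<24} {h.adduct.name:<10} "
            f"{h.theoretical_mz:>12.4f} {h.ppm_error:>+7.2f}"
        )
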