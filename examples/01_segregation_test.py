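"""Chi-square segregation tests and an F3 progeny test.

Tests the observed F2 phenotype counts of two crosses against the 3:1
ratio expected for a monogenic recessive trait, then infers an F2
genotype from its selfed F3 family.
"""

from mutseek import chi_square_ratio_test, progeny_test_genotype

for label, counts in [("cross 1 (578 F2)", (448, 130)),
                      ("cross 2 (1356 F2)", (1038, 318))]:
    res = chi_square_ratio_test(counts, (3, 1))
    print(f"{label}: normal/mutant = {counts}, chi2 = {res.chi2:.3f}, "
          f"P = {res.p_value:.3f}")
print("# P > 0.05 in both crosses: the counts are consistent with 3:1, "
      "i.e. a single recessive nuclear locus.\n")

call = progeny_test_genotype(36, 0)
print(f"F3 family of 36, all normal -> F2 genotype {call.genotype} "
      f"(misclassification probability {call.misclassification_probability:.2e})")
print("# A true heterozygote would show zero mutants in 36 selfed progeny "
      "with probability (3/4)^36, so the homozygous call is near-certain.")
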