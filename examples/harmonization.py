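"""Allele harmonization: flips, strand complements and palindromic SNPs.

Builds a tiny exposure/outcome pair by hand covering every case the
harmonizer distinguishes, and prints the per-SNP audit trail.
"""

import pandas as pd

from mrkit import harmonize

cols = ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval"]
exposure = pd.DataFrame([
    ("rs1", "A", "G", 0.20, 0.10, 0.01, 1e-9),    # same orientation
    ("rs2", "A", "G", 0.20, 0.10, 0.01, 1e-9),    # outcome swapped
    ("rs3", "A", "G", 0.20, 0.10, 0.01, 1e-9),    # outcome on other strand
    ("rs4", "A", "T", 0.10, 0.10, 0.01, 1e-9),    # palindromic, clear eaf
    ("rs5", "G", "C", 0.48, 0.10, 0.01, 1e-9),    # palindromic, ambiguous eaf
    ("rs6", "A", "G", 0.20, 0.10, 0.01, 1e-9),    # incompatible alleles
], columns=cols)
outcome = pd.DataFrame([
    ("rs1", "A", "G", 0.20, 0.05, 0.01, 1e-3),
    ("rs2", "G", "A", 0.80, -0.05, 0.01, 1e-3),
    ("rs3", "T", "C", 0.20, 0.05, 0.01, 1e-3),
    ("rs4", "A", "T", 0.11, 0.05, 0.01, 1e-3),
    ("rs5", "G", "C", 0.47, 0.05, 0.01, 1e-3),
    ("rs6", "A", "C", 0.20, 0.05, 0.01, 1e-3),
], columns=cols)

h = harmonize(exposure, outcome, palindrome_policy="conservative", eaf_threshold=0.42)
print(h.audit.to_string(index=False))
print(f"\n{h.n_snps} SNPs usable for estimation; aligned outcome betas:")
print(h.data[["snp_id", "beta_outcome"]].to_string(index=False))
# rs2's outcome beta is negated onto the exposure's effect allele; rs5 is
# dropped because a ~50% frequency cannot resolve the strand of a G/C SNP.
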