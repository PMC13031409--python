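"""Panel QC: concordance against a reference set, HWE and imputation.

Compares amplicon-style genotypes against a reference genotype set with the
five-level concordance score, drops loci with too many discordances or
heterozygote excess, and imputes residual missing calls with the modal
genotype of the sample's population.
"""

import numpy as np

from gtpanel import BaselineSpec, simulate_baseline_pair
from gtpanel.hybrid_model import inject_missing
from gtpanel.panel_qc import (
    concordance_matrix,
    filter_concordant,
    hwe_excess_het_filter,
    impute_most_frequent,
    missingness_profile,
)

bf, reference = simulate_baseline_pair(BaselineSpec(n_loci=120, n_samples_per_pop=40, seed=6))
# the "new" dataset: same truth with some dropout, mimicking re-genotyping
new = inject_missing(reference, 0.05, seed=7)

scores = concordance_matrix(reference, new)
kept, hist = filter_concordant(scores, max_discordant=4)
print(f"concordance filter kept {len(kept)} of {scores.shape[1]} loci")

retained, hwe = hwe_excess_het_filter(new, population="A", alpha=0.05, max_missing=0.2)
print(f"HWE/missingness filter kept {len(retained)} loci "
      f"({(hwe['reason'] == 'excess_het').sum()} excess-het, "
      f"{(hwe['reason'] == 'missingness').sum()} high-missing)")

per_sample, per_locus = missingness_profile(new)
print(f"missingness: {per_sample.mean():.3f} per sample, {per_locus.mean():.3f} per locus")

completed = impute_most_frequent(new)
print(f"missing cells after modal imputation: {completed.missing_mask().sum()}")
# Imputation standardises completeness before simulation-based power tests;
# it never alters a called genotype.
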