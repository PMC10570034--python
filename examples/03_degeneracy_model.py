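"""Codon degeneracy vs methylation status: logistic regression and contrasts.

Annotates every coding position with its degeneracy class (0/2/3/4-fold under
the standard genetic code), joins methylation calls onto coding CpGs, fits
methylated ~ degeneracy * housekeeping, and reports likelihood-ratio term
tests plus Tukey-style pairwise contrasts between degeneracy levels.
"""

import numpy as np

from gbmeth import fit_methylation_model, pairwise_contrasts
from gbmeth.simulate import simulate_site_observations

# Site-level observations with a +0.5 logit shift at 0-fold degenerate sites:
# the structure expected if methylation is enriched at selectively constrained
# coding positions.
rng = np.random.default_rng(11)
obs = simulate_site_observations(50_000, rng, p_base=0.2,
                                 hk_logit_effect=0.5, deg_shifts={0: 0.5})

fit = fit_methylation_model(obs)
for term, t in fit.term_tests.items():
    print(f"{term:>12}: X2 = {t.statistic:7.1f}, df = {t.df}, p = {t.p_value:.3g}")

print("\npairwise degeneracy contrasts (positive z: lower fold more methylated):")
for c in pairwise_contrasts(fit, adjust="single_step"):
    print(f"  {c.level_a} vs {c.level_b}: z = {c.z:6.2f}, adj. p = {c.p_adjusted:.3g}")
# The 0-fold level sits above all others (positive z against 2/3/4-fold);
# contrasts among the unshifted levels are null.
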