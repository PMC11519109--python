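"""Reader-concordance machinery: inconsistency sets and Cohen's kappa.

When a reconstruction hallucinates (creates or erases lesion-like
structure), the detector's patient score changes between the reference
and accelerated conditions.  The cases with the largest |score change|
form the 'inconsistent set' a radiologist would review; chance-corrected
agreement between the reader's calls and the detector's is summarised by
Cohen's kappa on the {consistent, minor variation} vs {inconsistent}
collapse.
"""

import numpy as np

from diagqm import cohens_kappa, select_inconsistency_sets

rng = np.random.default_rng(0)
n = 60
case_ids = [f"case_{i:03d}" for i in range(n)]
scores_r1 = rng.random(n)
# accelerated scores mostly track R1 with noise; a handful diverge strongly
scores_r4 = np.clip(scores_r1 + 0.05 * rng.standard_normal(n), 0, 1)
halluc = rng.choice(n, size=8, replace=False)
scores_r4[halluc] = rng.random(8)

inconsistent, consistent = select_inconsistency_sets(case_ids, scores_r1, scores_r4, k=15)
print(f"inconsistent set (top 15 |score change|): {inconsistent[:5]} ...")
print(f"consistent set  (bottom 15):              {consistent[:5]} ...")

# a simulated reader agrees with the detector on most inconsistent cases
detector = ["inconsistent" if c in inconsistent else "consistent" for c in case_ids]
reader = list(detector)
for i in rng.choice(n, size=12, replace=False):  # reader disagrees on some
    reader[i] = "minor variation" if reader[i] == "inconsistent" else reader[i]
res = cohens_kappa(reader, detector)
print(f"\nCohen's kappa (collapsed 2x2): {res.kappa:.3f} "
      f"(95% CI {res.ci[0]:.3f} to {res.ci[1]:.3f})")
print("kappa of 0 would mean chance-level agreement; 1 perfect agreement.")
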