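"""Read-mixture plasmode benchmark with a known reference structure.

Simulates five dissimilar individuals, builds 12-sample mixture plasmodes
(pure samples, 2/3:1/3 and 1/2:1/2 binomial read mixtures), and reports how
strongly each dissimilarity measure correlates with the reference
dissimilarity implied by the known shared-read proportions.  A good measure
should track the planted structure (r well above the raw-scale measures).
"""

import numpy as np

import plasmodeval as pv
from plasmodeval.synthetic_base import five_individual_design

N_PLASMODES = 5

cm, _, _ = pv.simulate_base_counts(five_individual_design(seed=2))
cm = cm.drop_all_zero()
design = pv.MixtureDesign(base_ids=cm.sample_ids, n_plasmodes=N_PLASMODES, seed=2)
ref = pv.reference_similarity(design)

print("reference dendrogram from the shared-reads dissimilarity:")
print(pv.to_newick(pv.complete_linkage(ref.d_ref, ref.sample_ids)))

refcor = {m: [] for m in pv.MEASURES}
for k in range(N_PLASMODES):
    rep = pv.build_mixture_plasmode(cm, design, k)
    for m in pv.MEASURES:
        d = pv.compute_measure(rep.counts, m)
        refcor[m].append(pv.reference_correlation(d, ref))

print(f"\ncorrelation with the reference dissimilarity "
      f"(mean over {N_PLASMODES} plasmodes):")
for m in pv.MEASURES:
    print(f"  {m:4s}  r = {np.mean(refcor[m]):.3f}")
print("\nhigh r: the measure recovers the known mixture structure.")
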