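"""Correct a count matrix into an unbiased co-expression network.

Shows the full normalization stack — low-count filter, TMM, asinh-log2
transform, first-principal-component removal, Pearson correlations, spatial
quantile normalization — and the per-bin diagnostic showing the
mean-expression-linked bias before and after correction.
"""

import numpy as np

from regumine.coexpression import coexpression_pipeline, critical_pcc
from regumine.synthetic import default_scenario

scenario = default_scenario(seed=1)
corr, diagnostics = coexpression_pipeline(scenario.counts)

print(f"{corr.pcc.shape[0]} genes x {corr.n_samples} samples")
print(f"critical |PCC| at alpha=0.05: {critical_pcc(corr.n_samples):.2f}")

print("within-bin correlation medians by mean-expression decile:")
for stage in ("normalized", "pc1_removed", "spqn"):
    meds = diagnostics[stage]["median"].to_numpy()
    print(f"  {stage:12s} " + " ".join(f"{m:+.2f}" for m in meds))

reg = scenario.truth.regulator_gene
members = sorted(scenario.truth.regulon_genes)
rr = corr.pcc.loc[reg, members].to_numpy()
print(f"median PCC(regulator, planted regulon) after correction: {np.median(rr):.2f}")
# Before correction every bin's median is pushed away from zero by the
# planted batch-style confounder; after PC1 removal + spqn the bins are
# near zero while the true repressor anti-correlation survives.
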