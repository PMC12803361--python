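"""Paired pre/on-treatment dynamics stratified by response group.

Generates a cohort in which the Tfh_LAG3 subset doubles on treatment in
expanders only, then recovers: the per-subset expansion-bias delta, the
Tfh_LAG3/Tfh_IGFL2 abundance-ratio delta per patient, and the
response-specific differential-expression classification.
"""

from tmeniche.dynamics import (
    classify_response_genes,
    de_wilcoxon,
    expansion_bias,
    paired_log2fc,
    subset_frequencies,
    tfh_ratio_delta,
)
from tmeniche.simulate import CohortSpec, generate_repertoire_cohort

clono, design, ds = generate_repertoire_cohort(CohortSpec(seed=0))
meta = ds.cell_table().rename(columns={"cluster_label": "subset_label"})

freqs = subset_frequencies(meta, pseudocount=0.5)
fcs = paired_log2fc(freqs, design)
bias = expansion_bias(fcs, design)
print("expansion bias (delta = expander mean log2FC - non-expander mean):")
print(bias.round(3).to_string(index=False))
# Tfh_LAG3 carries the planted expander-specific doubling: positive
# delta with a small rank-sum p; null subsets hover near zero.

per, comp = tfh_ratio_delta(meta, design, "Tfh_LAG3", "Tfh_IGFL2")
print(
    f"Tfh_LAG3/Tfh_IGFL2 ratio delta: expanders {comp['mean_delta_expander']:+.2f}, "
    f"non-expanders {comp['mean_delta_nonexpander']:+.2f}, p={comp['p_value']:.3g}"
)
# a rising ratio on treatment in expanders only mirrors the
# abundance-shift readout used to track the cytotoxic Tfh state.

de_e = de_wilcoxon(ds, "Tfh_LAG3", "expander")
de_n = de_wilcoxon(ds, "Tfh_LAG3", "non_expander")
records, stats = classify_response_genes(de_e, de_n)
print("response-gene categories:", records["category"].value_counts().to_dict())
print(f"DEG ratio expander/non-expander: {stats['deg_ratio']:.1f}")
# the expander-skewed DEG count reflects the planted, response-specific
# transcriptional program in this subset.
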