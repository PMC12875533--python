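"""Rank driver TFs and TF perturbation targets by multilayer random walk.

Reverse walks start from each cluster's differentially expressed genes
and climb the hierarchy TG -> CRE -> TF; the stationary scores, weighted
by cluster-specific differential expression, rank candidate driver TFs.
Forward walks from one TF rank its downstream perturbation targets.
"""

from hrnetx import EncoderConfig, LossConfig, RetentionConfig, \
    SyntheticSpec, build_hrnet, generate, mrwr_cts, mrwr_pert, train
from hrnetx.pipeline import DEFAULT_CONFIG, prepare_labels

data = generate(SyntheticSpec(seed=7))
labels, _ = prepare_labels(data.graph, data.features,
                           DEFAULT_CONFIG["labels"], seed=7)
result = train(data.graph, data.features, labels, LossConfig(seed=7),
               EncoderConfig())
hrnet = build_hrnet(data.graph, data.features, result, RetentionConfig())

for clu, master in data.master_tfs.items():
    degs = data.deg_table[data.deg_table["cluster"] == clu]
    ranked = mrwr_cts(hrnet, degs, target_layer="TF")
    top3 = list(ranked["node"].head(3))
    print(f"cluster {clu}: top driver TFs {top3} "
          f"(planted master: {master}, "
          f"{'recovered' if master in top3 else 'missed'})")
# the planted master TF of each cluster should surface in the top ranks

tf = data.master_tfs[0]
targets = mrwr_pert(hrnet, tf)
planted_downstream = {t for (s, c) in data.truth["TF-CRE"].pairs
                      if s == tf
                      for (c2, t) in data.truth["CRE-TG"].pairs
                      if c2 == c}
top10 = list(targets["node"].head(10))
hits = len(set(top10) & planted_downstream)
print(f"forward walk from {tf}: {hits}/10 of the top targets are "
      f"planted downstream genes "
      f"({len(planted_downstream)}/{len(targets)} in the universe)")
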