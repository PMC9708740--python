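"""Tumor-microenvironment scores and regulon TF activity by subtype.

Scores immune-cell signatures and stromal/immune signatures per sample,
then computes regulon-based TF activities and tests which TFs differ
between the two EMT subtypes.
"""

import dataclasses

import numpy as np
import pandas as pd

import lncemt as L
from lncemt.containers import GeneSetCollection
from lncemt.simulate import simulate_regulons

cfg = L.SimConfig(n_samples=200, seed=0)
expr, clinical, sets, truth = L.simulate_cohort(cfg)
subtype = pd.Series(
    np.where(truth.subtype == 1, "C2", "C1"), index=truth.subtype.index
)

immune = GeneSetCollection(
    {n: sets[n] for n in sets.names() if n.startswith("immune_cell")}
)
scores = L.immune_infiltration(expr, immune)
cmp_ = L.compare_groups(scores, subtype, test="student_t")
print("immune-cell signatures higher in C2:",
      int((cmp_.table["q"] < 0.05).sum()), "of", len(scores))

est = L.estimate_scores(expr, sets["stromal_signature"], sets["immune_signature"])
est_cmp = L.compare_groups(est, subtype, test="student_t")
print("stromal/immune score q-values:",
      {i: f"{q:.2g}" for i, q in est_cmp.table["q"].items()})

regsim = simulate_regulons(cfg, subtype=truth.subtype.to_numpy())
activity = L.tf_activity(expr, regsim.regulons)
diff = L.differential_tf(activity, subtype)
hits = diff.index[(diff["q"] < 0.05) & (diff["direction"] == "up")]
planted = regsim.differential.index[regsim.differential]
print(f"TFs up in C2 at q<0.05: {list(hits)}")
print(f"planted differential TFs: {list(planted)}")
# The subtype-shifted immune activities and TF regulons built into the
# generator should surface here as significant C2-vs-C1 differences.
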