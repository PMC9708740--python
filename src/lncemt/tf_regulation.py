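"""Regulon-based TF activity, differential activity and lncRNA-TF links.

TF activity per sample is the signed, size-normalized mean of target-gene
z-scores: activity(tf, s) = sum over targets of mode * z(target, s) /
sqrt(#targets), with rows standardized afterwards. Subtype-differential
activity uses a Welch t test per TF with BH adjustment; cross-cohort
consensus keeps TFs significant with the same direction in every cohort.
Localization calls are sign-based on the relative concentration index
(RCI > 0 cytoplasmic, RCI < 0 nuclear).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, RegulonTable
from .subtyping import pearson_with_p

logger = logging.getLogger("lncemt")


def tf_activity(expr: ExpressionMatrix, regulons: RegulonTable) -> pd.DataFrame:
    """TF x sample activity matrix from signed regulons.

    Target genes are z-scored across samples; regulons with fewer than two
    targets present in the matrix are dropped with a warning. Activity rows
    are standardized (mean 0, SD 1) across samples.
    """
    X = expr.values
    z = X.sub(X.mean(axis=1), axis=0)
    sd = X.std(axis=1, ddof=0).replace(0.0, np.nan)
    z = z.div(sd, axis=0).fillna(0.0)
    rows = {}
    for tf in regulons.tfs():
        tgt = regulons.targets_of(tf)
        present = tgt[tgt["target"].isin(X.index)]
        if len(present) < 2:
            logger.warning("regulon %s: <2 targets present, dropped", tf)
            continue
        zt = z.loc[present["target"]].to_numpy()
        modes = present["mode"].to_numpy()[:, None]
        act = (modes * zt).sum(axis=0) / np.sqrt(len(present))
        rows[tf] = act
    if not rows:
        raise ValueError("no regulon has >= 2 targets in the expression matrix")
    A = pd.DataFrame(rows, index=expr.sample_ids).T
    A = A.sub(A.mean(axis=1), axis=0)
    A = A.div(A.std(axis=1, ddof=0).replace(0.0, 1.0), axis=0)
    return A


def differential_tf(activity: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Welch t test of activity between two subtypes, per TF.

    ``direction`` is "up" when the mean activity is higher in the
    lexicographically later group (C2 for C1/C2 labels).
    """
    labels = labels.reindex(activity.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("differential TF test needs exactly 2 groups")
    g1 = (labels == groups[0]).to_numpy()
    g2 = (labels == groups[1]).to_numpy()
    if g1.sum() < 3 or g2.sum() < 3:
        raise ValueError("each group needs >= 3 samples")
    A1, A2 = activity.to_numpy()[:, g1], activity.to_numpy()[:, g2]
    t, p = stats.ttest_ind(A2, A1, axis=1, equal_var=False)
    delta = A2.mean(axis=1) - A1.mean(axis=1)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "delta": delta,
            "t": t,
            "p": p,
            "q": q,
            "direction": np.where(delta > 0, "up", "down"),
        },
        index=activity.index,
    )


def consensus_differential_tfs(
    tables: list[pd.DataFrame], q_thresh: float = 0.05
) -> list[str]:
    """TFs significant (q < q_thresh) with the same direction in all cohorts."""
    if not tables:
        raise ValueError("no differential tables")
    common = set(tables[0].index)
    for t in tables[1:]:
        common &= set(t.index)
    out = []
    for tf in tables[0].index:
        if tf not in common:
            continue
        sig = all(t.loc[tf, "q"] < q_thresh for t in tables)
        dirs = {t.loc[tf, "direction"] for t in tables}
        if sig and len(dirs) == 1:
            out.append(tf)
    return out


@dataclass
class LncTfCorrelation:
    pairs: pd.DataFrame  # lncRNA, tf, r, p, q — sorted by |r| descending
    top_tfs: list[str]
    linked_lncrnas: list[str]


def lncrna_tf_correlation(
    lnc_expr: ExpressionMatrix,
    activity: pd.DataFrame,
    fdr_thresh: float = 0.05,
    top_k: int = 10,
) -> LncTfCorrelation:
    """Pearson correlation of every (lncRNA, TF-activity) pair.

    Returns the BH-adjusted pair table ranked by |r|, the ``top_k`` TFs by
    their best absolute correlation, and the lncRNAs with at least one
    significant pair.
    """
    if list(lnc_expr.sample_ids) != list(activity.columns):
        if set(lnc_expr.sample_ids) != set(activity.columns):
            raise ValueError("sample ids of expression and activity do not match")
        activity = activity[lnc_expr.sample_ids]
    recs = []
    L = lnc_expr.values.to_numpy()
    for tf in activity.index:
        a = activity.loc[tf].to_numpy(dtype=float)
        r, p = pearson_with_p(a, L)
        for lnc, ri, pi in zip(lnc_expr.feature_ids, r, p):
            recs.append((lnc, tf, ri, pi))
    pairs = pd.DataFrame(recs, columns=["lncrna", "tf", "r", "p"])
    finite = pairs["p"].notna()
    q = np.full(len(pairs), np.nan)
    if finite.any():
        _, qv, _, _ = multipletests(pairs.loc[finite, "p"].to_numpy(), method="fdr_bh")
        q[finite.to_numpy()] = qv
    pairs["q"] = q
    pairs = pairs.sort_values("r", key=lambda s: -s.abs(), kind="stable").reset_index(
        drop=True
    )
    best = pairs.groupby("tf")["r"].apply(lambda s: s.abs().max())
    top_tfs = list(best.sort_values(ascending=False).index[:top_k])
    sig = pairs.loc[pairs["q"] < fdr_thresh]
    linked = list(dict.fromkeys(sig["lncrna"]))
    return LncTfCorrelation(pairs=pairs, top_tfs=top_tfs, linked_lncrnas=linked)


@dataclass
class LocalizationResult:
    calls: pd.Series  # "cytoplasmic" / "nuclear" (RCI == 0 excluded)
    nuclear_proportion: float  # NaN when undefined


def classify_localization(rci: pd.Series) -> LocalizationResult:
    """Sign-based localization from the relative concentration index."""
    if len(rci) == 0:
        raise ValueError("empty RCI table")
    nonzero = rci[rci != 0]
    calls = pd.Series(
        np.where(nonzero > 0, "cytoplasmic", "nuclear"),
        index=nonzero.index,
        name="localization",
    )
    if len(nonzero) == 0:
        logger.warning("all RCI values are 0; nuclear proportion undefined")
        prop = float("nan")
    else:
        prop = float((calls == "nuclear").mean())
    return LocalizationResult(calls=calls, nuclear_proportion=prop)
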