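"""Gene-set enrichment: single-sample scores, two-group GSEA, ORA.

``ssgsea_score`` is a rank-weighted running-sum statistic computed per
sample: features are ranked by expression (descending, average ranks for
ties); in-set genes contribute weight ``(rank from bottom)**alpha`` and the
enrichment score is the sum over the whole ranking of the difference between
the weighted in-set CDF and the uniform out-of-set CDF. It powers the EMT
score, the 28 immune-cell infiltration scores and the ESTIMATE-style
stromal/immune scores.

``gsea_two_group`` is classic phenotype-permutation GSEA with a
signal-to-noise ranking metric, weighted Kolmogorov-Smirnov enrichment
score, sign-matched NES normalization and the signed-NES FDR procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSetCollection


@dataclass
class SsgseaParams:
    """Rank-weight exponent alpha >= 0 and optional [0,1] normalization."""

    alpha: float = 0.25
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def _check_set(expr: ExpressionMatrix, genes) -> np.ndarray:
    import logging

    present = expr.feature_ids.isin(genes)
    n_present = int(present.sum())
    if n_present == 0:
        missing = sorted(set(genes) - set(expr.feature_ids))
        raise ValueError(
            f"no gene-set member present in the expression matrix; "
            f"missing: {missing[:10]}"
        )
    if n_present < 2:
        missing = sorted(set(genes) - set(expr.feature_ids))
        logging.getLogger("lncemt").warning(
            "gene set has a single member in the expression matrix; missing: %s",
            missing[:10],
        )
    if n_present == expr.n_features:
        raise ValueError("gene set covers the whole feature universe")
    return present


def ssgsea_score(
    expr: ExpressionMatrix, genes, params: SsgseaParams | None = None
) -> pd.Series:
    """Single-sample enrichment score of one gene set, per sample.

    Scores depend only on within-sample ranks, so they are invariant to any
    strictly increasing transform of a sample's expression values.
    """
    params = params or SsgseaParams()
    in_set = _check_set(expr, genes)
    X = expr.values.to_numpy()
    n_feat, n_samp = X.shape
    m = int(in_set.sum())
    scores = np.empty(n_samp)
    for s in range(n_samp):
        x = X[:, s]
        # rank from bottom (1 = lowest expression), average ranks for ties
        rank_bottom = stats.rankdata(x, method="average")
        w = rank_bottom**params.alpha
        order = np.argsort(-x, kind="stable")
        hit = in_set[order]
        w_ord = np.where(hit, w[order], 0.0)
        p_in = np.cumsum(w_ord) / w_ord.sum()
        p_out = np.cumsum(~hit) / (n_feat - m)
        scores[s] = float(np.sum(p_in - p_out))
    out = pd.Series(scores, index=expr.sample_ids, name="ssgsea")
    if params.normalize:
        rng_ = out.max() - out.min()
        if rng_ > 0:
            out = (out - out.min()) / rng_
        else:
            out = out * 0.0
    return out


def score_collection(
    expr: ExpressionMatrix, sets: GeneSetCollection, params: SsgseaParams | None = None
) -> pd.DataFrame:
    """ssGSEA for every set in a collection -> sets x samples ScoreMatrix."""
    rows = {name: ssgsea_score(expr, sets[name], params) for name in sets.names()}
    return pd.DataFrame(rows).T.loc[sets.names()]


def estimate_scores(
    expr: ExpressionMatrix,
    stromal_set,
    immune_set,
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """ESTIMATE-style stromal and immune enrichment scores (raw ES scale)."""
    params = params or SsgseaParams()
    if params.normalize:
        params = SsgseaParams(alpha=params.alpha, normalize=False)
    return pd.DataFrame(
        {
            "stromal": ssgsea_score(expr, stromal_set, params),
            "immune": ssgsea_score(expr, immune_set, params),
        }
    ).T


def immune_infiltration(
    expr: ExpressionMatrix,
    signatures: GeneSetCollection,
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """Per-cell-type infiltration scores: one ssGSEA row per signature."""
    for name in signatures.names():
        if not expr.feature_ids.isin(signatures[name]).any():
            raise ValueError(f"immune signature {name!r} fully absent from expression")
    return score_collection(expr, signatures, params)


# ---------------------------------------------------------------------------
# two-group GSEA


def _signal_to_noise(X: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    g1, g0 = X[:, mask1], X[:, ~mask1]
    mu1, mu0 = g1.mean(axis=1), g0.mean(axis=1)
    s1, s0 = g1.std(axis=1, ddof=1), g0.std(axis=1, ddof=1)
    s1 = np.maximum(s1, 0.2 * np.abs(mu1) + 1e-8)
    s0 = np.maximum(s0, 0.2 * np.abs(mu0) + 1e-8)
    return (mu1 - mu0) / (s1 + s0)


def _es_from_metric(metric: np.ndarray, in_set: np.ndarray, weight: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score (signed max deviation)."""
    order = np.argsort(-metric, kind="stable")
    hit = in_set[order]
    w = np.abs(metric[order]) ** weight
    w_hit = np.where(hit, w, 0.0)
    denom = w_hit.sum()
    if denom == 0:  # all in-set metrics exactly zero: uniform steps
        w_hit = hit.astype(float)
        denom = w_hit.sum()
    p_hit = np.cumsum(w_hit) / denom
    p_miss = np.cumsum(~hit) / (len(hit) - hit.sum())
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


@dataclass
class GseaResult:
    """Per-set ES, NES, nominal p, FDR q and direction for group1 vs group0."""

    table: pd.DataFrame  # index set name; columns es, nes, p, q, direction


def gsea_two_group(
    expr: ExpressionMatrix,
    labels,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    weight: float = 1.0,
) -> GseaResult:
    """Phenotype-permutation GSEA comparing group 1 against group 0.

    ``labels`` is a binary vector aligned to the samples. With
    ``exhaustive=True`` every label split preserving group sizes is
    enumerated (only sensible for very small cohorts) and nominal p-values
    are exact.
    """
    labels = pd.Series(labels, index=expr.sample_ids) if not isinstance(
        labels, pd.Series
    ) else labels.reindex(expr.sample_ids)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    mask1 = labels.to_numpy().astype(int) == 1
    n1, n0 = int(mask1.sum()), int((~mask1).sum())
    if min(n1, n0) < 3:
        raise ValueError("both groups need >= 3 samples")
    X = expr.values.to_numpy()
    if (X[:, mask1].std(axis=1) == 0).all() or (X[:, ~mask1].std(axis=1) == 0).all():
        raise ValueError("a group has zero variance in every gene")

    metric = _signal_to_noise(X, mask1)
    in_sets = {name: np.asarray(expr.feature_ids.isin(sets[name])) for name in sets.names()}
    for name, m in in_sets.items():
        if m.sum() < 2:
            raise ValueError(f"gene set {name!r}: fewer than 2 members present")
    es_obs = {name: _es_from_metric(metric, m, weight) for name, m in in_sets.items()}

    n = len(labels)
    if exhaustive:
        perm_masks = []
        for idx in combinations(range(n), n1):
            pm = np.zeros(n, dtype=bool)
            pm[list(idx)] = True
            perm_masks.append(pm)
    else:
        rng = np.random.default_rng(seed)
        perm_masks = []
        base = mask1.copy()
        for _ in range(n_perm):
            perm_masks.append(rng.permutation(base))

    null_es = {name: np.empty(len(perm_masks)) for name in in_sets}
    for i, pm in enumerate(perm_masks):
        pmetric = _signal_to_noise(X, pm)
        for name, m in in_sets.items():
            null_es[name][i] = _es_from_metric(pmetric, m, weight)

    rows = {}
    nes_null_pool: list[np.ndarray] = []
    for name in in_sets:
        es = es_obs[name]
        null = null_es[name]
        same = null >= 0 if es >= 0 else null < 0
        if same.any():
            p = float(np.mean(np.abs(null[same]) >= abs(es)))
            mean_abs = float(np.abs(null[same]).mean())
            nes = es / mean_abs if mean_abs > 0 else np.nan
        else:
            p, nes = 1.0, np.nan
        # normalize the null the same way for the FDR pool
        pos, neg = null[null >= 0], null[null < 0]
        nn = np.concatenate(
            [
                pos / pos.mean() if len(pos) and pos.mean() > 0 else pos * 0,
                neg / np.abs(neg).mean() if len(neg) else neg,
            ]
        )
        nes_null_pool.append(nn)
        rows[name] = {"es": es, "nes": nes, "p": p}

    pool = np.concatenate(nes_null_pool) if nes_null_pool else np.array([])
    nes_obs = np.array([rows[name]["nes"] for name in rows], dtype=float)
    for name in rows:
        nes = rows[name]["nes"]
        if not np.isfinite(nes):
            rows[name]["q"] = np.nan
            continue
        if nes >= 0:
            num_pool = pool[pool >= 0]
            frac_null = np.mean(num_pool >= nes) if len(num_pool) else 0.0
            obs = nes_obs[np.isfinite(nes_obs) & (nes_obs >= 0)]
            frac_obs = np.mean(obs >= nes) if len(obs) else 1.0
        else:
            num_pool = pool[pool < 0]
            frac_null = np.mean(num_pool <= nes) if len(num_pool) else 0.0
            obs = nes_obs[np.isfinite(nes_obs) & (nes_obs < 0)]
            frac_obs = np.mean(obs <= nes) if len(obs) else 1.0
        rows[name]["q"] = float(min(1.0, frac_null / max(frac_obs, 1e-300)))

    table = pd.DataFrame(rows).T
    table["direction"] = np.where(table["nes"] > 0, "activated", "suppressed")
    return GseaResult(table=table)


# ---------------------------------------------------------------------------
# over-representation


def ora_hypergeometric(query, gene_set, universe) -> float:
    """Upper-tail hypergeometric p-value of the query / set overlap."""
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    q = set(query) & uni
    s = set(gene_set) & uni
    if set(query) - uni or set(gene_set) - uni:
        raise ValueError("query and gene set must be subsets of the universe")
    k = len(q & s)
    return float(stats.hypergeom.sf(k - 1, len(uni), len(s), len(q)))


def ora_collection(query, sets: GeneSetCollection, universe) -> pd.DataFrame:
    """ORA across a collection with Benjamini-Hochberg adjustment."""
    names = sets.names()
    pvals = [ora_hypergeometric(query, sets[n], universe) for n in names]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    uni = set(universe)
    qset = set(query) & uni
    return pd.DataFrame(
        {
            "overlap": [len(qset & set(sets[n])) for n in names],
            "set_size": [len(set(sets[n]) & uni) for n in names],
            "p": pvals,
            "q": qvals,
        },
        index=names,
    )
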