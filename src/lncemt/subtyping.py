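"""EMT-lncRNA screening, bootstrap consensus clustering and group tests.

The screen correlates each lncRNA with the per-sample EMT score and keeps
features with |Pearson r| > r_thresh and p < p_thresh; the dual-cohort
intersection keeps lncRNAs that pass in every cohort with a consistent
correlation sign. Consensus clustering repeatedly k-means-clusters random
80% subsamples and summarizes co-clustering frequencies in a consensus
matrix; k is chosen by minimizing the PAC (proportion of ambiguous
clustering: consensus-CDF mass between 0.1 and 0.9).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .containers import ClinicalTable, ExpressionMatrix, RunConfig
from .survival import km_curve, restricted_mean_survival

logger = logging.getLogger("lncemt")


@dataclass
class ScreenResult:
    """Per-lncRNA Pearson correlation with the EMT score plus pass flags."""

    table: pd.DataFrame  # index lncRNA; columns r, p, pass, sign
    r_thresh: float
    p_thresh: float

    def passing(self) -> pd.DataFrame:
        return self.table.loc[self.table["pass"]]


def pearson_with_p(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each row of Y with x, with two-sided t-distribution p.

    Rows with zero variance get r = NaN, p = NaN.
    """
    n = len(x)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yc @ xc) / (sy * sx)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    bad = sy == 0
    r[bad] = np.nan
    p[bad] = np.nan
    return r, p


def emt_correlation_screen(
    lnc_expr: ExpressionMatrix,
    emt_score: pd.Series,
    r_thresh: float = 0.25,
    p_thresh: float = 0.05,
) -> ScreenResult:
    """Screen lncRNAs by Pearson correlation with the EMT score.

    Zero-variance lncRNAs are flagged undefined (r = NaN) and fail the
    screen rather than raising.
    """
    if lnc_expr.n_samples < 3:
        raise ValueError("screen needs at least 3 samples")
    if set(lnc_expr.sample_ids) != set(emt_score.index):
        raise ValueError("sample ids of expression and EMT score do not match")
    score = emt_score.reindex(lnc_expr.sample_ids).to_numpy(dtype=float)
    r, p = pearson_with_p(score, lnc_expr.values.to_numpy())
    ok = np.isfinite(r)
    passed = ok & (np.abs(r) > r_thresh) & (p < p_thresh)
    table = pd.DataFrame(
        {
            "r": r,
            "p": p,
            "pass": passed,
            "sign": np.sign(np.nan_to_num(r)).astype(int),
        },
        index=lnc_expr.feature_ids,
    )
    return ScreenResult(table=table, r_thresh=r_thresh, p_thresh=p_thresh)


def intersect_screens(results: list[ScreenResult], require_sign: bool = True) -> list[str]:
    """lncRNAs passing in every cohort (with consistent sign by default)."""
    if not results:
        raise ValueError("no screen results")
    common = None
    for res in results:
        ids = set(res.passing().index)
        common = ids if common is None else common & ids
    out = []
    for lnc in results[0].table.index:
        if lnc not in common:
            continue
        if require_sign:
            signs = {int(res.table.loc[lnc, "sign"]) for res in results}
            if len(signs) > 1:
                continue
        out.append(lnc)
    if not out:
        logger.warning("cross-cohort screen intersection is empty")
    return out


@dataclass
class ConsensusResult:
    """Per-k consensus matrices/CDF/PAC, the chosen k and final labels."""

    consensus: dict[int, pd.DataFrame]
    pac: pd.Series  # indexed by k
    chosen_k: int
    labels: pd.Series  # cluster index 1..k per sample

    def cdf(self, k: int, grid: np.ndarray | None = None):
        """Empirical CDF of the upper-triangle consensus entries at k."""
        m = self.consensus[k].to_numpy()
        iu = np.triu_indices_from(m, k=1)
        vals = np.sort(m[iu])
        grid = np.linspace(0, 1, 101) if grid is None else grid
        return grid, np.searchsorted(vals, grid, side="right") / len(vals)


def _pac(m: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    iu = np.triu_indices_from(m, k=1)
    v = m[iu]
    return float(np.mean(v <= upper) - np.mean(v <= lower))


def consensus_cluster(
    X: pd.DataFrame,
    cfg: RunConfig | None = None,
    seed: int | None = None,
    k_min: int | None = None,
    k_max: int | None = None,
    n_boot: int | None = None,
    subsample: float | None = None,
    n_init: int = 10,
) -> ConsensusResult:
    """Bootstrap consensus k-means over k in [k_min, k_max].

    ``X`` is samples x features. Each of ``n_boot`` iterations draws
    ``ceil(subsample * n)`` samples without replacement and clusters them
    with Euclidean k-means (k-means++ with ``n_init`` restarts, seeded
    deterministically per (k, bootstrap)). The consensus entry for a sample
    pair is (# co-clustered) / (# co-sampled); pairs never co-sampled are
    set to 0 with a logged count. Final labels come from average-linkage
    hierarchical clustering of 1 - consensus at the PAC-minimizing k
    (ties broken toward smaller k).
    """
    cfg = cfg or RunConfig()
    seed = cfg.seed if seed is None else seed
    k_min = cfg.k_min if k_min is None else k_min
    k_max = cfg.k_max if k_max is None else k_max
    n_boot = cfg.n_boot if n_boot is None else n_boot
    subsample = cfg.subsample if subsample is None else subsample
    if n_boot < 50:
        logger.warning("n_boot=%d is small; consensus entries will be noisy", n_boot)
    n = X.shape[0]
    if n <= k_max:
        raise ValueError("need more samples than k_max")
    m_sub = int(np.ceil(subsample * n))
    data = X.to_numpy(dtype=float)

    consensus: dict[int, pd.DataFrame] = {}
    pac: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        co = np.zeros((n, n))
        both = np.zeros((n, n))
        for b in range(n_boot):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(k, b))
            rng = np.random.default_rng(ss)
            idx = rng.choice(n, size=m_sub, replace=False)
            km_seed = int(rng.integers(0, 2**31 - 1))
            lab = KMeans(
                n_clusters=k, n_init=n_init, random_state=km_seed
            ).fit_predict(data[idx])
            same = lab[:, None] == lab[None, :]
            co[np.ix_(idx, idx)] += same
            both[np.ix_(idx, idx)] += 1
        never = (both == 0) & ~np.eye(n, dtype=bool)
        if never.any():
            logger.warning(
                "k=%d: %d sample pairs never co-sampled; consensus set to 0",
                k,
                int(never.sum()) // 2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(both > 0, co / np.maximum(both, 1), 0.0)
        np.fill_diagonal(m, 1.0)
        m = (m + m.T) / 2.0
        consensus[k] = pd.DataFrame(m, index=X.index, columns=X.index)
        pac[k] = _pac(m)

    pac_s = pd.Series(pac).sort_index()
    chosen_k = int(pac_s.index[np.argmin(pac_s.to_numpy())])  # ties -> smallest k
    d = 1.0 - consensus[chosen_k].to_numpy()
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    labels = pd.Series(fcluster(z, t=chosen_k, criterion="maxclust"), index=X.index)
    return ConsensusResult(consensus=consensus, pac=pac_s, chosen_k=chosen_k, labels=labels)


def label_subtypes(labels: pd.Series, clinical: ClinicalTable) -> pd.Series:
    """Rename clusters C1..Ck so C1 has the best overall survival.

    Ordering uses the Kaplan-Meier median when every cluster reaches it,
    otherwise the restricted mean survival time; exact ties are broken by
    cluster size (larger cluster first) with a log message.
    """
    clin = clinical.table.loc[labels.index]
    clusters = sorted(labels.unique())
    stats_rows = []
    medians = {}
    for c in clusters:
        mask = labels == c
        curve = km_curve(
            clin.loc[mask.to_numpy(), "os_time"].to_numpy(),
            clin.loc[mask.to_numpy(), "os_event"].to_numpy(),
        )
        medians[c] = curve.median()
        stats_rows.append(
            (
                c,
                restricted_mean_survival(curve, clin["os_time"].max()),
                int(mask.sum()),
            )
        )
    use_median = all(np.isfinite(medians[c]) for c in clusters)
    order_stat = {
        c: (medians[c] if use_median else rm) for (c, rm, _) in stats_rows
    }
    sizes = {c: sz for (c, _, sz) in stats_rows}
    if len({round(order_stat[c], 12) for c in clusters}) < len(clusters):
        logger.info("survival tie between clusters; breaking by cluster size")
    ordered = sorted(clusters, key=lambda c: (-order_stat[c], -sizes[c], c))
    mapping = {c: f"C{i + 1}" for i, c in enumerate(ordered)}
    return labels.map(mapping).rename("subtype")


@dataclass
class GroupComparison:
    """Per-feature two-group test results with BH adjustment."""

    table: pd.DataFrame  # statistic, p, q, mean/median per group
    test: str


def compare_groups(values: pd.DataFrame, labels: pd.Series, test: str) -> GroupComparison:
    """Two-group feature-wise tests: wilcoxon, student_t (Welch) or fisher.

    ``values`` is features x samples (binary for fisher); ``labels`` a
    two-level grouping aligned to the samples.
    """
    labels = labels.reindex(values.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g0 = labels == groups[0]
    g1 = labels == groups[1]
    min_n = 1 if test == "fisher" else 2
    if g0.sum() < min_n or g1.sum() < min_n:
        raise ValueError("a group has too few observations")
    A = values.loc[:, g0.to_numpy()].to_numpy()
    B = values.loc[:, g1.to_numpy()].to_numpy()
    rows = []
    for i in range(values.shape[0]):
        a, b = A[i], B[i]
        if test == "wilcoxon":
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
            stat, p = float(res.statistic), float(res.pvalue)
        elif test == "student_t":
            res = stats.ttest_ind(a, b, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
        elif test == "fisher":
            table = [
                [int(a.sum()), int(len(a) - a.sum())],
                [int(b.sum()), int(len(b) - b.sum())],
            ]
            stat, p = stats.fisher_exact(table, alternative="two-sided")
            stat, p = float(stat), float(p)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "statistic": stat,
                "p": p,
                f"mean_{groups[0]}": float(np.mean(a)),
                f"mean_{groups[1]}": float(np.mean(b)),
                f"median_{groups[0]}": float(np.median(a)),
                f"median_{groups[1]}": float(np.median(b)),
            }
        )
    table = pd.DataFrame(rows, index=values.index)
    _, q, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table["q"] = q
    return GroupComparison(table=table, test=test)
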