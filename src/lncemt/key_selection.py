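"""First-order partial-correlation screening for key (mediator) lncRNAs.

For every candidate lncRNA z the unadjusted correlations r(EMT score, EMT
gene) over all EMT genes are compared with the first-order partial
correlations pcor(score, gene | z); a candidate whose conditioning makes
the absolute correlations stochastically smaller (one-sided two-sample
Kolmogorov-Smirnov test) with a material median drop is flagged *key* —
it carries the statistical signal linking the EMT genes to the EMT score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .subtyping import pearson_with_p

logger = logging.getLogger("lncemt")


def partial_correlation(r_xy, r_xz, r_yz):
    """First-order partial correlation of x and y given z.

    pcor = (r_xy - r_xz*r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2)); inputs may
    be scalars or arrays. Degenerate conditioning (|r_xz| = 1 or
    |r_yz| = 1) raises.
    """
    r_xy = np.asarray(r_xy, dtype=float)
    r_xz = np.asarray(r_xz, dtype=float)
    r_yz = np.asarray(r_yz, dtype=float)
    for name, r in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if (np.abs(r) > 1 + 1e-12).any():
            raise ValueError(f"{name} outside [-1, 1]")
    if (np.abs(r_xz) >= 1 - 1e-15).any() or (np.abs(r_yz) >= 1 - 1e-15).any():
        raise ValueError("degenerate conditioning: |r| = 1 with the conditioner")
    out = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    return float(out) if out.ndim == 0 else out


def ks_two_sample(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    ``alternative="greater"`` tests that the empirical CDF of ``a`` lies
    above that of ``b`` (i.e. values of ``a`` are stochastically smaller).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 values")
    res = stats.ks_2samp(a, b, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass
class PartialCorResult:
    """Per-candidate adjusted/unadjusted correlation summary."""

    table: pd.DataFrame  # index candidate; D, p, median_drop, key — by D desc
    unadjusted: pd.Series  # |r(score, gene)| per EMT gene
    adjusted: pd.DataFrame  # candidate x gene |pcor|

    def key_lncrnas(self) -> list[str]:
        return list(self.table.index[self.table["key"]])


def select_key_lncrnas(
    emt_score: pd.Series,
    emt_gene_expr: ExpressionMatrix,
    candidates: ExpressionMatrix,
    p_thresh: float = 0.05,
    drop_thresh: float = 0.1,
    signed: bool = False,
) -> PartialCorResult:
    """Rank candidate lncRNAs by how much conditioning on them attenuates
    the EMT-score / EMT-gene correlations.

    Absolute coefficients enter the CDFs by default (``signed=False``);
    candidates constant across samples are skipped with a warning. The key
    flag requires one-sided KS p < ``p_thresh`` AND a median |coefficient|
    drop > ``drop_thresh``; candidates are returned ranked by the KS
    statistic D.
    """
    samples = [s for s in emt_score.index if s in emt_gene_expr.sample_ids]
    samples = [s for s in samples if s in candidates.sample_ids]
    if len(samples) < 10:
        raise ValueError("need >= 10 shared samples")
    if emt_gene_expr.n_features < 5:
        raise ValueError("need >= 5 EMT genes")
    score = emt_score.loc[samples].to_numpy(dtype=float)
    G = emt_gene_expr.values[samples].to_numpy()
    genes = emt_gene_expr.feature_ids

    r_sx, _ = pearson_with_p(score, G)
    if np.isnan(r_sx).any():
        keep = ~np.isnan(r_sx)
        logger.warning("%d constant EMT genes dropped", int((~keep).sum()))
        G, genes, r_sx = G[keep], genes[keep], r_sx[keep]
    unadj = r_sx if signed else np.abs(r_sx)

    rows, adj_rows, adj_index = [], [], []
    for lnc in candidates.feature_ids:
        zvec = candidates.values.loc[lnc, samples].to_numpy(dtype=float)
        if np.std(zvec) == 0:
            logger.warning("candidate %s constant across samples; skipped", lnc)
            continue
        r_sz = float(pearson_with_p(score, zvec[None, :])[0][0])
        r_xz, _ = pearson_with_p(zvec, G)
        pcor = partial_correlation(r_sx, np.full_like(r_xz, r_sz), r_xz)
        adj = pcor if signed else np.abs(pcor)
        d, p = ks_two_sample(adj, unadj, alternative="greater")
        drop = float(np.median(unadj) - np.median(adj))
        rows.append(
            {
                "candidate": lnc,
                "D": d,
                "p": p,
                "median_unadjusted": float(np.median(unadj)),
                "median_adjusted": float(np.median(adj)),
                "median_drop": drop,
                "r_score_candidate": r_sz,
                "key": (p < p_thresh) and (drop > drop_thresh),
            }
        )
        adj_rows.append(adj)
        adj_index.append(lnc)
    if not rows:
        raise ValueError("no usable candidates")
    table = (
        pd.DataFrame(rows)
        .set_index("candidate")
        .sort_values("D", ascending=False, kind="stable")
    )
    return PartialCorResult(
        table=table,
        unadjusted=pd.Series(unadj, index=genes, name="unadjusted"),
        adjusted=pd.DataFrame(adj_rows, index=adj_index, columns=genes),
    )
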