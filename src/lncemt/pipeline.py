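"""End-to-end orchestration of the subtyping analysis across cohorts.

``run_all`` chains the stages the way the study design intends: per-cohort
EMT ssGSEA scoring, the |r| > 0.25 / p < 0.05 lncRNA screen with
sign-consistent cross-cohort intersection, bootstrap consensus subtyping
with survival-ordered C1/C2 naming, tumor-microenvironment
characterization, regulon TF activity with cross-cohort consensus of
differential TFs, lncRNA-TF linkage, first-order partial-correlation key
selection, and the univariate-Cox risk score with a Kaplan-Meier /
log-rank readout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as lio
from .containers import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    RegulonTable,
    RunConfig,
)
from .enrichment import (
    SsgseaParams,
    estimate_scores,
    gsea_two_group,
    immune_infiltration,
    ssgsea_score,
)
from .key_selection import select_key_lncrnas
from .subtyping import (
    compare_groups,
    consensus_cluster,
    emt_correlation_screen,
    intersect_screens,
    label_subtypes,
)
from .survival import fit_risk_features, logrank_test, risk_model
from .tf_regulation import (
    consensus_differential_tfs,
    differential_tf,
    lncrna_tf_correlation,
    tf_activity,
)

logger = logging.getLogger("lncemt")

EMT_SET_NAME = "HALLMARK_EMT"


@dataclass
class Cohort:
    name: str
    expr: ExpressionMatrix
    clinical: ClinicalTable


@dataclass
class CohortResult:
    emt_score: pd.Series
    screen: object
    subtype: pd.Series
    consensus: object
    subtype_logrank: tuple[float, float]
    emt_score_comparison: object
    immune_scores: pd.DataFrame | None
    estimate: pd.DataFrame | None
    gsea: object | None
    tf_activity: pd.DataFrame | None
    differential_tf: pd.DataFrame | None
    key_result: object | None
    risk: object | None
    risk_logrank: tuple[float, float] | None


@dataclass
class RunAllResult:
    cohorts: dict[str, CohortResult]
    intersected_lncrnas: list[str]
    consensus_tfs: list[str] | None
    key_lncrnas: list[str]


def run_all(
    cohorts: list[Cohort],
    gene_sets: GeneSetCollection,
    config: RunConfig | None = None,
    regulons: RegulonTable | None = None,
    emt_set_name: str = EMT_SET_NAME,
    immune_signatures: GeneSetCollection | None = None,
    stromal_set_name: str | None = None,
    immune_set_name: str | None = None,
    gsea_sets: GeneSetCollection | None = None,
    n_perm: int = 200,
    n_risk_features: int = 5,
) -> RunAllResult:
    """Run the full analysis on one or more cohorts sharing a design.

    The screen intersection, consensus differential TFs and key-lncRNA
    intersection pool across cohorts; everything else is per cohort.
    When no candidate is flagged key, the risk model falls back to the
    top ``n_risk_features`` candidates by KS D (logged).
    """
    config = config or RunConfig()
    params = SsgseaParams(alpha=config.ssgsea_alpha)

    # stage 1-2: EMT score + screen per cohort
    scores, screens = {}, {}
    for c in cohorts:
        scores[c.name] = ssgsea_score(c.expr, gene_sets[emt_set_name], params)
        lnc = c.expr.subset_biotype("lncRNA")
        screens[c.name] = emt_correlation_screen(
            lnc, scores[c.name], config.r_thresh, config.p_thresh
        )
    intersected = intersect_screens([screens[c.name] for c in cohorts])
    if not intersected:
        raise RuntimeError("no lncRNA passes the screen in every cohort")

    results: dict[str, CohortResult] = {}
    diff_tables, key_sets = [], []
    for c in cohorts:
        feat = c.expr.values.loc[intersected]
        feat = feat.sub(feat.mean(axis=1), axis=0).div(
            feat.std(axis=1, ddof=0).replace(0.0, 1.0), axis=0
        )
        cons = consensus_cluster(feat.T, cfg=config)
        subtype = label_subtypes(cons.labels, c.clinical)
        clin = c.clinical.table.loc[subtype.index]
        lr = logrank_test(
            clin["os_time"].to_numpy(), clin["os_event"].to_numpy(), subtype.to_numpy()
        )
        emt_cmp = compare_groups(
            scores[c.name].to_frame("emt_score").T, subtype, test="wilcoxon"
        )

        immune = est = gsea = None
        if immune_signatures is not None:
            immune = immune_infiltration(c.expr, immune_signatures, params)
        if stromal_set_name and immune_set_name:
            est = estimate_scores(
                c.expr, gene_sets[stromal_set_name], gene_sets[immune_set_name], params
            )
        if gsea_sets is not None:
            labels01 = (subtype == "C2").astype(int)
            gsea = gsea_two_group(
                c.expr, labels01, gsea_sets, n_perm=n_perm, seed=config.seed
            )

        act = dtf = keyres = None
        candidates = intersected
        if regulons is not None:
            act = tf_activity(c.expr, regulons)
            dtf = differential_tf(act, subtype)
            diff_tables.append(dtf)
            sig_dtf = dtf.loc[dtf["q"] < config.fdr_thresh]
            if len(sig_dtf):
                link = lncrna_tf_correlation(
                    c.expr.subset_features(intersected),
                    act.loc[sig_dtf.index],
                    fdr_thresh=config.fdr_thresh,
                )
                if link.linked_lncrnas:
                    candidates = link.linked_lncrnas

        emt_genes = [g for g in gene_sets[emt_set_name] if g in c.expr.feature_ids]
        keyres = select_key_lncrnas(
            scores[c.name],
            c.expr.subset_features(emt_genes),
            c.expr.subset_features(candidates),
            p_thresh=config.p_thresh,
        )
        key_sets.append(set(keyres.key_lncrnas()))

        results[c.name] = CohortResult(
            emt_score=scores[c.name],
            screen=screens[c.name],
            subtype=subtype,
            consensus=cons,
            subtype_logrank=lr,
            emt_score_comparison=emt_cmp,
            immune_scores=immune,
            estimate=est,
            gsea=gsea,
            tf_activity=act,
            differential_tf=dtf,
            key_result=keyres,
            risk=None,
            risk_logrank=None,
        )

    consensus_tfs = (
        consensus_differential_tfs(diff_tables, config.fdr_thresh)
        if diff_tables
        else None
    )
    keys = sorted(set.intersection(*key_sets)) if key_sets else []
    if not keys:
        # fall back to the candidates most attenuating in the first cohort
        first = results[cohorts[0].name].key_result
        keys = list(first.table.index[: min(n_risk_features, len(first.table))])
        logger.warning(
            "no lncRNA flagged key in every cohort; using top %d by KS D", len(keys)
        )

    for c in cohorts:
        fits = fit_risk_features(c.expr, c.clinical.subset(c.expr.sample_ids), keys)
        rm = risk_model(c.expr, fits)
        clin = c.clinical.table.loc[rm.groups.index]
        rlr = logrank_test(
            clin["os_time"].to_numpy(),
            clin["os_event"].to_numpy(),
            rm.groups.to_numpy(),
        )
        results[c.name].risk = rm
        results[c.name].risk_logrank = rlr

    return RunAllResult(
        cohorts=results,
        intersected_lncrnas=intersected,
        consensus_tfs=consensus_tfs,
        key_lncrnas=keys,
    )


def write_results(result: RunAllResult, config: RunConfig, out_dir) -> None:
    """Write the per-cohort result tables and a YAML run manifest."""
    out = lio.ensure_dir(out_dir)
    import os

    pd.Series(result.intersected_lncrnas, name="lncrna").to_csv(
        os.path.join(out, "intersected_lncrnas.tsv"), sep="\t", index=False
    )
    pd.Series(result.key_lncrnas, name="lncrna").to_csv(
        os.path.join(out, "key_lncrnas.tsv"), sep="\t", index=False
    )
    if result.consensus_tfs is not None:
        pd.Series(result.consensus_tfs, name="tf").to_csv(
            os.path.join(out, "consensus_differential_tfs.tsv"), sep="\t", index=False
        )
    stages = ["score", "screen", "cluster", "characterize", "tf", "select-key", "risk"]
    for name, res in result.cohorts.items():
        pre = os.path.join(out, name)
        lio.ensure_dir(pre)
        res.emt_score.rename("emt_score").to_csv(
            os.path.join(pre, "emt_score.tsv"), sep="\t"
        )
        res.screen.table.to_csv(os.path.join(pre, "screen.tsv"), sep="\t")
        res.subtype.to_csv(os.path.join(pre, "subtype.tsv"), sep="\t")
        res.consensus.pac.rename("pac").to_csv(os.path.join(pre, "pac.tsv"), sep="\t")
        pd.DataFrame(
            {
                "stat": [res.subtype_logrank[0]],
                "p": [res.subtype_logrank[1]],
            },
            index=["subtype_logrank"],
        ).to_csv(os.path.join(pre, "subtype_logrank.tsv"), sep="\t")
        if res.immune_scores is not None:
            res.immune_scores.to_csv(os.path.join(pre, "immune_scores.tsv"), sep="\t")
        if res.estimate is not None:
            res.estimate.to_csv(os.path.join(pre, "estimate_scores.tsv"), sep="\t")
        if res.gsea is not None:
            res.gsea.table.to_csv(os.path.join(pre, "gsea.tsv"), sep="\t")
        if res.differential_tf is not None:
            res.differential_tf.to_csv(os.path.join(pre, "differential_tf.tsv"), sep="\t")
        if res.key_result is not None:
            res.key_result.table.to_csv(os.path.join(pre, "key_selection.tsv"), sep="\t")
        if res.risk is not None:
            pd.DataFrame(
                {"score": res.risk.scores, "group": res.risk.groups}
            ).to_csv(os.path.join(pre, "risk.tsv"), sep="\t")
            pd.DataFrame(
                {"stat": [res.risk_logrank[0]], "p": [res.risk_logrank[1]]},
                index=["risk_logrank"],
            ).to_csv(os.path.join(pre, "risk_logrank.tsv"), sep="\t")
    lio.write_manifest(os.path.join(out, "manifest.yaml"), config, stages)
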