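"""Synthetic two-cohort generator with planted ground truth.

The generative model mirrors the statistical structure the pipeline assumes:

* a latent EMT axis ``e_s`` per sample, shifted between two subtypes and
  driven by a small block of co-regulated *mediator* latents;
* EMT genes loading on the axis; lncRNAs with graded correlation to it
  (``key`` mediators that drive the axis, ``assoc`` passengers correlated
  with it, and pure-noise ``null`` lncRNAs);
* subtype-structured immune-cell signatures and stromal/immune signatures;
* signed TF regulons with subtype-differential planted activity;
* exponential overall survival with hazard increasing in the EMT axis,
  censored by an independent uniform time calibrated to a target fraction.

Mediator latents share a common factor (loading ``sqrt(mediator_rho)``), so
each individual key lncRNA carries a strong signature of the whole axis —
the property the first-order partial-correlation stage detects. Fixing the
seed fixes every output byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    RegulonTable,
)

EMT_SET_NAME = "HALLMARK_EMT"
STROMAL_SET_NAME = "stromal_signature"
IMMUNE_SET_NAME = "immune_signature"


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    The latent axis is ``e = emt_shift*z + mediator_weight*B + eps`` with
    ``z ~ Bernoulli(subtype_fraction)`` the subtype, ``B`` the co-regulated,
    subtype-shifted mediator block (unit conditional variance) and
    ``eps ~ N(0, resid_sd^2)``; ``e`` is then standardized. Loadings ``loading_key``/``loading_assoc`` are linear
    coefficients of lncRNAs on their latent (mediator / axis), with additive
    ``N(0, noise_sd^2)`` noise, so e.g. corr(key lncRNA, its mediator) =
    b_key / sqrt(b_key^2 + noise_sd^2).
    """

    n_samples: int = 200
    n_emt_genes: int = 100
    n_key: int = 5
    n_assoc: int = 100
    n_null: int = 400
    n_background_pcg: int = 200
    subtype_fraction: float = 0.5
    emt_shift: float = 1.5  # subtype mean difference on the raw axis
    loading_key: float = 0.9
    loading_assoc: float = 0.4
    gene_loading: float = 1.0
    noise_sd: float = 1.0
    mediator_rho: float = 0.95  # shared-factor loading^2 across mediators
    mediator_weight: float = 1.5  # weight of the mediator block in the axis
    mediator_subtype_shift: float = 1.0  # subtype shift of each mediator latent
    resid_sd: float = 0.2  # axis residual SD
    # immune / stromal structure
    n_immune_signatures: int = 6
    immune_sig_size: int = 10
    immune_shift: float = 1.0  # subtype shift of immune activities (SD units)
    # regulons
    n_tf: int = 20
    targets_per_tf: int = 10
    n_diff_tf: int = 7
    tf_activity_shift: float = 2.0
    repressed_fraction: float = 0.3
    # survival
    hazard_baseline: float = 1.0 / 1000.0  # events per day at e = 0
    beta_surv: float = 0.7  # log-hazard per SD of the EMT axis
    censor_fraction: float = 0.3
    # mutations
    n_mut_genes: int = 20
    n_enriched_mut: int = 5
    mut_rate_enriched: float = 0.4
    mut_rate_base: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.subtype_fraction < 1):
            raise ValueError("subtype_fraction must lie in (0, 1)")
        if abs(self.loading_key) <= abs(self.loading_assoc) and self.n_key > 0:
            raise ValueError("|loading_key| must exceed |loading_assoc|")
        if not (0 <= self.censor_fraction < 1):
            raise ValueError("censor_fraction must lie in [0, 1)")
        if min(self.n_key, self.n_assoc, self.n_null) < 0:
            raise ValueError("lncRNA counts must be non-negative")
        if self.n_key + self.n_assoc + self.n_null == 0:
            raise ValueError("at least one lncRNA required")
        if not (0 <= self.mediator_rho < 1):
            raise ValueError("mediator_rho must lie in [0, 1)")

    @property
    def n_lncrna(self) -> int:
        return self.n_key + self.n_assoc + self.n_null


@dataclass
class GroundTruth:
    """Planted truth for parameter-recovery tests."""

    subtype: pd.Series  # 0/1 per sample (1 = high-EMT subtype)
    latent: pd.Series  # standardized EMT axis e_s
    lnc_class: pd.Series  # key / assoc / null per lncRNA
    mediators: pd.DataFrame  # mediator latents (n_key x samples)
    tf_differential: pd.Series | None = None  # bool per TF
    tf_activity: pd.DataFrame | None = None  # planted activities
    mutation_enriched: pd.Series | None = None


@dataclass
class RegulonSim:
    regulons: RegulonTable
    expression: pd.DataFrame  # target genes x samples
    activity: pd.DataFrame  # TF x samples planted activities
    differential: pd.Series  # bool per TF


def _mediator_block(cfg: SimConfig, z: np.ndarray, rng: np.random.Generator):
    """Co-regulated, subtype-shifted mediator latents and the block score.

    Conditional on subtype, each mediator is standard normal with a shared
    factor (loading sqrt(mediator_rho)); the high-EMT subtype shifts every
    mediator mean by ``mediator_subtype_shift`` — prognostic key lncRNAs
    must themselves differ between subtypes. The block is normalized by the
    SD of its subtype-conditional distribution.
    """
    n, k = cfg.n_samples, cfg.n_key
    if k == 0:
        return np.zeros((0, n)), np.zeros(n)
    shared = rng.normal(size=n)
    uniq = rng.normal(size=(k, n))
    m = (
        cfg.mediator_subtype_shift * z
        + np.sqrt(cfg.mediator_rho) * shared
        + np.sqrt(1 - cfg.mediator_rho) * uniq
    )
    block_var = k + k * (k - 1) * cfg.mediator_rho
    block = m.sum(axis=0) / np.sqrt(block_var)
    return m, block


def _censor_horizon(rates: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting the target fraction.

    For T ~ Exp(rate) and C ~ U(0, c), P(censored) = (1 - exp(-rate*c)) /
    (rate*c); the cohort-average of this is matched to ``target`` by root
    finding (monotone decreasing in c).
    """

    def frac(c: float) -> float:
        x = rates * c
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1.0
    while frac(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("censoring horizon search failed")
    return optimize.brentq(lambda c: frac(c) - target, lo, hi)


def simulate_regulons(
    cfg: SimConfig, subtype: np.ndarray | None = None, rng: np.random.Generator | None = None
) -> RegulonSim:
    """Simulate signed regulons with planted subtype-differential activity.

    Each TF receives ``targets_per_tf`` target genes (a ``repressed_fraction``
    of them with mode -1); target expression is ``mode * activity_s`` plus
    noise. The first ``n_diff_tf`` TFs get their activity shifted by
    ``tf_activity_shift`` in subtype 1.
    """
    if cfg.targets_per_tf < 2:
        raise ValueError("each regulon needs at least 2 targets")
    rng = np.random.default_rng(cfg.seed + 1_000_003) if rng is None else rng
    n = cfg.n_samples
    if subtype is None:
        subtype = rng.binomial(1, cfg.subtype_fraction, size=n)
    samples = [f"S{i:04d}" for i in range(n)]
    tf_ids = [f"TF{t:02d}" for t in range(cfg.n_tf)]
    diff = pd.Series(
        [t < cfg.n_diff_tf for t in range(cfg.n_tf)], index=tf_ids, name="differential"
    )
    rows, expr_rows, expr_index = [], [], []
    activity = np.empty((cfg.n_tf, n))
    for t, tf in enumerate(tf_ids):
        act = rng.normal(size=n)
        if diff[tf]:
            act = act + cfg.tf_activity_shift * subtype
        activity[t] = act
        n_rep = int(round(cfg.repressed_fraction * cfg.targets_per_tf))
        modes = np.array([1] * (cfg.targets_per_tf - n_rep) + [-1] * n_rep)
        for j, mode in enumerate(modes):
            gene = f"{tf}_T{j:02d}"
            rows.append((tf, gene, int(mode)))
            expr_index.append(gene)
            expr_rows.append(mode * act + rng.normal(0, cfg.noise_sd, size=n))
    reg = RegulonTable(pd.DataFrame(rows, columns=["tf", "target", "mode"]))
    expression = pd.DataFrame(expr_rows, index=expr_index, columns=samples)
    return RegulonSim(
        regulons=reg,
        expression=expression,
        activity=pd.DataFrame(activity, index=tf_ids, columns=samples),
        differential=diff,
    )


def simulate_mutations(
    cfg: SimConfig, subtype: np.ndarray | None = None, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Binary gene x sample mutation matrix with subtype-enriched genes.

    Enriched genes mutate at ``mut_rate_enriched`` in subtype 1 and
    ``mut_rate_base`` in subtype 0; the rest at ``mut_rate_base`` everywhere.
    Returns the matrix and a boolean per-gene enrichment flag.
    """
    rng = np.random.default_rng(cfg.seed + 2_000_003) if rng is None else rng
    n = cfg.n_samples
    if subtype is None:
        subtype = rng.binomial(1, cfg.subtype_fraction, size=n)
    samples = [f"S{i:04d}" for i in range(n)]
    genes = [f"MUT{g:02d}" for g in range(cfg.n_mut_genes)]
    enriched = pd.Series(
        [g < cfg.n_enriched_mut for g in range(cfg.n_mut_genes)],
        index=genes,
        name="enriched",
    )
    rates = np.full((cfg.n_mut_genes, n), cfg.mut_rate_base)
    rates[enriched.to_numpy()] = np.where(
        subtype == 1, cfg.mut_rate_enriched, cfg.mut_rate_base
    )
    mat = (rng.random((cfg.n_mut_genes, n)) < rates).astype(int)
    return pd.DataFrame(mat, index=genes, columns=samples), enriched


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, GeneSetCollection, GroundTruth]:
    """Simulate one cohort under the generative model.

    Returns the log-scale expression matrix (EMT genes, background
    protein-coding genes, immune-signature genes, TF-regulon targets and
    lncRNAs), a clinical table with exponential survival, the gene-set
    collection (the EMT set contains exactly the EMT gene ids, plus
    immune-cell and stromal/immune signatures) and the planted ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    z = rng.binomial(1, cfg.subtype_fraction, size=n)
    m, block = _mediator_block(cfg, z, rng)
    e_raw = cfg.emt_shift * z + cfg.mediator_weight * block + rng.normal(
        0, cfg.resid_sd, size=n
    )
    e = (e_raw - e_raw.mean()) / e_raw.std()

    index: list[str] = []
    blocks: list[np.ndarray] = []
    biotype: list[str] = []
    sets: dict[str, list[str]] = {}

    emt_genes = [f"EMTG{g:03d}" for g in range(cfg.n_emt_genes)]
    blocks.append(cfg.gene_loading * e + rng.normal(0, cfg.noise_sd, (cfg.n_emt_genes, n)))
    index += emt_genes
    biotype += ["protein_coding"] * cfg.n_emt_genes
    sets[EMT_SET_NAME] = emt_genes

    bg = [f"PCG{g:04d}" for g in range(cfg.n_background_pcg)]
    blocks.append(rng.normal(0, cfg.noise_sd, (cfg.n_background_pcg, n)))
    index += bg
    biotype += ["protein_coding"] * cfg.n_background_pcg

    # subtype-structured immune-cell signatures + stromal/immune signatures
    for name, tag in [
        *[(f"immune_cell_{c:02d}", f"IMM{c:02d}") for c in range(cfg.n_immune_signatures)],
        (STROMAL_SET_NAME, "STRO"),
        (IMMUNE_SET_NAME, "IMMS"),
    ]:
        act = cfg.immune_shift * z + rng.normal(size=n)
        genes = [f"{tag}_G{j:02d}" for j in range(cfg.immune_sig_size)]
        blocks.append(act + rng.normal(0, cfg.noise_sd, (cfg.immune_sig_size, n)))
        index += genes
        biotype += ["protein_coding"] * cfg.immune_sig_size
        sets[name] = genes

    regsim = None
    if cfg.n_tf > 0:
        regsim = simulate_regulons(cfg, subtype=z, rng=rng)
        blocks.append(regsim.expression.to_numpy())
        index += list(regsim.expression.index)
        biotype += ["protein_coding"] * regsim.expression.shape[0]

    lnc_ids, lnc_class = [], []
    key_ids = [f"LNC_KEY{j:02d}" for j in range(cfg.n_key)]
    if cfg.n_key:
        blocks.append(cfg.loading_key * m + rng.normal(0, cfg.noise_sd, (cfg.n_key, n)))
        lnc_ids += key_ids
        lnc_class += ["key"] * cfg.n_key
    if cfg.n_assoc:
        ids = [f"LNC_ASSOC{j:03d}" for j in range(cfg.n_assoc)]
        blocks.append(cfg.loading_assoc * e + rng.normal(0, cfg.noise_sd, (cfg.n_assoc, n)))
        lnc_ids += ids
        lnc_class += ["assoc"] * cfg.n_assoc
    if cfg.n_null:
        ids = [f"LNC_NULL{j:03d}" for j in range(cfg.n_null)]
        blocks.append(rng.normal(0, cfg.noise_sd, (cfg.n_null, n)))
        lnc_ids += ids
        lnc_class += ["null"] * cfg.n_null
    index += lnc_ids
    biotype += ["lncRNA"] * len(lnc_ids)

    values = pd.DataFrame(np.vstack(blocks), index=index, columns=samples)
    expr = ExpressionMatrix(values, pd.Series(biotype, index=index))

    # exponential survival, hazard increasing in the EMT axis
    rates = cfg.hazard_baseline * np.exp(cfg.beta_surv * e)
    t_event = rng.exponential(1.0 / rates)
    if cfg.censor_fraction > 0:
        horizon = _censor_horizon(rates, cfg.censor_fraction)
        c_time = rng.uniform(0, horizon, size=n)
        os_time = np.minimum(t_event, c_time)
        os_event = (t_event <= c_time).astype(int)
    else:
        os_time, os_event = t_event, np.ones(n, dtype=int)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "stage": np.where(rng.random(n) < 0.5, "I", "II"),
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )

    truth = GroundTruth(
        subtype=pd.Series(z, index=samples, name="subtype"),
        latent=pd.Series(e, index=samples, name="emt_axis"),
        lnc_class=pd.Series(lnc_class, index=lnc_ids, name="lnc_class"),
        mediators=pd.DataFrame(m, index=key_ids, columns=samples),
        tf_differential=None if regsim is None else regsim.differential,
        tf_activity=None if regsim is None else regsim.activity,
    )
    gene_sets = GeneSetCollection(sets)
    return expr, clinical, gene_sets, truth


def simulate_two_cohorts(cfg: SimConfig, seeds: tuple[int, int] = (0, 1)):
    """Two cohorts from one config (shared loadings, independent noise)."""
    import dataclasses

    cohorts = []
    for s in seeds:
        c = dataclasses.replace(cfg, seed=s)
        cohorts.append(simulate_cohort(c))
    return cohorts
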