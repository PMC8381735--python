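"""Synthetic cohorts with planted ground truth.

The generator emulates the statistical structure the pipeline assumes,
so that every downstream stage has a recoverable planted signal:

* per-gene log2 expression is Gaussian with a single shared latent
  "immune activity" factor per sample; all immune protein-coding genes
  and a chosen subset of lncRNAs load on it (loading 0.8, residual sd
  0.6, hence pairwise log-scale correlation ~0.64, comfortably above
  the 0.4 screening cut); FPKM = 2**x;
* planted differentially expressed lncRNAs get a +/-1.5 log2-unit tumor
  mean shift (mostly up-shifted, as in real tumor-vs-normal contrasts);
* prognostic signal enters through binary pair indicators: survival
  times for tumor samples are exponential with rate
  baseline_hazard * exp(eta), eta = sum_k beta_k * C_k over the planted
  pairs, with C computed by the exact rank-pair rule the encoder uses;
* censoring is independent exponential, its rate calibrated so the
  expected censored fraction (including administrative truncation at
  the horizon) matches ``censor_rate``;
* stage/T/N/M are drawn from cumulative-logit models whose advanced-
  category probability increases monotonically in eta; immune-cell
  fractions are inverse-logit(a_j + b_j*eta + noise); IC50 columns are
  c_d - d_d*eta + noise with d_d > 0 for drugs made more effective in
  high-risk samples.

Planted pairs use disjoint gene sets drawn from the DE-and-co-expressed
lncRNAs, with the two genes of a pair given matched shifts and nearby
baseline means so the pair's indicator prevalence lands strictly inside
the (20%, 80%) validity window by construction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ingest import NORMAL, TUMOR, ValidationError
from .pairenc import pair_id

CELL_TYPES = [
    "B_cells",
    "CD4_T_cells",
    "CD8_T_cells",
    "Tregs",
    "NK_cells",
    "Monocytes",
    "Macrophages_M0",
    "Macrophages_M1",
    "Macrophages_M2",
    "Neutrophils",
]

DRUGS = [
    "Cisplatin",
    "Oxaliplatin",
    "Paclitaxel",
    "Gemcitabine",
    "Docetaxel",
    "Sorafenib",
    "Sunitinib",
    "Erlotinib",
]
N_SENSITIVE_DRUGS = 4  # first drugs get d_d > 0 (more effective at high risk)

FACTOR_LOADING = 0.8
FACTOR_RESID_SD = 0.6
DE_SHIFT = 1.5  # log2 units
P_UP = 0.8  # fraction of DE genes shifted up in tumor
CLIN_STRENGTH = 1.0  # slope of eta in the clinical cumulative-logit models


@dataclass
class SimConfig:
    """Cohort dimensions and effect sizes for the generator.

    Defaults describe a desk-scale analogue of a TCGA-style cohort: a
    large tumor arm with a small normal arm, a couple hundred lncRNAs of
    which a core subset is immune co-expressed, and a handful of planted
    prognostic pairs with log-hazard weights around 1.
    """

    n_tumor: int = 600
    n_normal: int = 40
    n_lnc: int = 200
    n_imm: int = 100
    n_coexpr: int = 60
    n_de: int = 30
    n_true_pairs: int = 4
    beta_range: tuple[float, float] = (0.8, 1.2)
    baseline_hazard: float = 1e-4  # per day at eta = 0; a typical sample (eta ~ 2
    # with the default planted pairs) then has a median survival near 2.5 years
    censor_rate: float = 0.6
    admin_horizon: float = 3650.0  # days
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_tumor=self.n_tumor,
            n_normal=self.n_normal,
            n_lnc=self.n_lnc,
            n_imm=self.n_imm,
            n_coexpr=self.n_coexpr,
            n_de=self.n_de,
        )
        for k, v in counts.items():
            if v <= 0:
                raise ValidationError(f"{k} must be positive, got {v}")
        if self.n_true_pairs < 0:
            raise ValidationError("n_true_pairs must be >= 0")
        if self.n_de > self.n_lnc:
            raise ValidationError("n_de cannot exceed n_lnc")
        if self.n_coexpr > self.n_lnc:
            raise ValidationError("n_coexpr cannot exceed n_lnc")
        if not (0 <= self.censor_rate < 1):
            raise ValidationError("censor_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0 or self.admin_horizon <= 0:
            raise ValidationError("baseline_hazard and admin_horizon must be positive")
        if self.beta_range[0] > self.beta_range[1]:
            raise ValidationError("beta_range must be (lo, hi) with lo <= hi")
        n_plantable = min(self.n_de, self.n_coexpr)
        if 2 * self.n_true_pairs > n_plantable:
            raise ValidationError(
                f"n_true_pairs={self.n_true_pairs} needs {2 * self.n_true_pairs} distinct "
                f"DE+co-expressed lncRNAs but only {n_plantable} are available"
            )


@dataclass
class CohortStructure:
    """Gene-level parameters fixed by the structural seed.

    Sharing a structure between two cohorts (training/validation) keeps
    the gene universe, planted effects and true pairs identical while
    the samples are redrawn.
    """

    lnc_ids: list[str]
    imm_ids: list[str]
    lnc_mu: np.ndarray
    imm_mu: np.ndarray
    coexpr_ids: list[str]
    de_ids: list[str]
    de_shift: dict  # gene -> signed log2 shift in tumor
    true_pairs: list[tuple[str, str, float]]  # canonical orientation
    immune_intercept: np.ndarray
    immune_slope: np.ndarray  # b_j per cell type
    drug_intercept: np.ndarray
    drug_slope: np.ndarray  # d_d per drug


@dataclass
class GroundTruth:
    de_gene_ids: set
    coexpr_gene_ids: set
    true_pairs: list[tuple[str, str, float]]
    true_linear_predictor: pd.Series
    immune_slopes: dict = field(default_factory=dict)
    drug_slopes: dict = field(default_factory=dict)


@dataclass
class SimulatedCohort:
    expression: pd.DataFrame  # genes x samples, FPKM
    groups: pd.Series
    catalog: pd.DataFrame  # gene_id, biotype
    immune_genes: list[str]
    clinical: pd.DataFrame
    fractions: pd.DataFrame  # tumor samples x cell types
    ic50: pd.DataFrame  # tumor samples x drugs
    ground_truth: GroundTruth
    structure: CohortStructure


def _gene_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def build_structure(config: SimConfig, rng: np.random.Generator) -> CohortStructure:
    lnc_ids = _gene_ids("LNC", config.n_lnc)
    imm_ids = _gene_ids("IMM", config.n_imm)
    lnc_mu = rng.uniform(2.0, 7.0, size=config.n_lnc)
    imm_mu = rng.uniform(3.0, 8.0, size=config.n_imm)

    coexpr_idx = rng.choice(config.n_lnc, size=config.n_coexpr, replace=False)
    coexpr_ids = [lnc_ids[i] for i in sorted(coexpr_idx)]
    # DE genes drawn from the co-expressed set first so planted pairs can
    # survive both screens; extras (if any) come from the remainder
    n_from_co = min(config.n_de, config.n_coexpr)
    de_from_co = rng.choice(config.n_coexpr, size=n_from_co, replace=False)
    de_ids = [coexpr_ids[i] for i in sorted(de_from_co)]
    if config.n_de > n_from_co:
        rest = [g for g in lnc_ids if g not in set(coexpr_ids)]
        extra = rng.choice(len(rest), size=config.n_de - n_from_co, replace=False)
        de_ids += [rest[i] for i in sorted(extra)]

    de_shift = {}
    for g in de_ids:
        de_shift[g] = DE_SHIFT if rng.random() < P_UP else -DE_SHIFT

    # planted prognostic pairs: disjoint genes from DE ∩ coexpr, with
    # matched shifts and nearby means so prevalence lands in (0.2, 0.8)
    plantable = [g for g in de_ids if g in set(coexpr_ids)]
    order = rng.permutation(len(plantable))
    true_pairs = []
    pos = {g: i for i, g in enumerate(lnc_ids)}
    taken = 0
    for _ in range(config.n_true_pairs):
        a, b = plantable[order[taken]], plantable[order[taken + 1]]
        taken += 2
        de_shift[b] = de_shift[a]  # matched shift keeps the indicator informative
        lnc_mu[pos[b]] = lnc_mu[pos[a]] + rng.uniform(-0.5, 0.5)
        beta = rng.uniform(*config.beta_range)
        ga, gb = sorted((a, b))
        # beta is defined for the canonical indicator C = 1[expr(ga) >= expr(gb)]
        true_pairs.append((ga, gb, float(beta)))

    imm_slope = np.where(
        np.arange(len(CELL_TYPES)) % 2 == 0,
        rng.uniform(0.4, 0.8, size=len(CELL_TYPES)),
        -rng.uniform(0.4, 0.8, size=len(CELL_TYPES)),
    )
    drug_slope = np.concatenate(
        [
            rng.uniform(0.4, 0.8, size=N_SENSITIVE_DRUGS),
            np.zeros(len(DRUGS) - N_SENSITIVE_DRUGS),
        ]
    )
    return CohortStructure(
        lnc_ids=lnc_ids,
        imm_ids=imm_ids,
        lnc_mu=lnc_mu,
        imm_mu=imm_mu,
        coexpr_ids=coexpr_ids,
        de_ids=de_ids,
        de_shift=de_shift,
        true_pairs=true_pairs,
        immune_intercept=rng.uniform(-2.5, -1.0, size=len(CELL_TYPES)),
        immune_slope=imm_slope,
        drug_intercept=rng.uniform(2.0, 5.0, size=len(DRUGS)),
        drug_slope=drug_slope,
    )


def _calibrate_censor_rate(lam: np.ndarray, target: float, horizon: float) -> float:
    """Exponential censoring rate c such that E[censored fraction] = target.

    With T ~ Exp(lam_i), C ~ Exp(c), both administratively truncated at
    the horizon H, P(event_i) = lam/(lam+c) * (1 - exp(-(lam+c)H)).
    Solved by bisection; returns 0 when even c = 0 over-censors (pure
    administrative censoring already exceeds the target).
    """

    def censored_frac(c):
        rate = lam + c
        p_event = lam / rate * (1.0 - np.exp(-rate * horizon))
        return 1.0 - p_event.mean()

    if censored_frac(0.0) >= target:
        return 0.0
    lo, hi = 0.0, 1.0
    while censored_frac(hi) < target:
        hi *= 2.0
        if hi > 1e6:
            break
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if censored_frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _cumlogit_draw(rng, eta_c, cum_base, slope):
    """Ordered categories 0..K with P(advanced) monotone increasing in eta."""
    alphas = np.log(np.asarray(cum_base) / (1.0 - np.asarray(cum_base)))
    u = rng.random(eta_c.size)
    cat = np.zeros(eta_c.size, dtype=int)
    for a in alphas:
        p_le = 1.0 / (1.0 + np.exp(-(a - slope * eta_c)))
        cat += (u > p_le).astype(int)
    return cat


def simulate_cohort(
    config: SimConfig,
    structure: CohortStructure | None = None,
    sample_seed: int | None = None,
) -> SimulatedCohort:
    """Draw a full synthetic cohort.

    All randomness derives from ``config.seed`` (structure and samples);
    pass an existing ``structure`` plus a ``sample_seed`` to draw an
    independent validation cohort with the same planted effects.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    struct_ss, samp_ss = ss.spawn(2)
    if structure is None:
        structure = build_structure(config, np.random.default_rng(struct_ss))
    if sample_seed is not None:
        samp_ss = np.random.SeedSequence(sample_seed)
    rng = np.random.default_rng(samp_ss)
    st = structure

    n_t, n_n = config.n_tumor, config.n_normal
    n = n_t + n_n
    tumor_ids = [f"TUM{i + 1:04d}" for i in range(n_t)]
    normal_ids = [f"NRM{i + 1:04d}" for i in range(n_n)]
    sample_ids = tumor_ids + normal_ids
    is_tumor = np.array([True] * n_t + [False] * n_n)

    z = rng.normal(size=n)  # latent immune-activity factor
    coexpr_set = set(st.coexpr_ids)

    n_lnc, n_imm = len(st.lnc_ids), len(st.imm_ids)
    load_l = np.array([FACTOR_LOADING if g in coexpr_set else 0.0 for g in st.lnc_ids])
    sd_l = np.where(load_l > 0, FACTOR_RESID_SD, 1.0)
    shift_l = np.array([st.de_shift.get(g, 0.0) for g in st.lnc_ids])

    Xl = (
        st.lnc_mu[:, None]
        + shift_l[:, None] * is_tumor[None, :]
        + load_l[:, None] * z[None, :]
        + sd_l[:, None] * rng.normal(size=(n_lnc, n))
    )
    Xi = (
        st.imm_mu[:, None]
        + FACTOR_LOADING * z[None, :]
        + FACTOR_RESID_SD * rng.normal(size=(n_imm, n))
    )
    expr = pd.DataFrame(
        np.vstack([2.0**Xl, 2.0**Xi]),
        index=st.lnc_ids + st.imm_ids,
        columns=sample_ids,
    )
    groups = pd.Series(
        [TUMOR if t else NORMAL for t in is_tumor], index=sample_ids, name="group"
    )

    # planted linear predictor from the exact rank-pair indicators
    eta = np.zeros(n_t)
    fpkm_t = expr[tumor_ids]
    for ga, gb, beta in st.true_pairs:
        c = (fpkm_t.loc[ga].to_numpy() >= fpkm_t.loc[gb].to_numpy()).astype(float)
        eta += beta * c

    lam = config.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    c_rate = _calibrate_censor_rate(lam, config.censor_rate, config.admin_horizon)
    t_cens = (
        rng.exponential(1.0 / c_rate, size=n_t) if c_rate > 0 else np.full(n_t, np.inf)
    )
    t_cens = np.minimum(t_cens, config.admin_horizon)
    fustat = (t_event <= t_cens).astype(int)
    futime = np.maximum(np.rint(np.minimum(t_event, t_cens)), 1.0)

    eta_c = eta - eta.mean() if np.ptp(eta) > 0 else np.zeros(n_t)
    age = np.clip(np.rint(rng.normal(66, 11, size=n_t)), 30, 90).astype(int)
    stage = _cumlogit_draw(rng, eta_c, [0.18, 0.55, 0.82], CLIN_STRENGTH) + 1
    t_cat = _cumlogit_draw(rng, eta_c, [0.05, 0.25, 0.60], CLIN_STRENGTH) + 1
    n_cat = _cumlogit_draw(rng, eta_c, [0.45, 0.75], CLIN_STRENGTH)
    m_cat = (
        rng.random(n_t) < 1.0 / (1.0 + np.exp(-(-1.8 + CLIN_STRENGTH * eta_c)))
    ).astype(int)
    roman = {1: "I", 2: "II", 3: "III", 4: "IV"}
    clinical = pd.DataFrame(
        {
            "sample": tumor_ids,
            "futime": futime,
            "fustat": fustat,
            "age": age,
            "stage": [roman[s] for s in stage],
            "T": [f"T{v}" for v in t_cat],
            "M": [f"M{v}" for v in m_cat],
            "N": [f"N{v}" for v in n_cat],
        }
    )

    frac = 1.0 / (
        1.0
        + np.exp(
            -(
                st.immune_intercept[None, :]
                + st.immune_slope[None, :] * eta_c[:, None]
                + 0.5 * rng.normal(size=(n_t, len(CELL_TYPES)))
            )
        )
    )
    fractions = pd.DataFrame(frac, index=tumor_ids, columns=CELL_TYPES)

    ic50 = pd.DataFrame(
        st.drug_intercept[None, :]
        - st.drug_slope[None, :] * eta_c[:, None]
        + 0.6 * rng.normal(size=(n_t, len(DRUGS))),
        index=tumor_ids,
        columns=DRUGS,
    )

    catalog = pd.DataFrame(
        {
            "gene_id": st.lnc_ids + st.imm_ids,
            "biotype": ["lncRNA"] * n_lnc + ["protein_coding"] * n_imm,
        }
    )
    gt = GroundTruth(
        de_gene_ids=set(st.de_ids),
        coexpr_gene_ids=set(st.coexpr_ids),
        true_pairs=list(st.true_pairs),
        true_linear_predictor=pd.Series(eta, index=tumor_ids, name="eta"),
        immune_slopes=dict(zip(CELL_TYPES, st.immune_slope)),
        drug_slopes=dict(zip(DRUGS, st.drug_slope)),
    )
    return SimulatedCohort(
        expression=expr,
        groups=groups,
        catalog=catalog,
        immune_genes=list(st.imm_ids),
        clinical=clinical,
        fractions=fractions,
        ic50=ic50,
        ground_truth=gt,
        structure=st,
    )


# ---------------------------------------------------------------------------
# serialization


def write_cohort(cohort: SimulatedCohort, directory: str) -> dict:
    """Write all tables in the dialects the ingest module reads.

    Returns a dict of logical name -> path.
    """
    if not directory:
        raise IOError("empty directory path")
    os.makedirs(directory, exist_ok=True)
    paths = {
        "expression": os.path.join(directory, "expression.tsv"),
        "groups": os.path.join(directory, "groups.tsv"),
        "catalog": os.path.join(directory, "gene_catalog.tsv"),
        "immune_genes": os.path.join(directory, "immune_genes.txt"),
        "clinical": os.path.join(directory, "clinical.tsv"),
        "fractions": os.path.join(directory, "immune_fractions.tsv"),
        "ic50": os.path.join(directory, "ic50.tsv"),
        "ground_truth": os.path.join(directory, "ground_truth.json"),
    }
    cohort.expression.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    cohort.groups.rename("group").to_csv(paths["groups"], sep="\t", index_label="sample")
    cohort.catalog.to_csv(paths["catalog"], sep="\t", index=False)
    with open(paths["immune_genes"], "w") as fh:
        fh.write("\n".join(cohort.immune_genes) + "\n")
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    cohort.fractions.to_csv(paths["fractions"], sep="\t", index_label="sample")
    cohort.ic50.to_csv(paths["ic50"], sep="\t", index_label="sample")
    gt = cohort.ground_truth
    record = {
        "de_gene_ids": sorted(gt.de_gene_ids),
        "coexpr_gene_ids": sorted(gt.coexpr_gene_ids),
        "true_pairs": [[a, b, beta] for a, b, beta in gt.true_pairs],
        "true_linear_predictor": {k: float(v) for k, v in gt.true_linear_predictor.items()},
        "immune_slopes": {k: float(v) for k, v in gt.immune_slopes.items()},
        "drug_slopes": {k: float(v) for k, v in gt.drug_slopes.items()},
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
    return paths


def read_ground_truth(path: str) -> GroundTruth:
    with open(path) as fh:
        rec = json.load(fh)
    return GroundTruth(
        de_gene_ids=set(rec["de_gene_ids"]),
        coexpr_gene_ids=set(rec["coexpr_gene_ids"]),
        true_pairs=[(a, b, float(beta)) for a, b, beta in rec["true_pairs"]],
        true_linear_predictor=pd.Series(rec["true_linear_predictor"], name="eta"),
        immune_slopes=rec.get("immune_slopes", {}),
        drug_slopes=rec.get("drug_slopes", {}),
    )
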