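"""Synthetic data with planted ground truth for the oncomotif analysis chain.

Three generators emulate the three data tiers the analysis consumes:

* :func:`generate_screen` — a pooled miR-Vec overexpression screen: negative-
  binomial read counts over three conditions in triplicate, with planted
  enriched (pro-proliferative) and depleted (drug-sensitizing) vectors whose
  mature sequences carry a shared seed motif, plus a motif-free background
  library.
* :func:`generate_omics` — mimic-vs-control transcriptome and proteome
  replicate matrices (log2 scale, Gaussian noise) with planted repressed
  targets whose prediction-algorithm consensus counts are stochastically
  elevated.
* :func:`generate_cohort` — a tumor/normal cohort in which a single latent
  "oncomotif activity" per sample drives family-miRNA expression upward,
  tumor-suppressor mRNAs downward, cell-cycle mRNAs upward, TP53-mutation
  probability upward, and relapse hazard upward — the coupling structure the
  downstream signature, genotype and survival analyses are designed to
  detect.

Every generator is a pure function of its config: identical seeds give
byte-identical outputs.  Each returns a :class:`TruthLabels` sidecar with the
planted ids / latent activities for parameter-recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .motif import MiRNACatalogue, MiRNARecord, RNA_ALPHABET
from .screen import ScreenCountTable

_NT = np.array(list("ACGU"))
MATURE_LENGTH = 22
SEED_LENGTH = 8


@dataclass(frozen=True)
class ScreenSimConfig:
    """Pooled-screen generator settings.

    Counts are negative-binomial with variance mu + dispersion * mu^2 around
    depth x relative clone abundance.  Planted enriched vectors gain
    ``2**log2_effect_enrich`` abundance in the second condition relative to
    the first; planted depleted vectors lose ``2**log2_effect_deplete`` in
    the third relative to the second.  ``n_dual`` of the depleted vectors are
    drawn from the enriched set, emulating clones that both proliferate
    faster and sensitize to the drug.
    """

    n_vectors: int = 450
    conditions: tuple[str, ...] = ("Ctrl0", "Ctrl30", "Gef30")
    n_replicates: int = 3
    depth: float = 1e6
    dispersion: float = 0.05
    n_enriched: int = 15
    n_depleted: int = 15
    n_dual: int = 11
    log2_effect_enrich: float = 2.5
    log2_effect_deplete: float = 2.5
    motif: str = "AAGUGC"
    abundance_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_vectors, self.n_replicates) < 1 or len(self.conditions) < 2:
            raise ValueError("counts must be positive; need >=2 conditions")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0 or self.abundance_sigma < 0:
            raise ValueError("dispersion and abundance_sigma must be nonnegative")
        if not (
            np.isfinite(self.log2_effect_enrich)
            and np.isfinite(self.log2_effect_deplete)
        ):
            raise ValueError("effects must be finite")
        if min(self.n_enriched, self.n_depleted, self.n_dual) < 0:
            raise ValueError("hit counts must be nonnegative")
        if self.n_dual > min(self.n_enriched, self.n_depleted):
            raise ValueError("n_dual exceeds a planted class size")
        if self.n_enriched + self.n_depleted > self.n_vectors:
            raise ValueError("planted hits exceed library size")
        if set(self.motif) - RNA_ALPHABET:
            raise ValueError(f"motif {self.motif!r} not over ACGU")
        if len(self.motif) > SEED_LENGTH:
            raise ValueError("motif longer than the 8-nt seed")


@dataclass(frozen=True)
class OmicsSimConfig:
    """Mimic-vs-control omics generator settings.

    Per-gene replicate values are Normal(mu_g, noise_sd) on the log2 scale;
    mimic-arm means of the planted targets are shifted by ``delta_mrna``
    (mRNA) and ``delta_protein`` (protein, where covered).  Prediction
    counts are Binomial(9, p) with p = ``pred_p_target`` for targets and
    ``pred_p_null`` otherwise, emulating a nine-algorithm consensus.
    """

    n_genes: int = 12000
    n_targets: int = 500
    n_replicates: int = 3
    delta_mrna: float = -1.0
    delta_protein: float = -0.8
    noise_sd: float = 0.3
    protein_coverage: float = 0.7
    n_algorithms: int = 9
    pred_p_target: float = 0.7
    pred_p_null: float = 0.1
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_replicates) < 1 or self.n_targets < 0:
            raise ValueError("counts must be positive")
        if self.n_targets > self.n_genes:
            raise ValueError("n_targets exceeds n_genes")
        if not 0 <= self.protein_coverage <= 1:
            raise ValueError("protein_coverage outside [0,1]")
        for p in (self.pred_p_target, self.pred_p_null):
            if not 0 <= p <= 1:
                raise ValueError("prediction probabilities outside [0,1]")
        if self.delta_mrna > 0 or self.delta_protein > 0:
            raise ValueError("target deltas must be <= 0 (repression)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


DEFAULT_TS_PANEL = (
    "TGFBR2", "CDKN1A", "LATS2", "RBL2", "ZBTB7A", "PTEN", "RB1",
)


@dataclass(frozen=True)
class CohortSimConfig:
    """Latent-activity cohort generator settings.

    One latent activity a_s per sample (standard Normal for tumors, shifted
    by ``normal_offset`` for normal-tissue samples) couples everything:
    family-miRNA log2 expression rises with slope ``mirna_coupling``;
    TS-panel mRNA falls with slope ``beta_ts``; cell-cycle mRNA rises with
    ``beta_cc``; TP53 mutation is Bernoulli(logistic(mut_base +
    mut_slope * a)); relapse time is exponential with log-hazard
    ``hazard_slope * a``.  miRNA columns are rescaled per sample to reads
    per million.
    """

    n_tumors: int = 400
    n_normals: int = 20
    n_family_mirnas: int = 8
    n_background_mirnas: int = 40
    ts_genes: tuple[str, ...] = DEFAULT_TS_PANEL
    n_cellcycle: int = 90
    n_repressed: int = 45
    n_null: int = 500
    beta_ts: float = 0.8
    beta_cc: float = 0.8
    mut_base: float = -1.2
    mut_slope: float = 1.0
    hazard_slope: float = 0.8
    base_hazard: float = 0.15
    censor_rate: float = 0.3
    noise_sd: float = 0.7
    mirna_coupling: float = 1.0
    mirna_noise_sd: float = 0.5
    normal_offset: float = -2.0
    normal_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 0.5
    cancer_type: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tumors, self.n_normals, self.n_family_mirnas) < 1:
            raise ValueError("sample and family counts must be positive")
        if min(
            self.n_cellcycle, self.n_repressed, self.n_null,
            self.n_background_mirnas,
        ) < 0:
            raise ValueError("gene counts must be nonnegative")
        for v in (self.beta_ts, self.beta_cc, self.mut_slope, self.hazard_slope):
            if not np.isfinite(v):
                raise ValueError("couplings must be finite")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate outside [0,1)")
        if self.base_hazard <= 0:
            raise ValueError("base_hazard must be positive")
        if len(set(self.ts_genes)) != len(self.ts_genes):
            raise ValueError("duplicate TS gene labels")


@dataclass
class TruthLabels:
    """Planted ground truth emitted alongside every generated dataset."""

    seed_used: int
    enriched_ids: list[str] = field(default_factory=list)
    depleted_ids: list[str] = field(default_factory=list)
    target_ids: list[str] = field(default_factory=list)
    activity: dict[str, float] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthLabels":
        with open(path) as fh:
            return cls(**json.load(fh))


# --------------------------------------------------------------------------
# screen


def _random_sequences(rng, n, motif=None, forbid=None):
    """n mature sequences; if motif given, plant it at a random seed offset;
    if forbid given, rejection-sample seeds until motif-free."""
    out = []
    for _ in range(n):
        while True:
            seq = "".join(rng.choice(_NT, size=MATURE_LENGTH))
            if motif is not None:
                off = int(rng.integers(0, SEED_LENGTH - len(motif) + 1))
                seq = seq[:off] + motif + seq[off + len(motif):]
            if forbid is not None and forbid in seq[:SEED_LENGTH]:
                continue
            out.append(seq)
            break
    return out


def generate_screen(
    cfg: ScreenSimConfig,
) -> tuple[ScreenCountTable, MiRNACatalogue, TruthLabels]:
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_vectors
    ids = [f"miRVec-{i:04d}" for i in range(1, n + 1)]

    # planted classes: depleted overlaps enriched by n_dual clones
    order = rng.permutation(n)
    enriched_idx = order[: cfg.n_enriched]
    depleted_idx = np.concatenate(
        [
            enriched_idx[: cfg.n_dual],
            order[cfg.n_enriched : cfg.n_enriched + cfg.n_depleted - cfg.n_dual],
        ]
    ).astype(int)
    enriched = sorted(ids[i] for i in enriched_idx)
    depleted = sorted(ids[i] for i in depleted_idx)
    hit_idx = sorted(set(enriched_idx) | set(depleted_idx))

    # relative clone abundances per condition
    base = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=n)
    w = {}
    conds = cfg.conditions
    w[conds[0]] = base.copy()
    w1 = base.copy()
    w1[enriched_idx] *= 2.0 ** cfg.log2_effect_enrich
    w[conds[1]] = w1
    if len(conds) > 2:
        w2 = w1.copy()
        w2[depleted_idx] *= 2.0 ** (-cfg.log2_effect_deplete)
        w[conds[2]] = w2
        for c in conds[3:]:
            w[c] = w2.copy()

    counts = {}
    design = {}
    for cond in conds:
        mu = cfg.depth * w[cond] / w[cond].sum()
        for r in range(1, cfg.n_replicates + 1):
            if cfg.dispersion > 0:
                lam = rng.gamma(
                    shape=1.0 / cfg.dispersion, scale=cfg.dispersion * mu
                )
            else:
                lam = mu
            col = f"{cond}_rep{r}"
            counts[col] = rng.poisson(lam)
            design[col] = cond
    count_df = pd.DataFrame(counts, index=pd.Index(ids, name="vector_id"))

    # mature sequences: hits carry the motif in the seed; background is
    # motif-free in the seed by rejection sampling
    seqs = _random_sequences(rng, n, forbid=cfg.motif)
    hit_seqs = _random_sequences(rng, len(hit_idx), motif=cfg.motif)
    for j, i in enumerate(hit_idx):
        seqs[i] = hit_seqs[j]
    catalogue = MiRNACatalogue(
        [MiRNARecord(ids[i], seqs[i]) for i in range(n)]
    )

    truth = TruthLabels(
        seed_used=cfg.seed,
        enriched_ids=enriched,
        depleted_ids=depleted,
        extra={"motif": cfg.motif},
    )
    return ScreenCountTable(counts=count_df, design=design), catalogue, truth


# --------------------------------------------------------------------------
# omics


def generate_omics(
    cfg: OmicsSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, TruthLabels]:
    """Returns (mrna, protein, prediction_counts, truth).

    ``mrna`` and ``protein`` are gene x replicate log2 matrices whose columns
    are ``mimic_rep#`` / ``ctrl_rep#``; the protein matrix holds the covered
    gene subset only.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = pd.Index(
        [f"GENE{i:05d}" for i in range(1, cfg.n_genes + 1)], name="gene_id"
    )
    target_pos = np.sort(
        rng.choice(cfg.n_genes, size=cfg.n_targets, replace=False)
    )
    is_target = np.zeros(cfg.n_genes, dtype=bool)
    is_target[target_pos] = True

    cols = [f"mimic_rep{r}" for r in range(1, cfg.n_replicates + 1)] + [
        f"ctrl_rep{r}" for r in range(1, cfg.n_replicates + 1)
    ]

    def arm_matrix(base, delta_mask):
        m = np.empty((cfg.n_genes, 2 * cfg.n_replicates))
        mimic_mu = base + delta_mask
        m[:, : cfg.n_replicates] = mimic_mu[:, None] + rng.normal(
            0, cfg.noise_sd, (cfg.n_genes, cfg.n_replicates)
        )
        m[:, cfg.n_replicates :] = base[:, None] + rng.normal(
            0, cfg.noise_sd, (cfg.n_genes, cfg.n_replicates)
        )
        return m

    base_m = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    mrna = pd.DataFrame(
        arm_matrix(base_m, np.where(is_target, cfg.delta_mrna, 0.0)),
        index=genes,
        columns=cols,
    )

    n_prot = int(round(cfg.protein_coverage * cfg.n_genes))
    prot_pos = np.sort(rng.choice(cfg.n_genes, size=n_prot, replace=False))
    base_p = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    prot_full = arm_matrix(base_p, np.where(is_target, cfg.delta_protein, 0.0))
    protein = pd.DataFrame(
        prot_full[prot_pos], index=genes[prot_pos], columns=cols
    )

    pred_p = np.where(is_target, cfg.pred_p_target, cfg.pred_p_null)
    predictions = pd.Series(
        rng.binomial(cfg.n_algorithms, pred_p),
        index=genes,
        name="prediction_count",
    )

    truth = TruthLabels(
        seed_used=cfg.seed, target_ids=[genes[i] for i in target_pos]
    )
    return mrna, protein, predictions, truth


# --------------------------------------------------------------------------
# cohort


@dataclass
class CohortDataset:
    """Paired miRNA/mRNA expression with clinical metadata.

    ``mirna_expr`` and ``mrna_expr`` are sample x feature frames; miRNA
    expression is reads-per-million (rows sum to 1e6), mRNA is log2
    fpkm-like.  ``metadata`` is indexed by sample_id with columns is_tumor,
    TP53_mut, MYC_gain, rfs_time, rfs_event.
    """

    mirna_expr: pd.DataFrame
    mrna_expr: pd.DataFrame
    metadata: pd.DataFrame
    family_ids: list[str]
    cancer_type: str = "SYN"

    def __post_init__(self) -> None:
        if not (
            self.mirna_expr.index.equals(self.mrna_expr.index)
            and self.mirna_expr.index.equals(self.metadata.index)
        ):
            raise ValueError("sample dimensions are inconsistent")


def generate_cohort(cfg: CohortSimConfig) -> tuple[CohortDataset, TruthLabels]:
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_tumors + cfg.n_normals
    samples = pd.Index(
        [f"T{i:04d}" for i in range(1, cfg.n_tumors + 1)]
        + [f"N{i:04d}" for i in range(1, cfg.n_normals + 1)],
        name="sample_id",
    )
    is_tumor = np.array([1] * cfg.n_tumors + [0] * cfg.n_normals)
    activity = rng.normal(0.0, 1.0, n)
    # normal tissue: shifted down and more homogeneous than tumors
    n_nrm = cfg.n_normals
    activity[is_tumor == 0] = cfg.normal_offset + cfg.normal_sd * rng.normal(
        0.0, 1.0, n_nrm
    )

    # miRNA tier: family members coupled to activity, background not;
    # per-sample rescale to reads-per-million
    fam_ids = [f"oncomiR-{i:02d}" for i in range(1, cfg.n_family_mirnas + 1)]
    bg_ids = [f"bg-miR-{i:03d}" for i in range(1, cfg.n_background_mirnas + 1)]
    fam_base = rng.normal(10.0, 1.0, cfg.n_family_mirnas)
    bg_base = rng.normal(10.0, 1.0, cfg.n_background_mirnas)
    fam_log = (
        fam_base[None, :]
        + cfg.mirna_coupling * activity[:, None]
        + rng.normal(0, cfg.mirna_noise_sd, (n, cfg.n_family_mirnas))
    )
    bg_log = bg_base[None, :] + rng.normal(
        0, cfg.mirna_noise_sd, (n, cfg.n_background_mirnas)
    )
    raw = np.concatenate([2.0 ** fam_log, 2.0 ** bg_log], axis=1)
    rpm = raw / raw.sum(axis=1, keepdims=True) * 1e6
    mirna = pd.DataFrame(rpm, index=samples, columns=fam_ids + bg_ids)

    # mRNA tier
    # gene tiers: the curated TS panel and a wider class of repressed target
    # genes fall with activity; cell-cycle genes rise; null genes are noise
    cc_ids = [f"CCG{i:03d}" for i in range(1, cfg.n_cellcycle + 1)]
    rep_ids = [f"TGT{i:03d}" for i in range(1, cfg.n_repressed + 1)]
    null_ids = [f"NULL{i:04d}" for i in range(1, cfg.n_null + 1)]
    genes = list(cfg.ts_genes) + rep_ids + cc_ids + null_ids
    slopes = np.concatenate(
        [
            np.full(len(cfg.ts_genes), -cfg.beta_ts),
            np.full(cfg.n_repressed, -cfg.beta_ts),
            np.full(cfg.n_cellcycle, cfg.beta_cc),
            np.zeros(cfg.n_null),
        ]
    )
    gene_base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, len(genes))
    expr = (
        gene_base[None, :]
        + slopes[None, :] * activity[:, None]
        + rng.normal(0, cfg.noise_sd, (n, len(genes)))
    )
    mrna = pd.DataFrame(expr, index=samples, columns=genes)

    # genotype and survival tiers
    def logistic(x):
        return 1.0 / (1.0 + np.exp(-x))

    p_mut = logistic(cfg.mut_base + cfg.mut_slope * activity)
    tp53 = rng.binomial(1, p_mut) * is_tumor
    myc = rng.binomial(1, logistic(cfg.mut_base + cfg.mut_slope * activity)) * is_tumor
    rate = cfg.base_hazard * np.exp(cfg.hazard_slope * activity)
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(n) < cfg.censor_rate
    t_obs = np.where(censored, t_event * rng.uniform(1e-3, 1.0, n), t_event)
    meta = pd.DataFrame(
        {
            "is_tumor": is_tumor,
            "TP53_mut": tp53,
            "MYC_gain": myc,
            "rfs_time": t_obs,
            "rfs_event": (~censored).astype(int),
        },
        index=samples,
    )

    dataset = CohortDataset(
        mirna_expr=mirna,
        mrna_expr=mrna,
        metadata=meta,
        family_ids=fam_ids,
        cancer_type=cfg.cancer_type,
    )
    truth = TruthLabels(
        seed_used=cfg.seed,
        activity={s: float(a) for s, a in zip(samples, activity)},
        extra={
            "family_ids": fam_ids,
            "ts_genes": list(cfg.ts_genes),
            "repressed_genes": rep_ids,
            "cellcycle_genes": cc_ids,
            "null_genes": null_ids,
        },
    )
    return dataset, truth
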