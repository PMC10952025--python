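"""Seeded synthetic study bundles with planted ground truth.

The generator emulates the statistical structure of a bulk-RNA-seq
colorectal-cancer cohort as consumed by the pipeline: a log2-scale gene x
sample expression matrix with biotype labels, OS/PFS survival tables whose
hazard is driven by one planted prognostic checkpoint gene, a clinical
feature table, a six-cell-type immune-infiltration table, tabular
lncRNA–miRNA / miRNA–mRNA prediction databases, a small gene-set
collection, and two validation cohorts.  Every planted effect (hazard
ratio, DE shifts, infiltration correlations, ceRNA triads, near-miss
decoys) is recorded in a :class:`TruthRecord` so each stage's recovery can
be scored exactly.

Generative model
----------------
* Checkpoint expression is Gaussian; the cohort is split at the planted
  checkpoint's median into "high" and "low" halves.
* Survival times are exponential conditional on the half, with the
  configured low/high hazard ratio; censoring is an independent
  exponential.
* Two latent infiltration factors (CD4, CD8) are correlated standard
  normals; reported abundances are monotone (exponential) transforms of
  the factors, so Spearman correlations against genes are preserved.
* Immune-module genes load linearly on one factor (or on the normalized
  sum of both, for the shared "key" genes) with loadings solved so the
  marginal correlation with the factor equals the planted value; all DE
  genes additionally receive a mean shift between the checkpoint halves.
* Planted ceRNA lncRNAs are noisy averages of their partner mRNA groups,
  which makes the intended lncRNA–mRNA correlations clear the 0.7
  threshold while same-module background pairs stay well below it.

Identifiers are synthetic (MRNA####, LNC####, mir-s####) except the 14
checkpoint gene symbols, which use their standard names.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cerna import CELL_TYPES, PREDICTION_SOURCES, PredictionDB
from .diffexpr import ExpressionMatrix
from .errors import InvalidInputError

CHECKPOINT_GENES = (
    "PDCD1", "CTLA4", "PDL1", "LAG3", "HAVCR2", "TIGIT", "ICOS",
    "TNFRSF4", "TNFRSF9", "CD73", "CD47", "BTLA", "SIRPA", "VTCN1",
)


@dataclass
class SimConfig:
    """All dials of the synthetic study; the defaults are the study conditions."""

    seed: int
    n_samples: int = 300
    n_mrna: int = 800
    n_lncrna: int = 200
    n_mirna: int = 150
    prognostic_gene: str = "ICOS"
    hazard_ratio: float = 2.5          # low-checkpoint vs high-checkpoint hazard, OS
    pfs_hazard_ratio: float = 1.8
    baseline_hazard: float = 0.02      # events/month in the favorable (high) group
    censor_rate: float = 0.012         # independent exponential censoring
    de_effect: float = 3.0             # planted log2 shift, high - low
    noise_sd: float = 1.0
    module_noise_sd: float = math.sqrt(6.0)
    lnc_copy_noise_sd: float = 0.5
    planted_rho: float = 0.6           # module gene vs its infiltration factor
    shared_rho: float = 0.7            # key gene vs the combined factor
    factor_corr: float = 0.3           # corr(CD4 factor, CD8 factor)
    n_module_per_branch: int = 8
    n_shared_keys: int = 4
    n_mirna_per_key: int = 3
    n_de_up_extra: int = 30            # non-immune planted up mRNAs
    n_de_down: int = 5
    n_de_lnc_up_extra: int = 12
    n_de_lnc_down: int = 3
    background_lnc_mir: int = 300      # random sub-threshold DB records
    background_mir_mrna: int = 600
    validation_n: int = 150
    validation_rho: float = 0.5
    n_random_gene_sets: int = 10
    gene_set_size: int = 15

    def validate(self) -> "SimConfig":
        counts = [
            self.n_samples, self.n_mrna, self.n_lncrna, self.n_mirna,
            self.n_module_per_branch, self.n_shared_keys, self.n_mirna_per_key,
        ]
        if any(c <= 0 for c in counts):
            raise InvalidInputError("all counts must be positive")
        for r in (self.planted_rho, self.shared_rho, self.factor_corr, self.validation_rho):
            if not (0.0 <= r < 1.0):
                raise InvalidInputError("correlations must lie in [0, 1)")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0 or self.censor_rate < 0:
            raise InvalidInputError("hazards must be positive")
        n_planted_mrna = (
            2 * self.n_module_per_branch + self.n_shared_keys
            + self.n_de_up_extra + self.n_de_down
        )
        if n_planted_mrna >= self.n_mrna:
            raise InvalidInputError("n_mrna too small for the planted effects")
        if 2 * self.n_module_per_branch < 2:
            raise InvalidInputError("need at least one module gene per branch")
        return self


@dataclass
class TruthRecord:
    """Ground truth planted by the generator."""

    prognostic_gene: str
    hazard_ratio: float
    high_samples: list[str]
    de_mrna_up: list[str]
    de_mrna_down: list[str]
    de_lnc_up: list[str]
    de_lnc_down: list[str]
    module_cd4: list[str]
    module_cd8: list[str]
    key_genes: list[str]
    module_lnc_cd4: list[str]
    module_lnc_cd8: list[str]
    shared_lnc: list[str]
    planted_rho: dict[str, float]
    triads_cd4: list[tuple[str, str, str]]
    triads_cd8: list[tuple[str, str, str]]
    decoys: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Bundle:
    """Everything a full pipeline run consumes, plus the truth."""

    expression: ExpressionMatrix
    survival: pd.DataFrame            # long table, endpoints OS and PFS
    clinical: pd.DataFrame
    infiltration: pd.DataFrame
    predictions: PredictionDB
    gene_sets: dict[str, list[str]]
    validation_cohorts: dict[str, pd.DataFrame]
    truth: TruthRecord
    config: SimConfig


def _loading(target_rho: float, group_var: float, noise_var: float) -> float:
    """Factor loading giving the requested marginal correlation with the factor."""
    return target_rho * math.sqrt((group_var + noise_var) / (1.0 - target_rho**2))


def _mrna_ids(cfg: SimConfig) -> list[str]:
    return [f"MRNA{i:04d}" for i in range(1, cfg.n_mrna + 1)]


def _lnc_ids(cfg: SimConfig) -> list[str]:
    return [f"LNC{i:04d}" for i in range(1, cfg.n_lncrna + 1)]


def _mir_ids(cfg: SimConfig) -> list[str]:
    return [f"mir-s{i:04d}" for i in range(1, cfg.n_mirna + 1)]


def generate_cohort(cfg: SimConfig):
    """Expression + survival + clinical + infiltration + truth.

    Returns ``(ExpressionMatrix, survival, clinical, infiltration, TruthRecord)``.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.n_samples
    samples = [f"S{i:04d}" for i in range(1, n + 1)]

    # --- checkpoint genes and the prognostic split -------------------------
    if cfg.prognostic_gene not in CHECKPOINT_GENES:
        raise InvalidInputError(f"{cfg.prognostic_gene!r} is not a known checkpoint")
    cp_expr = {g: 5.0 + rng.normal(0.0, 1.0, n) for g in CHECKPOINT_GENES}
    prog = cp_expr[cfg.prognostic_gene]
    high = prog > np.median(prog)
    ind = high.astype(float)  # 0/1 group indicator
    group_var = cfg.de_effect**2 / 4.0

    # --- latent infiltration factors ---------------------------------------
    c = cfg.factor_corr
    z = rng.normal(size=(n, 2))
    f_cd4 = z[:, 0]
    f_cd8 = c * z[:, 0] + math.sqrt(1.0 - c**2) * z[:, 1]
    f_shared = (f_cd4 + f_cd8) / math.sqrt(2.0 * (1.0 + c))

    # --- mRNA layer ---------------------------------------------------------
    mrna_ids = _mrna_ids(cfg)
    nb = cfg.n_module_per_branch
    cd4_genes = mrna_ids[:nb]
    cd8_genes = mrna_ids[nb : 2 * nb]
    key_genes = mrna_ids[2 * nb : 2 * nb + cfg.n_shared_keys]
    pos = 2 * nb + cfg.n_shared_keys
    extra_up = mrna_ids[pos : pos + cfg.n_de_up_extra]
    pos += cfg.n_de_up_extra
    down_genes = mrna_ids[pos : pos + cfg.n_de_down]

    lam_branch = _loading(cfg.planted_rho, group_var, cfg.module_noise_sd**2)
    lam_shared = _loading(cfg.shared_rho, group_var, cfg.module_noise_sd**2)

    # Planted up-genes start low (immune genes are near-silent in the
    # checkpoint-low, immune-cold half) so the +effect shift carries them
    # into the top of the within-sample rank distribution.
    expr = {}
    baseline = dict(zip(mrna_ids, rng.uniform(2.0, 8.0, cfg.n_mrna)))
    for g in (
        mrna_ids[: 2 * nb + cfg.n_shared_keys + cfg.n_de_up_extra]
    ):
        baseline[g] = float(rng.uniform(2.0, 4.0))
    for g in mrna_ids:
        mu = baseline[g]
        if g in cd4_genes or g in cd8_genes:
            f = f_cd4 if g in cd4_genes else f_cd8
            expr[g] = (
                mu + cfg.de_effect * ind + lam_branch * f
                + rng.normal(0.0, cfg.module_noise_sd, n)
            )
        elif g in key_genes:
            expr[g] = (
                mu + cfg.de_effect * ind + lam_shared * f_shared
                + rng.normal(0.0, cfg.module_noise_sd, n)
            )
        elif g in extra_up:
            expr[g] = mu + cfg.de_effect * ind + rng.normal(0.0, cfg.noise_sd, n)
        elif g in down_genes:
            expr[g] = mu - cfg.de_effect * ind + rng.normal(0.0, cfg.noise_sd, n)
        else:
            expr[g] = mu + rng.normal(0.0, cfg.noise_sd, n)

    # --- lncRNA layer -------------------------------------------------------
    lnc_ids = _lnc_ids(cfg)
    half = nb // 2
    lnc_cd4 = lnc_ids[:2]
    lnc_cd8 = lnc_ids[2:4]
    lnc_shared = lnc_ids[4:6]
    lnc_decoy = {"cd4": lnc_ids[6], "cd8": lnc_ids[7]}
    pos = 8
    lnc_extra_up = lnc_ids[pos : pos + cfg.n_de_lnc_up_extra]
    pos += cfg.n_de_lnc_up_extra
    lnc_down = lnc_ids[pos : pos + cfg.n_de_lnc_down]

    # which mRNAs each planted lncRNA co-expresses with
    lnc_partner_groups: dict[str, list[str]] = {
        lnc_cd4[0]: cd4_genes[:half],
        lnc_cd4[1]: cd4_genes[half:],
        lnc_cd8[0]: cd8_genes[:half],
        lnc_cd8[1]: cd8_genes[half:],
        lnc_shared[0]: key_genes,
        lnc_shared[1]: key_genes,
    }
    for g in lnc_ids:
        mu = float(rng.uniform(1.0, 6.0))
        if g in lnc_partner_groups:
            partners = lnc_partner_groups[g]
            expr[g] = np.mean([expr[m] for m in partners], axis=0) + rng.normal(
                0.0, cfg.lnc_copy_noise_sd, n
            )
        elif g == lnc_decoy["cd4"]:
            expr[g] = (
                mu + cfg.de_effect * ind + lam_branch * f_cd4
                + rng.normal(0.0, cfg.module_noise_sd, n)
            )
        elif g == lnc_decoy["cd8"]:
            expr[g] = (
                mu + cfg.de_effect * ind + lam_branch * f_cd8
                + rng.normal(0.0, cfg.module_noise_sd, n)
            )
        elif g in lnc_extra_up:
            expr[g] = mu + cfg.de_effect * ind + rng.normal(0.0, cfg.noise_sd, n)
        elif g in lnc_down:
            expr[g] = mu - cfg.de_effect * ind + rng.normal(0.0, cfg.noise_sd, n)
        else:
            expr[g] = mu + rng.normal(0.0, cfg.noise_sd, n)

    for g in CHECKPOINT_GENES:
        expr[g] = cp_expr[g]

    gene_order = list(CHECKPOINT_GENES) + mrna_ids + lnc_ids + ["PSEUDO0001", "PSEUDO0002"]
    for g in ("PSEUDO0001", "PSEUDO0002"):
        expr[g] = 3.0 + rng.normal(0.0, 1.0, n)
    values = pd.DataFrame(
        np.vstack([np.asarray(expr[g], dtype=float) for g in gene_order]),
        index=pd.Index(gene_order, name="gene_id"),
        columns=samples,
    )
    lnc_biotype_cycle = [
        "lincRNA", "antisense", "processed_transcript", "sense_intronic",
        "sense_overlapping", "non_coding", "3prime_overlapping_ncRNA",
    ]
    biotype = pd.Series(
        (["protein_coding"] * (len(CHECKPOINT_GENES) + cfg.n_mrna))
        + [lnc_biotype_cycle[i % len(lnc_biotype_cycle)] for i in range(cfg.n_lncrna)]
        + ["pseudogene", "pseudogene"],
        index=values.index,
        name="biotype",
    )
    matrix = ExpressionMatrix(values, biotype)

    # --- survival -----------------------------------------------------------
    surv_rows = []
    for endpoint, hr, base in (
        ("OS", cfg.hazard_ratio, cfg.baseline_hazard),
        ("PFS", cfg.pfs_hazard_ratio, cfg.baseline_hazard * 1.5),
    ):
        hazard = np.where(high, base, base * hr)
        t_event = rng.exponential(1.0 / hazard)
        t_cens = (
            rng.exponential(1.0 / cfg.censor_rate, n)
            if cfg.censor_rate > 0
            else np.full(n, np.inf)
        )
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        for s, t, e in zip(samples, time, event):
            surv_rows.append(
                {"sample_id": s, "time": round(float(t), 4), "event": int(e), "endpoint": endpoint}
            )
    survival = pd.DataFrame(surv_rows)

    # --- clinical -----------------------------------------------------------
    stage_p_high = [0.35, 0.35, 0.2, 0.1]
    stage_p_low = [0.15, 0.25, 0.3, 0.3]
    stages = [
        rng.choice(["I", "II", "III", "IV"], p=stage_p_high if h else stage_p_low)
        for h in high
    ]
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "gender": rng.choice(["female", "male"], n),
            "age": rng.integers(35, 85, n),
            "stage": stages,
            "location": rng.choice(["colon", "rectum"], n),
        }
    )

    # --- infiltration (monotone transforms keep Spearman structure) --------
    infiltration = pd.DataFrame(
        {
            "B_cell": np.exp(0.4 * rng.normal(size=n) - 1.5),
            "CD4_T": np.exp(0.5 * f_cd4 - 1.0),
            "CD8_T": np.exp(0.5 * f_cd8 - 1.0),
            "neutrophil": np.exp(0.4 * rng.normal(size=n) - 2.0),
            "macrophage": np.exp(0.4 * rng.normal(size=n) - 1.8),
            "dendritic": np.exp(0.4 * rng.normal(size=n) - 1.2),
        },
        index=pd.Index(samples, name="sample_id"),
    )

    # --- truth --------------------------------------------------------------
    mirs = _mir_ids(cfg)
    key_mirs = {
        g: mirs[i * cfg.n_mirna_per_key : (i + 1) * cfg.n_mirna_per_key]
        for i, g in enumerate(key_genes)
    }
    pos = cfg.n_shared_keys * cfg.n_mirna_per_key
    branch_mirs = {}
    for g in cd4_genes + cd8_genes:
        branch_mirs[g] = mirs[pos]
        pos += 1
    decoy_mirs = mirs[pos : pos + 4]

    triads_cd4, triads_cd8 = [], []
    for lnc in lnc_shared:
        for g in key_genes:
            for m in key_mirs[g]:
                triads_cd4.append((lnc, m, g))
                triads_cd8.append((lnc, m, g))
    for lnc, partners in (
        (lnc_cd4[0], cd4_genes[:half]),
        (lnc_cd4[1], cd4_genes[half:]),
    ):
        triads_cd4.extend((lnc, branch_mirs[g], g) for g in partners)
    for lnc, partners in (
        (lnc_cd8[0], cd8_genes[:half]),
        (lnc_cd8[1], cd8_genes[half:]),
    ):
        triads_cd8.extend((lnc, branch_mirs[g], g) for g in partners)

    decoys = [
        {
            "kind": "coexpression",
            "lncRNA": lnc_decoy["cd4"],
            "miRNA": decoy_mirs[0],
            "mRNA": cd4_genes[0],
            "fails": "lncRNA-mRNA correlation <= 0.7",
        },
        {
            "kind": "coexpression",
            "lncRNA": lnc_decoy["cd8"],
            "miRNA": decoy_mirs[1],
            "mRNA": cd8_genes[0],
            "fails": "lncRNA-mRNA correlation <= 0.7",
        },
        {
            "kind": "score",
            "lncRNA": lnc_shared[0],
            "miRNA": decoy_mirs[2],
            "mRNA": key_genes[0],
            "fails": "lncRNA-miRNA score <= 0.9",
        },
        {
            "kind": "db_count",
            "lncRNA": lnc_shared[0],
            "miRNA": decoy_mirs[3],
            "mRNA": key_genes[0],
            "fails": "miRNA-mRNA supported by < 5 databases",
        },
    ]

    planted_rho = {g: cfg.planted_rho for g in cd4_genes + cd8_genes}
    planted_rho.update({g: cfg.shared_rho for g in key_genes})

    truth = TruthRecord(
        prognostic_gene=cfg.prognostic_gene,
        hazard_ratio=cfg.hazard_ratio,
        high_samples=[s for s, h in zip(samples, high) if h],
        de_mrna_up=cd4_genes + cd8_genes + key_genes + extra_up,
        de_mrna_down=list(down_genes),
        de_lnc_up=lnc_cd4 + lnc_cd8 + lnc_shared + list(lnc_decoy.values()) + lnc_extra_up,
        de_lnc_down=list(lnc_down),
        module_cd4=cd4_genes + key_genes,
        module_cd8=cd8_genes + key_genes,
        key_genes=key_genes,
        module_lnc_cd4=lnc_cd4 + lnc_shared + [lnc_decoy["cd4"]],
        module_lnc_cd8=lnc_cd8 + lnc_shared + [lnc_decoy["cd8"]],
        shared_lnc=lnc_shared,
        planted_rho=planted_rho,
        triads_cd4=sorted(set(triads_cd4)),
        triads_cd8=sorted(set(triads_cd8)),
        decoys=decoys,
    )
    return matrix, survival, clinical, infiltration, truth


def generate_prediction_dbs(cfg: SimConfig, truth: TruthRecord) -> PredictionDB:
    """Prediction tables: planted triads pass, decoys near-miss, rest noise."""
    rng = np.random.default_rng([cfg.seed, 1])
    lnc_mir_rows: list[dict] = []
    mir_mrna_rows: list[dict] = []

    def add_lnc_mir(lnc, mir, score):
        lnc_mir_rows.append({"lncRNA": lnc, "miRNA": mir, "score": round(float(score), 4)})

    def add_mir_mrna(mir, mrna, n_sources):
        flags = {s: 0 for s in PREDICTION_SOURCES}
        for s in rng.choice(PREDICTION_SOURCES, size=n_sources, replace=False):
            flags[s] = 1
        mir_mrna_rows.append({"miRNA": mir, "mRNA": mrna, **flags})

    seen_lm, seen_mm = set(), set()
    for triads in (truth.triads_cd4, truth.triads_cd8):
        for lnc, mir, mrna in triads:
            if (lnc, mir) not in seen_lm:
                seen_lm.add((lnc, mir))
                add_lnc_mir(lnc, mir, rng.uniform(0.92, 0.99))
            if (mir, mrna) not in seen_mm:
                seen_mm.add((mir, mrna))
                add_mir_mrna(mir, mrna, 6)

    for d in truth.decoys:
        lnc, mir, mrna = d["lncRNA"], d["miRNA"], d["mRNA"]
        score = rng.uniform(0.85, 0.90) if d["kind"] == "score" else rng.uniform(0.92, 0.99)
        n_src = int(rng.integers(3, 5)) if d["kind"] == "db_count" else 6
        seen_lm.add((lnc, mir))
        seen_mm.add((mir, mrna))
        add_lnc_mir(lnc, mir, score)
        add_mir_mrna(mir, mrna, n_src)

    lncs, mirs = _lnc_ids(cfg), _mir_ids(cfg)
    mrnas = _mrna_ids(cfg)
    n_bg = 0
    while n_bg < cfg.background_lnc_mir:
        pair = (str(rng.choice(lncs)), str(rng.choice(mirs)))
        if pair in seen_lm:
            continue
        seen_lm.add(pair)
        add_lnc_mir(*pair, rng.uniform(0.0, 0.88))
        n_bg += 1
    n_bg = 0
    while n_bg < cfg.background_mir_mrna:
        pair = (str(rng.choice(mirs)), str(rng.choice(mrnas)))
        if pair in seen_mm:
            continue
        seen_mm.add(pair)
        add_mir_mrna(*pair, int(rng.integers(0, 5)))
        n_bg += 1

    return PredictionDB(pd.DataFrame(lnc_mir_rows), pd.DataFrame(mir_mrna_rows))


def generate_gene_sets(cfg: SimConfig, truth: TruthRecord) -> dict[str, list[str]]:
    """A planted immune-module set plus random background sets."""
    rng = np.random.default_rng([cfg.seed, 2])
    module = sorted(set(truth.module_cd4 + truth.module_cd8))
    background = [
        g for g in _mrna_ids(cfg)
        if g not in set(truth.de_mrna_up) | set(truth.de_mrna_down)
    ]
    sets = {"SET_IMMUNE_MODULE": module}
    for i in range(1, cfg.n_random_gene_sets + 1):
        members = rng.choice(background, size=cfg.gene_set_size, replace=False)
        sets[f"SET_RANDOM_{i:02d}"] = sorted(str(m) for m in members)
    return sets


def generate_validation_cohorts(cfg: SimConfig, truth: TruthRecord) -> dict[str, pd.DataFrame]:
    """Two independent cohorts with planted key-gene/checkpoint correlation."""
    rng = np.random.default_rng([cfg.seed, 3])
    cohorts = {}
    rho = cfg.validation_rho
    for name in ("cohortA", "cohortB"):
        n = cfg.validation_n
        samples = [f"{name}_{i:03d}" for i in range(1, n + 1)]
        z = rng.normal(size=n)
        rows = {truth.prognostic_gene: 5.0 + z}
        for g in truth.key_genes:
            rows[g] = 4.0 + rho * z + math.sqrt(1.0 - rho**2) * rng.normal(size=n)
        for i in range(20):  # uncorrelated filler genes
            rows[f"VAL{i:03d}"] = 3.0 + rng.normal(size=n)
        cohorts[name] = pd.DataFrame(rows, index=samples).T
    return cohorts


def generate_bundle(cfg: SimConfig) -> Bundle:
    """The complete seeded study bundle."""
    matrix, survival, clinical, infiltration, truth = generate_cohort(cfg)
    return Bundle(
        expression=matrix,
        survival=survival,
        clinical=clinical,
        infiltration=infiltration,
        predictions=generate_prediction_dbs(cfg, truth),
        gene_sets=generate_gene_sets(cfg, truth),
        validation_cohorts=generate_validation_cohorts(cfg, truth),
        truth=truth,
        config=cfg,
    )
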