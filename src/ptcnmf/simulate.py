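"""Synthetic thyroid-cancer expression cohorts with planted metagene
structure and matched clinical tables.

The generator emulates the structure observed in papillary thyroid carcinoma
bulk transcriptomes: three nonnegative metagene signatures (a RAS-driven
program, an immune program, and a BRAF-driven program) mixed across four
sample clusters. Cluster archetypes follow the IR/ID layout — RAS-IR
(high RAS + high immune), RAS-ID (high RAS, low immune), BRAF-IR (high BRAF
+ high immune), BRAF-ID (high BRAF, low immune). Expression is the
nonnegative product basis x activity under multiplicative log-normal noise,
which keeps values nonnegative and mimics the mean-variance behaviour of
RSEM/FPKM estimates. Clinical covariates, cluster-linked recurrence and
exponential follow-up times give every downstream statistical stage a ground
truth to recover.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .readwrite import ExpressionMatrix, write_expression_tsv

logger = logging.getLogger(__name__)

CLUSTER_NAMES = ("NMF1", "NMF2", "NMF3", "NMF4")
CLUSTER_LABELS = ("RAS-IR", "RAS-ID", "BRAF-IR", "BRAF-ID")

# immune markers planted on the immune signature: cytolytic effectors,
# checkpoints, and the chemokines that top immune-metagene rankings
DEFAULT_IMMUNE_GENES = ("GZMA", "PRF1", "CD274", "CTLA4", "CCL19", "CCL21")

# per-cluster mean activity of (RAS, immune, BRAF) signatures; columns are
# the four archetypes RAS-IR, RAS-ID, BRAF-IR, BRAF-ID
_ARCHETYPES = np.array([
    [10.0, 10.0, 1.0, 1.0],   # RAS signature
    [8.0, 1.0, 8.0, 1.0],     # immune signature
    [1.0, 1.0, 10.0, 10.0],   # BRAF signature
])


class ConfigError(ValueError):
    """Raised for inconsistent generator configuration."""


@dataclass
class SyntheticConfig:
    """Study-condition parameters for cohort generation.

    Cluster proportions default to those observed across the four NMF
    clusters of the TCGA thyroid cohort; recurrence rates default to the
    published 13.1% in the BRAF-IR (NMF3) cluster versus 5.8% elsewhere.
    Follow-up is in months.
    """

    n_genes: int = 2000
    n_samples: int = 400
    k: int = 3
    cluster_proportions: tuple = (0.13, 0.19, 0.32, 0.36)
    signature_sparsity: float = 0.05
    noise_sd: float = 0.2
    immune_gene_ids: tuple = DEFAULT_IMMUNE_GENES
    recurrence_rate_by_cluster: tuple = (0.058, 0.058, 0.131, 0.058)
    censoring_rate: float = 0.2
    followup_window: float = 120.0
    event_time_scale_by_cluster: tuple = (60.0, 60.0, 36.0, 60.0)
    normal_fraction_cluster1: float = 0.15
    leukocyte_corr: float = 0.8
    activity_dispersion: float = 1 / 3  # within-cluster CV of signature activity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError("k must be >= 2")
        if self.k != 3:
            raise ConfigError("the four-cluster IR/ID layout requires k = 3 signatures")
        if len(self.cluster_proportions) != 4:
            raise ConfigError("cluster_proportions must have 4 entries")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-8:
            raise ConfigError("cluster_proportions must sum to 1")
        for r in (*self.recurrence_rate_by_cluster, self.censoring_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        if self.n_genes < self.k * 10:
            raise ConfigError("n_genes too small for the signature block layout")


@dataclass
class SyntheticCohort:
    """A generated cohort with full ground truth."""

    expression: ExpressionMatrix
    true_basis: pd.DataFrame          # genes x k
    true_activity: pd.DataFrame       # k x samples
    true_cluster: pd.Series           # NMF1..NMF4 per sample
    driver_label: pd.Series           # RAS-like / BRAF-like / normal
    clinical: pd.DataFrame
    features: pd.DataFrame            # planted external immune features
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


def _gene_names(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    """Gene ids with immune markers embedded inside the immune block."""
    names = [f"G{i:05d}" for i in range(cfg.n_genes)]
    block = max(int(cfg.signature_sparsity * cfg.n_genes), cfg.k * 3)
    # dominant blocks: signature s owns genes [s*block, (s+1)*block)
    immune_block = np.arange(block, 2 * block)
    slots = rng.choice(immune_block, size=len(cfg.immune_gene_ids), replace=False)
    for slot, g in zip(slots, cfg.immune_gene_ids):
        names[slot] = g
    return names, np.full(cfg.n_genes, block)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a cohort under the configured study conditions.

    Deterministic for a fixed seed. With ``noise_sd=0`` the expression matrix
    equals ``basis @ activity`` exactly.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, m, k = cfg.n_genes, cfg.n_samples, cfg.k
    block = max(int(cfg.signature_sparsity * n), k * 3)

    gene_ids, _ = _gene_names(cfg, rng)
    sample_ids = [f"S{j:04d}" for j in range(m)]

    # sparse nonnegative basis: gamma loadings on a disjoint dominant block
    # per signature plus a small dense background
    W = rng.gamma(shape=2.0, scale=0.005, size=(n, k))
    for s in range(k):
        rows = slice(s * block, (s + 1) * block)
        W[rows, s] = rng.gamma(shape=2.0, scale=1.0, size=block) + 0.5

    # cluster memberships and activity archetypes with multiplicative jitter
    cluster_idx = rng.choice(4, size=m, p=np.asarray(cfg.cluster_proportions))
    # multiplicative gamma jitter sets the within-cluster activity spread;
    # the default ~33% CV is typical of bulk tumour signature dispersion and
    # keeps the planted rank identifiable while leaving over-complete
    # factorizations unstable
    shape = 1.0 / cfg.activity_dispersion ** 2
    jitter = rng.gamma(shape=shape, scale=1 / shape, size=(k, m))
    H = _ARCHETYPES[:, cluster_idx] * jitter

    clean = W @ H
    noise = np.exp(rng.normal(0.0, cfg.noise_sd, size=(n, m))) if cfg.noise_sd > 0 else 1.0
    X = clean * noise

    expression = ExpressionMatrix(
        pd.DataFrame(X, index=gene_ids, columns=sample_ids), scale="linear")

    true_cluster = pd.Series([CLUSTER_NAMES[c] for c in cluster_idx],
                             index=sample_ids, name="true_cluster")
    driver = np.where(cluster_idx < 2, "RAS-like", "BRAF-like")
    # some normal thyroid profiles co-cluster with RAS-like tumours
    in_c1 = np.flatnonzero(cluster_idx == 0)
    n_normal = int(round(cfg.normal_fraction_cluster1 * in_c1.size))
    if n_normal:
        normals = rng.choice(in_c1, size=n_normal, replace=False)
        driver = driver.astype(object)
        driver[normals] = "normal"
    driver_label = pd.Series(driver, index=sample_ids, name="driver_label")

    clinical = _clinical_table(cfg, rng, cluster_idx, driver_label, sample_ids)
    features = _feature_table(cfg, rng, H, sample_ids)

    return SyntheticCohort(
        expression=expression,
        true_basis=pd.DataFrame(W, index=gene_ids,
                                columns=["RAS", "Immune", "BRAF"]),
        true_activity=pd.DataFrame(H, index=["RAS", "Immune", "BRAF"],
                                   columns=sample_ids),
        true_cluster=true_cluster,
        driver_label=driver_label,
        clinical=clinical,
        features=features,
        config=cfg,
    )


def _clinical_table(cfg, rng, cluster_idx, driver_label, sample_ids) -> pd.DataFrame:
    """Clinical covariates with cluster-linked recurrence and follow-up."""
    m = len(sample_ids)
    rates = np.asarray(cfg.recurrence_rate_by_cluster)[cluster_idx]
    recurrence = (rng.uniform(size=m) < rates).astype(int)

    scales = np.asarray(cfg.event_time_scale_by_cluster)[cluster_idx]
    event_time = rng.exponential(scales)
    censor_time = rng.uniform(0.0, cfg.followup_window, size=m)
    time = np.where(recurrence == 1, np.maximum(event_time, 0.01), censor_time)
    event = recurrence.copy()
    # administrative censoring of a fraction of the recurrent samples
    admin = (rng.uniform(size=m) < cfg.censoring_rate) & (recurrence == 1)
    cut = censor_time < time
    drop = admin & cut
    event[drop] = 0
    time[drop] = censor_time[drop]

    age = np.clip(rng.normal(47, 14, size=m), 18, 90).round().astype(int)
    sex = rng.choice(["Female", "Male"], size=m, p=[0.73, 0.27])

    variant = np.empty(m, dtype=object)
    for j, c in enumerate(cluster_idx):
        if c in (0, 1):
            variant[j] = rng.choice(["Follicular variant", "Classic"], p=[0.6, 0.4])
        elif c == 2:
            variant[j] = rng.choice(["Classic", "Tall cell variant"], p=[0.75, 0.25])
        else:
            variant[j] = rng.choice(["Classic", "Tall cell variant"], p=[0.94, 0.06])

    braf_side = np.isin(cluster_idx, (2, 3))
    ete = (rng.uniform(size=m) < np.where(braf_side, 0.4, 0.1)).astype(int)
    pn1 = (rng.uniform(size=m) < np.where(braf_side, 0.5, 0.12)).astype(int)
    pt = rng.choice(["pT1", "pT2", "pT3", "pT4"], size=m, p=[0.3, 0.34, 0.32, 0.04])
    stage = rng.choice(["stage 1", "stage 2", "stage 3", "stage 4"],
                       size=m, p=[0.57, 0.10, 0.22, 0.11])
    mutations = rng.poisson(np.where(braf_side, 13.0, 9.0))

    return pd.DataFrame({
        "sample_id": sample_ids,
        "age": age,
        "sex": sex,
        "histologic_variant": variant,
        "extrathyroidal_extension": ete,
        "pT": pt,
        "pN": np.where(pn1 == 1, "pN1", "pN0/NX"),
        "stage": stage,
        "driver_class": driver_label.values,
        "mutation_count": mutations,
        "cluster": [CLUSTER_NAMES[c] for c in cluster_idx],
        "recurrence": recurrence,
        "followup_time": time,
        "event": event,
    }).set_index("sample_id")


def _feature_table(cfg, rng, H, sample_ids) -> pd.DataFrame:
    """External immune features correlated with the planted immune activity."""
    m = len(sample_ids)
    immune = H[1]
    z = (immune - immune.mean()) / immune.std()

    def planted(r, loc, scale, floor=None):
        x = r * z + np.sqrt(max(1 - r * r, 0.0)) * rng.normal(size=m)
        x = loc + scale * x
        return np.clip(x, floor, None) if floor is not None else x

    leuk = np.clip(planted(cfg.leukocyte_corr, 0.12, 0.08), 0.0, 1.0)
    purity = np.clip(planted(-0.7, 0.75, 0.12), 0.05, 1.0)
    tcr = np.exp(planted(0.73, 3.0, 0.8))
    return pd.DataFrame({
        "sample_id": sample_ids,
        "tumor_purity": purity,
        "leukocyte_fraction": leuk,
        "tcr_richness": tcr,
    }).set_index("sample_id")


def write_cohort(cohort: SyntheticCohort, directory, overwrite: bool = False) -> dict[str, Path]:
    """Write expression, clinical, feature and truth files plus a manifest."""
    out = Path(directory)
    if out.exists() and not overwrite:
        if any(out.iterdir()):
            raise FileExistsError(f"{out} exists and is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.csv",
        "features": out / "features.csv",
        "true_basis": out / "truth_basis.csv",
        "true_activity": out / "truth_activity.csv",
        "true_labels": out / "truth_labels.csv",
        "manifest": out / "manifest.json",
    }
    write_expression_tsv(cohort.expression, paths["expression"])
    cohort.clinical.to_csv(paths["clinical"])
    cohort.features.to_csv(paths["features"])
    cohort.true_basis.to_csv(paths["true_basis"])
    cohort.true_activity.to_csv(paths["true_activity"])
    pd.DataFrame({"true_cluster": cohort.true_cluster,
                  "driver_label": cohort.driver_label}).to_csv(paths["true_labels"])
    manifest = dataclasses.asdict(cohort.config) if cohort.config else {}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=list))
    logger.info("wrote cohort (%d genes x %d samples) to %s",
                cohort.expression.n_genes, cohort.expression.n_samples, out)
    return paths
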