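"""Expression-based immunoprofiling: cytolytic activity, gene-set signature
scores, reference-based immune cell fractions, feature-signature
correlations, and pre-ranked enrichment of metagene weights.

The cytolytic activity (CYT) score is the geometric mean of GZMA and PRF1
expression on linear scale. Immune/stromal signature scores are mean
per-gene z-scores over a gene set (a transparent surrogate for
single-sample enrichment scores). Immune cell fractions are estimated by
nonnegative least squares against a reference expression profile of sorted
cell types, library-size normalised on the shared genes — a deliberately
simple deconvolution whose outputs should be read as relative abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .classify import ClusterAssignment
from .nmf import MetageneActivity
from .readwrite import ExpressionMatrix

logger = logging.getLogger(__name__)


class GeneLookupError(KeyError):
    """Raised when a required gene is absent from the matrix."""


class ScoringError(ValueError):
    """Raised when a gene set has no overlap with the expression matrix."""


class DeconvolutionError(ValueError):
    """Raised when the reference overlap is insufficient for NNLS."""


@dataclass
class ReferenceProfile:
    """Genes x cell-types reference expression (linear scale)."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        if self.profiles.index.has_duplicates:
            raise ValueError("duplicate gene ids in reference profile")
        if (self.profiles.sum(axis=0) <= 0).any():
            raise ValueError("reference has an all-zero cell-type column")

    @property
    def gene_ids(self) -> list[str]:
        return self.profiles.index.tolist()

    @property
    def cell_type_names(self) -> list[str]:
        return self.profiles.columns.tolist()


def cyt_score(E: ExpressionMatrix, gzma_id: str = "GZMA", prf1_id: str = "PRF1",
              offset: float = 0.01) -> pd.Series:
    """Cytolytic activity: geometric mean of GZMA and PRF1 linear expression.

    ``offset`` avoids zero scores for samples with no detected transcripts.
    """
    if E.scale != "linear":
        raise ValueError("cyt_score requires linear-scale expression")
    for g in (gzma_id, prf1_id):
        if g not in E.data.index:
            raise GeneLookupError(f"gene {g!r} not found in expression matrix")
    a = E.data.loc[gzma_id].astype(float) + offset
    b = E.data.loc[prf1_id].astype(float) + offset
    return np.sqrt(a * b).rename("cyt_score")


def signature_score(E: ExpressionMatrix, gene_set: list[str],
                    name: str = "signature_score") -> pd.Series:
    """Mean per-gene z-score of a gene set (log-scale expression).

    Genes absent from the matrix are dropped (count logged); zero-variance
    genes contribute a z-score of 0.
    """
    present = [g for g in dict.fromkeys(gene_set) if g in E.data.index]
    if not present:
        raise ScoringError("gene set has no overlap with the expression matrix")
    if len(present) < len(set(gene_set)):
        logger.info("signature_score: %d/%d set genes present",
                    len(present), len(set(gene_set)))
    sub = E.data.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=0)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd.replace(0.0, np.inf), axis=0)
    return z.mean(axis=0).rename(name)


def nnls_cell_fractions(E: ExpressionMatrix, R: ReferenceProfile,
                        min_overlap: int = 50) -> pd.DataFrame:
    """Per-sample immune cell fractions by nonnegative least squares.

    Sample and reference columns are normalised to equal library size on the
    shared genes; each sample solves ``min ||R f - e||_2, f >= 0`` and ``f``
    is renormalised to sum to 1. Returns cell-types x samples fractions with
    a ``residual_norm`` row appended.
    """
    shared = [g for g in R.gene_ids if g in E.data.index]
    if len(shared) < min_overlap:
        raise DeconvolutionError(
            f"only {len(shared)} genes shared with the reference (minimum {min_overlap})")
    # the reference is taken as already being on a common scale; each sample
    # is rescaled to the reference's mean column sum so the solution is
    # invariant to the sample's library size
    Rm = R.profiles.loc[shared].to_numpy(dtype=float)
    Em = E.data.loc[shared].to_numpy(dtype=float)
    target = Rm.sum(axis=0).mean()

    fracs = np.zeros((Rm.shape[1], Em.shape[1]))
    resid = np.zeros(Em.shape[1])
    for j in range(Em.shape[1]):
        e = Em[:, j]
        tot = e.sum()
        if tot <= 0:
            raise DeconvolutionError(f"sample {E.sample_ids[j]!r} is all zero")
        e = e / tot * target
        f, rnorm = nnls(Rm, e)
        s = f.sum()
        fracs[:, j] = f / s if s > 0 else 0.0
        resid[j] = rnorm
    out = pd.DataFrame(fracs, index=R.cell_type_names, columns=E.sample_ids)
    out.loc["residual_norm"] = resid
    return out


def feature_signature_correlation(H: MetageneActivity,
                                  features: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between each metagene signature and each immune feature.

    Missing feature values are handled pairwise-complete; zero-variance
    pairs are reported as NaN with a warning.
    """
    shared = [s for s in H.sample_ids if s in features.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    levels = pd.DataFrame(H.levels, index=H.signature_names,
                          columns=H.sample_ids)[shared]
    out = pd.DataFrame(index=H.signature_names, columns=features.columns, dtype=float)
    for feat in features.columns:
        y = features.loc[shared, feat].astype(float)
        ok = y.notna().values
        for sig in H.signature_names:
            x = levels.loc[sig].values[ok]
            yy = y.values[ok]
            if ok.sum() < 3 or np.std(x) == 0 or np.std(yy) == 0:
                logger.warning("correlation undefined for (%s, %s)", sig, feat)
                out.loc[sig, feat] = np.nan
            else:
                out.loc[sig, feat] = float(np.corrcoef(x, yy)[0, 1])
    return out


def enrichment_running_sum(ranked_genes: list[str], weights: np.ndarray,
                           gene_set: set[str], exponent: float = 1.0) -> np.ndarray:
    """Weighted Kolmogorov-Smirnov running sum along a gene ranking."""
    in_set = np.array([g in gene_set for g in ranked_genes])
    if not in_set.any():
        raise ScoringError("gene set does not overlap the ranking")
    w = np.abs(np.asarray(weights, dtype=float)) ** exponent
    hit = np.where(in_set, w, 0.0)
    hit_total = hit.sum()
    if hit_total == 0:
        hit = in_set.astype(float)
        hit_total = hit.sum()
    miss = (~in_set).astype(float)
    n_miss = miss.sum()
    if n_miss > 0:
        miss_term = miss / n_miss
    else:
        # set covers the whole ranking: compare against the uniform walk so
        # the running sum returns to 0
        miss_term = np.full(len(in_set), 1.0 / len(in_set))
    running = np.cumsum(hit / hit_total - miss_term)
    return running


def preranked_enrichment(ranked_genes: list[str], weights: np.ndarray,
                         gene_set: list[str], n_perm: int = 1000,
                         seed: int = 0) -> tuple[float, float]:
    """Pre-ranked enrichment score of a gene set against weighted rankings.

    ES is the maximum-deviation value of the weighted KS running sum
    (weight exponent 1). The p-value permutes gene labels and uses the
    plus-one estimator ``(1 + #{|ES*| >= |ES|}) / (n_perm + 1)``, so it is
    never 0 and never below ``1/(n_perm+1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = list(ranked_genes)
    gset = set(gene_set)
    running = enrichment_running_sum(genes, weights, gset)
    es = float(running[np.argmax(np.abs(running))])

    rng = np.random.default_rng(seed)
    n = len(genes)
    m = int(sum(g in gset for g in genes))
    idx = np.arange(n)
    hits = np.array([g in gset for g in genes])
    w = np.abs(np.asarray(weights, dtype=float))
    count = 0
    for _ in range(n_perm):
        perm_hits = np.zeros(n, dtype=bool)
        perm_hits[rng.choice(idx, size=m, replace=False)] = True
        hit = np.where(perm_hits, w, 0.0)
        ht = hit.sum()
        if ht == 0:
            hit = perm_hits.astype(float)
            ht = hit.sum()
        miss = (~perm_hits).astype(float)
        nm = miss.sum()
        miss_term = miss / nm if nm > 0 else np.full(n, 1.0 / n)
        run = np.cumsum(hit / ht - miss_term)
        es_p = run[np.argmax(np.abs(run))]
        if abs(es_p) >= abs(es) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return es, p


def cluster_feature_summary(features: pd.DataFrame,
                            assignment: ClusterAssignment,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Per-cluster feature means with a one-way ANOVA p-value per feature.

    Features with p below ``alpha`` are flagged for display; degenerate
    features (constant, or fewer than two populated clusters) are skipped
    with a warning.
    """
    labels = assignment.to_frame()["cluster"]
    shared = [s for s in labels.index if s in features.index]
    labels = labels.loc[shared]
    rows = []
    for feat in features.columns:
        y = features.loc[shared, feat].astype(float)
        groups = [y[labels == c].dropna().values for c in sorted(labels.unique())]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            logger.warning("feature %r skipped: fewer than 2 usable clusters", feat)
            continue
        if all(np.allclose(g, np.concatenate(groups).mean()) for g in groups):
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*groups)
        row = {"feature": feat, "F": float(f_stat), "p": float(p),
               "significant": bool(p < alpha)}
        for c in sorted(labels.unique()):
            row[f"mean_{c}"] = float(y[labels == c].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
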