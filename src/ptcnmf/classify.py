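"""From metagene activities to the four named tumour clusters, and
projection of a learned basis onto external cohorts.

Samples are clustered hierarchically (Ward linkage on per-signature
z-scored activities) and the tree is cut at four clusters. Signatures are
annotated RAS / Immune / BRAF from their contrast between RAS-like and
BRAF-like driver classes, with the immune signature cross-checked against an
immune marker score. Clusters are then labelled RAS-IR, RAS-ID, BRAF-IR,
BRAF-ID: the RAS/BRAF side comes from the dominant driver signature, IR/ID
from the within-side ranking of mean immune activity. The fixed
correspondence NMF1=RAS-IR, NMF2=RAS-ID, NMF3=BRAF-IR, NMF4=BRAF-ID is
applied throughout.

External cohorts are classified by metagene projection: activities are the
Moore-Penrose pseudoinverse of the basis applied to the new expression
matrix, with negative entries clamped to zero (or solved nonnegatively when
``mode='nnls'``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls

from .nmf import MetageneActivity, MetageneBasis
from .readwrite import ExpressionMatrix, align_genes

logger = logging.getLogger(__name__)

LABEL_BY_CLUSTER = {"NMF1": "RAS-IR", "NMF2": "RAS-ID",
                    "NMF3": "BRAF-IR", "NMF4": "BRAF-ID"}
CLUSTER_BY_LABEL = {v: k for k, v in LABEL_BY_CLUSTER.items()}


class AnnotationError(ValueError):
    """Raised when signature roles cannot be resolved unambiguously."""


class LabelingError(ValueError):
    """Raised when the four clusters cannot be split into IR/ID pairs."""


class ProjectionError(ValueError):
    """Raised when gene overlap is insufficient for metagene projection."""


@dataclass
class SignatureAnnotation:
    """Mapping of signature names to RAS / Immune / BRAF roles."""

    roles: dict[str, str]                 # signature_name -> role
    evidence: pd.DataFrame                # mean activity by driver class

    def __post_init__(self) -> None:
        if sorted(self.roles.values()) != ["BRAF", "Immune", "RAS"]:
            raise AnnotationError(
                f"roles must be a bijection onto RAS/Immune/BRAF, got {self.roles}")

    def signature_for(self, role: str) -> str:
        for sig, r in self.roles.items():
            if r == role:
                return sig
        raise KeyError(role)


@dataclass
class ClusterAssignment:
    """Per-sample NMF1-4 membership with the IR/ID driver labels."""

    sample_ids: list[str]
    cluster: list[str]
    label: list[str]

    def __post_init__(self) -> None:
        for c, l in zip(self.cluster, self.label):
            if LABEL_BY_CLUSTER.get(c) != l:
                raise ValueError(f"cluster {c} paired with label {l}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cluster": self.cluster, "label": self.label},
                            index=pd.Index(self.sample_ids, name="sample_id"))


def cluster_samples(H: MetageneActivity, n_clusters: int = 4,
                    method: str = "ward") -> np.ndarray:
    """Hierarchical clustering of samples on z-scored signature activities.

    Returns raw integer cluster ids (1..n_clusters); deterministic for a
    fixed input.
    """
    X = H.levels.T.astype(float)  # samples x k
    if n_clusters > X.shape[0]:
        raise ValueError(f"n_clusters={n_clusters} exceeds {X.shape[0]} samples")
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    tree = linkage(Z, method=method)
    return fcluster(tree, t=n_clusters, criterion="maxclust")


def annotate_signatures(
    H: MetageneActivity,
    driver_label: pd.Series,
    immune_marker_score: pd.Series,
) -> SignatureAnnotation:
    """Resolve RAS / Immune / BRAF roles for three signatures.

    The RAS signature maximises mean activity in RAS-like minus BRAF-like
    samples; the BRAF signature maximises the reverse contrast; the
    remaining signature is Immune and should correlate best with the immune
    marker score (warned otherwise).
    """
    if H.k != 3:
        raise AnnotationError("role annotation requires exactly 3 signatures")
    levels = pd.DataFrame(H.levels, index=H.signature_names, columns=H.sample_ids)
    driver = driver_label.reindex(H.sample_ids)
    ras_mask = (driver == "RAS-like").values
    braf_mask = (driver == "BRAF-like").values
    if not ras_mask.any() or not braf_mask.any():
        raise AnnotationError("both RAS-like and BRAF-like samples are required")

    contrast = levels.values[:, ras_mask].mean(axis=1) - levels.values[:, braf_mask].mean(axis=1)
    ras_idx = int(np.argmax(contrast))
    braf_idx = int(np.argmax(-contrast))
    if ras_idx == braf_idx:
        raise AnnotationError("RAS/BRAF contrasts select the same signature")
    immune_idx = ({0, 1, 2} - {ras_idx, braf_idx}).pop()

    marker = immune_marker_score.reindex(H.sample_ids).astype(float).values
    cors = [np.corrcoef(levels.values[i], marker)[0, 1] for i in range(3)]
    if int(np.nanargmax(cors)) != immune_idx:
        logger.warning(
            "immune marker score correlates best with %s, not the inferred "
            "immune signature %s (r=%s)",
            H.signature_names[int(np.nanargmax(cors))],
            H.signature_names[immune_idx], np.round(cors, 3))

    roles = {H.signature_names[ras_idx]: "RAS",
             H.signature_names[immune_idx]: "Immune",
             H.signature_names[braf_idx]: "BRAF"}
    evidence = pd.DataFrame({
        "mean_RAS_like": levels.values[:, ras_mask].mean(axis=1),
        "mean_BRAF_like": levels.values[:, braf_mask].mean(axis=1),
        "marker_correlation": cors,
    }, index=H.signature_names)
    return SignatureAnnotation(roles, evidence)


def label_clusters(
    raw_clusters: np.ndarray,
    annotation: SignatureAnnotation,
    H: MetageneActivity,
) -> ClusterAssignment:
    """Name four raw clusters RAS-IR / RAS-ID / BRAF-IR / BRAF-ID.

    The two clusters with the highest mean (RAS - BRAF) activity form the
    RAS side, the other two the BRAF side; within each side the cluster with
    the higher mean immune activity is IR, the other ID. Ties in either
    ranking are reported as errors.
    """
    raw = np.asarray(raw_clusters)
    ids = np.unique(raw)
    if ids.size != 4:
        raise LabelingError(f"expected 4 raw clusters, got {ids.size}")
    levels = pd.DataFrame(H.levels, index=H.signature_names, columns=H.sample_ids)
    ras = levels.loc[annotation.signature_for("RAS")].values
    braf = levels.loc[annotation.signature_for("BRAF")].values
    imm = levels.loc[annotation.signature_for("Immune")].values

    side_score = {c: (ras[raw == c] - braf[raw == c]).mean() for c in ids}
    imm_score = {c: imm[raw == c].mean() for c in ids}
    ordered = sorted(ids, key=lambda c: -side_score[c])
    if np.isclose(side_score[ordered[1]], side_score[ordered[2]]):
        raise LabelingError("RAS/BRAF side scores tie at the split point; "
                            f"scores={side_score}")
    ras_side, braf_side = ordered[:2], ordered[2:]
    sign_split = sum(side_score[c] > 0 for c in ids)
    if sign_split not in (2,):
        logger.warning("driver-contrast signs split %d/%d rather than 2/2; "
                       "using rank-based side assignment", sign_split, 4 - sign_split)

    mapping: dict[int, str] = {}
    for side, (ir, id_) in (("RAS", ("NMF1", "NMF2")), ("BRAF", ("NMF3", "NMF4"))):
        pair = ras_side if side == "RAS" else braf_side
        if np.isclose(imm_score[pair[0]], imm_score[pair[1]]):
            raise LabelingError(f"immune means tie within the {side} pair: "
                                f"{ {c: imm_score[c] for c in pair} }")
        hi, lo = sorted(pair, key=lambda c: -imm_score[c])
        mapping[hi], mapping[lo] = ir, id_

    cluster = [mapping[c] for c in raw]
    label = [LABEL_BY_CLUSTER[c] for c in cluster]
    return ClusterAssignment(list(H.sample_ids), cluster, label)


def project_metagenes(
    W: MetageneBasis,
    E_new: ExpressionMatrix,
    min_overlap_frac: float = 0.5,
    min_genes: int = 200,
    mode: str = "pinv",
) -> MetageneActivity:
    """Project an external cohort onto a fixed metagene basis.

    Genes are aligned to the basis; activities solve ``W h = v`` per sample
    via the Moore-Penrose pseudoinverse with negative entries clamped to 0
    (``mode='pinv'``), or by nonnegative least squares (``mode='nnls'``).
    """
    aligned = align_genes(E_new, W.gene_ids)
    shared = aligned.matrix.gene_ids
    frac = len(shared) / len(W.gene_ids)
    if frac < min_overlap_frac or len(shared) < min_genes:
        raise ProjectionError(
            f"gene overlap {len(shared)}/{len(W.gene_ids)} ({frac:.1%}) below "
            f"minimum ({min_overlap_frac:.0%}, floor {min_genes})")
    logger.info("projection gene overlap: %d/%d (%.1f%%)",
                len(shared), len(W.gene_ids), 100 * frac)

    idx = [W.gene_ids.index(g) for g in shared]
    Wa = W.weights[idx, :]
    V = aligned.matrix.values
    V = V - min(V.min(), 0.0)  # identical shift convention as factorization

    if np.linalg.matrix_rank(Wa) < W.k:
        logger.warning("aligned basis is rank-deficient; least-norm solution used")
    if mode == "pinv":
        Hn = np.linalg.pinv(Wa) @ V
        Hn = np.clip(Hn, 0.0, None)
    elif mode == "nnls":
        Hn = np.column_stack([nnls(Wa, V[:, j])[0] for j in range(V.shape[1])])
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    return MetageneActivity(E_new.sample_ids, Hn, signature_names=list(W.signature_names))


def classify_external(
    W: MetageneBasis,
    annotation: SignatureAnnotation,
    E_new: ExpressionMatrix,
    **project_kwargs,
) -> tuple[ClusterAssignment, MetageneActivity]:
    """Project an external cohort and assign the four named clusters."""
    H_new = project_metagenes(W, E_new, **project_kwargs)
    raw = cluster_samples(H_new, n_clusters=4)
    assignment = label_clusters(raw, annotation, H_new)
    return assignment, H_new
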