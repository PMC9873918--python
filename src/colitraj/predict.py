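"""Signature-derived sample features and cross-cohort histology prediction.

Each signature is reduced to a fixed 10-term feature vector per sample —
the first three principal components of the signature-restricted gene and
exon log2-CPM matrices, the median expression over the signature for each
level, and the two adaptive-immunity scores (VDJ read CPM and clonality).
A random forest regresses the histopathology score on these features in the
training cohort; validation cohorts are projected with the training loadings
(never refit) and scored by Spearman correlation, a kappa on disease-status
binarization, and permutation-importance rankings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold

from . import stats
from .io import Signature
from .stats import WeightedExpression

logger = logging.getLogger("colitraj")

GENE_PC_COLUMNS = ["PC1_gene", "PC2_gene", "PC3_gene"]
EXON_PC_COLUMNS = ["PC1_exon", "PC2_exon", "PC3_exon"]
FEATURE_COLUMNS = GENE_PC_COLUMNS + EXON_PC_COLUMNS + [
    "median_expression", "median_splice", "vdj_read_cpm", "vdj_clonality",
]


# ---------------------------------------------------------------------------
# principal components of a signature
# ---------------------------------------------------------------------------


@dataclass
class PCProjection:
    """Training-set loadings for projecting new samples onto signature PCs."""

    genes: list[str]
    means: np.ndarray              # per-gene training means
    loadings: np.ndarray           # genes x n components
    explained_variance_ratio: np.ndarray


def signature_pcs(
    we: WeightedExpression, signature: Signature, n: int = 3
) -> tuple[PCProjection, pd.DataFrame]:
    """PCA of the gene-centered, signature-restricted expression matrix.

    Samples are observations, signature genes are variables.  Component signs
    are fixed so each loading vector has a positive sum (first nonzero
    loading positive on a tie), making scores reproducible across runs.
    Returns the projection (for validation cohorts) and the training scores.
    """
    genes = [g for g in signature.genes if g in we.E.index]
    if not genes:
        raise ValueError(f"signature {signature.label!r} has no genes in the matrix")
    if len(genes) < n:
        warnings.warn(
            f"signature {signature.label!r}: only {len(genes)} genes; reducing "
            f"components from {n}"
        )
        n = len(genes)
    X = we.E.loc[genes].to_numpy().T          # samples x genes
    means = X.mean(axis=0)
    Xc = X - means
    # economy SVD; deterministic up to sign, which we fix below
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:n].T                               # genes x n
    for j in range(n):
        s = V[:, j].sum()
        if s < 0 or (s == 0 and V[np.nonzero(V[:, j])[0][0], j] < 0):
            V[:, j] = -V[:, j]
    scores = Xc @ V
    var = S ** 2
    evr = var[:n] / var.sum() if var.sum() > 0 else np.zeros(n)
    proj = PCProjection(genes=genes, means=means, loadings=V,
                        explained_variance_ratio=evr)
    cols = [f"PC{j + 1}" for j in range(n)]
    return proj, pd.DataFrame(scores, index=we.E.columns, columns=cols)


def project_pcs(proj: PCProjection, we: WeightedExpression) -> pd.DataFrame:
    """Project samples onto training loadings (centering by training means)."""
    missing = [g for g in proj.genes if g not in we.E.index]
    if missing:
        raise ValueError(f"projection genes missing from matrix: {missing[:5]}")
    X = we.E.loc[proj.genes].to_numpy().T
    scores = (X - proj.means) @ proj.loadings
    cols = [f"PC{j + 1}" for j in range(proj.loadings.shape[1])]
    return pd.DataFrame(scores, index=we.E.columns, columns=cols)


def median_score(we: WeightedExpression, signature: Signature) -> pd.Series:
    """Per-sample median log2-CPM over the signature genes."""
    genes = [g for g in signature.genes if g in we.E.index]
    if not genes:
        raise ValueError(f"signature {signature.label!r} disjoint from matrix")
    return we.E.loc[genes].median(axis=0)


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


@dataclass
class FeatureBuilder:
    """Holds everything fitted on the training cohort.

    ``exon_proj`` is ``None`` when the exon signature was empty after
    intersection; exon PC and median-splice columns are then zero-filled and
    the degenerate path recorded in ``flags``.
    """

    gene_signature: Signature
    exon_signature: Signature | None
    gene_proj: PCProjection
    exon_proj: PCProjection | None
    flags: list[str] = field(default_factory=list)


def fit_feature_builder(
    we_gene: WeightedExpression,
    we_exon: WeightedExpression,
    gene_signature: Signature,
    exon_signature: Signature | None,
    n_pcs: int = 3,
) -> FeatureBuilder:
    gene_proj, _ = signature_pcs(we_gene, gene_signature, n=n_pcs)
    exon_proj = None
    flags: list[str] = []
    if exon_signature is not None and any(
        g in we_exon.E.index for g in exon_signature.genes
    ):
        exon_proj, _ = signature_pcs(we_exon, exon_signature, n=n_pcs)
    else:
        flags.append("exon_signature_empty")
        warnings.warn("exon signature empty: exon feature columns zero-filled")
    return FeatureBuilder(gene_signature, exon_signature, gene_proj, exon_proj, flags)


def build_features(
    builder: FeatureBuilder,
    we_gene: WeightedExpression,
    we_exon: WeightedExpression,
    vdj_profile: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the 10-column feature table for one cohort.

    Validation cohorts are projected with the training loadings, never refit.
    Every sample must appear in all sources; missing-clonality samples (no
    detected clones) get clonality 0.
    """
    samples = list(we_gene.E.columns)
    for name, available in (
        ("exon expression", set(we_exon.E.columns)),
        ("vdj profile", set(vdj_profile.index)),
    ):
        missing = [s for s in samples if s not in available]
        if missing:
            raise ValueError(f"samples missing from {name}: {missing[:5]}")

    gene_scores = project_pcs(builder.gene_proj, we_gene)
    out = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    for j, col in enumerate(GENE_PC_COLUMNS):
        out[col] = (
            gene_scores.iloc[:, j] if j < gene_scores.shape[1] else 0.0
        )
    if builder.exon_proj is not None:
        exon_scores = project_pcs(builder.exon_proj, we_exon).loc[samples]
        for j, col in enumerate(EXON_PC_COLUMNS):
            out[col] = exon_scores.iloc[:, j] if j < exon_scores.shape[1] else 0.0
        out["median_splice"] = median_score(we_exon, builder.exon_signature).loc[samples]
    else:
        for col in EXON_PC_COLUMNS:
            out[col] = 0.0
        out["median_splice"] = 0.0
    out["median_expression"] = median_score(we_gene, builder.gene_signature).loc[samples]
    out["vdj_read_cpm"] = vdj_profile.loc[samples, "vdj_read_cpm"]
    out["vdj_clonality"] = vdj_profile.loc[samples, "clonality"].fillna(0.0)
    out = out[FEATURE_COLUMNS]
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing values after feature construction: {bad}")
    return out


# ---------------------------------------------------------------------------
# random forest with CV-based feature retention
# ---------------------------------------------------------------------------


@dataclass
class RFModel:
    forest: RandomForestRegressor
    retained: list[str]
    seed: int
    n_trees: int


def train_rf(
    features: pd.DataFrame,
    histo: pd.Series,
    n_trees: int = 500,
    cv_folds: int = 10,
    seed: int = 0,
    cv_trees: int = 100,
) -> RFModel:
    """Fit the histology regression forest with cross-validated retention.

    For each CV fold a forest is fitted on the training part and permutation
    importances are computed on the held-out part; features whose importance
    is <= 0 in a majority of folds are dropped and the forest is refitted on
    the retained set (at least one feature is always kept).  Fold-level
    screening forests use ``cv_trees`` trees (importance ranks stabilize well
    before the final ensemble size); the final model uses ``n_trees``.
    Deterministic given ``seed``.
    """
    y = histo.loc[features.index].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")
    n = len(features)
    if n < cv_folds:
        raise ValueError(f"need >= {cv_folds} samples for {cv_folds}-fold CV")
    X = features.to_numpy(dtype=float)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    nonpos = np.zeros(X.shape[1], dtype=int)
    mean_imp = np.zeros(X.shape[1])
    for fold, (tr, te) in enumerate(kf.split(X)):
        rf = RandomForestRegressor(
            n_estimators=min(cv_trees, n_trees), random_state=seed + fold, n_jobs=1
        )
        rf.fit(X[tr], y[tr])
        imp = permutation_importance(
            rf, X[te], y[te], n_repeats=5, random_state=seed + fold, n_jobs=1
        ).importances_mean
        nonpos += (imp <= 0).astype(int)
        mean_imp += imp / cv_folds
    retained_mask = nonpos <= cv_folds // 2
    if not retained_mask.any():
        retained_mask[np.argmax(mean_imp)] = True
    retained = [c for c, keep in zip(features.columns, retained_mask) if keep]
    logger.info("train_rf: retained %d/%d features", len(retained), X.shape[1])

    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(features[retained].to_numpy(), y)
    return RFModel(forest=forest, retained=retained, seed=seed, n_trees=n_trees)


def cohen_kappa(a, b) -> float:
    """Cohen's kappa for two label vectors; 1.0 when chance agreement is
    total and observed agreement is also total."""
    a = np.asarray(a)
    b = np.asarray(b)
    labels = np.unique(np.concatenate([a, b]))
    n = a.size
    po = float(np.mean(a == b))
    pe = 0.0
    for lab in labels:
        pe += float(np.mean(a == lab)) * float(np.mean(b == lab))
    if pe >= 1.0 - 1e-15:
        return 1.0 if po >= 1.0 - 1e-15 else 0.0
    return (po - pe) / (1.0 - pe)


def default_status_rule(scores: np.ndarray) -> np.ndarray:
    """Disease iff the (observed or predicted) histology score exceeds 0."""
    return (np.asarray(scores, dtype=float) > 0).astype(int)


def validate(
    model: RFModel,
    features_val: pd.DataFrame,
    histo_val: pd.Series,
    status_rule=default_status_rule,
    signature_label: str = "",
    validation_label: str = "",
) -> dict:
    """Score a trained model on a disjoint validation cohort.

    Returns Spearman rho and p between predicted and observed scores, the
    kappa of the status-binarized predictions, and the top-3 validation-set
    permutation importances.
    """
    if len(features_val) < 3:
        raise ValueError("need >= 3 validation samples")
    Xv = features_val[model.retained].to_numpy(dtype=float)
    yv = histo_val.loc[features_val.index].to_numpy(dtype=float)
    pred = model.forest.predict(Xv)
    rho, p = stats.spearman(pred, yv)
    kappa = cohen_kappa(status_rule(pred), status_rule(yv))
    imp = permutation_importance(
        model.forest, Xv, yv, n_repeats=10, random_state=model.seed, n_jobs=1
    ).importances_mean
    order = np.argsort(-imp, kind="stable")[:3]
    top3 = [(model.retained[i], float(imp[i])) for i in order]
    return {
        "signature": signature_label,
        "validation_set": validation_label,
        "rho": rho,
        "p": p,
        "neg_log10_p": float(-np.log10(max(p, 1e-300))) if np.isfinite(p) else np.nan,
        "kappa": kappa,
        "top_predictors": top3,
        "predictions": pd.Series(pred, index=features_val.index),
    }
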