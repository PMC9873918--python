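"""Dynamic (disease:time interaction) signatures and trajectory clustering.

Genes whose disease-vs-control difference itself changes across days are
found with a likelihood-ratio test between nested NB GLMs (full model
``~ group + day + group:day`` vs reduced ``~ group + day``).  The median
disease trajectories of significant genes are standardized and soft-clustered
with fuzzy c-means into temporal classes; clusters are assigned the canonical
letters A (early), B (late), C (very early), D (day-12 up), E (day-12 down)
by correlation of their centers with the canonical shapes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nbglm, splicing, stats
from .design import interaction_columns, trajectory_design
from .io import CountMatrix, ExonAnnotation, Signature
from .stats import WeightedExpression

logger = logging.getLogger("colitraj")

#: canonical temporal class shapes over the 4 default days, pre-standardization
CANONICAL_SHAPES: dict[str, tuple[float, ...]] = {
    "A": (1.0, 1.0, 0.0, 0.0),        # early: high at days 5 and 12
    "B": (0.0, 1 / 3, 2 / 3, 1.0),    # late: progressively increasing
    "C": (1.0, 0.0, 0.0, 0.0),        # very early: highest at day 5
    "D": (0.0, 1.0, 0.0, 0.0),        # day-12 up-regulated
    "E": (0.0, -1.0, 0.0, 0.0),       # day-12 down-regulated
}


@dataclass
class TrajectoryClusters:
    membership: pd.DataFrame   # genes x cluster labels, rows sum to 1
    centers: pd.DataFrame      # cluster labels x days
    fuzzifier: float
    hard_labels: pd.Series     # gene -> cluster label (argmax membership)


# ---------------------------------------------------------------------------
# interaction LRT
# ---------------------------------------------------------------------------


def interaction_lrt(
    gene_counts: CountMatrix, meta: pd.DataFrame, min_mean: float = 1.0
) -> pd.DataFrame:
    """NB LRT for a disease:day interaction, per gene.

    The dispersion is estimated once under the full model (df-corrected
    moment estimator shrunk toward the mean-dispersion trend) and shared by
    both fits so the likelihood ratio is well-defined.  Returns a frame with
    ``stat``, ``df``, ``p``, ``q``.
    """
    from .fixed import filter_low_counts

    days = sorted(meta["day"].unique())
    for d in days:
        m = meta[meta["day"] == d]
        if not ((m["group"] == "disease").any() and (m["group"] == "control").any()):
            raise ValueError(f"day {d}: both groups must be observed")
    counts = gene_counts.subset_samples(meta["sample_id"].tolist())
    counts, _ = filter_low_counts(counts, min_mean=min_mean)
    meta = meta.set_index("sample_id").loc[counts.sample_ids].reset_index()

    X_full = trajectory_design(meta, interaction=True).to_numpy()
    X_red = trajectory_design(meta, interaction=False).to_numpy()
    y = counts.counts.to_numpy(dtype=float)
    offset = np.log(counts.library_sizes.to_numpy(dtype=float))

    # shared dispersion: the unshrunk df-corrected Pearson estimates under
    # the full and reduced models are averaged.  The full-model estimate is
    # biased low under the null (the interaction fit absorbs noise into the
    # cell means), the reduced-model one is the null-constrained estimate
    # biased high under the alternative; their average keeps both the bulk
    # and the far tail of the null LRT distribution calibrated
    phi = 0.5 * (
        nbglm.estimate_dispersion(y, X_full, offset, shrink=0.0)
        + nbglm.estimate_dispersion(y, X_red, offset, shrink=0.0)
    )
    stat, df, p = nbglm.lrt(y, X_full, X_red, offset, phi)
    n_fail = int(np.isnan(p).sum())
    if n_fail:
        logger.warning("interaction_lrt: %d gene(s) failed to converge", n_fail)
    return pd.DataFrame(
        {
            "gene_id": counts.feature_ids,
            "stat": stat,
            "df": df,
            "p": p,
            "q": stats.bh_adjust(p),
        }
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def median_disease_trajectories(
    we: WeightedExpression, meta: pd.DataFrame, genes: list[str]
) -> pd.DataFrame:
    """Per-gene median log2-CPM over disease samples at each day (genes x days)."""
    missing = [g for g in genes if g not in we.E.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
    days = sorted(meta["day"].unique())
    cols = {}
    for d in days:
        samp = meta.loc[
            (meta["day"] == d) & (meta["group"] == "disease"), "sample_id"
        ].tolist()
        if not samp:
            raise ValueError(f"no disease samples at day {d}")
        cols[d] = we.E.loc[genes, samp].median(axis=1)
    return pd.DataFrame(cols)


def standardize_trajectories(T: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize to mean 0, sample sd 1; constant rows are dropped."""
    arr = T.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all trajectories are constant")
    if (~keep).any():
        warnings.warn(f"dropped {(~keep).sum()} constant trajectory row(s)")
    arr = arr[keep]
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.DataFrame(z, index=T.index[keep], columns=T.columns)


# ---------------------------------------------------------------------------
# fuzzy c-means
# ---------------------------------------------------------------------------


def estimate_fuzzifier(n_rows: int, n_cols: int) -> float:
    """Heuristic fuzzifier from data size and dimensionality.

    Uses the published empirical formula relating the fuzzifier to the number
    of profiles N and dimensions D; falls back to 1.25 when it degenerates.
    """
    N, D = float(n_rows), float(n_cols)
    if N < 2 or D < 1:
        return 1.25
    m = 1.0 + (1418.0 / N + 22.05) * D ** -2.0 + (
        12.33 / N + 0.243
    ) * D ** (-0.0406 * np.log(N) - 0.1134)
    if not np.isfinite(m) or m <= 1.0:
        return 1.25
    return float(m)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded k-means++-style center draw."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            ((X[:, None, :] - np.array(centers)[None, :, :]) ** 2).sum(-1), axis=1
        )
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)])
            continue
        probs = d2 / total
        centers.append(X[rng.choice(n, p=probs)])
    return np.array(centers)


def _fcm_once(X: np.ndarray, k: int, m: float, tol: float, max_iter: int,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
    C = _kmeanspp_init(X, k, rng)
    expo = 1.0 / (m - 1.0)
    U = None
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(-1)  # (n, k)
        zero = d2 < 1e-300
        with np.errstate(divide="ignore"):
            inv = d2 ** -expo
        U = np.where(zero.any(axis=1, keepdims=True), zero.astype(float), inv)
        U = U / U.sum(axis=1, keepdims=True)
        Um = U ** m
        newC = (Um.T @ X) / Um.sum(axis=0)[:, None]
        shift = np.abs(newC - C).max()
        C = newC
        if shift < tol:
            break
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(-1)
    objective = float((U ** m * d2).sum())
    return U, C, objective


def fuzzy_cmeans(
    Tz: pd.DataFrame,
    k: int = 5,
    m: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    n_init: int = 5,
) -> TrajectoryClusters:
    """Soft c-means clustering of standardized trajectories.

    Alternates membership updates u_gc (inverse-squared-distance weights to
    the power 1/(m-1), normalized per gene) and center updates (u^m-weighted
    means) until the largest center shift falls below ``tol``.  A gene that
    coincides exactly with a center gets membership 1 there.  ``n_init``
    seeded k-means++-style starts are run and the lowest-objective solution
    kept (the objective is sum u^m * squared distance).  Clusters are
    relabeled A-E by maximal correlation with the canonical temporal shapes
    (ties broken by cluster size, largest first).
    """
    X = Tz.to_numpy(dtype=float)
    n, d = X.shape
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("fewer rows than clusters")
    if m is None:
        m = estimate_fuzzifier(n, d)
    if m <= 1.0:
        raise ValueError("fuzzifier must exceed 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_init, 1)):
        U, C, obj = _fcm_once(X, k, m, tol, max_iter, rng)
        if best is None or obj < best[2]:
            best = (U, C, obj)
    U, C, _ = best

    labels = _assign_letters(C, U, list(Tz.columns))
    member = pd.DataFrame(U, index=Tz.index, columns=labels)
    member = member[sorted(member.columns)]
    centers = pd.DataFrame(C, index=labels, columns=Tz.columns).sort_index()
    hard = member.idxmax(axis=1)
    return TrajectoryClusters(
        membership=member, centers=centers, fuzzifier=float(m), hard_labels=hard
    )


def _assign_letters(C: np.ndarray, U: np.ndarray, days) -> list[str]:
    """Greedy 1:1 match of centers to canonical shapes by correlation."""
    k = C.shape[0]
    shape_names = list(CANONICAL_SHAPES)
    shapes = []
    for name in shape_names:
        v = np.asarray(CANONICAL_SHAPES[name], dtype=float)
        if len(v) != C.shape[1]:
            # resample canonical shape onto the observed day grid
            v = np.interp(np.linspace(0, 1, C.shape[1]), np.linspace(0, 1, len(v)), v)
        v = (v - v.mean()) / (v.std() if v.std() > 0 else 1.0)
        shapes.append(v)
    shapes = np.array(shapes)
    Cz = C - C.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Cz, axis=1, keepdims=True)
    Cz = Cz / np.where(norm > 0, norm, 1.0)
    Sz = shapes / np.linalg.norm(shapes, axis=1, keepdims=True)
    corr = Cz @ Sz.T                                   # (k, n_shapes)
    sizes = U.sum(axis=0)
    order = np.argsort(-sizes, kind="stable")          # big clusters pick first
    labels = [""] * k
    taken: set[int] = set()
    extra = 0
    for ci in order:
        best, best_r = None, -np.inf
        for si in range(len(shape_names)):
            if si in taken:
                continue
            if corr[ci, si] > best_r:
                best, best_r = si, corr[ci, si]
        if best is None:
            labels[ci] = f"X{extra}"
            extra += 1
        else:
            labels[ci] = shape_names[best]
            taken.add(best)
    return labels


def cluster_signatures(clusters: TrajectoryClusters) -> list[Signature]:
    sigs = []
    for label in clusters.centers.index:
        genes = clusters.hard_labels.index[clusters.hard_labels == label].tolist()
        sigs.append(Signature(label=f"cluster-{label}", genes=genes))
    return sigs


# ---------------------------------------------------------------------------
# splicing trajectories
# ---------------------------------------------------------------------------


def splicing_trajectory_lrt(
    exon_counts: CountMatrix,
    annotation: ExonAnnotation,
    meta: pd.DataFrame,
    min_mean: float = 1.0,
) -> pd.DataFrame:
    """Gene-level evidence of a disease:time change in exon usage.

    The exon-level weighted LM with interaction columns is fitted; for each
    interaction coefficient the exon deviations from the gene average are
    scored with moderated t, the per-exon evidence across interaction columns
    is combined with a moderated F, and a Simes combination across the gene's
    exons yields the gene p (BH-adjusted across genes).  Single-exon genes
    are untestable and excluded.
    """
    from scipy import stats as sps

    from .fixed import filter_low_counts

    counts = exon_counts.subset_samples(meta["sample_id"].tolist())
    counts, _ = filter_low_counts(counts, min_mean=min_mean)
    meta = meta.set_index("sample_id").loc[counts.sample_ids].reset_index()

    design = trajectory_design(meta, interaction=True)
    we = stats.logcpm_transform(counts, design=design)
    fit = stats.fit_weighted_lm(we, design)
    int_cols = interaction_columns(design)
    mod = stats.moderate(fit, coefficients=int_cols)

    devs = []
    ses = []
    df_total = None
    gene_ids = None
    exon_ids = None
    for col in int_cols:
        dev = splicing.exon_deviations(fit, mod, annotation, col)
        devs.append(dev["dev"].to_numpy())
        ses.append(dev["dev_se_unscaled"].to_numpy())
        if df_total is None:
            df_total = dev["df_total"].to_numpy()
            gene_ids = dev["gene_id"].to_numpy()
            exon_ids = dev["exon_id"].to_numpy()
    D = np.column_stack(devs)                       # (E, n_int)
    S = np.column_stack(ses)
    n_int = len(int_cols)

    # whiten with the coefficient correlation: the interaction estimates share
    # the reference-day samples and are positively correlated, so a naive sum
    # of squared t's would overstate the evidence
    col_idx = [list(design.columns).index(c) for c in int_cols]
    row_of = {f: i for i, f in enumerate(fit.coefficients.index)}
    rows = np.array([row_of[e] for e in exon_ids])
    V = fit.cov_unscaled[np.ix_(rows, col_idx, col_idx)]   # (E, n_int, n_int)
    d0 = np.sqrt(np.maximum(np.diagonal(V, axis1=1, axis2=2), 1e-300))
    corr = V / (d0[:, :, None] * d0[:, None, :])
    cov_dev = corr * (S[:, :, None] * S[:, None, :])
    sol = np.linalg.solve(cov_dev, D[..., None])[..., 0]
    var_post = mod.var_post.reindex(exon_ids).to_numpy()
    f_stat = np.einsum("ei,ei->e", D, sol) / (n_int * var_post)
    p_exon = sps.f.sf(f_stat, n_int, df_total)

    exon_df = pd.DataFrame(
        {"exon_id": exon_ids, "gene_id": gene_ids, "f": f_stat, "p": p_exon}
    )
    rows = [
        (gene, stats.simes_combine(g["p"].to_numpy()))
        for gene, g in exon_df.groupby("gene_id", sort=True)
    ]
    gene_df = pd.DataFrame(rows, columns=["gene_id", "p"])
    gene_df["q"] = stats.bh_adjust(gene_df["p"])
    return gene_df
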