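"""Mouse-to-human signature translation, spline regression and network overlap.

Mouse signatures are projected through an ortholog map, reduced to principal
components in the human expression data (by the machinery in ``predict``),
and related to histology indices with an AIC-penalized OLS including
restricted-cubic-spline terms (three knots by default) per component.  The
apparent adjusted R-squared of the selected model is de-optimismed by
bootstrap resampling with the selection rerun inside every replicate.
Signature relevance to human disease networks is scored by upper-tail
hypergeometric overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .io import Network, Signature

logger = logging.getLogger("colitraj")


# ---------------------------------------------------------------------------
# ortholog projection
# ---------------------------------------------------------------------------


def map_orthologs(
    signature: Signature, ortholog_map: dict[str, set[str]], policy: str = "all"
) -> Signature:
    """Project a signature through a one-to-many ortholog map.

    ``policy='all'`` expands one-to-many mappings; ``policy='one_to_one'``
    keeps only genes mapping to exactly one target that no other source gene
    maps to.  Unmapped genes are counted and logged.
    """
    if policy not in ("all", "one_to_one"):
        raise ValueError(f"policy must be 'all' or 'one_to_one', got {policy!r}")
    unmapped = [g for g in signature.genes if g not in ortholog_map]
    if unmapped:
        logger.info("map_orthologs: %d/%d genes unmapped", len(unmapped), len(signature))
    mapped: set[str] = set()
    if policy == "all":
        for g in signature.genes:
            mapped |= ortholog_map.get(g, set())
    else:
        target_counts: dict[str, int] = {}
        for targets in ortholog_map.values():
            for t in targets:
                target_counts[t] = target_counts.get(t, 0) + 1
        for g in signature.genes:
            targets = ortholog_map.get(g, set())
            if len(targets) == 1:
                (t,) = targets
                if target_counts.get(t, 0) == 1:
                    mapped.add(t)
    if not mapped:
        raise ValueError(f"signature {signature.label!r}: no genes mapped")
    return Signature(label=f"{signature.label}|human", genes=sorted(mapped))


# ---------------------------------------------------------------------------
# restricted cubic splines
# ---------------------------------------------------------------------------

DEFAULT_KNOT_QUANTILES = {3: (0.1, 0.5, 0.9), 4: (0.05, 0.35, 0.65, 0.95),
                          5: (0.05, 0.275, 0.5, 0.725, 0.95)}


def rcs_knots(x: np.ndarray, n_knots: int = 3) -> np.ndarray:
    qs = DEFAULT_KNOT_QUANTILES.get(
        n_knots, tuple(np.linspace(0.05, 0.95, n_knots))
    )
    return np.quantile(np.asarray(x, dtype=float), qs)


def rcs_basis(x, n_knots: int = 3, knots: np.ndarray | None = None) -> np.ndarray:
    """Restricted cubic spline truncated-power basis with linear tails.

    Returns ``n_knots - 1`` columns: the linear term followed by the
    ``n_knots - 2`` restricted cubic terms (normalized by the squared knot
    range).  With too few distinct values for the requested knots, falls back
    to the linear column alone with a warning.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if np.unique(x).size < n_knots:
            warnings.warn("too few distinct values for spline knots; linear only")
            return x[:, None]
        knots = rcs_knots(x, n_knots)
    t = np.asarray(knots, dtype=float)
    k = t.size
    if np.unique(t).size < k:
        warnings.warn("degenerate knots; linear only")
        return x[:, None]
    cols = [x]
    norm = (t[-1] - t[0]) ** 2
    for j in range(k - 2):
        term = (
            np.maximum(x - t[j], 0.0) ** 3
            - np.maximum(x - t[-2], 0.0) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
            + np.maximum(x - t[-1], 0.0) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# AIC-penalized OLS with grouped spline terms
# ---------------------------------------------------------------------------


@dataclass
class SplineModel:
    """Selected AIC-minimal spline OLS model for one signature x outcome."""

    selected_terms: list[str]           # PC names kept (group selection)
    coefficients: np.ndarray            # incl. intercept, in design order
    column_names: list[str]
    aic: float
    r2: float
    adj_r2: float
    corrected_r2: float | None = None
    knots: dict[str, np.ndarray] = field(default_factory=dict)
    kept_cols: dict[str, list[int]] = field(default_factory=dict)

    def design(self, X: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(X))]
        for term in self.selected_terms:
            kn = self.knots.get(term)
            x = X[term].to_numpy(dtype=float)
            if kn is None or kn.size == 0:   # term entered as a bare linear column
                block = x[:, None]
            else:
                block = rcs_basis(x, knots=kn)
            keep = self.kept_cols.get(term)
            if keep is not None:
                block = block[:, keep]
            cols.append(block)
        return np.column_stack(cols)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.design(X) @ self.coefficients

    def r2_on(self, X: pd.DataFrame, y: np.ndarray) -> tuple[float, float]:
        """(R2, adjusted R2) of this fitted model evaluated on (X, y)."""
        y = np.asarray(y, dtype=float)
        resid = y - self.predict(X)
        tss = float(((y - y.mean()) ** 2).sum())
        if tss == 0:
            return 0.0, 0.0
        r2 = 1.0 - float(resid @ resid) / tss
        k = len(self.coefficients) - 1
        n = y.size
        adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - k - 1, 1)
        return r2, adj


def _ols(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid)


def _aic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2.0 * k


def _drop_collinear(
    blocks: dict[str, np.ndarray], n: int
) -> tuple[dict[str, np.ndarray], dict[str, list[int]]]:
    """Drop columns that add nothing to the design rank, warning once."""
    kept: dict[str, np.ndarray] = {}
    kept_idx: dict[str, list[int]] = {}
    current = np.ones((n, 1))
    dropped = 0
    for name, block in blocks.items():
        cols = []
        for j in range(block.shape[1]):
            col = block[:, j]
            # collinear iff the residual after projection on the current
            # design is negligible relative to the column's own scale
            sol, *_ = np.linalg.lstsq(current, col, rcond=None)
            resid = col - current @ sol
            if np.linalg.norm(resid) > 1e-8 * max(np.linalg.norm(col), 1.0):
                current = np.column_stack([current, col])
                cols.append(j)
            else:
                dropped += 1
        if cols:
            kept[name] = block[:, cols]
            kept_idx[name] = cols
    if dropped:
        warnings.warn(f"dropped {dropped} collinear spline column(s)")
    return kept, kept_idx


def penalized_ols_aic(
    feature_pcs: pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    n_knots: int = 3,
) -> SplineModel:
    """Backward-stepwise OLS minimizing AIC over grouped spline terms.

    Each feature column (a signature PC) contributes a group of restricted
    cubic spline columns that is kept or deleted jointly; deletion proceeds
    while it lowers AIC = n ln(RSS/n) + 2k.  The final model is refitted by
    OLS and its apparent (adjusted) R-squared recorded.
    """
    y = np.asarray(outcome, dtype=float)
    n = y.size
    pc_names = list(feature_pcs.columns)
    knots: dict[str, np.ndarray] = {}
    blocks: dict[str, np.ndarray] = {}
    for name in pc_names:
        x = feature_pcs[name].to_numpy(dtype=float)
        if np.unique(x).size >= n_knots:
            knots[name] = rcs_knots(x, n_knots)
            blocks[name] = rcs_basis(x, knots=knots[name])
        else:
            knots[name] = np.array([])
            blocks[name] = x[:, None]
    blocks, kept_idx = _drop_collinear(blocks, n)
    pc_names = list(blocks.keys())
    total_cols = sum(b.shape[1] for b in blocks.values())
    if n <= total_cols + 1:
        raise ValueError("need more observations than candidate columns")

    def fit(terms: list[str]):
        A = np.column_stack(
            [np.ones(n)] + [blocks[t] for t in terms]
        ) if terms else np.ones((n, 1))
        coef, rss = _ols(A, y)
        return coef, rss, _aic(rss, n, A.shape[1])

    terms = list(pc_names)
    coef, rss, aic = fit(terms)
    improved = True
    while improved and terms:
        improved = False
        best = (aic, None)
        for t in terms:
            trial = [u for u in terms if u != t]
            _, _, a = fit(trial)
            if a < best[0] - 1e-12:
                best = (a, t)
        if best[1] is not None:
            terms = [u for u in terms if u != best[1]]
            coef, rss, aic = fit(terms)
            improved = True

    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    k = sum(blocks[t].shape[1] for t in terms)
    adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - k - 1, 1) if terms else 0.0
    col_names = ["intercept"] + [
        f"{t}:{j}" for t in terms for j in range(blocks[t].shape[1])
    ]
    return SplineModel(
        selected_terms=terms,
        coefficients=coef,
        column_names=col_names,
        aic=aic,
        r2=r2,
        adj_r2=adj,
        knots={t: knots[t] for t in terms},
        kept_cols={t: kept_idx[t] for t in terms},
    )


def bootstrap_bias_corrected_r2(
    feature_pcs: pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    n_knots: int = 3,
    B: int = 300,
    seed: int = 0,
) -> dict:
    """Optimism-corrected adjusted R-squared with selection inside the loop.

    For each of ``B`` bootstrap resamples the full stepwise selection is
    rerun; optimism is the mean excess of the bootstrap model's fit on its
    own sample over its fit on the original data, and the corrected value is
    apparent minus optimism.  Degenerate resamples (constant outcome) are
    skipped and logged.  With no candidate columns the model is the
    intercept alone and apparent = corrected = 0 exactly.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(outcome, dtype=float)
    n = y.size
    if feature_pcs.shape[1] == 0:
        model = SplineModel([], np.array([y.mean()]), ["intercept"], _aic(
            float(((y - y.mean()) ** 2).sum()), n, 1), 0.0, 0.0, corrected_r2=0.0)
        return {"model": model, "apparent_adj_r2": 0.0, "optimism": 0.0,
                "corrected_r2": 0.0, "n_boot_used": 0}

    apparent = penalized_ols_aic(feature_pcs, y, n_knots=n_knots)
    rng = np.random.default_rng(seed)
    optimisms = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if np.ptp(yb) == 0:
            skipped += 1
            continue
        Xb = feature_pcs.iloc[idx].reset_index(drop=True)
        try:
            mb = penalized_ols_aic(Xb, yb, n_knots=n_knots)
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
            continue
        _, adj_boot = mb.r2_on(Xb, yb)
        _, adj_orig = mb.r2_on(feature_pcs.reset_index(drop=True), y)
        optimisms.append(adj_boot - adj_orig)
    if skipped:
        logger.info("bootstrap: skipped %d degenerate replicate(s)", skipped)
    optimism = float(np.mean(optimisms)) if optimisms else 0.0
    corrected = apparent.adj_r2 - optimism
    apparent.corrected_r2 = corrected
    return {
        "model": apparent,
        "apparent_adj_r2": apparent.adj_r2,
        "optimism": optimism,
        "corrected_r2": corrected,
        "n_boot_used": len(optimisms),
    }


# ---------------------------------------------------------------------------
# region averaging and network overlap
# ---------------------------------------------------------------------------


def region_average(
    biopsies: pd.DataFrame, exclude_regions: tuple[str, ...] = ("ileum",)
) -> pd.Series:
    """Per-patient unweighted mean score over non-excluded biopsy regions.

    ``biopsies`` needs columns patient_id, region, score.  Patients whose
    biopsies all fall in excluded regions are dropped with a log entry.
    """
    required = {"patient_id", "region", "score"}
    if not required.issubset(biopsies.columns):
        raise ValueError(f"biopsy table requires columns {sorted(required)}")
    excl = {r.lower() for r in exclude_regions}
    kept = biopsies[~biopsies["region"].str.lower().isin(excl)]
    dropped = set(biopsies["patient_id"]) - set(kept["patient_id"])
    if dropped:
        logger.info("region_average: dropped %d patient(s) with only excluded "
                    "regions", len(dropped))
    return kept.groupby("patient_id")["score"].mean().sort_index()


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    overlap: int
    universe: int
    p: float
    neg_log10_p: float


def network_overlap(
    signature_genes: set[str], subnetwork_genes: set[str], universe: set[str]
) -> OverlapResult:
    """Upper-tail hypergeometric overlap of two gene sets in a universe."""
    a = set(signature_genes) & set(universe)
    b = set(subnetwork_genes) & set(universe)
    if len(universe) < max(len(signature_genes & universe), len(subnetwork_genes & universe)):
        raise ValueError("universe smaller than a set")
    k = len(a & b)
    p = stats.hypergeom_overlap_p(k, len(a), len(b), len(universe))
    return OverlapResult(
        n_a=len(a), n_b=len(b), overlap=k, universe=len(universe),
        p=p, neg_log10_p=float(-np.log10(max(p, 1e-300))),
    )


def first_neighbors(network: Network, seed_genes: set[str]) -> set[str]:
    """Seed genes plus every node adjacent to a seed (undirected)."""
    g = network.graph
    present = {s for s in seed_genes if s in g}
    if not present:
        warnings.warn("no seed gene present in the network")
        return set()
    out = set(present)
    for s in present:
        out |= set(g.neighbors(s))
    return out
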