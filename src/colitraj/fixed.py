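"""Timepoint-specific disease-vs-control differential expression signatures.

At each sacrifice day, disease and control samples are compared with either a
negative-binomial GLM Wald test (``nbglm``, the gene-level default) or the
log-CPM weighted-LM moderated-t route (``wlm``, the exon-level default).
Signatures are the genes passing a fold-change/FDR rule at that day.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from . import nbglm, stats
from .design import group_design
from .io import CountMatrix, Signature

logger = logging.getLogger("colitraj")

LOG2E = np.log2(np.e)


def _day_subset(counts: CountMatrix, meta: pd.DataFrame, day: int):
    m = meta[meta["day"] == int(day)]
    n_dis = (m["group"] == "disease").sum()
    n_con = (m["group"] == "control").sum()
    if n_dis < 2 or n_con < 2:
        raise ValueError(
            f"day {day}: need >= 2 samples per group, got {n_dis} disease / {n_con} control"
        )
    sub = counts.subset_samples(m["sample_id"].tolist())
    return sub, m.reset_index(drop=True)


def filter_low_counts(counts: CountMatrix, min_mean: float = 1.0):
    """Drop features with mean count below ``min_mean`` (and all-zero rows)."""
    mean = counts.counts.mean(axis=1)
    keep = mean >= min_mean
    dropped = counts.counts.index[~keep].tolist()
    if dropped:
        logger.info("filtered %d low-count features (mean < %g)", len(dropped), min_mean)
    kept = CountMatrix(counts.counts.loc[keep], counts.library_sizes)
    return kept, dropped


def timepoint_de(
    gene_counts: CountMatrix,
    meta: pd.DataFrame,
    day: int,
    engine: str = "nbglm",
    min_mean: float = 1.0,
) -> pd.DataFrame:
    """Disease-vs-control DE at one day.

    Returns a per-gene frame with columns ``log2fc``, ``se``, ``stat``, ``p``,
    ``q`` (BH within the day) and ``day``.  log2 fold changes are disease
    minus control.
    """
    if engine not in ("nbglm", "wlm"):
        raise ValueError(f"engine must be 'nbglm' or 'wlm', got {engine!r}")
    sub, m = _day_subset(gene_counts, meta, day)
    sub, dropped = filter_low_counts(sub, min_mean=min_mean)
    design = group_design(m).loc[sub.sample_ids]
    X = design.to_numpy()
    y = sub.counts.to_numpy(dtype=float)

    if engine == "nbglm":
        offset = np.log(sub.library_sizes.to_numpy(dtype=float))
        phi = nbglm.estimate_dispersion(y, X, offset)
        beta, se, z, p = nbglm.wald_test(y, X, offset, phi, coef_index=1)
        log2fc = beta * LOG2E
        se_out = se * LOG2E
        stat = z
    else:
        we = stats.logcpm_transform(sub, design=design)
        fit = stats.fit_weighted_lm(we, design)
        mod = stats.moderate(fit, coefficients=["disease"])
        log2fc = fit.coefficients["disease"].to_numpy()
        se_out = (fit.stdev_unscaled["disease"] * np.sqrt(mod.var_post)).to_numpy()
        stat = mod.t["disease"].to_numpy()
        p = mod.p["disease"].to_numpy()

    out = pd.DataFrame(
        {
            "gene_id": sub.feature_ids,
            "log2fc": log2fc,
            "se": se_out,
            "stat": stat,
            "p": p,
            "q": stats.bh_adjust(p),
            "day": int(day),
        }
    )
    if dropped:
        out.attrs["filtered"] = dropped
    return out


def extract_signature(
    de: pd.DataFrame,
    lfc_min: float = 0.0,
    q_max: float = 0.05,
    direction: str = "up",
    label: str | None = None,
) -> Signature:
    """Genes passing the fold-change/FDR rule, labeled ``fixed-day-<d>``."""
    if direction not in ("up", "down", "both"):
        raise ValueError(f"direction must be up/down/both, got {direction!r}")
    lfc = de["log2fc"].to_numpy()
    q = de["q"].to_numpy()
    sig_q = q <= q_max
    if direction == "up":
        keep = sig_q & (lfc > lfc_min)
    elif direction == "down":
        keep = sig_q & (lfc < -lfc_min)
    else:
        keep = sig_q & (np.abs(lfc) > lfc_min)
    genes = de.loc[keep, "gene_id"].tolist()
    if label is None:
        day = int(de["day"].iloc[0]) if len(de) else 0
        label = f"fixed-day-{day}"
    if not genes:
        warnings.warn(f"signature {label}: empty at q<={q_max}, |lfc|>{lfc_min}")
    dirs = {g: (1 if f > 0 else -1) for g, f in zip(genes, lfc[keep])}
    return Signature(label=label, genes=genes, direction=dirs)


def timepoint_specificity(signatures: dict[int, Signature]) -> float:
    """Fraction of signature genes present in exactly one day's signature."""
    if len(signatures) < 2:
        raise ValueError("need signatures for >= 2 days")
    from collections import Counter

    counts = Counter(g for sig in signatures.values() for g in sig.genes)
    if not counts:
        raise ValueError("all signatures are empty")
    unique = sum(1 for c in counts.values() if c == 1)
    return unique / len(counts)
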