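"""Adaptive immune burden and clonality from VDJ clone abundance tables.

Burden is the library-size-normalized count of reads mapping to rearranged
immune-receptor loci (reads per million); clonality is the normalized
Shannon-entropy concentration of the clone frequency vector, 1 - H/ln K,
which is 0 for a perfectly even repertoire and 1 for a single dominant clone
(a single-clone sample is 1 by convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats


def vdj_read_cpm(clone_table: pd.DataFrame, library_sizes: pd.Series) -> pd.Series:
    """Per-sample VDJ reads per million total library reads."""
    totals = clone_table.groupby("sample_id")["reads"].sum()
    missing = set(totals.index) - set(library_sizes.index)
    if missing:
        raise ValueError(f"samples absent from library table: {sorted(missing)[:5]}")
    out = pd.Series(0.0, index=library_sizes.index, name="vdj_read_cpm")
    lib = library_sizes.astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    out.loc[totals.index] = 1e6 * totals / lib.loc[totals.index]
    return out.sort_index()


def clonality(abundances) -> float:
    """1 - H/ln K for clone abundance vector (K = number of positive clones)."""
    a = np.asarray(abundances, dtype=float)
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("clonality undefined for all-zero abundances")
    if a.size == 1:
        return 1.0
    f = a / a.sum()
    h = float(-(f * np.log(f)).sum())
    return 1.0 - h / np.log(a.size)


def vdj_profile(clone_table: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Per-sample burden, clone count and clonality.

    Samples with library sizes but no detected clones get burden 0, clone
    count 0 and missing clonality.
    """
    cpm = vdj_read_cpm(clone_table, library_sizes)
    rows = {}
    grouped = dict(list(clone_table.groupby("sample_id")))
    for s in library_sizes.index:
        if s in grouped and (grouped[s]["reads"] > 0).any():
            reads = grouped[s]["reads"].to_numpy()
            rows[s] = (int((reads > 0).sum()), clonality(reads))
        else:
            rows[s] = (0, np.nan)
    prof = pd.DataFrame.from_dict(rows, orient="index", columns=["clone_count", "clonality"])
    prof.insert(0, "vdj_read_cpm", cpm)
    prof.index.name = "sample_id"
    return prof.sort_index()


def vdj_severity_correlation(values: pd.Series, histology: pd.Series) -> tuple[float, float]:
    """Spearman correlation between a VDJ measurement and paired severity scores."""
    common = values.index.intersection(histology.index)
    if len(common) < 3:
        raise ValueError("need >= 3 paired samples")
    return stats.spearman(values.loc[common], histology.loc[common])
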