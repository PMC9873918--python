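"""Design-matrix construction from sample metadata.

Treatment coding throughout: control and the earliest day are the reference
levels, so the ``disease`` column is the disease-vs-control contrast at the
reference day and the interaction columns are day-specific modifications of
that contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GROUP_DISEASE


def group_design(meta: pd.DataFrame) -> pd.DataFrame:
    """Intercept + disease indicator for a single-day comparison."""
    x = (meta["group"] == GROUP_DISEASE).astype(float).to_numpy()
    return pd.DataFrame(
        {"intercept": 1.0, "disease": x}, index=meta["sample_id"].to_numpy()
    )


def trajectory_design(meta: pd.DataFrame, interaction: bool = True) -> pd.DataFrame:
    """~ group + day (+ group:day), day as a categorical factor.

    Columns: intercept, disease, day<d> dummies for each non-reference day,
    and (when ``interaction``) disease:day<d> columns.
    """
    days = sorted(meta["day"].unique())
    if len(days) < 2:
        raise ValueError("trajectory design needs >= 2 days")
    dis = (meta["group"] == GROUP_DISEASE).astype(float).to_numpy()
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(meta)),
        "disease": dis,
    }
    for d in days[1:]:
        ind = (meta["day"] == d).astype(float).to_numpy()
        cols[f"day{d}"] = ind
    if interaction:
        for d in days[1:]:
            ind = (meta["day"] == d).astype(float).to_numpy()
            cols[f"disease:day{d}"] = dis * ind
    return pd.DataFrame(cols, index=meta["sample_id"].to_numpy())


def interaction_columns(design: pd.DataFrame) -> list[str]:
    return [c for c in design.columns if c.startswith("disease:day")]
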