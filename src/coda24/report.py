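"""Publication-shaped report tables.

Builders for the four standard outputs of the analysis:

* cohort description — covariate frequencies with per-category WEMWBS
  mean (SD), and geometric-mean behaviour hours / percentage of 24 h;
* association table — per-behaviour ILR coefficients (beta, SE, p) for
  each requested model with shared model fit (R², overall-F p);
* focal substitution table — the four public-health 30-min reallocations
  per model with 95% CIs;
* full substitution grid and its plot-ready long format.

All builders return full-precision DataFrames; :func:`round_report`
produces the 2-decimal display version.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coda import PART_ORDER, geometric_mean_composition, variation_matrix
from .regression import CATEGORY_LEVELS, behaviour_betas
from .substitution import export_curves, focal_table, substitution_grid


def describe_composition(participants: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean behaviour table: hours/day and percentage of 24 h.

    Percentages are computed from unrounded minutes, so they sum to 100.
    """
    comp = participants[list(PART_ORDER)].to_numpy(dtype=float)
    gm = geometric_mean_composition(comp)
    return pd.DataFrame(
        {
            "behaviour": PART_ORDER,
            "minutes": gm,
            "hours": gm / 60.0,
            "pct_24h": gm / 1440.0 * 100.0,
        }
    )


def describe_covariates(participants: pd.DataFrame) -> pd.DataFrame:
    """Covariate frequency table with per-category WEMWBS mean (SD)."""
    rows = [
        {
            "variable": "age",
            "category": "mean (sd)",
            "n": len(participants),
            "pct": 100.0,
            "wemwbs_mean": float(participants["wemwbs"].mean()),
            "wemwbs_sd": float(participants["wemwbs"].std()),
        }
    ]
    for var, levels in CATEGORY_LEVELS.items():
        if var not in participants:
            continue
        seen = list(levels) + (["missing"] if (participants[var] == "missing").any() else [])
        for level in seen:
            sub = participants[participants[var] == level]
            rows.append(
                {
                    "variable": var,
                    "category": level,
                    "n": len(sub),
                    "pct": 100.0 * len(sub) / len(participants),
                    "wemwbs_mean": float(sub["wemwbs"].mean()) if len(sub) else np.nan,
                    "wemwbs_sd": float(sub["wemwbs"].std()) if len(sub) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def variation_report(participants: pd.DataFrame) -> pd.DataFrame:
    """Variation matrix as a labelled DataFrame."""
    v = variation_matrix(participants[list(PART_ORDER)].to_numpy(dtype=float))
    return pd.DataFrame(v, index=PART_ORDER, columns=PART_ORDER)


def association_table(participants: pd.DataFrame, models=(1, 2, 3)) -> pd.DataFrame:
    """Per-behaviour coefficient table across the covariate ladder."""
    return pd.concat(
        [behaviour_betas(participants, model_id=m) for m in models],
        ignore_index=True,
    )


def substitution_report(
    participants: pd.DataFrame,
    models=(1, 2, 3),
    minutes_grid=None,
    focal_minutes: float = 30.0,
    alpha: float = 0.05,
):
    """Focal 30-min table, full grid and plot-ready curves for all models.

    The reference composition is the sample geometric mean of the analysed
    participants.  Returns (focal_df, grid_df, curves_df).
    """
    from .regression import fit_model
    from .substitution import DEFAULT_GRID

    reference = geometric_mean_composition(
        participants[list(PART_ORDER)].to_numpy(dtype=float)
    )
    grid = DEFAULT_GRID if minutes_grid is None else tuple(minutes_grid)
    focal, grids, curves = [], [], []
    for m in models:
        fit = fit_model(participants, model_id=m)
        focal.append(focal_table(fit, reference, minutes=focal_minutes, alpha=alpha))
        g = substitution_grid(fit, reference, minutes_grid=grid, alpha=alpha)
        grids.append(g)
        curves.append(export_curves(g))
    return (
        pd.concat(focal, ignore_index=True),
        pd.concat(grids, ignore_index=True),
        pd.concat(curves, ignore_index=True),
    )


def round_report(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Display version: floats rounded to ``decimals`` (default 2)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(decimals)
    return out
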