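"""Compositional isotemporal substitution.

Predicts the change in well-being associated with reallocating t minutes
from one behaviour to another at a reference composition (by default the
sample geometric-mean composition), holding the 1440-min total and the
other two behaviours fixed.  Because the regression is linear in the ILR
coordinates and covariates enter additively, covariate values cancel in
the difference; the predicted change is

    delta(t) = (z_new - z_ref)' beta_ilr

with a delta-method confidence interval built from the ILR block of the
coefficient covariance and the t distribution at the fit's residual df.

The default grid is every ordered behaviour pair at 5-60 min in 5-min
steps: 12 pairs x 12 durations = 144 estimates per model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .coda import PART_ORDER, TOTAL_MIN, ilr, sbp_pivot
from .regression import RegressionFit

#: Default substitution durations (minutes).
DEFAULT_GRID: tuple[int, ...] = tuple(range(5, 65, 5))

#: The public-health focal reallocations reported at 30 min.
FOCAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("sb", "lpa"),
    ("sb", "mvpa"),
    ("lpa", "mvpa"),
    ("sb", "tst"),
)

ALL_PAIRS: tuple[tuple[str, str], ...] = tuple(permutations(PART_ORDER, 2))


class ReallocationError(ValueError):
    """Raised when a reallocation would exhaust the donor behaviour."""


@dataclass(frozen=True)
class SubstitutionEstimate:
    """Predicted well-being difference for one reallocation."""

    from_behaviour: str
    to_behaviour: str
    minutes: float
    model_id: int
    delta: float
    ci_low: float
    ci_high: float

    @property
    def significant(self) -> bool:
        """CI excludes zero (two-sided at the level the CI was built at)."""
        return self.ci_low > 0 or self.ci_high < 0


def reallocate(reference, from_behaviour: str, to_behaviour: str, minutes: float) -> np.ndarray:
    """Move ``minutes`` from one behaviour to another, total preserved.

    E.g. a 30-min SB-to-MVPA reallocation subtracts 30 min from SB and adds
    30 min to MVPA, leaving sleep and LPA unchanged.
    """
    if from_behaviour == to_behaviour:
        raise ValueError("from and to behaviours must differ")
    if minutes < 0:
        raise ValueError("minutes must be >= 0")
    x = np.asarray(reference, dtype=float).copy()
    i, j = PART_ORDER.index(from_behaviour), PART_ORDER.index(to_behaviour)
    if minutes >= x[i]:
        raise ReallocationError(
            f"cannot move {minutes} min out of {from_behaviour} ({x[i]:.1f} min)"
        )
    x[i] -= minutes
    x[j] += minutes
    return x


def predict_delta(
    fit: RegressionFit,
    reference,
    from_behaviour: str,
    to_behaviour: str,
    minutes: float,
    alpha: float = 0.05,
) -> SubstitutionEstimate:
    """Delta-method estimate and CI for one reallocation.

    The ILR basis is taken from the fit's own pivot; the estimate is
    invariant to which rotation was used because all pivot bases span the
    same coordinate space.
    """
    sbp = sbp_pivot(len(PART_ORDER), fit.pivot_index)
    z_ref = ilr(np.asarray(reference, dtype=float), sbp)
    z_new = ilr(reallocate(reference, from_behaviour, to_behaviour, minutes), sbp)
    d = z_new - z_ref
    delta = float(d @ fit.ilr_params)
    se = float(np.sqrt(d @ fit.ilr_cov @ d))
    tcrit = float(stats.t.ppf(1 - alpha / 2, fit.df_resid))
    return SubstitutionEstimate(
        from_behaviour=from_behaviour,
        to_behaviour=to_behaviour,
        minutes=float(minutes),
        model_id=fit.model_id,
        delta=delta,
        ci_low=delta - tcrit * se,
        ci_high=delta + tcrit * se,
    )


def substitution_grid(
    fit: RegressionFit,
    reference,
    minutes_grid=DEFAULT_GRID,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All ordered behaviour pairs x the duration grid for one fitted model.

    Returns one row per (pair, t) cell with delta, CI bounds and a
    significance flag; infeasible cells (t would exhaust the donor) are
    kept as rows with missing estimates and a reason, never dropped
    silently.
    """
    rows = []
    for frm, to in ALL_PAIRS:
        for t in minutes_grid:
            row = {
                "from": frm,
                "to": to,
                "minutes": float(t),
                "model": fit.model_id,
            }
            try:
                est = predict_delta(fit, reference, frm, to, t, alpha)
                row.update(
                    delta=est.delta,
                    ci_low=est.ci_low,
                    ci_high=est.ci_high,
                    significant=est.significant,
                    status="ok",
                )
            except ReallocationError as exc:
                row.update(
                    delta=np.nan,
                    ci_low=np.nan,
                    ci_high=np.nan,
                    significant=False,
                    status=f"infeasible: {exc}",
                )
            rows.append(row)
    return pd.DataFrame(rows)


def focal_table(
    fit: RegressionFit,
    reference,
    minutes: float = 30.0,
    pairs=FOCAL_PAIRS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """The focal 30-min reallocations (SB->LPA, SB->MVPA, LPA->MVPA, SB->sleep)."""
    rows = []
    for frm, to in pairs:
        est = predict_delta(fit, reference, frm, to, minutes, alpha)
        rows.append(
            {
                "from": frm,
                "to": to,
                "minutes": minutes,
                "model": fit.model_id,
                "delta": est.delta,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "significant": est.significant,
            }
        )
    return pd.DataFrame(rows)


def export_curves(grid_table: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready long table of substitution curves.

    One row per (pair, t, model) with delta and CI bounds, for a 12-panel
    figure of well-being change against reallocated minutes.
    """
    out = grid_table.copy()
    out["pair"] = out["from"].str.upper() + " to " + out["to"].str.upper()
    cols = ["pair", "from", "to", "minutes", "delta", "ci_low", "ci_high", "model", "significant", "status"]
    return out[[c for c in cols if c in out.columns]].reset_index(drop=True)


def plot_curves(curves: pd.DataFrame, path=None):
    """12-panel substitution-curve figure (delta vs minutes, with CI band)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = list(dict.fromkeys(curves["pair"]))
    fig, axes = plt.subplots(4, 3, figsize=(11, 12), sharex=True)
    for ax, pair in zip(axes.ravel(), pairs):
        sub = curves[(curves["pair"] == pair) & curves["delta"].notna()]
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.plot(sub["minutes"], sub["delta"], color="C0")
        ax.fill_between(sub["minutes"], sub["ci_low"], sub["ci_high"], alpha=0.25)
        ax.set_title(pair, fontsize=9)
    fig.supxlabel("reallocated minutes")
    fig.supylabel("predicted WEMWBS change")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
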