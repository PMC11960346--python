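"""Synthetic cohort generator.

The study data behind this pipeline are not publicly deposited, so every
stage is exercised on synthetic cohorts whose statistical structure is
calibrated to the published marginals of the source cohort of 410
community-dwelling adults aged 55+:

* compositions are logistic-normal: ILR coordinates drawn from a
  multivariate normal centred at the ILR of the geometric-mean composition
  (TST 5.65 h, SB 13.88 h, LPA 2.58 h, MVPA 1.89 h) with a covariance
  whose implied pairwise log-ratio variances span 0.103 (TST-SB, the most
  co-dependent pair) to 0.550 (LPA-MVPA);
* covariates are drawn independently from the published frequency table
  (71% female, education 45/32/20, 77% married/cohabitant, 4% professionally
  active, 3% smokers, chronic condition 39/54/7 yes/no/missing, age
  ~ N(71.3, 6.3) truncated to the 55+ inclusion range);
* WEMWBS is a rounded, truncated linear response:
  score = intercept + z' beta_true + covariate effects + N(0, noise_sd),
  clipped to the 14-70 scale range.

The default ``beta_true`` is the ILR vector whose four pivot-rotated
first coordinates equal the published unadjusted per-behaviour
coefficients (-2.17, -0.43, 1.96, 0.64 for TST, SB, LPA, MVPA) — those
four numbers sum to zero, which is exactly the constraint a single ILR
vector imposes, so the mapping is one-to-one.  The intercept and residual
noise SD are solved analytically from the configured effect sizes and
marginals so that the simulated score has mean 53.75 and SD 8.43 by
construction.

The epoch-stream generator lays each day out as contiguous blocks
(sleep, SB, LPA, MVPA, non-wear) with behaviour-conditional count regimes
chosen so the preprocessing chain recovers the target daily minutes; it
emulates block structure and marginal durations only, not realistic
diurnal count waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coda import PART_ORDER, TOTAL_MIN, contrast_matrix, ilr, ilr_inverse, sbp_pivot
from .regression import CATEGORY_LEVELS

#: Geometric-mean composition of the source cohort, minutes (hours x 60).
DEFAULT_MEAN_COMPOSITION: tuple[float, ...] = (339.0, 832.8, 154.8, 113.4)

#: Per-part log-scale variances; pairwise log-ratio variance of parts i, j
#: is s_i + s_j, giving 0.103 for TST-SB and 0.550 for LPA-MVPA.
DEFAULT_LOG_PART_VAR: tuple[float, ...] = (0.0515, 0.0515, 0.275, 0.275)

#: Published unadjusted per-behaviour coefficients used to build beta_true.
DEFAULT_BEHAVIOUR_BETAS: tuple[float, ...] = (-2.17, -0.43, 1.96, 0.64)

#: Covariate category probabilities (normalised from published counts).
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"male": 120 / 410, "female": 290 / 410},
    "education": {"low": 183 / 398, "medium": 133 / 398, "high": 82 / 398},
    "marital": {"married/cohabitant": 315 / 410, "single": 95 / 410},
    "professional": {"active": 17 / 406, "inactive": 389 / 406},
    "smoking": {"no": 390 / 404, "yes": 14 / 404},
    "chronic": {"yes": 160 / 411, "no": 222 / 411, "missing": 29 / 411},
}

#: Additive WEMWBS effects per category (reference categories are 0);
#: magnitudes follow the published per-category score differences.
DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, float]] = {
    "sex": {"female": -1.39},
    "education": {"medium": 1.67, "high": 3.28},
    "marital": {"single": -4.28},
    "professional": {"active": -2.5},
    "smoking": {"yes": 0.35},
    "chronic": {"yes": 0.77},
}


def default_logratio_cov() -> np.ndarray:
    """ILR (pivot-1 basis) covariance implied by the default per-part
    log-scale variances."""
    v = contrast_matrix(sbp_pivot(4, 1))
    return v.T @ np.diag(DEFAULT_LOG_PART_VAR) @ v


def default_beta_true() -> np.ndarray:
    """ILR effect vector reproducing the published per-behaviour betas.

    For 4 parts, the pivot-rotated first coordinate for behaviour k has clr
    coefficient vector u_k with u_k' c = (2/sqrt(3)) c_k for any zero-sum
    clr vector c, so c = sqrt(3)/2 x (per-behaviour betas) and
    beta = V' c in the pivot-1 basis.
    """
    c = np.sqrt(3.0) / 2.0 * np.asarray(DEFAULT_BEHAVIOUR_BETAS)
    return contrast_matrix(sbp_pivot(4, 1)).T @ c


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n: int = 410
    seed: int = 0
    mean_composition: tuple[float, ...] = DEFAULT_MEAN_COMPOSITION
    logratio_cov: np.ndarray = field(default_factory=default_logratio_cov)
    beta_true: np.ndarray = field(default_factory=default_beta_true)
    covariate_marginals: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()})
    covariate_effects: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()})
    age_mean: float = 71.3
    age_sd: float = 6.3
    age_range: tuple[float, float] = (55.0, 95.0)
    age_effect: float = -0.05  # WEMWBS points per year, centred at age_mean
    wemwbs_mean: float = 53.75
    wemwbs_sd: float = 8.43
    noise_sd: float | None = None  # solved from wemwbs_sd when None
    confounded: bool = False
    short_wear_fraction: float = 43 / 453

    def __post_init__(self) -> None:
        mc = np.asarray(self.mean_composition, dtype=float)
        if np.any(mc <= 0):
            raise ValueError("mean_composition must be positive")
        self.mean_composition = tuple(mc * (TOTAL_MIN / mc.sum()))
        cov = np.asarray(self.logratio_cov, dtype=float)
        if not np.allclose(cov, cov.T) or np.any(np.linalg.eigvalsh(cov) < -1e-12):
            raise ValueError("logratio_cov must be symmetric positive semi-definite")
        self.logratio_cov = cov
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        for var, probs in self.covariate_marginals.items():
            p = np.asarray(list(probs.values()))
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
                raise ValueError(f"marginals for {var} must be a probability vector")

    # -- analytic calibration ------------------------------------------------

    def _covariate_mean_var(self) -> tuple[float, float]:
        """Mean and variance of the summed covariate effects."""
        mean = 0.0
        var = (self.age_effect * self.age_sd) ** 2
        for cov, probs in self.covariate_marginals.items():
            effects = self.covariate_effects.get(cov, {})
            vals = np.array([effects.get(level, 0.0) for level in probs])
            p = np.array(list(probs.values()))
            m = float(p @ vals)
            mean += m
            var += float(p @ vals**2) - m**2
        return mean, var

    def systematic_variance(self) -> float:
        """Variance of the linear predictor (ILR effects + covariates)."""
        ilr_var = float(self.beta_true @ self.logratio_cov @ self.beta_true)
        return ilr_var + self._covariate_mean_var()[1]

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        resid = self.wemwbs_sd**2 - self.systematic_variance()
        if resid <= 0:
            raise ValueError(
                "wemwbs_sd too small for the configured effect sizes; "
                "set noise_sd explicitly"
            )
        return float(np.sqrt(resid))

    def intercept(self) -> float:
        sbp = sbp_pivot(4, 1)
        z_mean = ilr(np.asarray(self.mean_composition), sbp)
        cov_mean, _ = self._covariate_mean_var()
        return float(self.wemwbs_mean - z_mean @ self.beta_true - cov_mean)


def _draw_age(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.age_range
    a, b = (lo - cfg.age_mean) / cfg.age_sd, (hi - cfg.age_mean) / cfg.age_sd
    return stats.truncnorm.rvs(
        a, b, loc=cfg.age_mean, scale=cfg.age_sd, size=cfg.n, random_state=rng
    )


def generate_participants(cfg: GeneratorConfig, items: bool = False) -> pd.DataFrame:
    """Simulate the participant analysis table.

    Columns: participant_id, the four behaviour minutes (closed to 1440),
    age and categorical covariates, and the wemwbs score (integer, clipped
    to 14..70).  With ``items=True``, 14 item columns consistent with the
    total score are added.  Deterministic given the config (seed included).
    """
    rng = np.random.default_rng(cfg.seed)
    sbp = sbp_pivot(4, 1)
    z_mean = ilr(np.asarray(cfg.mean_composition), sbp)

    age = _draw_age(cfg, rng)
    cats = {
        var: rng.choice(list(probs), size=cfg.n, p=list(probs.values()))
        for var, probs in cfg.covariate_marginals.items()
    }

    z = rng.multivariate_normal(np.zeros(3), cfg.logratio_cov, size=cfg.n)
    z += z_mean
    if cfg.confounded:
        # age and sex shift the composition mean: older and female -> more
        # sleep/SB, less MVPA; exercises covariate adjustment in tests
        z += np.outer((age - cfg.age_mean) / cfg.age_sd, [0.08, 0.05, 0.15])
        z += np.outer(cats["sex"] == "female", [0.05, 0.03, 0.09])
    comp = ilr_inverse(z, sbp)

    effects = np.full(cfg.n, cfg.intercept())
    effects += cfg.age_effect * (age - cfg.age_mean)
    for var, vals in cats.items():
        eff = cfg.covariate_effects.get(var, {})
        for level, e in eff.items():
            effects += np.where(vals == level, e, 0.0)
    score = effects + z @ cfg.beta_true + rng.normal(0.0, cfg.resolved_noise_sd(), cfg.n)
    wemwbs = np.clip(np.round(score), 14, 70).astype(int)

    df = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:04d}" for i in range(cfg.n)],
            **dict(zip(PART_ORDER, comp.T)),
            "age": age,
            **cats,
            "wemwbs": wemwbs,
        }
    )
    if items:
        item_cols = np.array(
            [rng.multivariate_hypergeometric([4] * 14, s - 14) + 1 for s in wemwbs]
        )
        for j in range(14):
            df[f"item{j + 1:02d}"] = item_cols[:, j]
    return df


# -- epoch streams -----------------------------------------------------------

#: Count regimes (counts per 60-s epoch) used to synthesise streams; chosen
#: so the default cut-points and sleep scorer recover the block labels.
SLEEP_COUNTS = (1, 30)
SB_COUNTS = (110, 2860)
LPA_COUNTS = (2861, 3940)
MVPA_COUNTS = (3941, 8000)
SB_RAMP_EPOCHS = 3  # low-count SB epochs after waking, keeps the sleep scorer sharp


def _day_counts(target_min: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One 1440-epoch day: [sleep][SB][LPA][MVPA][non-wear zeros]."""
    tst, sb, lpa, mvpa = (int(round(m)) for m in target_min)
    nonwear = 1440 - (tst + sb + lpa + mvpa)
    if nonwear < 0:
        raise ValueError("target minutes exceed 1440")
    blocks = [
        rng.integers(SLEEP_COUNTS[0], SLEEP_COUNTS[1] + 1, tst),
        rng.integers(SB_COUNTS[0], 191, min(SB_RAMP_EPOCHS, sb)),
        rng.integers(SB_COUNTS[0], SB_COUNTS[1] + 1, max(sb - SB_RAMP_EPOCHS, 0)),
        rng.integers(LPA_COUNTS[0], LPA_COUNTS[1] + 1, lpa),
        rng.integers(MVPA_COUNTS[0], MVPA_COUNTS[1] + 1, mvpa),
        np.zeros(nonwear, dtype=int),
    ]
    return np.concatenate(blocks)


def epoch_stream(
    participant_id: str,
    target_min: np.ndarray,
    n_days: int,
    rng: np.random.Generator,
    start: str = "2023-05-01",
) -> pd.DataFrame:
    """Synthetic 60-s epoch stream with ``n_days`` complete calendar days."""
    counts = np.concatenate([_day_counts(target_min, rng) for _ in range(n_days)])
    ts = pd.date_range(start, periods=counts.size, freq="60s")
    return pd.DataFrame(
        {"participant_id": participant_id, "timestamp": ts, "vm3": counts}
    )


def generate_epoch_streams(
    cfg: GeneratorConfig,
    days_per_participant: int = 6,
    wear_total_min: float = 1340.0,
    participants: pd.DataFrame | None = None,
):
    """Yield (participant_id, epoch DataFrame) for a whole cohort.

    Daily targets are each participant's composition scaled so sleep +
    waking wear fills ``wear_total_min`` of the day (the rest is a
    contiguous non-wear block).  A deterministic ``short_wear_fraction`` of
    participants get only 3 valid days (the other days heavily truncated),
    so they fail the 4-valid-day inclusion rule downstream.
    """
    if participants is None:
        participants = generate_participants(cfg)
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31))
    n = len(participants)
    n_short = int(round(cfg.short_wear_fraction * n))
    short = np.zeros(n, dtype=bool)
    if n_short:
        short[rng.choice(n, size=n_short, replace=False)] = True

    comp = participants[list(PART_ORDER)].to_numpy(dtype=float)
    for i, pid in enumerate(participants["participant_id"]):
        target = comp[i] * (wear_total_min / TOTAL_MIN)
        if not short[i]:
            yield pid, epoch_stream(pid, target, days_per_participant, rng)
            continue
        # 3 normal days then days with < 10 h waking wear (scaled down)
        waking = target[1:].sum()
        cut = target * (400.0 / waking)
        frames = [epoch_stream(pid, target, 3, rng)]
        tail_start = frames[0]["timestamp"].iloc[-1] + pd.Timedelta(seconds=60)
        tail = epoch_stream(pid, cut, days_per_participant - 3, rng, start=tail_start)
        frames.append(tail)
        yield pid, pd.concat(frames, ignore_index=True)


def fixture_small(seed: int = 20240401) -> dict[str, pd.DataFrame]:
    """Deterministic 12-participant mini-cohort for unit tests.

    Contains one zero-MVPA raw composition (P0011, exercising the zero
    check/replacement path) and one participant with only 3 valid wear
    days (P0012, excluded by the inclusion rule).  Returns dict with:

    * ``raw`` — 12 raw behaviour-minute vectors (one with mvpa = 0),
    * ``participants`` — the 11-participant analysis table (zeros replaced
      multiplicatively, compositions closed to 1440),
    * ``daily`` — per-day summaries, P0012 having 3 valid + 2 invalid days.
    """
    from .accel import DailySummary
    from .coda import closure, replace_zeros

    cfg = GeneratorConfig(n=12, seed=seed)
    base = generate_participants(cfg)
    raw = base[["participant_id", *PART_ORDER]].copy()
    raw[list(PART_ORDER)] = raw[list(PART_ORDER)].round(0)
    raw.loc[10, "mvpa"] = 0.0

    fixed = np.vstack(
        [replace_zeros(r, delta=1.0) for r in raw[list(PART_ORDER)].to_numpy()]
    )
    participants = base.copy()
    participants[list(PART_ORDER)] = closure(fixed)
    participants = participants.drop(index=11).reset_index(drop=True)

    daily_rows = []
    for i, row in raw.iterrows():
        pid = row["participant_id"]
        mins = np.maximum(row[list(PART_ORDER)].to_numpy(dtype=float), 1.0) * (1340.0 / 1440.0)
        n_valid, n_invalid = (3, 2) if pid == "P0012" else (4, 0)
        for d in range(n_valid):
            daily_rows.append(
                DailySummary(pid, pd.Timestamp("2023-05-01").date() + pd.Timedelta(days=d).to_pytimedelta(),
                             *mins, waking_wear_min=float(mins[1:].sum()), is_valid=True)
            )
        for d in range(n_invalid):
            cut = mins * (400.0 / mins[1:].sum())
            daily_rows.append(
                DailySummary(pid, pd.Timestamp("2023-05-01").date() + pd.Timedelta(days=n_valid + d).to_pytimedelta(),
                             *cut, waking_wear_min=float(cut[1:].sum()), is_valid=False)
            )
    daily = pd.DataFrame([vars(d) for d in daily_rows])
    return {"raw": raw, "participants": participants, "daily": daily}
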