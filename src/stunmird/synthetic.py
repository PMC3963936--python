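"""Seeded synthetic cohorts with the statistical structure of the study.

Every generator is a pure function of its config and seed, so the whole
pipeline is testable without animal data.  Defaults encode the study
conditions: four injected-activity groups (10/25/100/150 MBq with n =
4/9/9/29) whose decay-corrected %ID distributions are 2.84±0.63, 2.6±0.35,
2.67±0.33 and 2.63±0.47; a 1 h uptake peak sampled at 1/3/7 h; an effective
washout of median 0.23 h⁻¹ (log-normal, geometric SD 1.15 — calibrated so
the four group mean absorbed doses land on 2.6/4.8/19.6/28.4 Gy, see
docs/methods.md); a 22 Gy stunning threshold with mean uptake changes
−3.95% below and −17.5% above; and recovery to 100% of baseline by day 4
after a 55%-of-baseline trough at day 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emissions import TC99M_HALF_LIFE_H
from .tac import TACFit, tac_model

__all__ = [
    "CohortConfig",
    "StunningConfig",
    "ConfigError",
    "synth_cohort",
    "synth_stunning",
    "synth_recovery",
    "synth_qpcr",
    "DEFAULT_GROUPS",
    "DEFAULT_DELTA_CT",
]

DEFAULT_SEED = 20140324

#: (injected_MBq, n, %ID mean, %ID sd) per group — the study's cohort design.
DEFAULT_GROUPS: tuple[tuple[float, int, float, float], ...] = (
    (10.0, 4, 2.84, 0.63),
    (25.0, 9, 2.6, 0.35),
    (100.0, 9, 2.67, 0.33),
    (150.0, 29, 2.63, 0.47),
)

#: Group mean ΔCt (target − reference) giving 2.5-fold and 12-fold NIS
#: downregulation at 20 and 30 Gy relative to control; 5 Gy has no effect.
DEFAULT_DELTA_CT: dict[str, float] = {
    "control": 3.0,
    "5Gy": 3.0,
    "20Gy": 3.0 + float(np.log2(2.5)),
    "30Gy": 3.0 + float(np.log2(12.0)),
}


class ConfigError(ValueError):
    """Raised when a generator config is invalid; lists every offender."""


def _validate(conditions: list[tuple[bool, str]]) -> None:
    bad = [msg for ok, msg in conditions if not ok]
    if bad:
        raise ConfigError("invalid config: " + "; ".join(bad))


@dataclass(frozen=True)
class CohortConfig:
    """Imaging-cohort generator settings.

    ``pid_mean``/``pid_sd`` per group are *decay-corrected* %ID at the peak
    scan; the emitted (measured) activities are not decay-corrected, matching
    how time–activity curves are recorded.
    """

    groups: tuple[tuple[float, int, float, float], ...] = DEFAULT_GROUPS
    peak_time: float = 1.0  # h
    lambda_eff_median: float = 0.23  # 1/h
    lambda_eff_gsd: float = 1.15  # geometric SD (1 = no spread)
    sample_times: tuple[float, ...] = (1.0, 3.0, 7.0)
    measurement_cv: float = 0.05
    half_life: float = TC99M_HALF_LIFE_H
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        _validate(
            [
                (len(self.groups) > 0, "groups must be non-empty"),
                (all(g[1] >= 1 for g in self.groups), "every group n must be >= 1"),
                (all(g[0] > 0 for g in self.groups), "injected activity must be > 0"),
                (all(g[2] > 0 for g in self.groups), "pid_mean must be > 0"),
                (all(g[3] >= 0 for g in self.groups), "pid_sd must be >= 0"),
                (self.peak_time > 0, "peak_time must be > 0"),
                (self.lambda_eff_median > 0, "lambda_eff_median must be > 0"),
                (self.lambda_eff_gsd >= 1.0, "lambda_eff_gsd must be >= 1"),
                (self.measurement_cv >= 0, "measurement_cv must be >= 0"),
                (
                    len(self.sample_times) > 0
                    and bool(np.all(np.diff(self.sample_times) > 0)),
                    "sample_times must be strictly increasing",
                ),
            ]
        )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal draws redrawn (not clipped) until positive, keeping the shape
    of the distribution near zero unbiased."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        neg = out <= 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean, sd, int(neg.sum()))
    raise ConfigError(f"cannot draw positive values from N({mean}, {sd})")


def synth_cohort(config: CohortConfig = CohortConfig()) -> pd.DataFrame:
    """Generate a per-animal time–activity table.

    Per animal: %ID ~ N(pid_mean, pid_sd) truncated positive; the measured
    peak activity is %ID·injected/100 decayed over ``peak_time``;
    λ_eff ~ log-normal(median, gsd); activities at ``sample_times`` follow
    the piecewise linear/mono-exponential model with mean-preserving
    multiplicative log-normal noise of CV ``measurement_cv``.

    Returns the TAC CSV schema: ``animal_id,time_h,activity_MBq,injected_MBq``.
    """
    rng = np.random.default_rng(config.seed)
    sigma = float(np.sqrt(np.log1p(config.measurement_cv**2)))
    times = np.asarray(config.sample_times)
    rows = []
    for gi, (injected, n, pid_mean, pid_sd) in enumerate(config.groups):
        pid = _truncated_normal(rng, pid_mean, pid_sd, n)
        lam = rng.lognormal(
            np.log(config.lambda_eff_median), np.log(config.lambda_eff_gsd), n
        )
        for i in range(n):
            peak = (
                pid[i] / 100.0 * injected * 2.0 ** (-config.peak_time / config.half_life)
            )
            fit = TACFit(
                peak_time=config.peak_time, peak_activity=peak, lambda_eff=float(lam[i])
            )
            ideal = tac_model(fit, times)
            noise = (
                np.exp(rng.normal(-0.5 * sigma**2, sigma, len(times)))
                if sigma > 0
                else np.ones(len(times))
            )
            act = np.minimum(ideal * noise, injected)
            for t, a in zip(times, act):
                rows.append(
                    {
                        "animal_id": f"g{gi + 1}_m{int(round(injected)):03d}_{i + 1:02d}",
                        "time_h": float(t),
                        "activity_MBq": float(a),
                        "injected_MBq": float(injected),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StunningConfig:
    """Stunning / recovery generator settings.

    ``mean_change_below``/``mean_change_above`` are the mean percent changes
    in rechallenge uptake on either side of ``threshold`` Gy;
    ``recovery_by_day`` maps follow-up day to the mean uptake as percent of
    day 0.
    """

    threshold: float = 22.0  # Gy
    mean_change_below: float = -3.95  # %
    mean_change_above: float = -17.5  # %
    change_sd: float = 5.0  # %
    recovery_by_day: dict[int, float] = field(
        default_factory=lambda: {1: 55.0, 2: 60.0, 4: 100.0, 8: 100.0}
    )
    recovery_sd: float = 8.0  # % of baseline
    baseline_mean: float = 2.63  # %ID-like baseline uptake scale
    baseline_sd: float = 0.47
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        _validate(
            [
                (self.threshold > 0, "threshold must be > 0"),
                (
                    self.mean_change_above <= self.mean_change_below <= 0,
                    "stunning scenario needs mean_change_above <= mean_change_below <= 0",
                ),
                (self.change_sd >= 0, "change_sd must be >= 0"),
                (self.recovery_sd >= 0, "recovery_sd must be >= 0"),
                (
                    all(v > 0 for v in self.recovery_by_day.values()),
                    "recovery means must be > 0",
                ),
                (self.baseline_mean > 0, "baseline_mean must be > 0"),
                (self.baseline_sd >= 0, "baseline_sd must be >= 0"),
            ]
        )


def synth_stunning(
    config: StunningConfig, doses: list[float] | np.ndarray, day: int = 1
) -> pd.DataFrame:
    """Generate rechallenge records for given initial absorbed doses.

    Percent change ~ N(mean_change_below, change_sd) below the threshold and
    N(mean_change_above, change_sd) at or above it; the rechallenge uptake is
    derived from a positive baseline draw and the sampled change.
    Schema: ``animal_id,initial_dose_Gy,baseline_uptake,rechallenge_uptake,day``.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ConfigError("doses must be non-empty")
    rng = np.random.default_rng(config.seed)
    baseline = _truncated_normal(rng, config.baseline_mean, config.baseline_sd, doses.size)
    means = np.where(
        doses < config.threshold, config.mean_change_below, config.mean_change_above
    )
    change = rng.normal(means, config.change_sd) if config.change_sd > 0 else means
    rechallenge = baseline * (1.0 + change / 100.0)
    return pd.DataFrame(
        {
            "animal_id": [f"s{i + 1:02d}" for i in range(doses.size)],
            "initial_dose_Gy": doses,
            "baseline_uptake": baseline,
            "rechallenge_uptake": rechallenge,
            "day": int(day),
        }
    )


def synth_recovery(
    config: StunningConfig, n_per_day: int = 3, initial_dose: float = 30.0
) -> pd.DataFrame:
    """Generate the longitudinal recovery cohort.

    For each day in ``config.recovery_by_day``, ``n_per_day`` animals get an
    uptake of N(mean_day, recovery_sd) percent of their day-0 baseline
    (truncated positive).  Same schema as :func:`synth_stunning`.
    """
    if n_per_day < 1:
        raise ConfigError("n_per_day must be >= 1")
    rng = np.random.default_rng(config.seed)
    rows = []
    idx = 0
    for day in sorted(config.recovery_by_day):
        mean_pct = config.recovery_by_day[day]
        baseline = _truncated_normal(rng, config.baseline_mean, config.baseline_sd, n_per_day)
        pct = _truncated_normal(rng, mean_pct, config.recovery_sd, n_per_day)
        for b, p in zip(baseline, pct):
            idx += 1
            rows.append(
                {
                    "animal_id": f"r{idx:02d}",
                    "initial_dose_Gy": float(initial_dose),
                    "baseline_uptake": float(b),
                    "rechallenge_uptake": float(b * p / 100.0),
                    "day": int(day),
                }
            )
    return pd.DataFrame(rows)


def synth_qpcr(
    n_per_group: int = 4,
    delta_ct_means: dict[str, float] | None = None,
    sd: float = 0.5,
    seed: int = DEFAULT_SEED,
    reference_ct: float = 20.0,
) -> pd.DataFrame:
    """Generate a comparative-CT qPCR table.

    Each sample draws a reference Ct ~ N(reference_ct, sd) and a target Ct =
    reference Ct + ΔCt_group + N(0, sd), so group expression ratios equal the
    configured fold changes in expectation (exactly, when ``sd = 0``).
    Schema: ``sample_id,group,ct_target,ct_reference``.
    """
    if sd < 0:
        raise ConfigError("sd must be >= 0")
    if n_per_group < 1:
        raise ConfigError("n_per_group must be >= 1")
    if delta_ct_means is None:
        delta_ct_means = DEFAULT_DELTA_CT
    rng = np.random.default_rng(seed)
    rows = []
    for group in delta_ct_means:  # preserve caller ordering
        dct = delta_ct_means[group]
        for i in range(n_per_group):
            ct_ref = reference_ct + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            ct_tgt = ct_ref + dct + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1:02d}",
                    "group": group,
                    "ct_target": float(ct_tgt),
                    "ct_reference": float(ct_ref),
                }
            )
    return pd.DataFrame(rows)
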