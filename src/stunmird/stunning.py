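"""Thyroid stunning statistics.

Stunning is a reversible loss of radiotracer uptake capacity after a prior
radiation exposure, without tissue destruction.  This module quantifies it
three ways:

* :func:`percent_change` — signed percent change between a baseline scan and
  a rechallenge scan (negative = stunning);
* :func:`threshold_scan` — dose-threshold detection: candidate thresholds are
  midpoints between consecutive distinct observed doses, each split is
  compared with a two-sided Student t-test on the percent changes, the
  maximally separating candidate is selected, and the *selection-adjusted*
  significance is calibrated by permutation of the max-|t| statistic (an
  uncorrected per-candidate p is also reported, and ``adjust="none"``
  reproduces the uncorrected smallest-significant-candidate rule);
* :func:`recovery_profile` — longitudinal per-day uptake relative to day 0,
  with per-day t-tests against 100% and a one-way ANOVA across days.

:func:`relative_expression` implements the comparative-CT qPCR measure
2^(−ΔCT) used for NIS mRNA quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StunningRecord",
    "ThresholdResult",
    "RecoveryDay",
    "RecoveryProfile",
    "percent_change",
    "threshold_scan",
    "recovery_profile",
    "relative_expression",
    "qpcr_fold_changes",
]


@dataclass(frozen=True)
class StunningRecord:
    """One animal's rechallenge outcome after an initial absorbed dose.

    ``baseline_uptake`` and ``rechallenge_uptake`` must share a unit (%ID or
    MBq); ``day`` is the interval between the two scans in days.
    """

    animal_id: str
    initial_dose: float  # Gy
    baseline_uptake: float
    rechallenge_uptake: float
    day: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.baseline_uptake) or self.baseline_uptake <= 0:
            raise ValueError(
                f"animal {self.animal_id!r}: baseline uptake must be a positive "
                "finite number (missing day-0 pairing?)"
            )
        if self.day < 1:
            raise ValueError(f"animal {self.animal_id!r}: day must be >= 1")

    @property
    def percent_change(self) -> float:
        return percent_change(self.baseline_uptake, self.rechallenge_uptake)


def percent_change(baseline: float, rechallenge: float) -> float:
    """Signed percent change 100·(rechallenge − baseline)/baseline."""
    if baseline <= 0:
        raise ValueError("baseline uptake must be > 0")
    return 100.0 * (rechallenge - baseline) / baseline


@dataclass(frozen=True)
class ThresholdResult:
    """Detected stunning dose threshold.

    ``p_value`` is the selection-adjusted (permutation) p when
    ``adjust="permutation"`` was used, otherwise the per-candidate Student-t
    p.  ``p_naive`` is always the unadjusted t-test p at the selected split.
    """

    threshold: float  # Gy
    p_value: float
    mean_below: float  # mean percent change below the threshold
    mean_above: float
    n_below: int
    n_above: int
    significant: bool
    p_naive: float
    method: str = "max-t + permutation"
    candidates: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def _split_t_stats(values: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Student t statistics for all prefix splits of ``values``.

    ``values`` has shape (P, n), one row per (permuted) dataset sorted by
    dose; ``ks`` are the below-group sizes.  Returns shape (P, len(ks)).
    """
    p, n = values.shape
    cs = np.cumsum(values, axis=1)
    css = np.cumsum(values**2, axis=1)
    tot, tots = cs[:, -1][:, None], css[:, -1][:, None]
    k = ks[None, :].astype(float)
    s1 = cs[:, ks - 1]
    ss1 = css[:, ks - 1]
    n2 = n - k
    m1 = s1 / k
    m2 = (tot - s1) / n2
    sse = (ss1 - k * m1**2) + ((tots - ss1) - n2 * m2**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = sse / (n - 2)
        t = (m1 - m2) / np.sqrt(pooled * (1.0 / k + 1.0 / n2))
    return np.where(np.isfinite(t), t, np.inf * np.sign(m1 - m2))


def threshold_scan(
    records: list[StunningRecord],
    alpha: float = 0.05,
    *,
    min_per_side: int = 3,
    adjust: str = "permutation",
    n_permutations: int = 999,
    seed: int = 20140324,
    equal_var: bool = True,
) -> ThresholdResult:
    """Scan candidate dose thresholds for a stunning effect.

    Candidates are midpoints between consecutive distinct observed doses with
    at least ``min_per_side`` records on each side.  Each candidate is scored
    with a two-sided two-sample Student t-test (Welch with
    ``equal_var=False``) comparing percent changes below vs above.

    With ``adjust="permutation"`` (default) the candidate with maximal |t| is
    selected and its p-value is the permutation tail probability of the
    max-|t| statistic, which keeps the family-wise false-positive rate at
    ``alpha`` despite the search.  With ``adjust="none"`` the smallest
    candidate whose unadjusted p falls below ``alpha`` is returned (or, if
    none, the minimal-p candidate flagged non-significant).

    Raises
    ------
    ValueError
        If all doses are identical or no candidate split has
        ``min_per_side`` records on each side.
    """
    if adjust not in ("permutation", "none"):
        raise ValueError(f"unknown adjust mode {adjust!r}")
    if len(records) < 2 * min_per_side:
        raise ValueError(
            f"need >= {2 * min_per_side} records for a threshold scan, got {len(records)}"
        )
    doses = np.array([r.initial_dose for r in records])
    changes = np.array([r.percent_change for r in records])
    order = np.argsort(doses, kind="stable")
    doses, changes = doses[order], changes[order]
    if np.ptp(doses) == 0:
        raise ValueError("all doses identical; no candidate thresholds exist")

    # below-group sizes k at which dose[k-1] < dose[k] (distinct-value splits)
    distinct = np.nonzero(np.diff(doses) > 0)[0] + 1
    ks = distinct[(distinct >= min_per_side) & (len(doses) - distinct >= min_per_side)]
    if len(ks) == 0:
        raise ValueError(
            f"no candidate threshold has >= {min_per_side} records on each side"
        )
    mids = 0.5 * (doses[ks - 1] + doses[ks])

    if equal_var:
        t_obs = _split_t_stats(changes[None, :], ks)[0]
        df = len(doses) - 2
        p_naive = 2.0 * stats.t.sf(np.abs(t_obs), df)
    else:
        t_obs = np.empty(len(ks))
        p_naive = np.empty(len(ks))
        for i, k in enumerate(ks):
            res = stats.ttest_ind(changes[:k], changes[k:], equal_var=False)
            t_obs[i], p_naive[i] = res.statistic, res.pvalue

    cand = pd.DataFrame(
        {
            "threshold_Gy": mids,
            "n_below": ks,
            "n_above": len(doses) - ks,
            "t": t_obs,
            "p_naive": p_naive,
        }
    )

    if adjust == "permutation":
        best = int(np.argmax(np.abs(t_obs)))
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(changes) for _ in range(n_permutations)])
        if equal_var:
            t_perm = _split_t_stats(perms, ks)
        else:  # pragma: no cover - slow path, same logic
            t_perm = np.empty((n_permutations, len(ks)))
            for j in range(n_permutations):
                for i, k in enumerate(ks):
                    t_perm[j, i] = stats.ttest_ind(
                        perms[j, :k], perms[j, k:], equal_var=False
                    ).statistic
        max_obs = float(np.max(np.abs(t_obs)))
        exceed = int(np.sum(np.max(np.abs(t_perm), axis=1) >= max_obs))
        p_sel = (1.0 + exceed) / (n_permutations + 1.0)
        significant = p_sel < alpha
    else:
        sig = np.nonzero(p_naive < alpha)[0]
        best = int(sig[0]) if len(sig) else int(np.argmin(p_naive))
        p_sel = float(p_naive[best])
        significant = len(sig) > 0

    k = int(ks[best])
    return ThresholdResult(
        threshold=float(mids[best]),
        p_value=float(p_sel),
        mean_below=float(changes[:k].mean()),
        mean_above=float(changes[k:].mean()),
        n_below=k,
        n_above=len(doses) - k,
        significant=bool(significant),
        p_naive=float(p_naive[best]),
        method=(
            "max-|t| selection, permutation-adjusted p"
            if adjust == "permutation"
            else "smallest candidate with unadjusted p < alpha (no multiplicity correction)"
        ),
        candidates=cand,
    )


@dataclass(frozen=True)
class RecoveryDay:
    """Summary of one follow-up day: uptake as percent of day 0."""

    day: int
    mean: float
    sd: float | None
    n: int
    p_vs_day0: float | None
    recovered: bool | None


@dataclass(frozen=True)
class RecoveryProfile:
    """Per-day recovery summaries plus a one-way ANOVA across days."""

    days: tuple[RecoveryDay, ...]
    anova_p: float | None

    def day(self, d: int) -> RecoveryDay:
        for rd in self.days:
            if rd.day == d:
                return rd
        raise KeyError(f"no records for day {d}")


def recovery_profile(
    records: list[StunningRecord], alpha: float = 0.05
) -> RecoveryProfile:
    """Longitudinal recovery: per-day mean ± SD of 100·(uptake/day-0 uptake).

    Each record's ``baseline_uptake`` is its own day-0 value (the record
    validates positivity and finiteness, naming the animal on failure).
    A day is flagged ``recovered`` when its mean lies within one SD of 100%
    or the per-day t-test against 100% is non-significant; with a single
    animal SD and p-value are undefined and the flag is ``None``.
    """
    if not records:
        raise ValueError("no records")
    by_day: dict[int, list[float]] = {}
    for r in records:
        by_day.setdefault(r.day, []).append(
            100.0 * r.rechallenge_uptake / r.baseline_uptake
        )

    days: list[RecoveryDay] = []
    groups = []
    for d in sorted(by_day):
        vals = np.asarray(by_day[d])
        n = len(vals)
        mean = float(vals.mean())
        if n >= 2:
            sd = float(vals.std(ddof=1))
            p = float(stats.ttest_1samp(vals, 100.0).pvalue)
            recovered = abs(mean - 100.0) <= sd or p >= alpha
            groups.append(vals)
        else:
            sd, p, recovered = None, None, None
        days.append(
            RecoveryDay(day=int(d), mean=mean, sd=sd, n=n, p_vs_day0=p, recovered=recovered)
        )

    anova_p = (
        float(stats.f_oneway(*groups).pvalue) if len(groups) >= 2 else None
    )
    return RecoveryProfile(days=tuple(days), anova_p=anova_p)


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """Comparative-CT relative expression 2^(−(ct_target − ct_reference))."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (-(ct_target - ct_reference)))


def qpcr_fold_changes(
    table: pd.DataFrame, control_group: str = "control"
) -> pd.DataFrame:
    """Per-group relative expression and fold change versus a control group.

    ``table`` needs columns ``sample_id, group, ct_target, ct_reference``.
    Fold change is the ratio of group-mean 2^(−ΔCT) computed on mean ΔCt
    (i.e. the geometric-mean expression ratio); the p-value is a two-sided
    Student t-test on ΔCt against the control group.
    """
    for col in ("group", "ct_target", "ct_reference"):
        if col not in table.columns:
            raise ValueError(f"qPCR table is missing column {col!r}")
    df = table.copy()
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    if control_group not in set(df["group"]):
        raise ValueError(f"control group {control_group!r} not present")
    ctrl = df.loc[df["group"] == control_group, "delta_ct"].to_numpy()
    rows = []
    for grp, sub in df.groupby("group", sort=True):
        dct = sub["delta_ct"].to_numpy()
        mean_dct = float(dct.mean())
        fold_vs_control = float(2.0 ** (-(mean_dct - ctrl.mean())))
        if grp == control_group or len(dct) < 2 or len(ctrl) < 2:
            p = None if grp != control_group else 1.0
        elif dct.var(ddof=1) == 0.0 and ctrl.var(ddof=1) == 0.0:
            # degenerate zero-noise tables: identical means are indistinct,
            # different means are trivially separated
            p = 1.0 if dct.mean() == ctrl.mean() else 0.0
        else:
            p = float(stats.ttest_ind(dct, ctrl, equal_var=True).pvalue)
        rows.append(
            {
                "group": grp,
                "n": len(dct),
                "mean_delta_ct": mean_dct,
                "relative_expression": float(2.0 ** (-mean_dct)),
                "fold_vs_control": fold_vs_control,
                "p_vs_control": p,
            }
        )
    return pd.DataFrame(rows)
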