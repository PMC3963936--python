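"""Table schemas, validation, report formatting and the end-to-end pipeline.

All on-disk tables are comma-separated UTF-8 with a required header and '.'
decimals.  Readers validate the schema and report offending line numbers;
writers round-trip losslessly through the readers.  JSON reports use sorted
keys and 12-significant-digit floats so identical inputs and seed produce
byte-identical output.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .dose import (
    DEFAULT_S_VALUE,
    calibrate_peak_to_dose,
    dose_records_to_frame,
    doses_from_tac_table,
)
from .emissions import load_emission_spectrum
from .phantom import build_phantom
from .stunning import StunningRecord, recovery_profile, threshold_scan
from .transport import self_svalue

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "read_tac_table",
    "read_stunning_table",
    "read_qpcr_table",
    "stunning_records_from_frame",
    "json_report",
    "run_pipeline",
]

log = logging.getLogger("stunmird")

TAC_COLUMNS = {
    "animal_id": str,
    "time_h": float,
    "activity_MBq": float,
    "injected_MBq": float,
}
STUNNING_COLUMNS = {
    "animal_id": str,
    "initial_dose_Gy": float,
    "baseline_uptake": float,
    "rechallenge_uptake": float,
    "day": int,
}
QPCR_COLUMNS = {
    "sample_id": str,
    "group": str,
    "ct_target": float,
    "ct_reference": float,
}


class SchemaError(ValueError):
    """Raised when an input table violates its schema."""


def _read_table(path: str | Path, schema: dict[str, type], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{name} table not found: {path}")
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{name} table {path} is empty") from exc
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{name} table {path} is missing required columns: {', '.join(missing)}"
        )
    if len(df) == 0:
        raise SchemaError(f"{name} table {path} has a header but no rows")
    for col, typ in schema.items():
        if typ is str:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            # +2: header line and 1-based numbering
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise SchemaError(
                f"{name} table {path}: non-numeric value(s) in column {col!r} "
                f"at line(s) {lines}"
            )
        df[col] = coerced.astype(typ)
    return df


def read_tac_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a time–activity CSV."""
    df = _read_table(path, TAC_COLUMNS, "TAC")
    if (df["activity_MBq"] < 0).any() or (df["injected_MBq"] <= 0).any():
        raise SchemaError(f"TAC table {path}: activities must be >= 0 and injected > 0")
    return df


def read_stunning_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a stunning-rechallenge CSV."""
    return _read_table(path, STUNNING_COLUMNS, "stunning")


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a qPCR Ct CSV."""
    return _read_table(path, QPCR_COLUMNS, "qPCR")


def stunning_records_from_frame(df: pd.DataFrame) -> list[StunningRecord]:
    return [
        StunningRecord(
            animal_id=str(r.animal_id),
            initial_dose=float(r.initial_dose_Gy),
            baseline_uptake=float(r.baseline_uptake),
            rechallenge_uptake=float(r.rechallenge_uptake),
            day=int(r.day),
        )
        for r in df.itertuples(index=False)
    ]


def _round_floats(obj: Any) -> Any:
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def json_report(payload: dict[str, Any]) -> str:
    """Serialise a report deterministically (sorted keys, 12-digit floats)."""
    return json.dumps(_round_floats(payload), sort_keys=True, indent=2)


@dataclass
class PipelineConfig:
    """End-to-end run settings.

    ``s_value`` is either a number in Gy·Bq⁻¹·s⁻¹ or the string
    ``"simulate"`` to recompute it by Monte Carlo on the default phantom.
    """

    s_value: float | str = DEFAULT_S_VALUE
    t_end: float = 24.0
    alpha: float = 0.05
    seed: int = 20140324
    peak_time_mode: str = "fixed"
    histories: int = 200_000
    thyroid_mass_mg: float = 5.4
    voxel_um: float = 200.0
    body_extent_mm: float = 20.0
    out_dir: Path | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.s_value, str):
            if self.s_value != "simulate":
                raise ValueError("s_value must be a positive number or 'simulate'")
        elif not self.s_value > 0:
            raise ValueError("s_value must be > 0")
        if not self.t_end > 0:
            raise ValueError("t_end must be > 0")


def _profile_to_dict(profile) -> dict[str, Any]:
    return {
        "anova_p": profile.anova_p,
        "days": [
            {
                "day": d.day,
                "mean_percent_of_day0": d.mean,
                "sd": d.sd,
                "n": d.n,
                "p_vs_day0": d.p_vs_day0,
                "recovered": d.recovered,
            }
            for d in profile.days
        ],
    }


def run_pipeline(
    config: PipelineConfig,
    tac_table: pd.DataFrame,
    stunning_table: pd.DataFrame | None = None,
) -> dict[str, Any]:
    """Run dosimetry (and optionally stunning analysis) over validated tables.

    Returns a bundle with the dose-record frame, the peak→dose calibration,
    threshold/recovery results when a stunning table is supplied, a metadata
    block and a human-readable summary.  Writes CSV/JSON into
    ``config.out_dir`` when set.
    """
    t0 = time.perf_counter()
    if isinstance(config.s_value, str):  # "simulate"
        phantom = build_phantom(
            config.thyroid_mass_mg, config.voxel_um, config.body_extent_mm
        )
        sres = self_svalue(
            phantom, load_emission_spectrum(), n=config.histories, seed=config.seed
        )
        s_value = sres.s_value
        s_meta: dict[str, Any] = {
            "mode": "simulate",
            "s_value": s_value,
            "relative_se": sres.relative_se,
            "n_histories": sres.n_histories,
            "electron_fraction": sres.electron_fraction,
        }
        log.info("simulated S-value %.3e Gy/(Bq s) [%d histories]", s_value, config.histories)
    else:
        s_value = float(config.s_value)
        s_meta = {"mode": "fixed", "s_value": s_value}

    records = doses_from_tac_table(
        tac_table, s_value=s_value, t_end=config.t_end, peak_time_mode=config.peak_time_mode
    )
    dose_frame = dose_records_to_frame(records)
    group_means = (
        dose_frame.groupby("injected_MBq")["dose_Gy"].agg(["mean", "std", "count"])
    )

    calibration = None
    if len(records) >= 3:
        try:
            cal = calibrate_peak_to_dose(records)
            calibration = {
                "slope_Gy_per_MBq": cal.slope,
                "intercept_Gy": cal.intercept,
                "r_squared": cal.r_squared,
            }
        except ValueError:
            pass

    threshold = None
    recovery = None
    if stunning_table is not None and len(stunning_table):
        srecords = stunning_records_from_frame(stunning_table)
        day1 = [r for r in srecords if r.day == 1]
        try:
            tr = threshold_scan(day1 if len(day1) >= 6 else srecords,
                                alpha=config.alpha, seed=config.seed)
            threshold = {
                "threshold_Gy": tr.threshold,
                "p_value": tr.p_value,
                "p_naive": tr.p_naive,
                "significant": tr.significant,
                "mean_change_below": tr.mean_below,
                "mean_change_above": tr.mean_above,
                "n_below": tr.n_below,
                "n_above": tr.n_above,
                "method": tr.method,
            }
        except ValueError as exc:
            log.warning("threshold scan skipped: %s", exc)
        if len(set(r.day for r in srecords)) >= 2:
            recovery = _profile_to_dict(recovery_profile(srecords, alpha=config.alpha))

    metadata = {
        "stunmird_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config": {
            "s_value": s_meta,
            "t_end_h": config.t_end,
            "alpha": config.alpha,
            "peak_time_mode": config.peak_time_mode,
        },
        "n_animals": int(dose_frame["animal_id"].nunique()),
        "elapsed_s": time.perf_counter() - t0,
    }

    lines = [f"stunmird pipeline report (seed {config.seed})"]
    lines.append(f"S-value: {s_value:.3e} Gy/(Bq s) [{s_meta['mode']}]")
    for inj, row in group_means.iterrows():
        lines.append(
            f"  {inj:g} MBq group (n={int(row['count'])}): "
            f"dose {row['mean']:.1f} +/- {0.0 if pd.isna(row['std']) else row['std']:.1f} Gy"
        )
    if calibration:
        lines.append(
            f"peak->dose calibration: slope {calibration['slope_Gy_per_MBq']:.2f} Gy/MBq, "
            f"R^2 {calibration['r_squared']:.3f}"
        )
    if threshold:
        lines.append(
            f"stunning threshold: {threshold['threshold_Gy']:.1f} Gy "
            f"(p={threshold['p_value']:.3g}, below {threshold['mean_change_below']:.2f}% "
            f"vs above {threshold['mean_change_above']:.2f}%)"
        )
    if recovery:
        rec_days = [str(d["day"]) for d in recovery["days"] if d["recovered"]]
        lines.append("recovery at day(s): " + (", ".join(rec_days) or "none"))

    bundle: dict[str, Any] = {
        "doses": dose_frame,
        "group_dose_means": group_means.reset_index().to_dict(orient="records"),
        "calibration": calibration,
        "threshold": threshold,
        "recovery": recovery,
        "metadata": metadata,
        "summary": "\n".join(lines),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dose_frame.to_csv(out / "doses.csv", index=False)
        report = {k: v for k, v in bundle.items() if k not in ("doses", "summary")}
        (out / "report.json").write_text(json_report(report), encoding="utf-8")
        (out / "summary.txt").write_text(bundle["summary"] + "\n", encoding="utf-8")
    return bundle
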