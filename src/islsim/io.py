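"""Parameter-file parsing, profile/band CSV round-trips, run logging."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import ExitRecord
from .experiment import MCResult, OutflowProfile, finite_differences
from .params import COMPOUND_PRESETS, ISLParams
from .similarity import ReferenceProfile, ReferenceSource, SMResult, TargetBand

__all__ = [
    "load_params",
    "save_params",
    "write_profile_csv",
    "read_profile_csv",
    "write_mcresult_csv",
    "write_event_log_csv",
    "read_event_log_csv",
    "read_mcresult_csv",
    "write_reference_csv",
    "read_reference_csv",
    "write_band_csv",
    "append_sm_report",
]

_PARAM_FIELDS = {f.name: f for f in dataclasses.fields(ISLParams)}
_TRUE = {"yes", "true", "1", "on"}
_FALSE = {"no", "false", "0", "off"}


def _parse_value(key: str, raw: str) -> object:
    field = _PARAM_FIELDS[key]
    raw = raw.strip()
    tp = field.type
    try:
        if tp == "bool":
            low = raw.lower()
            if low in _TRUE:
                return True
            if low in _FALSE:
                return False
            raise ValueError(f"not a boolean: {raw!r}")
        if tp == "int":
            return int(raw.replace(",", ""))
        if tp == "float":
            if raw.endswith("%"):
                # percent-style table entries ("50%") normalize to fractions
                return float(raw[:-1]) / 100.0
            return float(raw)
        return raw
    except ValueError as exc:
        raise ValueError(f"parameter {key!r}: cannot parse value {raw!r} ({exc})") from None


def load_params(path: str | Path | None = None, compound: str | None = None) -> ISLParams:
    """Read a key=value parameter file into a validated :class:`ISLParams`.

    Keys use the canonical parameter vocabulary (``MetabolismProb``, ...);
    ``#`` starts a comment; missing keys fall back to the reference defaults;
    unknown keys are rejected by name.  A ``compound`` preset (``diltiazem``
    or ``sucrose``) applies the species-specific MembraneCrossing/BileRatio
    pair before any explicit file entries.
    """
    overrides: dict[str, object] = {}
    if compound is not None:
        if compound not in COMPOUND_PRESETS:
            raise ValueError(f"unknown compound {compound!r}; known: {sorted(COMPOUND_PRESETS)}")
        overrides.update(COMPOUND_PRESETS[compound])
        overrides["compound_name"] = compound
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in _PARAM_FIELDS:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            overrides[key] = _parse_value(key, raw)
    try:
        return ISLParams(**overrides)  # type: ignore[arg-type]
    except ValueError as exc:
        raise ValueError(f"invalid parameter file {path}: {exc}") from exc


def save_params(params: ISLParams, path: str | Path) -> None:
    """Write a parameter snapshot readable by :func:`load_params`."""
    lines = [f"{k} = {v}" for k, v in params.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")


# -- profiles ---------------------------------------------------------------

def write_profile_csv(profile: OutflowProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "interval_start_s": profile.interval_starts,
            "fraction": profile.fractions,
            "route": profile.route,
            "species": profile.species,
        }
    ).to_csv(path, index=False)


def read_profile_csv(path: str | Path) -> OutflowProfile:
    df = _read_csv(path, ["interval_start_s", "fraction", "route", "species"])
    route = str(df["route"].iloc[0]) if len(df) else "CV"
    species = str(df["species"].iloc[0]) if len(df) else ""
    return OutflowProfile(
        interval_starts=df["interval_start_s"].to_numpy(dtype=float),
        fractions=df["fraction"].to_numpy(dtype=float),
        route=route,
        species=species,
    )


def write_mcresult_csv(result: MCResult, path: str | Path) -> None:
    """Summary table: mean, variance and finite differences per interval."""
    diffs = np.concatenate([[np.nan], result.finite_diffs])
    pd.DataFrame(
        {
            "interval_start_s": result.mean_profile.interval_starts,
            "mean_fraction": result.mean_profile.fractions,
            "variance": result.per_interval_variance,
            "finite_difference": diffs,
            "n_samples": result.n_samples,
        }
    ).to_csv(path, index=False)


def read_mcresult_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv(
        path,
        ["interval_start_s", "mean_fraction", "variance", "finite_difference", "n_samples"],
        nan_ok=("finite_difference",),  # first interval has no predecessor
    )


def write_event_log_csv(records: list[ExitRecord], path: str | Path) -> None:
    """CV/BD exit events: entity_id, species, route, exit_cycle."""
    pd.DataFrame(
        {
            "entity_id": [r.entity_id for r in records],
            "species": [r.species for r in records],
            "route": [r.route for r in records],
            "exit_cycle": [r.exit_cycle for r in records],
        }
    ).to_csv(path, index=False)


def read_event_log_csv(path: str | Path) -> list[ExitRecord]:
    df = _read_csv(path, ["entity_id", "species", "route", "exit_cycle"])
    return [
        ExitRecord(int(r.entity_id), str(r.species), str(r.route), int(r.exit_cycle))
        for r in df.itertuples()
    ]


# -- references and bands ---------------------------------------------------

def write_reference_csv(reference: ReferenceProfile, path: str | Path, band: TargetBand | None = None) -> None:
    data = {"time_s": reference.times, "d": reference.values}
    if band is not None:
        data["lower"] = band.lower
        data["upper"] = band.upper
    pd.DataFrame(data).to_csv(path, index=False)


def read_reference_csv(path: str | Path) -> ReferenceProfile:
    df = _read_csv(path, ["time_s", "d"])
    return ReferenceProfile(
        times=df["time_s"].to_numpy(dtype=float),
        values=df["d"].to_numpy(dtype=float),
        source=ReferenceSource.USER_FILE,
    )


def write_band_csv(band: TargetBand, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": band.times, "lower": band.lower, "upper": band.upper}
    ).to_csv(path, index=False)


def append_sm_report(result: SMResult, path: str | Path) -> None:
    """Append one JSON line per SM evaluation."""
    record = {
        "score": result.score,
        "n_in": result.n_in,
        "n_total": result.n_total,
        "threshold": result.threshold,
        "validated": result.validated,
    }
    with open(path, "a") as fh:
        fh.write(json.dumps(record) + "\n")


def _read_csv(path: str | Path, required: list[str], nan_ok: tuple[str, ...] = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in required:
        if col in nan_ok:
            continue
        if df[col].isna().any():
            bad = int(df.index[df[col].isna()][0]) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed value in column {col!r} at line {bad}")
    return df
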