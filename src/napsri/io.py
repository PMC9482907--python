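"""CSV/JSON readers and writers shared by the CLI and library surface.

All tabular interchange is RFC-4180 CSV (UTF-8, '.' decimal separator);
calibrations and provenance travel as JSON.  Writers use a fixed column
order and fixed float formatting (m/z 6 decimals, RT 3 decimals, RI nearest
integer, percentages 1 decimal) so identical inputs produce byte-identical
files.  Retention times are minutes everywhere.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_COLUMNS",
    "read_feature_table",
    "write_feature_table",
    "read_naps_table",
    "read_run_table",
    "write_library",
    "read_library",
]

#: Required columns of a feature table; optional extras pass through.
FEATURE_COLUMNS = ["feature_id", "mz", "rt_min", "intensity", "polarity"]
_OPTIONAL_FEATURE_COLUMNS = ["ri", "extrapolated", "below_usable", "compound_id"]

_POLARITIES = {"pos", "neg"}


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _check_numeric(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    for col in cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(
                f"{path}: non-numeric value {df.loc[bad.idxmax(), col]!r} "
                f"in column {col!r} at line {row}"
            )
        df[col] = numeric
    return df


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature CSV (feature_id, mz, rt_min, intensity, polarity)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"feature_id": str})
    _require_columns(df, FEATURE_COLUMNS, path)
    df = _check_numeric(df, ["mz", "rt_min", "intensity"], path)
    bad_pol = ~df["polarity"].isin(_POLARITIES)
    if bad_pol.any():
        row = int(bad_pol.idxmax()) + 2
        raise ValueError(
            f"{path}: polarity must be 'pos' or 'neg' "
            f"(got {df.loc[bad_pol.idxmax(), 'polarity']!r} at line {row})"
        )
    if "ri" in df.columns:
        df = _check_numeric(df, ["ri"], path)
    return df


_FORMATTERS = {
    "mz": "{:.6f}",
    "delta_mz": "{:.6f}",
    "library_mz": "{:.6f}",
    "rt_min": "{:.3f}",
    "mean_rt_min": "{:.3f}",
    "apex_rt": "{:.3f}",
    "delta_rt": "{:.3f}",
    "delta_rt_to_apex": "{:.3f}",
    "ri": "{:.0f}",
    "mean_ri": "{:.0f}",
    "library_ri": "{:.0f}",
    "delta_ri": "{:.1f}",
    "sd_ri": "{:.2f}",
    "rsd_ri_pct": "{:.1f}",
    "rsd_rt_pct": "{:.1f}",
    "rel_err_ri_pct": "{:.1f}",
    "rel_err_rt_pct": "{:.1f}",
    "pct_of_unspiked": "{:.1f}",
    "median_pct": "{:.1f}",
    "intensity": "{:.1f}",
    "intensity_spiked": "{:.1f}",
    "intensity_unspiked": "{:.1f}",
}


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col, fmt in _FORMATTERS.items():
        if col in out.columns:
            out[col] = [
                "" if pd.isna(v) else fmt.format(v) for v in out[col].to_numpy()
            ]
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table with the package's fixed float formatting."""
    _format_frame(df).to_csv(path, index=False, lineterminator="\n")


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in FEATURE_COLUMNS + _OPTIONAL_FEATURE_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    write_table(df[cols + extra], path)


def read_naps_table(path: str | Path) -> list[tuple[int, float]]:
    """Read a NAPS anchor CSV (n_carbons, rt_min) into (n, rt) pairs."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["n_carbons", "rt_min"], path)
    df = _check_numeric(df, ["n_carbons", "rt_min"], path)
    return [(int(n), float(rt)) for n, rt in zip(df["n_carbons"], df["rt_min"])]


def read_run_table(path: str | Path) -> pd.DataFrame:
    """Read a standard-run CSV (compound_id, adduct, polarity, rt_min)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"compound_id": str, "adduct": str, "polarity": str})
    _require_columns(df, ["compound_id", "adduct", "polarity", "rt_min"], path)
    return _check_numeric(df, ["rt_min"], path)


def _anchor_checksum(anchors) -> str:
    payload = json.dumps([list(anchors.ris), list(anchors.rts)]).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_library(
    library: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    """Write a library CSV plus a JSON provenance sidecar (<path>.json)."""
    path = Path(path)
    out = library.copy()
    out["usable"] = out["usable"].astype(bool)
    write_table(out, path)
    sidecar = {"n_entries": int(len(library))}
    if provenance:
        sidecar.update(provenance)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_library(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"compound_id": str, "adduct": str, "polarity": str})
    _require_columns(df, ["compound_id", "adduct", "polarity"], path)
    for col in ("mean_ri", "sd_ri", "mean_rt_min", "mz"):
        if col in df.columns:
            df = _check_numeric(df, [col], path)
    if "usable" in df.columns:
        df["usable"] = df["usable"].astype(str).str.lower().isin({"true", "1"})
    return df


def anchors_provenance(anchors, method: str) -> dict:
    """Provenance record for a library sidecar."""
    return {
        "method": method,
        "policy": anchors.source,
        "anchor_checksum": _anchor_checksum(anchors),
    }
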