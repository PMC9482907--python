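"""Build retention-index libraries from replicate standard runs.

Each standard run carries its own bracketing NAPS anchors; retention indices
are computed per replicate with that run's own calibration and only then
averaged across replicates, so that run-to-run RT drift (column ageing,
solvent batches) is absorbed by the per-run anchors rather than inflating
the library dispersion.  Entries whose mean RI falls at or below the C3
anchor (RI 300) are kept but flagged unusable: those compounds elute in or
near the void volume where indexing is not robust.

Dispersion is the sample standard deviation (n-1 denominator; replicates
are a sample of run-to-run variability) and RSD = 100 * sd / mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    DEFAULT_USABLE_RI_MIN,
    AnchorSet,
    CalibrationModel,
    Method,
    fit,
)

__all__ = [
    "StandardRun",
    "LIBRARY_COLUMNS",
    "index_replicates",
    "merge_libraries",
    "detection_mode_summary",
]

logger = logging.getLogger(__name__)

LIBRARY_COLUMNS = [
    "compound_id",
    "adduct",
    "polarity",
    "mean_ri",
    "sd_ri",
    "rsd_ri_pct",
    "mean_rt_min",
    "rsd_rt_pct",
    "n_replicates",
    "usable",
]

_KEY = ["compound_id", "adduct", "polarity"]


@dataclass
class StandardRun:
    """One replicate injection of a standard mixture.

    ``measurements`` has columns compound_id, adduct, polarity, rt_min with
    one row per (compound, adduct, polarity); ``anchors`` are the run's own
    bracketing NAPS anchors (already policy-resolved).
    """

    run_id: str
    anchors: AnchorSet
    measurements: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in (*_KEY, "rt_min") if c not in self.measurements.columns]
        if missing:
            raise ValueError(f"run {self.run_id!r}: missing measurement columns {missing}")
        if self.measurements.duplicated(_KEY).any():
            dups = self.measurements.loc[self.measurements.duplicated(_KEY), _KEY]
            raise ValueError(
                f"run {self.run_id!r}: duplicate (compound, adduct, polarity) rows: "
                f"{dups.to_records(index=False).tolist()}"
            )


def index_replicates(
    runs: list[StandardRun],
    method: Method = "linear",
    usable_ri_min: float = DEFAULT_USABLE_RI_MIN,
) -> pd.DataFrame:
    """Per-replicate RT->RI conversion, then averaging into library entries.

    Returns a library table (one row per compound/adduct/polarity) with
    mean/sd/RSD of the per-replicate RIs, mean RT, replicate count and the
    ``usable`` flag (mean RI above ``usable_ri_min``).
    """
    if not runs:
        raise ValueError("need at least one standard run")
    indexed = []
    for run in runs:
        model: CalibrationModel = fit(run.anchors, method=method, usable_ri_min=usable_ri_min)
        df = run.measurements.copy()
        conv = model.rt_to_ri_array(df["rt_min"].to_numpy())
        df["ri"] = conv["ri"].to_numpy()
        df["run_id"] = run.run_id
        indexed.append(df)
    alldf = pd.concat(indexed, ignore_index=True)

    grouped = alldf.groupby(_KEY, sort=True)
    lib = grouped.agg(
        mean_ri=("ri", "mean"),
        sd_ri=("ri", lambda s: s.std(ddof=1)),
        mean_rt_min=("rt_min", "mean"),
        sd_rt=("rt_min", lambda s: s.std(ddof=1)),
        n_replicates=("ri", "size"),
    ).reset_index()
    # single-replicate entries have no sample dispersion estimate
    lib["sd_ri"] = lib["sd_ri"].fillna(0.0)
    lib["sd_rt"] = lib["sd_rt"].fillna(0.0)
    lib["rsd_ri_pct"] = 100.0 * lib["sd_ri"] / lib["mean_ri"].abs()
    lib["rsd_rt_pct"] = 100.0 * lib["sd_rt"] / lib["mean_rt_min"].abs()
    lib["usable"] = lib["mean_ri"] > usable_ri_min
    lib = lib.drop(columns=["sd_rt"])
    return lib[LIBRARY_COLUMNS].copy()


def merge_libraries(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Union of two libraries keyed on (compound, adduct, polarity).

    Key collisions are resolved by pooling: means weighted by replicate
    count, pooled variance including the between-batch term, summed
    replicate counts.  Disagreeing compound metadata under one key (e.g. two
    different formulas) is an error.
    """
    if a.empty:
        return b.copy()
    if b.empty:
        return a.copy()
    meta_cols = [c for c in a.columns if c not in LIBRARY_COLUMNS and c in b.columns]
    merged = pd.concat([a, b], ignore_index=True)
    for col in meta_cols:
        conflict = merged.groupby(_KEY)[col].nunique(dropna=True) > 1
        if conflict.any():
            bad = conflict[conflict].index.tolist()
            raise ValueError(f"conflicting {col!r} values for keys {bad}")

    def _pool(g: pd.DataFrame) -> pd.Series:
        n = g["n_replicates"].to_numpy(dtype=float)
        total = n.sum()
        mean_ri = float(np.average(g["mean_ri"], weights=n))
        mean_rt = float(np.average(g["mean_rt_min"], weights=n))
        # pooled variance with between-batch contribution
        if total > 1:
            ss = ((n - 1) * g["sd_ri"] ** 2 + n * (g["mean_ri"] - mean_ri) ** 2).sum()
            sd_ri = float(np.sqrt(ss / (total - 1)))
        else:
            sd_ri = 0.0
        out = {
            "mean_ri": mean_ri,
            "sd_ri": sd_ri,
            "rsd_ri_pct": 100.0 * sd_ri / abs(mean_ri) if mean_ri else np.nan,
            "mean_rt_min": mean_rt,
            "rsd_rt_pct": float(np.average(g["rsd_rt_pct"], weights=n)),
            "n_replicates": int(total),
            "usable": bool(g["usable"].all()),
        }
        for col in meta_cols:
            vals = g[col].dropna()
            out[col] = vals.iloc[0] if len(vals) else np.nan
        return pd.Series(out)

    pooled = merged.groupby(_KEY, sort=True).apply(_pool, include_groups=False).reset_index()
    cols = LIBRARY_COLUMNS + [c for c in meta_cols if c not in LIBRARY_COLUMNS]
    pooled["n_replicates"] = pooled["n_replicates"].astype(int)
    pooled["usable"] = pooled["usable"].astype(bool)
    return pooled[cols]


def detection_mode_summary(library: pd.DataFrame) -> dict[str, int]:
    """Partition compounds by the ionization modes they were detected in.

    Returns counts ``{"both": ..., "pos_only": ..., "neg_only": ...}`` over
    distinct compound ids.
    """
    counts = {"both": 0, "pos_only": 0, "neg_only": 0}
    if library.empty:
        return counts
    modes = library.groupby("compound_id")["polarity"].agg(lambda s: frozenset(s))
    for polarities in modes:
        if "pos" in polarities and "neg" in polarities:
            counts["both"] += 1
        elif "pos" in polarities:
            counts["pos_only"] += 1
        elif "neg" in polarities:
            counts["neg_only"] += 1
    return counts
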