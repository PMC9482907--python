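"""Feature annotation against an RI library by m/z and retention index.

Matching on accurate mass alone cannot separate isomers (identical formula,
identical m/z) and often leaves several isobaric candidates inside a tight
mass window.  The retention index adds an orthogonal, instrument-portable
dimension: a feature is annotated when its m/z lies within ``mz_tol``
(default 0.005 Da) of a candidate adduct m/z, and -- in combined mode --
its RI additionally lies within ``ri_tol`` (default 10 index units) of the
library RI.  Tolerances are inclusive at the boundary.

Relative errors between a library (reference) value and the observed value
follow the convention used in cross-system comparisons here:
100 * |reference - observed| / observed, i.e. the observation under the
current system is the denominator.  For reporting, errors below 10% are
rounded to one decimal and larger ones to the nearest integer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import formula_adduct_mz

__all__ = [
    "MatchParams",
    "HIT_COLUMNS",
    "match_mz",
    "match_mz_ri",
    "relative_error",
]

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "feature_id",
    "compound_id",
    "adduct",
    "library_mz",
    "delta_mz",
    "library_ri",
    "delta_ri",
    "rel_err_ri_pct",
    "rel_err_rt_pct",
]


@dataclass(frozen=True)
class MatchParams:
    """Tolerances for annotation matching.

    Exactly one of ``mz_tol`` (absolute Da) or ``mz_tol_ppm`` may be set;
    ``ri_tol`` is in index units and may be ``inf`` to disable RI filtering.
    """

    mz_tol: float | None = 0.005
    mz_tol_ppm: float | None = None
    ri_tol: float = 10.0

    def __post_init__(self) -> None:
        if (self.mz_tol is None) == (self.mz_tol_ppm is None):
            raise ValueError("set exactly one of mz_tol (Da) or mz_tol_ppm")
        tol = self.mz_tol if self.mz_tol is not None else self.mz_tol_ppm
        if tol <= 0 or self.ri_tol <= 0:
            raise ValueError("tolerances must be positive")

    def mz_window(self, mz: float) -> float:
        """Absolute m/z tolerance at a given m/z."""
        if self.mz_tol is not None:
            return self.mz_tol
        return mz * self.mz_tol_ppm * 1e-6


def _candidate_mz(row: pd.Series) -> float:
    """Library candidate m/z: explicit 'mz' column, else computed from formula."""
    mz = row.get("mz")
    if mz is not None and not (isinstance(mz, float) and math.isnan(mz)):
        return float(mz)
    formula = row.get("formula")
    if isinstance(formula, str) and formula:
        return formula_adduct_mz(formula, row["adduct"])
    raise ValueError(
        f"library entry {row.get('compound_id')!r}/{row.get('adduct')!r} has "
        "neither an 'mz' value nor a neutral 'formula' to compute one"
    )


def relative_error(reference: float, observed: float) -> float:
    """Relative error (%) of a reference value against the observed value.

    100 * |reference - observed| / observed, rounded to the precision used
    in reporting: one decimal below 10%, nearest integer at or above 10%.
    """
    if observed <= 0:
        raise ValueError(f"observed value must be positive, got {observed}")
    pct = 100.0 * abs(reference - observed) / observed
    return round(pct, 1) if pct < 10.0 else float(round(pct))


def match_mz(
    features: pd.DataFrame, library: pd.DataFrame, params: MatchParams | None = None
) -> pd.DataFrame:
    """Annotate features by accurate mass alone.

    One hit row per (feature, candidate, adduct) whose |Δm/z| is within
    tolerance (inclusive), polarity-matched when both tables carry a
    polarity column.  Hits are sorted by feature then |Δm/z|.  Δ columns are
    observed minus library; relative errors (library RI/RT vs observed) are
    included when both sides provide the quantity.
    """
    if params is None:
        params = MatchParams()
    hits: list[dict] = []
    if features.empty or library.empty:
        return pd.DataFrame(columns=HIT_COLUMNS)

    lib = library.copy()
    lib["_mz"] = [_candidate_mz(row) for _, row in lib.iterrows()]
    lib_ri_col = "mean_ri" if "mean_ri" in lib.columns else ("ri" if "ri" in lib.columns else None)
    lib_rt_col = "mean_rt_min" if "mean_rt_min" in lib.columns else (
        "rt_min" if "rt_min" in lib.columns else None
    )

    for _, feat in features.iterrows():
        fmz = float(feat["mz"])
        cand = lib
        if "polarity" in feat.index and "polarity" in lib.columns:
            cand = lib[lib["polarity"] == feat["polarity"]]
        window = params.mz_window(fmz)
        sel = cand[(cand["_mz"] - fmz).abs() <= window]
        for _, c in sel.iterrows():
            hit = {
                "feature_id": feat.get("feature_id"),
                "compound_id": c.get("compound_id"),
                "adduct": c.get("adduct"),
                "library_mz": c["_mz"],
                "delta_mz": fmz - c["_mz"],
                "library_ri": np.nan,
                "delta_ri": np.nan,
                "rel_err_ri_pct": np.nan,
                "rel_err_rt_pct": np.nan,
            }
            if lib_ri_col is not None and not pd.isna(c.get(lib_ri_col)):
                hit["library_ri"] = float(c[lib_ri_col])
                if "ri" in feat.index and not pd.isna(feat["ri"]):
                    fri = float(feat["ri"])
                    hit["delta_ri"] = fri - hit["library_ri"]
                    if fri > 0:
                        hit["rel_err_ri_pct"] = relative_error(hit["library_ri"], fri)
            if (
                lib_rt_col is not None
                and not pd.isna(c.get(lib_rt_col))
                and "rt_min" in feat.index
                and not pd.isna(feat["rt_min"])
                and float(feat["rt_min"]) > 0
            ):
                hit["rel_err_rt_pct"] = relative_error(
                    float(c[lib_rt_col]), float(feat["rt_min"])
                )
            hits.append(hit)

    out = pd.DataFrame(hits, columns=HIT_COLUMNS)
    if not out.empty:
        out = out.assign(_abs=out["delta_mz"].abs()).sort_values(
            ["feature_id", "_abs"], kind="stable"
        ).drop(columns="_abs").reset_index(drop=True)
    return out


def match_mz_ri(
    features: pd.DataFrame, library: pd.DataFrame, params: MatchParams | None = None
) -> pd.DataFrame:
    """Annotate by combined m/z + RI: the m/z hits with |ΔRI| <= ri_tol.

    Features lacking an RI are skipped with a warning (they cannot enter the
    RI-filtered result); candidates lacking a library RI never pass.
    The result is always a subset of :func:`match_mz` on the same inputs.
    """
    if params is None:
        params = MatchParams()
    feats = features
    if "ri" not in feats.columns:
        logger.warning("no 'ri' column in features; RI-filtered matching yields no hits")
        return pd.DataFrame(columns=HIT_COLUMNS)
    missing = feats["ri"].isna()
    if missing.any():
        logger.warning("skipping %d features without RI in RI-filtered matching", missing.sum())
        feats = feats[~missing]
    hits = match_mz(feats, library, params)
    if hits.empty:
        return hits
    if math.isinf(params.ri_tol):
        return hits
    keep = hits["delta_ri"].abs() <= params.ri_tol
    return hits[keep.fillna(False)].reset_index(drop=True)
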