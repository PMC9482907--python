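"""RT <-> RI calibration from bracketing NAPS anchor sets.

A calibration maps retention time (minutes) to retention index by
interpolating between the homologous-series anchors: the n-carbon NAPS is
defined to have RI = 100*n, and an analyte's RI is obtained from its RT
relative to the bracketing anchors.  For the linear method the conversion
between the bracketing pair (RI0, RT0) and (RI1, RT1) is

    RI = RI0 + (RI1 - RI0) * (RT - RT0) / (RT1 - RT0)

applied piecewise over consecutive anchor pairs.  Cubic (natural boundary)
and Akima splines are alternatives; all three reproduce the anchors exactly
and agree for well-spread anchors, but cubic splines can overshoot where
anchor spacing changes abruptly -- notably below the C3 anchor, where the
C1-C3 homologs pile up near the void volume.

Because the linear map is invariant under affine transformations of the RT
axis (rt' = a*rt + b applied to both analyte and anchors leaves RI
unchanged), RIs computed against co-injected anchors transfer across
instruments whose RT warps are locally affine -- the mathematical core of
cross-system retention normalization.

RIs at or below ``usable_ri_min`` (default 300, the C3 anchor) are flagged
``below_usable`` rather than dropped: robust indices require elution after
the C3 standard, but batch conversion must never abort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import Akima1DInterpolator, CubicSpline

__all__ = [
    "AnchorSet",
    "CalibrationModel",
    "IndexedValue",
    "make_anchors",
    "fit",
    "rt_to_ri",
    "ri_to_rt",
    "compare_methods",
]

Method = Literal["linear", "cubic", "akima"]
Policy = Literal["before", "after", "average"]

METHODS = ("linear", "cubic", "akima")
POLICIES = ("before", "after", "average")

#: Default RT gap (minutes) below which consecutive anchors are treated as
#: co-eluting and collapsed (keeping the higher-RI anchor).
COELUTION_RT_GAP = 0.01

#: Default usable-RI floor: the C3 anchor, below which homologs elute in or
#: near the void volume and indices are not robust.
DEFAULT_USABLE_RI_MIN = 300.0


@dataclass(frozen=True)
class AnchorSet:
    """Ordered (RI, RT) anchors from one or two bracketing NAPS injections.

    ``ris`` must be strictly increasing and, after collapsing near-co-eluting
    anchors, ``rts`` strictly increasing too.  ``source`` records which
    bracketing policy produced the set.
    """

    ris: tuple[float, ...]
    rts: tuple[float, ...]
    source: str = "before"

    def __post_init__(self) -> None:
        if len(self.ris) != len(self.rts):
            raise ValueError("ris and rts must have equal length")
        if len(self.ris) < 2:
            raise ValueError("need at least 2 anchors")
        ris = np.asarray(self.ris, dtype=float)
        rts = np.asarray(self.rts, dtype=float)
        if not np.all(np.diff(ris) > 0):
            raise ValueError("anchor RIs must be strictly increasing")
        if not np.all(np.diff(rts) >= 0):
            raise ValueError("anchor RTs must be non-decreasing")

    def collapse_coelution(self, min_rt_gap: float = COELUTION_RT_GAP) -> "AnchorSet":
        """Collapse runs of anchors closer than ``min_rt_gap`` minutes.

        Within a run of near-identical RTs (the C1-C3 pileup near the void
        volume) only the highest-RI anchor is kept, guaranteeing the strict
        RT monotonicity every interpolant requires.
        """
        keep_ris: list[float] = [self.ris[0]]
        keep_rts: list[float] = [self.rts[0]]
        for ri, rt in zip(self.ris[1:], self.rts[1:]):
            if rt - keep_rts[-1] < min_rt_gap:
                # co-eluting: the later homolog supersedes the earlier one
                keep_ris[-1] = ri
                keep_rts[-1] = max(keep_rts[-1], rt)
            else:
                keep_ris.append(ri)
                keep_rts.append(rt)
        if len(keep_ris) < 2:
            raise ValueError("fewer than 2 anchors remain after collapsing co-elution")
        return AnchorSet(tuple(keep_ris), tuple(keep_rts), self.source)

    @property
    def rt_range(self) -> tuple[float, float]:
        return self.rts[0], self.rts[-1]

    @property
    def ri_range(self) -> tuple[float, float]:
        return self.ris[0], self.ris[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ri": self.ris, "rt_min": self.rts})


@dataclass(frozen=True)
class IndexedValue:
    """An RT converted to RI, with audit flags instead of failures."""

    ri: float
    extrapolated: bool
    below_usable: bool

    @property
    def ri_rounded(self) -> int:
        """RI rounded to the nearest integer, the conventional reporting form."""
        return int(round(self.ri))


def make_anchors(
    naps_before: Iterable[tuple[int, float]] | None,
    naps_after: Iterable[tuple[int, float]] | None = None,
    policy: Policy = "before",
) -> AnchorSet:
    """Build an anchor set from bracketing NAPS injections.

    ``naps_before`` / ``naps_after`` are (n_carbons, rt_min) pairs from the
    standard injections before and after a sample block.  ``policy`` selects
    the before run, the after run, or the per-homolog average of the two
    anchor RTs -- averaging the bracketing RTs compensates gradual drift over
    a block and is the recommended default for larger batches.
    """
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}, got {policy!r}")

    def _as_dict(pairs, label):
        if pairs is None:
            return None
        d = {}
        for n, rt in pairs:
            n = int(n)
            if rt <= 0:
                raise ValueError(f"non-positive RT {rt} for C{n} in {label} run")
            if n in d:
                raise ValueError(f"duplicate homolog C{n} in {label} run")
            d[n] = float(rt)
        return d

    before = _as_dict(naps_before, "before")
    after = _as_dict(naps_after, "after")

    if policy == "before":
        if before is None:
            raise ValueError("policy 'before' requires the before-run anchors")
        chosen = before
    elif policy == "after":
        if after is None:
            raise ValueError("policy 'after' requires the after-run anchors")
        chosen = after
    else:
        if before is None or after is None:
            raise ValueError("policy 'average' requires both bracketing runs")
        if set(before) != set(after):
            only_b = sorted(set(before) - set(after))
            only_a = sorted(set(after) - set(before))
            raise ValueError(
                "bracketing runs cover different homologs: "
                f"only in before={only_b}, only in after={only_a}"
            )
        chosen = {n: 0.5 * (before[n] + after[n]) for n in before}

    ns = sorted(chosen)
    return AnchorSet(
        ris=tuple(100.0 * n for n in ns),
        rts=tuple(chosen[n] for n in ns),
        source=policy,
    )


@dataclass
class CalibrationModel:
    """A fitted RT <-> RI interpolant over a (collapsed) anchor set."""

    anchors: AnchorSet
    method: Method
    usable_ri_min: float = DEFAULT_USABLE_RI_MIN
    _interp: object = field(default=None, repr=False, compare=False)

    @property
    def _rts(self) -> np.ndarray:
        return np.asarray(self.anchors.rts, dtype=float)

    @property
    def _ris(self) -> np.ndarray:
        return np.asarray(self.anchors.ris, dtype=float)

    # -- evaluation -------------------------------------------------------

    def _eval_inside(self, rt: np.ndarray) -> np.ndarray:
        if self.method == "linear":
            return np.interp(rt, self._rts, self._ris)
        return np.asarray(self._interp(rt), dtype=float)

    def _eval(self, rt: np.ndarray) -> np.ndarray:
        """Evaluate with linear terminal-chord extension outside the range."""
        rts, ris = self._rts, self._ris
        rt = np.asarray(rt, dtype=float)
        out = np.empty_like(rt)
        lo, hi = rts[0], rts[-1]
        inside = (rt >= lo) & (rt <= hi)
        out[inside] = self._eval_inside(rt[inside])
        slope_lo = (ris[1] - ris[0]) / (rts[1] - rts[0])
        slope_hi = (ris[-1] - ris[-2]) / (rts[-1] - rts[-2])
        below = rt < lo
        above = rt > hi
        out[below] = ris[0] + slope_lo * (rt[below] - lo)
        out[above] = ris[-1] + slope_hi * (rt[above] - hi)
        return out

    def rt_to_ri(self, rt: float) -> IndexedValue:
        """Convert one RT (minutes) to an RI with audit flags."""
        arr = np.asarray([float(rt)])
        ri = float(self._eval(arr)[0])
        lo, hi = self.anchors.rt_range
        return IndexedValue(
            ri=ri,
            extrapolated=bool(rt < lo or rt > hi),
            below_usable=bool(ri <= self.usable_ri_min),
        )

    def rt_to_ri_array(self, rts: Sequence[float]) -> pd.DataFrame:
        """Vectorized conversion: DataFrame with ri/extrapolated/below_usable."""
        rts_arr = np.asarray(rts, dtype=float)
        ris = self._eval(rts_arr)
        lo, hi = self.anchors.rt_range
        return pd.DataFrame(
            {
                "ri": ris,
                "extrapolated": (rts_arr < lo) | (rts_arr > hi),
                "below_usable": ris <= self.usable_ri_min,
            }
        )

    def ri_to_rt(self, ri: float) -> float:
        """Invert the calibration: RI -> RT, within the anchor RI range.

        The linear method inverts the bracketing-pair formula algebraically;
        spline methods locate the root of the interpolant within the
        bracketing segment.  A spline segment that is non-monotone at the
        requested RI (multiple roots) is reported as an error.
        """
        ris, rts = self._ris, self._rts
        if ri < ris[0] or ri > ris[-1]:
            raise ValueError(
                f"ri={ri} outside the anchor RI range [{ris[0]}, {ris[-1]}]"
            )
        if self.method == "linear":
            return float(np.interp(ri, ris, rts))
        roots = np.asarray(self._interp.solve(float(ri), extrapolate=False), dtype=float)
        roots = roots[(roots >= rts[0] - 1e-12) & (roots <= rts[-1] + 1e-12)]
        roots = np.unique(np.round(roots, 10))
        if roots.size == 0:
            # RI inside anchor range but spline non-monotone: no root in domain
            raise ValueError(f"no RT maps to ri={ri} under the {self.method} spline")
        if roots.size > 1:
            seg = int(np.searchsorted(rts, roots[0], side="right") - 1)
            seg = min(max(seg, 0), len(rts) - 2)
            raise ValueError(
                f"ri={ri} has {roots.size} preimages under the {self.method} spline; "
                f"segment [{rts[seg]:.4f}, {rts[seg + 1]:.4f}] min is non-monotone"
            )
        return float(roots[0])

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "policy": self.anchors.source,
            "usable_ri_min": self.usable_ri_min,
            "anchors": [
                {"n": int(round(ri / 100)), "ri": float(ri), "rt_min": float(rt)}
                for ri, rt in zip(self.anchors.ris, self.anchors.rts)
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        anchors = AnchorSet(
            ris=tuple(a["ri"] for a in d["anchors"]),
            rts=tuple(a["rt_min"] for a in d["anchors"]),
            source=d.get("policy", "before"),
        )
        return fit(
            anchors,
            method=d.get("method", "linear"),
            usable_ri_min=d.get("usable_ri_min", DEFAULT_USABLE_RI_MIN),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit(
    anchors: AnchorSet,
    method: Method = "linear",
    usable_ri_min: float = DEFAULT_USABLE_RI_MIN,
    collapse: bool = True,
) -> CalibrationModel:
    """Fit an interpolating calibration through the anchors.

    All three methods pass through every anchor exactly.  ``collapse``
    merges near-co-eluting anchors (C1-C3 pileup) first; disable only for
    anchor sets known to be strictly increasing in RT.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if collapse:
        anchors = anchors.collapse_coelution()
    rts = np.asarray(anchors.rts, dtype=float)
    ris = np.asarray(anchors.ris, dtype=float)
    if not np.all(np.diff(rts) > 0):
        raise ValueError("anchor RTs not strictly increasing after collapsing co-elution")

    interp = None
    if method == "cubic":
        interp = CubicSpline(rts, ris, bc_type="natural")
    elif method == "akima":
        interp = Akima1DInterpolator(rts, ris)
    return CalibrationModel(
        anchors=anchors, method=method, usable_ri_min=usable_ri_min, _interp=interp
    )


def rt_to_ri(model: CalibrationModel, rt: float) -> IndexedValue:
    """Functional alias for :meth:`CalibrationModel.rt_to_ri`."""
    return model.rt_to_ri(rt)


def ri_to_rt(model: CalibrationModel, ri: float) -> float:
    """Functional alias for :meth:`CalibrationModel.ri_to_rt`."""
    return model.ri_to_rt(ri)


def compare_methods(
    anchors: AnchorSet, rt_grid: Sequence[float], usable_ri_min: float = DEFAULT_USABLE_RI_MIN
) -> pd.DataFrame:
    """Evaluate all three methods on an RT grid.

    Returns columns ``rt, ri_linear, ri_cubic, ri_akima`` -- the diagnostic
    used to inspect cubic-spline overshoot in regions of abrupt anchor
    spacing (typically below RI ~750 when the early homologs co-elute).
    """
    grid = np.asarray(rt_grid, dtype=float)
    out = {"rt": grid}
    for method in METHODS:
        model = fit(anchors, method=method, usable_ri_min=usable_ri_min)
        out[f"ri_{method}"] = model._eval(grid)
    return pd.DataFrame(out)
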