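"""Ion-suppression evaluation for co-injected NAPS standards.

Because NAPS carry two permanent charges they can suppress the ESI response
of co-eluting metabolites.  The effect is quantified by comparing a
NAPS-spiked run of a biological matrix against the unspiked matrix:
features are paired one-to-one between the runs (nearest m/z, then nearest
RT, within tolerances), and each paired feature inside a window of
+/- 0.20 min around a NAPS elution apex is expressed as

    pct_of_unspiked = 100 * I_spiked / I_unspiked

so 100% means no effect, < 100% suppression and > 100% enhancement.  Only
NAPS with RI > 300 are evaluated: the C1-C3 homologs elute in the void
region where heavy matrix suppression occurs regardless of the spike.
Spiking at higher dilution (1:40, 1:80 instead of 1:20) reduces the effect,
which :func:`dilution_trend` summarizes as median percent per window and
dilution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SuppressionWindow",
    "make_windows",
    "pair_runs",
    "suppression_profile",
    "dilution_trend",
]

DEFAULT_HALF_WIDTH = 0.20
DEFAULT_MZ_TOL = 0.005
DEFAULT_RT_TOL = 0.10

#: NAPS at or below this RI elute in/near the void volume and are excluded.
MIN_EVALUATED_RI = 300


@dataclass(frozen=True)
class SuppressionWindow:
    """An evaluation window of ``+/- half_width`` minutes around a NAPS apex."""

    ri: float
    apex_rt: float
    half_width: float = DEFAULT_HALF_WIDTH

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    def contains(self, rt: float) -> bool:
        # inclusive at both edges; epsilon guards float representation of the bound
        return abs(rt - self.apex_rt) <= self.half_width + 1e-9


def make_windows(
    naps_apexes: pd.DataFrame, half_width: float = DEFAULT_HALF_WIDTH
) -> list[SuppressionWindow]:
    """Windows around NAPS apexes, restricted to homologs with RI > 300.

    ``naps_apexes`` needs columns ``n_carbons`` and ``rt_min``.
    """
    windows = []
    for _, row in naps_apexes.iterrows():
        ri = 100.0 * int(row["n_carbons"])
        if ri > MIN_EVALUATED_RI:
            windows.append(SuppressionWindow(ri=ri, apex_rt=float(row["rt_min"]), half_width=half_width))
    return sorted(windows, key=lambda w: w.apex_rt)


def pair_runs(
    spiked: pd.DataFrame,
    unspiked: pd.DataFrame,
    mz_tol: float = DEFAULT_MZ_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Greedy one-to-one pairing of features between spiked and unspiked runs.

    Candidate pairs within both tolerances are accepted best-first by
    (|Δm/z|, |ΔRT|); each feature is used at most once, which makes the
    result deterministic and order-independent.  Returns
    ``(pairs, unpaired_spiked, unpaired_unspiked)``; ``pairs`` has columns
    mz, rt_min, intensity_spiked, intensity_unspiked, delta_mz, delta_rt.
    """
    cols = ["mz", "rt_min", "intensity_spiked", "intensity_unspiked", "delta_mz", "delta_rt"]
    if spiked.empty or unspiked.empty:
        return pd.DataFrame(columns=cols), spiked.copy(), unspiked.copy()

    s_mz = spiked["mz"].to_numpy(dtype=float)
    s_rt = spiked["rt_min"].to_numpy(dtype=float)
    u_mz = unspiked["mz"].to_numpy(dtype=float)
    u_rt = unspiked["rt_min"].to_numpy(dtype=float)

    dmz = np.abs(s_mz[:, None] - u_mz[None, :])
    drt = np.abs(s_rt[:, None] - u_rt[None, :])
    si, ui = np.nonzero((dmz <= mz_tol) & (drt <= rt_tol))
    order = np.lexsort((drt[si, ui], dmz[si, ui]))

    used_s: set[int] = set()
    used_u: set[int] = set()
    rows = []
    for k in order:
        i, j = int(si[k]), int(ui[k])
        if i in used_s or j in used_u:
            continue
        used_s.add(i)
        used_u.add(j)
        rows.append(
            {
                "mz": u_mz[j],
                "rt_min": u_rt[j],
                "intensity_spiked": float(spiked["intensity"].iloc[i]),
                "intensity_unspiked": float(unspiked["intensity"].iloc[j]),
                "delta_mz": s_mz[i] - u_mz[j],
                "delta_rt": s_rt[i] - u_rt[j],
            }
        )
    pairs = pd.DataFrame(rows, columns=cols)
    unpaired_s = spiked.iloc[[i for i in range(len(spiked)) if i not in used_s]].copy()
    unpaired_u = unspiked.iloc[[j for j in range(len(unspiked)) if j not in used_u]].copy()
    return pairs, unpaired_s, unpaired_u


def suppression_profile(
    pairs: pd.DataFrame,
    windows: list[SuppressionWindow],
    dilution_label: str = "",
) -> pd.DataFrame:
    """Percent-of-unspiked for every pair inside a NAPS window.

    Each pair is assigned to the nearest apex; pairs outside all windows are
    excluded.  Pairs with zero unspiked intensity are flagged ``undefined``
    (pct NaN) and should be excluded from summaries.  Columns: mz, rt_min,
    window_ri, apex_rt, delta_rt_to_apex (signed), pct_of_unspiked,
    undefined, dilution.
    """
    cols = [
        "mz",
        "rt_min",
        "window_ri",
        "apex_rt",
        "delta_rt_to_apex",
        "pct_of_unspiked",
        "undefined",
        "dilution",
    ]
    if pairs.empty or not windows:
        return pd.DataFrame(columns=cols)
    apex_rts = np.array([w.apex_rt for w in windows])
    rows = []
    for _, p in pairs.iterrows():
        rt = float(p["rt_min"])
        k = int(np.argmin(np.abs(apex_rts - rt)))
        w = windows[k]
        if not w.contains(rt):
            continue
        i_un = float(p["intensity_unspiked"])
        undefined = i_un == 0
        pct = np.nan if undefined else 100.0 * float(p["intensity_spiked"]) / i_un
        rows.append(
            {
                "mz": p["mz"],
                "rt_min": rt,
                "window_ri": w.ri,
                "apex_rt": w.apex_rt,
                "delta_rt_to_apex": rt - w.apex_rt,
                "pct_of_unspiked": pct,
                "undefined": undefined,
                "dilution": dilution_label,
            }
        )
    return pd.DataFrame(rows, columns=cols)


def _dilution_factor(label: str) -> float:
    """Numeric factor from a '1:20'-style label (larger = more dilute)."""
    if ":" in label:
        num, den = label.split(":", 1)
        return float(den) / float(num)
    return float(label)


def dilution_trend(profiles: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Median percent-of-unspiked per (window, dilution), with trend check.

    ``profiles`` maps dilution labels ('1:20', '1:40', ...) to profile
    tables.  Returns one row per window RI and dilution with the median pct
    and pair count (NaN median / zero count when a cell has no defined
    pairs), ordered by increasing dilution, plus a ``monotone_increasing``
    column stating whether that window's medians rise with dilution.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two dilution levels for a trend")
    labels = sorted(profiles, key=_dilution_factor)
    rows = []
    all_ris = sorted(
        {ri for prof in profiles.values() if not prof.empty for ri in prof["window_ri"].unique()}
    )
    for ri in all_ris:
        medians = []
        for label in labels:
            prof = profiles[label]
            sel = prof[(prof["window_ri"] == ri) & (~prof["undefined"])] if not prof.empty else prof
            pct = sel["pct_of_unspiked"] if not sel.empty else pd.Series(dtype=float)
            med = float(pct.median()) if len(pct) else np.nan
            medians.append(med)
            rows.append(
                {"window_ri": ri, "dilution": label, "median_pct": med, "n_pairs": len(pct)}
            )
        finite = [m for m in medians if not np.isnan(m)]
        mono = len(finite) == len(medians) and all(
            b > a for a, b in zip(medians, medians[1:])
        )
        for row in rows[-len(labels):]:
            row["monotone_increasing"] = mono
    return pd.DataFrame(rows, columns=["window_ri", "dilution", "median_pct", "n_pairs", "monotone_increasing"])
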