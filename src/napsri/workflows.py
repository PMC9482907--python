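"""End-to-end study workflows built on the simulator.

These functions reproduce, on synthetic data, the two study designs that
motivate retention indexing:

* :func:`flow_rate_panel` -- measure how strongly retention times shift when
  only the flow rate changes, and how stable retention indices computed
  against co-injected NAPS anchors remain.  RT deviations of tens of percent
  shrinking to sub-2% RI deviations is the signature of successful
  normalization.
* :func:`suppression_study` -- quantify NAPS-induced ion suppression in a
  spiked matrix at several spike dilutions, returning per-window medians,
  the dilution trend, and where the suppression minimum sits relative to
  the NAPS apexes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calibration as cal
from . import simulate as sim
from . import suppression as sup

__all__ = ["flow_rate_panel", "suppression_study"]


def _mean_ri_rt(study: sim.SimulatedStudy, system: str, config: sim.StudyConfig,
                method: str = "linear") -> pd.DataFrame:
    """Per-compound mean RI and RT over replicates, each replicate indexed
    against its own co-injected NAPS anchors."""
    acc: dict[str, dict[str, list[float]]] = {}
    for rep in range(1, config.replicates + 1):
        naps = study.naps[(system, rep)]
        anchors = cal.make_anchors(list(zip(naps["n_carbons"], naps["rt_min"])))
        model = cal.fit(anchors, method=method)
        run = study.runs[(system, rep)]
        conv = model.rt_to_ri_array(run["rt_min"].to_numpy())
        for cid, ri, rt in zip(run["compound_id"], conv["ri"], run["rt_min"]):
            entry = acc.setdefault(cid, {"ri": [], "rt": []})
            entry["ri"].append(float(ri))
            entry["rt"].append(float(rt))
    return pd.DataFrame(
        {
            "compound_id": list(acc),
            "mean_ri": [np.mean(v["ri"]) for v in acc.values()],
            "mean_rt": [np.mean(v["rt"]) for v in acc.values()],
        }
    ).set_index("compound_id")


def flow_rate_panel(
    config: sim.StudyConfig | None = None,
    seed: int = 0,
    ri_dev_threshold_pct: float = 2.0,
) -> pd.DataFrame:
    """RT vs RI stability across the flow-rate panel.

    Simulates the configured study, indexes every replicate against its own
    NAPS anchors, and compares per-compound mean RT and RI at each flow rate
    against the reference flow.  Returns one row per non-reference flow rate
    with the median absolute RT deviation (percent), the median absolute RI
    deviation (percent), and the fraction of compounds with RI > 300 whose
    RI deviates by less than ``ri_dev_threshold_pct``.
    """
    config = config or sim.StudyConfig()
    study = sim.simulate_study(config, seed=seed)
    ref_name = f"F{config.reference_flow_rate:.2f}"
    ref = _mean_ri_rt(study, ref_name, config)
    rows = []
    for flow in config.flow_rates:
        name = f"F{flow:.2f}"
        if name == ref_name:
            continue
        panel = _mean_ri_rt(study, name, config).loc[ref.index]
        rt_dev = 100.0 * (panel["mean_rt"] - ref["mean_rt"]).abs() / ref["mean_rt"]
        ri_dev = 100.0 * (panel["mean_ri"] - ref["mean_ri"]).abs() / ref["mean_ri"]
        usable = ref["mean_ri"] > 300.0
        rows.append(
            {
                "flow_rate": flow,
                "median_rt_dev_pct": float(rt_dev.median()),
                "median_ri_dev_pct": float(ri_dev.median()),
                "frac_ri_within_tol": float((ri_dev[usable] < ri_dev_threshold_pct).mean()),
                "n_compounds": int(usable.sum()),
            }
        )
    return pd.DataFrame(rows)


def suppression_study(
    config: sim.StudyConfig | None = None, seed: int = 0
) -> dict:
    """Spiked-vs-unspiked suppression evaluation across dilutions.

    Returns a dict with the per-(window, dilution) ``trend`` table, pooled
    ``median_pct`` per dilution, the profile tables, and the signed distance
    from the NAPS apex at which the median suppression is deepest
    (``min_bin_center``, from 0.05-min bins of apex distance).
    """
    config = config or sim.StudyConfig()
    study = sim.simulate_study(config, seed=seed)
    windows = sup.make_windows(study.matrix_naps_apexes)
    profiles: dict[str, pd.DataFrame] = {}
    pooled: dict[str, float] = {}
    for dilution, spiked in study.matrix_spiked.items():
        pairs, _, _ = sup.pair_runs(spiked, study.matrix_unspiked)
        prof = sup.suppression_profile(pairs, windows, dilution_label=dilution)
        profiles[dilution] = prof
        ok = prof[~prof["undefined"]]
        pooled[dilution] = float(ok["pct_of_unspiked"].median())
    trend = sup.dilution_trend(profiles)

    # locate the suppression minimum for the strongest spike
    strongest = profiles[min(profiles, key=sup._dilution_factor)]
    edges = np.arange(-0.2, 0.2001, 0.05)
    centers = 0.5 * (edges[:-1] + edges[1:])
    binned = strongest.groupby(
        pd.cut(strongest["delta_rt_to_apex"], edges), observed=False
    )["pct_of_unspiked"].median()
    min_bin_center = float(centers[int(np.nanargmin(binned.to_numpy()))])
    return {
        "trend": trend,
        "pooled_median_pct": pooled,
        "profiles": profiles,
        "min_bin_center": min_bin_center,
    }
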