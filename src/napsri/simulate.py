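"""Gradient-elution LC simulator for testing retention-index workflows.

Retention is modeled with the linear-solvent-strength (LSS) relation

    log10 k(phi) = log_kw - S * phi

where ``phi`` is the organic-solvent fraction, ``log_kw`` the (log)
retention factor extrapolated to pure water, and ``S`` the solvent-strength
slope.  For a time-programmed gradient the apex retention time solves the
standard gradient-elution integral

    integral_0^(tR - t0)  dt / (t0 * k(phi_col(t)))  =  1

with column dead time ``t0 = dead_volume / flow_rate`` and the programmed
gradient delayed at the column inlet by ``dwell_volume / flow_rate``.  For
a flat gradient this reduces to the isocratic closed form
``tR = t0 * (1 + k)``.  The integral is evaluated numerically on a dense
time grid (vectorized over compounds), which keeps cross-flow-rate RT
warps smooth -- exactly the regime in which homologous-series retention
indexing is expected to normalize retention.

The NAPS homolog series gets ``log_kw`` increasing linearly with chain
length (constant methylene selectivity) and a shared slope ``S``; with the
default early-gradient hold the C1-C3 homologs then pile up at the void
volume naturally, while C4-C20 spread over the gradient.

``simulate_study`` generates the full synthetic study: replicate standard
runs with bracketing NAPS anchors across a panel of flow rates, plus
spiked/unspiked matrix runs with a Gaussian ion-suppression kernel centered
on each NAPS apex, and a ground-truth table for parameter-recovery tests.
RT noise (Gaussian, default sd 0.02 min) is added after the deterministic
retention calculation; intensity noise is log-normal (default sd 0.1 in
log10 units).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LcSystem",
    "RetentionParams",
    "StudyConfig",
    "SimulatedStudy",
    "default_reference_system",
    "default_naps_params",
    "gradient_rt",
    "gradient_rt_batch",
    "simulate_naps_series",
    "simulate_study",
]


@dataclass(frozen=True)
class LcSystem:
    """A gradient LC system: flow, volumes and the time-programmed gradient.

    ``gradient`` is a list of (time_min, phi) nodes, piecewise-linear in
    between and held constant beyond the last node.  ``dead_volume`` and
    ``dwell_volume`` are in mL; ``flow_rate`` in mL/min.
    """

    flow_rate: float
    dead_volume: float
    dwell_volume: float
    gradient: tuple[tuple[float, float], ...]
    column: str = ""

    def __post_init__(self) -> None:
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")
        if self.dead_volume <= 0 or self.dwell_volume < 0:
            raise ValueError("volumes must be positive (dwell may be zero)")
        times = [t for t, _ in self.gradient]
        phis = [p for _, p in self.gradient]
        if len(times) < 1 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("gradient times must be strictly increasing")
        if any(p < 0 or p > 1 for p in phis):
            raise ValueError("gradient phi values must lie in [0, 1]")

    @property
    def t0(self) -> float:
        """Column dead time, minutes."""
        return self.dead_volume / self.flow_rate

    @property
    def dwell_time(self) -> float:
        """Gradient delay from mixer to column inlet, minutes."""
        return self.dwell_volume / self.flow_rate

    def phi_at_column(self, t: np.ndarray) -> np.ndarray:
        """Organic fraction at the column inlet at time ``t`` after injection."""
        times = np.array([p[0] for p in self.gradient])
        phis = np.array([p[1] for p in self.gradient])
        return np.interp(np.asarray(t, dtype=float) - self.dwell_time, times, phis)

    def with_flow_rate(self, flow_rate: float) -> "LcSystem":
        """Same system at a different flow (time program unchanged)."""
        return replace(self, flow_rate=flow_rate)


@dataclass(frozen=True)
class RetentionParams:
    """LSS retention parameters of one compound: log10 kw and slope S."""

    log_kw: float
    S: float

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise ValueError("solvent-strength slope S must be positive")

    def k(self, phi: float | np.ndarray) -> float | np.ndarray:
        return 10.0 ** (self.log_kw - self.S * np.asarray(phi, dtype=float))


def default_reference_system(flow_rate: float = 0.30) -> LcSystem:
    """The default reference method: 2 min hold at 5% organic, linear ramp to
    99.9% over 15 min, 3 min high hold; 0.25 mL column dead volume and
    0.80 mL gradient dwell volume (a low-pressure-gradient mixer regime, the
    hardware class for which cross-system RT differences are largest)."""
    return LcSystem(
        flow_rate=flow_rate,
        dead_volume=0.25,
        dwell_volume=0.80,
        gradient=((0.0, 0.05), (2.0, 0.05), (17.0, 0.999), (20.0, 0.999)),
        column="C18 100x2.1mm sim",
    )


#: Methylene increment of log10 kw per CH2 in the NAPS defaults.
NAPS_LOG_KW_PER_CH2 = 0.30
NAPS_LOG_KW_BASE = -2.40
NAPS_S = 4.0


def default_naps_params(n_max: int = 20) -> list[RetentionParams]:
    """Default LSS parameters for the NAPS C1..C20 series.

    ``log_kw = -2.40 + 0.30 * n`` with shared slope ``S = 4``: constant
    methylene selectivity makes anchor spacing regular over the ramp, and
    the weakly retained C1-C3 members emerge at the void volume under the
    default initial hold.
    """
    return [
        RetentionParams(log_kw=NAPS_LOG_KW_BASE + NAPS_LOG_KW_PER_CH2 * n, S=NAPS_S)
        for n in range(1, n_max + 1)
    ]


def gradient_rt_batch(
    log_kws: np.ndarray,
    slopes: np.ndarray,
    system: LcSystem,
    max_time: float = 90.0,
    dt: float = 0.002,
) -> np.ndarray:
    """Apex retention times (minutes) for a batch of compounds.

    Solves the gradient-elution integral on a dense time grid shared by all
    compounds; returns NaN for compounds that do not elute within
    ``max_time`` minutes.
    """
    log_kws = np.atleast_1d(np.asarray(log_kws, dtype=float))
    slopes = np.atleast_1d(np.asarray(slopes, dtype=float))
    if log_kws.shape != slopes.shape:
        raise ValueError("log_kws and slopes must have matching shapes")
    t0 = system.t0
    t = np.arange(0.0, max_time + dt, dt)
    phi = system.phi_at_column(t)
    # integrand[i, j] = 1 / (t0 * k_i(phi_j)) = 10**(S_i*phi_j - log_kw_i) / t0
    log_integrand = slopes[:, None] * phi[None, :] - log_kws[:, None]
    integrand = 10.0 ** np.clip(log_integrand, -300, 300) / t0
    # cumulative trapezoid along the time axis
    seg = 0.5 * (integrand[:, 1:] + integrand[:, :-1]) * dt
    cum = np.concatenate([np.zeros((len(log_kws), 1)), np.cumsum(seg, axis=1)], axis=1)
    rts = np.full(len(log_kws), np.nan)
    for i in range(len(log_kws)):
        idx = np.searchsorted(cum[i], 1.0)
        if idx >= len(t):
            continue  # never elutes within max_time
        c0, c1 = cum[i, idx - 1], cum[i, idx]
        frac = (1.0 - c0) / (c1 - c0) if c1 > c0 else 0.0
        rts[i] = t0 + t[idx - 1] + frac * dt
    return rts


def gradient_rt(
    params: RetentionParams, system: LcSystem, max_time: float = 90.0, dt: float = 0.002
) -> float:
    """Apex retention time of one compound (NaN if it never elutes)."""
    return float(
        gradient_rt_batch(
            np.array([params.log_kw]), np.array([params.S]), system, max_time, dt
        )[0]
    )


def simulate_naps_series(
    system: LcSystem, naps_params: list[RetentionParams] | None = None
) -> pd.DataFrame:
    """Noise-free NAPS anchor table (n_carbons, rt_min) for one system."""
    if naps_params is None:
        naps_params = default_naps_params()
    log_kws = np.array([p.log_kw for p in naps_params])
    slopes = np.array([p.S for p in naps_params])
    rts = gradient_rt_batch(log_kws, slopes, system)
    return pd.DataFrame({"n_carbons": np.arange(1, len(naps_params) + 1), "rt_min": rts})


# ---------------------------------------------------------------------------
# full-study generator


@dataclass
class StudyConfig:
    """Conditions of the synthetic indexing study.

    Defaults emulate the reference design: a 50-compound panel of retained
    standards (``log_kw`` spanning the gradient; weakly retained compounds
    eluting at the void are not informative for index libraries) measured in
    triplicate on the reference method and a flow-rate panel
    (0.20-0.40 mL/min), plus matrix runs spiked with NAPS at dilutions
    1:20 / 1:40 / 1:80 with a Gaussian suppression kernel (half the signal
    lost at the apex for the strongest spike, amplitude inversely
    proportional to dilution, 0.1 min kernel width).
    """

    flow_rates: tuple[float, ...] = (0.20, 0.25, 0.30, 0.35, 0.40)
    reference_flow_rate: float = 0.30
    n_analytes: int = 50
    replicates: int = 3
    rt_jitter_sd: float = 0.02  # min
    intensity_log10_sd: float = 0.10
    analyte_log_kw_range: tuple[float, float] = (0.3, 3.5)
    analyte_s_mean: float = 4.0
    analyte_s_sd: float = 0.3
    mz_range: tuple[float, float] = (80.0, 900.0)
    n_matrix_features: int = 300
    dilutions: tuple[str, ...] = ("1:20", "1:40", "1:80")
    suppression_amplitude_1_20: float = 0.5
    suppression_width_min: float = 0.10
    polarity: str = "pos"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(open(path)) or {}
        valid = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("flow_rates", "dilutions", "analyte_log_kw_range", "mz_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def suppression_amplitude(self, dilution: str) -> float:
        """Apex fraction of signal lost, scaled inversely with dilution."""
        num, den = dilution.split(":")
        factor = float(den) / float(num)
        return self.suppression_amplitude_1_20 * 20.0 / factor


@dataclass
class SimulatedStudy:
    """Output bundle of :func:`simulate_study` (all plain DataFrames)."""

    naps: dict[tuple[str, int], pd.DataFrame]  # (system, replicate) -> anchors
    runs: dict[tuple[str, int], pd.DataFrame]  # (system, replicate) -> features
    ground_truth: pd.DataFrame
    matrix_unspiked: pd.DataFrame
    matrix_spiked: dict[str, pd.DataFrame]  # dilution -> features
    matrix_naps_apexes: pd.DataFrame
    systems: dict[str, LcSystem]


def _system_name(flow: float) -> str:
    return f"F{flow:.2f}"


def simulate_study(config: StudyConfig, seed: int) -> SimulatedStudy:
    """Generate the full synthetic study; identical (config, seed) inputs
    give identical outputs."""
    rng = np.random.default_rng(seed)

    # analyte panel: LSS parameters, m/z, base intensity
    lo, hi = config.analyte_log_kw_range
    log_kw = rng.uniform(lo, hi, config.n_analytes)
    S = np.clip(
        rng.normal(config.analyte_s_mean, config.analyte_s_sd, config.n_analytes),
        1.0,
        None,
    )
    mz = np.round(rng.uniform(*config.mz_range, config.n_analytes), 4)
    base_intensity = 10.0 ** rng.uniform(4.0, 6.5, config.n_analytes)
    compound_ids = [f"M{i + 1:03d}" for i in range(config.n_analytes)]

    naps_params = default_naps_params()
    naps_log_kw = np.array([p.log_kw for p in naps_params])
    naps_S = np.array([p.S for p in naps_params])

    systems = {
        _system_name(f): default_reference_system(flow_rate=f) for f in config.flow_rates
    }
    if _system_name(config.reference_flow_rate) not in systems:
        systems[_system_name(config.reference_flow_rate)] = default_reference_system(
            config.reference_flow_rate
        )

    truth_rows = []
    naps_out: dict[tuple[str, int], pd.DataFrame] = {}
    runs_out: dict[tuple[str, int], pd.DataFrame] = {}
    for name, system in systems.items():
        true_rts = gradient_rt_batch(log_kw, S, system)
        naps_rts = gradient_rt_batch(naps_log_kw, naps_S, system)
        for i, cid in enumerate(compound_ids):
            truth_rows.append(
                {
                    "compound_id": cid,
                    "system": name,
                    "flow_rate": system.flow_rate,
                    "mz": mz[i],
                    "log_kw": log_kw[i],
                    "S": S[i],
                    "true_rt_min": true_rts[i],
                }
            )
        for rep in range(1, config.replicates + 1):
            anchor_rt = naps_rts + rng.normal(0.0, config.rt_jitter_sd, naps_rts.size)
            anchor_rt = np.maximum.accumulate(anchor_rt)  # jitter must not reorder anchors
            naps_out[(name, rep)] = pd.DataFrame(
                {"n_carbons": np.arange(1, 21), "rt_min": anchor_rt}
            )
            feat_rt = true_rts + rng.normal(0.0, config.rt_jitter_sd, true_rts.size)
            intensity = base_intensity * 10.0 ** rng.normal(
                0.0, config.intensity_log10_sd, true_rts.size
            )
            runs_out[(name, rep)] = pd.DataFrame(
                {
                    "feature_id": [f"{name}_r{rep}_{cid}" for cid in compound_ids],
                    "compound_id": compound_ids,
                    "mz": mz,
                    "rt_min": feat_rt,
                    "intensity": intensity,
                    "polarity": config.polarity,
                }
            )

    # matrix runs for ion-suppression evaluation (reference system)
    ref_system = systems[_system_name(config.reference_flow_rate)]
    apex_rts = gradient_rt_batch(naps_log_kw, naps_S, ref_system)
    apexes = pd.DataFrame({"n_carbons": np.arange(1, 21), "rt_min": apex_rts})

    m_rt = rng.uniform(0.5, float(np.nanmax(apex_rts)) + 0.5, config.n_matrix_features)
    m_mz = np.round(rng.uniform(*config.mz_range, config.n_matrix_features), 4)
    m_base = 10.0 ** rng.uniform(4.0, 6.5, config.n_matrix_features)
    unspiked = pd.DataFrame(
        {
            "feature_id": [f"mx{i + 1:04d}" for i in range(config.n_matrix_features)],
            "mz": m_mz,
            "rt_min": m_rt,
            "intensity": m_base
            * 10.0 ** rng.normal(0.0, config.intensity_log10_sd, config.n_matrix_features),
            "polarity": config.polarity,
        }
    )

    eval_apexes = apex_rts[3:]  # suppression evaluated only for RI > 300
    spiked: dict[str, pd.DataFrame] = {}
    for dilution in config.dilutions:
        amp = config.suppression_amplitude(dilution)
        nearest = eval_apexes[
            np.argmin(np.abs(m_rt[:, None] - eval_apexes[None, :]), axis=1)
        ]
        kernel = amp * np.exp(
            -((m_rt - nearest) ** 2) / (2.0 * config.suppression_width_min**2)
        )
        spiked[dilution] = pd.DataFrame(
            {
                "feature_id": unspiked["feature_id"],
                "mz": m_mz,
                "rt_min": m_rt + rng.normal(0.0, 0.005, config.n_matrix_features),
                "intensity": m_base
                * (1.0 - kernel)
                * 10.0
                ** rng.normal(0.0, config.intensity_log10_sd, config.n_matrix_features),
                "polarity": config.polarity,
            }
        )

    return SimulatedStudy(
        naps=naps_out,
        runs=runs_out,
        ground_truth=pd.DataFrame(truth_rows),
        matrix_unspiked=unspiked,
        matrix_spiked=spiked,
        matrix_naps_apexes=apexes,
        systems=systems,
    )
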