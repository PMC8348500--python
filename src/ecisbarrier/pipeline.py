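"""Analysis chain for ECIS barrier experiments.

Confluence detection, baseline normalization, fixed-frequency resistance and
capacitance readouts, per-time-point inversion into (Rb, alpha, Cm)
trajectories, and AUC / midpoint / endpoint outcome extraction.

Conventions: treatment is applied at t = 0 h; every trace is normalized to
its value at the last sample at or before t = 0, which maps to exactly 1.
The primary whole-experiment outcome is the trapezoidal area under the
normalized curve (AUC) over 0–100 h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    BarrierParameters,
    ComplexSpectrum,
    ElectrodeModel,
    covered_impedance,
    fit_barrier_parameters,
    naked_impedance,
    series_capacitance,
)

__all__ = [
    "CONFLUENCE_THRESHOLD_NF",
    "RESISTANCE_READOUT_HZ",
    "CAPACITANCE_READOUT_HZ",
    "NormalizedTrace",
    "AucResult",
    "detect_confluence",
    "normalize",
    "channel_at_frequency",
    "frequency_of_max_contrast",
    "fit_trajectories",
    "auc",
    "well_outcomes",
    "outcome_table",
]

#: whole-well 64 kHz capacitance below which the monolayer is confluent
CONFLUENCE_THRESHOLD_NF = 20.0

#: default readout frequencies: total resistance is most sensitive to the
#: cell layer at 4 kHz, spreading (capacitance) at 64 kHz
RESISTANCE_READOUT_HZ = 4000.0
CAPACITANCE_READOUT_HZ = 64000.0

CHANNELS = ("impedance", "resistance", "capacitance", "Rb", "alpha", "Cm")


@dataclass(frozen=True)
class NormalizedTrace:
    """A per-well time series divided by its pre-treatment baseline."""

    times: np.ndarray  # hours, t = 0 at treatment
    values: np.ndarray  # dimensionless ratios; NaN where not calculable
    channel: str = "resistance"
    well_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class AucResult:
    """Trapezoidal AUC with the interval actually integrated.

    ``t_end`` may fall short of the requested interval end when the trace
    becomes not-calculable (e.g. alpha/Cm after Rb reaches zero); the area is
    then reported over the effective interval rather than zero-filled.
    """

    value: float  # dimensionless * h
    t_start: float
    t_end: float

    @property
    def truncated(self) -> bool:
        return False if np.isnan(self.t_end) else self.t_end < self._requested_end

    _requested_end: float = float("nan")


def detect_confluence(times, capacitance_nf, threshold: float = CONFLUENCE_THRESHOLD_NF):
    """First time at which the 64 kHz whole-well capacitance drops below
    ``threshold`` (nF); ``None`` if it never does.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(capacitance_nf, dtype=float)
    if t.size == 0 or c.shape != t.shape:
        raise ValueError("need equal-length, non-empty times and capacitance")
    below = np.flatnonzero(c < threshold)
    return float(t[below[0]]) if below.size else None


def normalize(times, values, treatment_time: float = 0.0, **trace_kw) -> NormalizedTrace:
    """Divide a trace by its value at the last sample at or before
    ``treatment_time``; that sample maps to exactly 1.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    pre = np.flatnonzero(t <= treatment_time)
    if pre.size == 0:
        raise ValueError("no sample at or before the treatment time")
    baseline = v[pre[-1]]
    if not np.isfinite(baseline) or baseline == 0:
        raise ValueError("baseline value is zero or not finite; ratio undefined")
    return NormalizedTrace(times=t, values=v / baseline, **trace_kw)


def channel_at_frequency(table, channel: str, f: float | None = None) -> pd.DataFrame:
    """Per-well time series of a series-RC readout at one grid frequency.

    ``channel`` is ``"resistance"`` (Ω, default readout 4000 Hz) or
    ``"capacitance"`` (nF, default readout 64,000 Hz).  Returns a long
    DataFrame with columns ``well_id, group, time_h, value``.
    """
    if channel not in ("resistance", "capacitance"):
        raise ValueError("channel must be 'resistance' or 'capacitance'")
    if f is None:
        f = RESISTANCE_READOUT_HZ if channel == "resistance" else CAPACITANCE_READOUT_HZ
    grid = table.frequencies
    if not np.any(np.isclose(grid, f)):
        raise ValueError(f"frequency {f} Hz not in table grid {list(grid)}")
    sub = table.data[np.isclose(table.data["frequency_hz"], f)].copy()
    if channel == "resistance":
        sub["value"] = sub["resistance_ohm"]
    else:
        z = sub["resistance_ohm"].to_numpy() + 1j * sub["reactance_ohm"].to_numpy()
        sub["value"] = series_capacitance(z, f)
    return sub[["well_id", "group", "time_h", "value"]].sort_values(
        ["well_id", "time_h"], kind="stable"
    ).reset_index(drop=True)


def frequency_of_max_contrast(
    electrode: ElectrodeModel,
    params: BarrierParameters,
    grid,
    channel: str = "resistance",
) -> float:
    """Grid frequency with the greatest cell-layer contrast.

    For ``resistance``: argmax of the covered/naked series-resistance ratio.
    For ``capacitance``: argmax of the relative series-capacitance drop of
    covered versus naked.  This is the model-based rationale for the 4 kHz
    resistance and 64 kHz capacitance readout choices.
    """
    f = np.asarray(grid, dtype=float)
    zn = naked_impedance(f, electrode)
    zc = covered_impedance(f, params, electrode)
    if channel == "resistance":
        contrast = zc.real / zn.real
    elif channel == "capacitance":
        cn = series_capacitance(zn, f)
        cc = series_capacitance(zc, f)
        contrast = (cn - cc) / cn
    else:
        raise ValueError("channel must be 'resistance' or 'capacitance'")
    return float(f[np.argmax(contrast)])


def fit_trajectories(
    table,
    electrode: ElectrodeModel,
    time_range: tuple = (0.0, None),
    wells=None,
) -> pd.DataFrame:
    """Invert every (well, time) spectrum into barrier parameters.

    Fits are warm-started from the previous time point of the same well for
    trajectory continuity.  Wherever the fitted Rb is zero, alpha and Cm are
    emitted as NaN (not calculable), never imputed.  Non-converged fits are
    emitted as all-NaN rows and counted in ``attrs['n_not_converged']``.

    Only times within ``time_range`` (default: from treatment onward, where
    the monolayer is confluent and the model applies) are fitted.

    Returns a long DataFrame with columns ``well_id, group, time_h, Rb,
    alpha, Cm, converged``.
    """
    area = electrode.electrode_area
    lo, hi = time_range
    rows = []
    n_not_converged = 0
    data = table.data
    if wells is not None:
        data = data[data["well_id"].isin(list(wells))]
    for well_id, wdf in data.groupby("well_id", sort=False):
        group = wdf["group"].iloc[0]
        warm = None
        for t, tdf in wdf.groupby("time_h", sort=True):
            if (lo is not None and t < lo) or (hi is not None and t > hi):
                continue
            tdf = tdf.sort_values("frequency_hz")
            z_spec = (
                tdf["resistance_ohm"].to_numpy() + 1j * tdf["reactance_ohm"].to_numpy()
            ) * area
            spectrum = ComplexSpectrum(
                tdf["frequency_hz"].to_numpy(), z_spec, time=float(t), well_id=str(well_id)
            )
            result = fit_barrier_parameters(spectrum, electrode, init=warm)
            if result.converged:
                p = result.params
                rows.append(
                    {
                        "well_id": well_id,
                        "group": group,
                        "time_h": float(t),
                        "Rb": p.Rb,
                        "alpha": p.alpha if p.alpha_valid else np.nan,
                        "Cm": p.Cm if p.Cm_valid else np.nan,
                        "converged": True,
                    }
                )
                warm = result.raw_params
            else:
                n_not_converged += 1
                rows.append(
                    {
                        "well_id": well_id,
                        "group": group,
                        "time_h": float(t),
                        "Rb": np.nan,
                        "alpha": np.nan,
                        "Cm": np.nan,
                        "converged": False,
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["n_not_converged"] = n_not_converged
    return out


def auc(trace: NormalizedTrace, interval: tuple = (0.0, 100.0)) -> AucResult:
    """Trapezoidal area under a normalized trace over ``interval`` (hours).

    Not-calculable samples (NaN) terminate the integrable region: the
    integral runs from the interval start to the last valid sample before
    the first NaN, and the effective interval is reported in the result.
    """
    t0, t1 = float(interval[0]), float(interval[1])
    if t1 <= t0:
        raise ValueError("interval end must exceed interval start")
    mask = (trace.times >= t0) & (trace.times <= t1)
    t = trace.times[mask]
    v = trace.values[mask]
    invalid = np.flatnonzero(~np.isfinite(v))
    if invalid.size:
        t, v = t[: invalid[0]], v[: invalid[0]]
    if t.size < 2:
        raise ValueError("fewer than 2 valid samples in the interval")
    value = float(np.trapezoid(v, t))
    return AucResult(value, float(t[0]), float(t[-1]), _requested_end=t1)


def _value_at(trace: NormalizedTrace, t: float) -> float:
    """Value at the sample nearest to t (NaN when not calculable there)."""
    i = int(np.argmin(np.abs(trace.times - t)))
    return float(trace.values[i])


def well_outcomes(
    traces,
    auc_interval: tuple = (0.0, 100.0),
    midpoint: float = 24.0,
    endpoint: float = 100.0,
) -> pd.DataFrame:
    """Per-well endpoint / midpoint / AUC outcomes.

    ``traces`` is an iterable of :class:`NormalizedTrace`.  Returns one row
    per trace with columns ``well_id, group, channel, endpoint, midpoint,
    auc, auc_t_end``; outcomes at not-calculable samples are NaN.
    """
    rows = []
    for tr in traces:
        try:
            a = auc(tr, auc_interval)
            auc_value, auc_t_end = a.value, a.t_end
        except ValueError:
            auc_value, auc_t_end = np.nan, np.nan
        rows.append(
            {
                "well_id": tr.well_id,
                "group": tr.group,
                "channel": tr.channel,
                "endpoint": _value_at(tr, endpoint),
                "midpoint": _value_at(tr, midpoint),
                "auc": auc_value,
                "auc_t_end": auc_t_end,
            }
        )
    return pd.DataFrame(rows)


def outcome_table(
    traces,
    auc_interval: tuple = (0.0, 100.0),
    midpoint: float = 24.0,
    endpoint: float = 100.0,
) -> pd.DataFrame:
    """Group-level mean ± SD of endpoint, midpoint and AUC per channel.

    Requires at least 2 replicate wells per (group, channel) for an SD; the
    per-well table is produced by :func:`well_outcomes`.
    """
    per_well = well_outcomes(traces, auc_interval, midpoint, endpoint)
    if per_well.empty:
        raise ValueError("no traces supplied")
    rows = []
    for (group, channel), gdf in per_well.groupby(["group", "channel"], sort=False):
        n = len(gdf)
        row = {"group": group, "channel": channel, "n_replicates": n}
        for stat in ("endpoint", "midpoint", "auc"):
            vals = gdf[stat].to_numpy(dtype=float)
            valid = vals[np.isfinite(vals)]
            row[f"{stat}_mean"] = float(np.mean(valid)) if valid.size else np.nan
            row[f"{stat}_sd"] = (
                float(np.std(valid, ddof=1)) if valid.size >= 2 else np.nan
            )
            row[f"{stat}_n_valid"] = int(valid.size)
        row["auc_t_end_min"] = float(np.nanmin(gdf["auc_t_end"])) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def trajectory_traces(fitted: pd.DataFrame, treatment_time: float = 0.0):
    """Normalize fitted Rb/alpha/Cm trajectories per well.

    Each fitted trace is divided by its own value at the last sample at or
    before the treatment time.  Yields :class:`NormalizedTrace` objects for
    channels Rb, alpha and Cm.
    """
    traces = []
    for well_id, wdf in fitted.groupby("well_id", sort=False):
        wdf = wdf.sort_values("time_h")
        group = wdf["group"].iloc[0]
        t = wdf["time_h"].to_numpy(dtype=float)
        for channel in ("Rb", "alpha", "Cm"):
            v = wdf[channel].to_numpy(dtype=float)
            traces.append(
                normalize(t, v, treatment_time, channel=channel, well_id=str(well_id), group=str(group))
            )
    return traces


def readout_traces(table, treatment_time: float = 0.0):
    """Normalized resistance@4 kHz and capacitance@64 kHz traces per well."""
    traces = []
    for channel, f in (
        ("resistance", RESISTANCE_READOUT_HZ),
        ("capacitance", CAPACITANCE_READOUT_HZ),
    ):
        long = channel_at_frequency(table, channel, f)
        for well_id, wdf in long.groupby("well_id", sort=False):
            traces.append(
                normalize(
                    wdf["time_h"].to_numpy(),
                    wdf["value"].to_numpy(),
                    treatment_time,
                    channel=channel,
                    well_id=str(well_id),
                    group=str(wdf["group"].iloc[0]),
                )
            )
    return traces
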