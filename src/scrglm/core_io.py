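"""Domain containers and file I/O for skin conductance analysis.

The two central objects are :class:`SCTimeSeries` (a uniformly sampled
conductance trace in microsiemens) and :class:`EventModel` (condition-labelled
stimulus onsets with optional per-trial parametric modulators).
:class:`CouplerSpec` describes the conductance-to-pulse-frequency recording
chain of a constant-voltage coupler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SCTimeSeries",
    "EventModel",
    "Condition",
    "CouplerSpec",
    "read_timeseries",
    "write_timeseries",
    "read_events",
    "write_events",
    "pulse_to_conductance",
    "conductance_to_pulse",
]


@dataclass(frozen=True)
class SCTimeSeries:
    """Uniformly sampled skin conductance trace.

    Parameters
    ----------
    values
        Conductance per sample, in μS.
    sampling_rate
        Sampling rate in Hz; must be positive.
    start_time
        Time of the first sample in seconds (default 0).

    Uniform sampling is an invariant of the container: no per-sample
    timestamps are stored, and readers validate spacing before construction.
    """

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if values.size < 2:
            raise ValueError("timeseries must contain at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("timeseries contains non-finite values")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total covered time in seconds (n / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def with_values(self, values: np.ndarray) -> "SCTimeSeries":
        return SCTimeSeries(values, self.sampling_rate, self.start_time)


@dataclass(frozen=True)
class Condition:
    """One experimental condition: a name, onsets (s) and optional pmods."""

    name: str
    onsets: np.ndarray
    pmods: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        if onsets.ndim != 1 or onsets.size == 0:
            raise ValueError(f"condition {self.name!r} has no onsets")
        if np.any(onsets < 0):
            raise ValueError(f"condition {self.name!r} has negative onsets")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError(
                f"onsets within condition {self.name!r} must be strictly increasing"
            )
        object.__setattr__(self, "onsets", onsets)
        pmods = {k: np.asarray(v, dtype=float) for k, v in self.pmods.items()}
        for name, vals in pmods.items():
            if vals.shape != onsets.shape:
                raise ValueError(
                    f"pmod {name!r} of condition {self.name!r} has "
                    f"{vals.size} values for {onsets.size} onsets"
                )
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"pmod {name!r} contains non-finite values")
        object.__setattr__(self, "pmods", pmods)

    @property
    def n_trials(self) -> int:
        return self.onsets.size


@dataclass(frozen=True)
class EventModel:
    """Condition-labelled stimulus onsets for one recording."""

    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        conditions = tuple(self.conditions)
        if len(conditions) < 1:
            raise ValueError("event model needs at least one condition")
        names = [c.name for c in conditions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate condition names")
        object.__setattr__(self, "conditions", conditions)

    @property
    def j(self) -> int:
        """Number of conditions."""
        return len(self.conditions)

    @property
    def n_trials(self) -> int:
        """Total trial count across conditions."""
        return sum(c.n_trials for c in self.conditions)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.conditions]

    def condition(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(f"unknown condition {name!r}")

    @property
    def all_onsets(self) -> np.ndarray:
        """All onsets pooled across conditions, sorted ascending."""
        return np.sort(np.concatenate([c.onsets for c in self.conditions]))


@dataclass(frozen=True)
class CouplerSpec:
    """Constant-voltage coupler: affine conductance → pulse-frequency map.

    ``offset_hz`` is the pulse frequency at zero conductance (the minimum
    sampling rate of the pulse train) and ``gain_hz_per_us`` the slope.
    """

    offset_hz: float = 100.0
    gain_hz_per_us: float = 31.0
    max_us: float = 50.0

    def __post_init__(self) -> None:
        if not (self.offset_hz > 0 and self.gain_hz_per_us > 0):
            raise ValueError("offset_hz and gain_hz_per_us must be positive")

    @property
    def max_hz(self) -> float:
        return self.offset_hz + self.gain_hz_per_us * self.max_us


def pulse_to_conductance(freq_hz: float, spec: CouplerSpec = CouplerSpec()) -> float:
    """Convert a coupler pulse frequency (Hz) to conductance (μS)."""
    freq_hz = float(freq_hz)
    if freq_hz < spec.offset_hz:
        raise ValueError(
            f"pulse frequency {freq_hz} Hz is below the coupler floor "
            f"of {spec.offset_hz} Hz"
        )
    return (freq_hz - spec.offset_hz) / spec.gain_hz_per_us


def conductance_to_pulse(conductance_us: float, spec: CouplerSpec = CouplerSpec()) -> float:
    """Convert conductance (μS) to the coupler pulse frequency (Hz)."""
    conductance_us = float(conductance_us)
    if conductance_us < 0:
        raise ValueError("conductance must be nonnegative")
    return spec.offset_hz + spec.gain_hz_per_us * conductance_us


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_timeseries(path, sampling_rate_override: float | None = None) -> SCTimeSeries:
    """Read a conductance trace from a one- or two-column CSV/TSV file.

    A two-column file is interpreted as (time_s, conductance_us); spacing of
    the time column must be uniform within 1 ppm and determines the sampling
    rate.  A one-column file requires ``sampling_rate_override``.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] not in (1, 2):
        raise ValueError(f"expected 1 or 2 columns, found {df.shape[1]} in {path}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric cell in column {col!r} at data row {row}")
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
            raise ValueError(f"missing value in column {col!r} at data row {row}")

    if df.shape[1] == 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        values = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0:
            raise ValueError("timeseries must contain at least 2 samples")
        ref = np.median(dt)
        if ref <= 0:
            raise ValueError("time column must be strictly increasing")
        off = np.abs(dt - ref) / ref
        if np.any(off > 1e-6):
            i = int(np.argmax(off > 1e-6))
            raise ValueError(
                "non-uniform sampling: gap between rows "
                f"{i} and {i + 1} is {dt[i]:.6g} s (expected {ref:.6g} s)"
            )
        sr = 1.0 / ref
        if sampling_rate_override is not None and not np.isclose(
            sampling_rate_override, sr, rtol=1e-6
        ):
            raise ValueError(
                f"override {sampling_rate_override} Hz conflicts with the "
                f"time column ({sr:.6g} Hz)"
            )
        return SCTimeSeries(values, sr, start_time=float(t[0]))

    if sampling_rate_override is None:
        raise ValueError("single-column file requires a sampling rate")
    values = df.iloc[:, 0].to_numpy(dtype=float)
    return SCTimeSeries(values, float(sampling_rate_override))


def write_timeseries(ts: SCTimeSeries, path, include_time: bool = True) -> None:
    """Write a trace to CSV/TSV (columns ``time_s, conductance_us``)."""
    if include_time:
        df = pd.DataFrame({"time_s": ts.times, "conductance_us": ts.values})
    else:
        df = pd.DataFrame({"conductance_us": ts.values})
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.10g")


def read_events(path) -> EventModel:
    """Read an event file (CSV: ``onset_s, condition[, pmod_*]``).

    Rows are grouped by condition preserving first-appearance order; each
    ``pmod_*`` column becomes a per-condition parametric modulator.  A pmod
    column may be blank for conditions it does not apply to, but must be
    complete within any condition where it appears.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.empty:
        raise ValueError(f"no events in {path}")
    cols = {c.lower(): c for c in df.columns}
    onset_col = cols.get("onset_s") or cols.get("onset")
    cond_col = cols.get("condition")
    if onset_col is None or cond_col is None:
        raise ValueError("event file must have 'onset_s' (or 'onset') and 'condition' columns")
    pmod_cols = [c for c in df.columns if c.lower().startswith("pmod_")]

    conditions: list[Condition] = []
    for name in df[cond_col].drop_duplicates():
        sub = df[df[cond_col] == name]
        onsets = sub[onset_col].to_numpy(dtype=float)
        if np.any(np.diff(onsets) <= 0):
            raise ValueError(f"onsets within condition {name!r} are not sorted")
        pmods = {}
        for pc in pmod_cols:
            vals = pd.to_numeric(sub[pc], errors="coerce")
            if vals.notna().any():
                if vals.isna().any():
                    raise ValueError(
                        f"pmod column {pc!r} has missing values in condition {name!r}"
                    )
                pmods[pc[len("pmod_"):]] = vals.to_numpy(dtype=float)
        conditions.append(Condition(str(name), onsets, pmods))
    return EventModel(tuple(conditions))


def write_events(events: EventModel, path) -> None:
    """Write an event model back to CSV (inverse of :func:`read_events`)."""
    rows = []
    for cond in events.conditions:
        for i, onset in enumerate(cond.onsets):
            row: dict = {"onset_s": onset, "condition": cond.name}
            for pname, vals in cond.pmods.items():
                row[f"pmod_{pname}"] = vals[i]
            rows.append(row)
    df = pd.DataFrame(rows).sort_values("onset_s", kind="stable")
    df.to_csv(path, sep=_sep_for(path), index=False)
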