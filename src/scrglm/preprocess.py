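"""First-order Butterworth filtering and downsampling.

Skin conductance traces mix fast phasic responses with slow tonic drift;
standard conditioning is a 5 Hz low-pass (anti-alias) followed by a high-pass
that removes the drift, then decimation to the 10 Hz model rate.  Both filter
directions apply a 1st-order Butterworth section exactly twice: *bidirectional*
runs forward then backward (zero phase, as in ``filtfilt``), *unidirectional*
runs forward twice so the effective filter order is identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import SCTimeSeries

__all__ = ["FilterSpec", "apply_filter", "default_preprocess", "downsample"]

MODEL_RATE_HZ = 10.0
ANTIALIAS_CUTOFF_HZ = 5.0
DEFAULT_HP_CUTOFF_HZ = 0.05
LEGACY_HP_CUTOFF_HZ = 0.0159  # 10 s time constant


@dataclass(frozen=True)
class FilterSpec:
    """A doubly-applied 1st-order Butterworth filter.

    ``direction='bidirectional'`` gives a zero-phase filter (forward +
    backward pass); ``'unidirectional'`` applies two forward passes, keeping
    the filter order the same but retaining causal phase.
    """

    kind: str  # {"highpass", "lowpass"}
    cutoff_hz: float
    direction: str = "unidirectional"
    order: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.direction not in ("unidirectional", "bidirectional"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.order != 1:
            raise ValueError("only 1st-order sections are supported")
        if not (self.cutoff_hz > 0):
            raise ValueError("cutoff must be positive")

    def validate_for(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if self.cutoff_hz >= nyq:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz is at or above the Nyquist "
                f"frequency ({nyq} Hz) for a {sampling_rate} Hz signal"
            )


def _filter_values(values: np.ndarray, spec: FilterSpec, sr: float) -> np.ndarray:
    b, a = signal.butter(spec.order, spec.cutoff_hz, btype=spec.kind, fs=sr)
    # Signal is filtered as-is (zero initial state, no padding/reflection);
    # edge transients therefore appear at the ends, as documented.
    y = signal.lfilter(b, a, values)
    if spec.direction == "bidirectional":
        y = signal.lfilter(b, a, y[::-1])[::-1]
    else:
        y = signal.lfilter(b, a, y)
    return y


def apply_filter(ts: SCTimeSeries, spec: FilterSpec) -> SCTimeSeries:
    """Apply a doubly-applied 1st-order Butterworth filter to a trace."""
    spec.validate_for(ts.sampling_rate)
    return ts.with_values(_filter_values(ts.values, spec, ts.sampling_rate))


def filter_array(values: np.ndarray, spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    """Filter a bare array with the same code path as the data (for regressors)."""
    spec.validate_for(sampling_rate)
    return _filter_values(np.asarray(values, dtype=float), spec, sampling_rate)


def downsample(ts: SCTimeSeries, target_hz: float) -> SCTimeSeries:
    """Decimate by sample-picking; assumes an anti-alias low-pass was applied.

    The source rate must be an integer multiple of ``target_hz``; samples
    0, r, 2r, ... are kept.
    """
    ratio = ts.sampling_rate / target_hz
    if not np.isclose(ratio, round(ratio), rtol=0, atol=1e-9):
        raise ValueError(
            f"sampling rate {ts.sampling_rate} Hz is not an integer multiple of "
            f"{target_hz} Hz; resample the signal first"
        )
    step = int(round(ratio))
    if step == 1:
        return ts
    return SCTimeSeries(ts.values[::step], target_hz, ts.start_time)


def default_preprocess(
    ts: SCTimeSeries,
    hp: FilterSpec | None = None,
    target_hz: float = MODEL_RATE_HZ,
    lp_cutoff_hz: float = ANTIALIAS_CUTOFF_HZ,
) -> SCTimeSeries:
    """Standard conditioning: 5 Hz bidirectional low-pass, high-pass, decimate.

    Both filters run at the acquisition rate; the low-pass doubles as the
    anti-alias stage for the decimation to ``target_hz`` (default 10 Hz).
    The default high-pass is 0.05 Hz unidirectional; pass
    ``FilterSpec("highpass", 0.0159, "bidirectional")`` for the legacy
    10 s-time-constant pathway.
    """
    if ts.sampling_rate < 2 * target_hz:
        raise ValueError(
            f"acquisition rate {ts.sampling_rate} Hz too low for a "
            f"{target_hz} Hz model rate"
        )
    if hp is None:
        hp = FilterSpec("highpass", DEFAULT_HP_CUTOFF_HZ, "unidirectional")
    if hp.kind != "highpass":
        raise ValueError("hp must be a highpass FilterSpec")
    # the high-pass must survive decimation: check it against the target Nyquist
    if hp.cutoff_hz >= target_hz / 2.0:
        raise ValueError(
            f"high-pass cutoff {hp.cutoff_hz} Hz is above the Nyquist frequency "
            f"of the {target_hz} Hz model rate"
        )
    lp = FilterSpec("lowpass", lp_cutoff_hz, "bidirectional")
    out = apply_filter(ts, lp)
    out = apply_filter(out, hp)
    return downsample(out, target_hz)
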