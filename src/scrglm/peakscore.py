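"""Operational trough-to-peak scoring of evoked skin conductance responses.

These are the classical, model-free baselines: locate a response onset inside
a post-stimulus latency window, take the subsequent peak, and score the
trough-to-peak difference.  *Magnitude* averages all trials (non-responses as
zero); *amplitude* averages responders only, omitting scores below the
minimum-response criterion.  A simpler variant subtracts a 1 s pre-stimulus
baseline from the post-stimulus maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import SCTimeSeries

__all__ = ["PeakScoreConfig", "spr_score", "peak_baseline_score"]


@dataclass(frozen=True)
class PeakScoreConfig:
    """Windows and criteria for trough-to-peak scoring.

    latency_window
        Post-stimulus window (s) in which the response onset may occur;
        published conventions are (1, 4) and (1, 3).
    peak_window
        Post-onset window (s) in which the peak is sought; default (0.5, 5).
    min_response
        Minimum trough-to-peak difference (μS) to count as a response.
    mode
        "magnitude" averages all trials including zeros; "amplitude" averages
        responders only.
    onset_criterion
        "local_min": onset = local minimum preceding the steepest positive
        slope inside the latency window (default); "max_slope": the steepest-
        slope point itself.
    """

    latency_window: tuple[float, float] = (1.0, 4.0)
    peak_window: tuple[float, float] = (0.5, 5.0)
    min_response: float = 0.01
    mode: str = "magnitude"
    onset_criterion: str = "local_min"

    def __post_init__(self) -> None:
        for lo, hi in (self.latency_window, self.peak_window):
            if not (0 <= lo < hi):
                raise ValueError("windows must be positive and ordered")
        if self.min_response <= 0:
            raise ValueError("min_response must be positive")
        if self.mode not in ("magnitude", "amplitude"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.onset_criterion not in ("local_min", "max_slope"):
            raise ValueError(f"unknown onset criterion {self.onset_criterion!r}")


def _score_trial(
    values: np.ndarray, sr: float, onset_s: float, cfg: PeakScoreConfig
) -> float | None:
    """Trough-to-peak score for one trial; None if the window leaves the
    recording, 0.0 for a non-response."""
    lat0 = int(round((onset_s + cfg.latency_window[0]) * sr))
    lat1 = int(round((onset_s + cfg.latency_window[1]) * sr))
    if lat0 < 0 or lat1 + int(round(cfg.peak_window[1] * sr)) > values.size:
        return None
    window = values[lat0:lat1 + 1]
    slopes = np.diff(window)
    if slopes.size == 0 or slopes.max() <= 0:
        return 0.0  # no positive deflection: non-response
    i_steep = int(np.argmax(slopes))
    if cfg.onset_criterion == "max_slope":
        i_on = i_steep
    else:
        # walk back from the steepest rise to the preceding local minimum
        i_on = i_steep
        while i_on > 0 and window[i_on - 1] <= window[i_on]:
            i_on -= 1
    onset_idx = lat0 + i_on
    p0 = onset_idx + int(round(cfg.peak_window[0] * sr))
    p1 = onset_idx + int(round(cfg.peak_window[1] * sr))
    peak = values[p0:p1 + 1].max()
    score = peak - values[onset_idx]
    return score if score >= cfg.min_response else 0.0


def spr_score(
    ts: SCTimeSeries,
    onsets: np.ndarray,
    cfg: PeakScoreConfig = PeakScoreConfig(),
) -> tuple[float, np.ndarray]:
    """Trough-to-peak scores for a set of trials.

    Returns ``(mean_score, per_trial_scores)``.  In amplitude mode the mean
    omits non-responses; with no responder at all it is NaN (mean over an
    empty set is undefined).  Trials whose windows exceed the recording are
    dropped with a warning and appear as NaN in the per-trial vector.
    """
    onsets = np.asarray(onsets, dtype=float)
    scores = np.full(onsets.size, np.nan)
    for i, onset in enumerate(onsets):
        s = _score_trial(ts.values, ts.sampling_rate, onset - ts.start_time, cfg)
        if s is None:
            warnings.warn(
                f"trial {i} at {onset:.2f} s: scoring window exceeds recording; dropped",
                stacklevel=2,
            )
        else:
            scores[i] = s
    valid = scores[~np.isnan(scores)]
    if valid.size == 0:
        return float("nan"), scores
    if cfg.mode == "amplitude":
        responders = valid[valid >= cfg.min_response]
        mean = float(responders.mean()) if responders.size else float("nan")
    else:
        mean = float(valid.mean())
    return mean, scores


def peak_baseline_score(
    ts: SCTimeSeries,
    onsets: np.ndarray,
    response_window: tuple[float, float] = (1.0, 4.0),
    baseline: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Peak minus pre-stimulus baseline, no thresholding.

    Per trial: max over ``onset + response_window`` minus the mean of the
    ``baseline`` seconds before onset.  Scores may be negative (e.g. under
    downward drift); all trials enter the mean.
    """
    sr = ts.sampling_rate
    onsets = np.asarray(onsets, dtype=float)
    scores = np.full(onsets.size, np.nan)
    for i, onset in enumerate(onsets):
        o = onset - ts.start_time
        b0 = int(round((o - baseline) * sr))
        b1 = int(round(o * sr))
        r0 = int(round((o + response_window[0]) * sr))
        r1 = int(round((o + response_window[1]) * sr))
        if b0 < 0 or r1 + 1 > ts.n_samples:
            warnings.warn(
                f"trial {i} at {onset:.2f} s lacks a full baseline/response window; dropped",
                stacklevel=2,
            )
            continue
        scores[i] = ts.values[r0:r1 + 1].max() - ts.values[b0:b1].mean()
    valid = scores[~np.isnan(scores)]
    mean = float(valid.mean()) if valid.size else float("nan")
    return mean, scores
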