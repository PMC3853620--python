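"""Forward simulator of skin conductance cohorts.

Generates data with the statistical structure the analysis assumes:
condition-dependent sympathetic burst amplitudes with trial-to-trial
variability and linear habituation, a per-subject perturbed canonical
response function (latency shift and dispersion scaling — the
between-subject variability that motivates derivative basis functions),
optional per-trial neural latency jitter, slow tonic drift (sub-0.01 Hz
sinusoids plus an optional random walk), and white measurement noise.
Trial schedules for the two reference paradigms are built in:

``exp1``
    2 conditions × 45 trials, 1 s stimuli, ISI drawn from {7.65, 9, 10.35} s
    (minimum onset asynchrony 8.65 s), 3 blocks with 45 s breaks.
``exp2``
    3 conditions × 16 trials, 1 s stimuli, fixed 4.4 s ISI, one block.

Everything is reproducible from ``(seed, subject_index)``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .basis import SCRFParams, canonical_scrf
from .core_io import (
    Condition,
    EventModel,
    SCTimeSeries,
    write_events,
    write_timeseries,
)

__all__ = [
    "ConditionSpec",
    "ScheduleSpec",
    "DriftSpec",
    "RFJitter",
    "SimConfig",
    "SimTruth",
    "simulate_subject",
    "simulate_cohort",
    "exp1_config",
    "exp2_config",
]


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    mean_amplitude: float  # μS
    trial_sd: float = 0.1  # μS

    def __post_init__(self) -> None:
        if self.mean_amplitude < 0:
            raise ValueError(f"condition {self.name!r}: mean amplitude must be >= 0")
        if self.trial_sd < 0:
            raise ValueError("trial_sd must be >= 0")


@dataclass(frozen=True)
class ScheduleSpec:
    stimulus_dur: float = 1.0     # s
    isi_set: tuple[float, ...] = (7.65, 9.0, 10.35)  # s, offset-to-onset
    n_blocks: int = 1
    block_gap: float = 45.0       # s
    lead_in: float = 10.0         # s before first stimulus
    lead_out: float = 30.0        # s after last stimulus

    @property
    def min_soa(self) -> float:
        """Shortest stimulus onset asynchrony (onset-to-onset)."""
        return self.stimulus_dur + min(self.isi_set)


@dataclass(frozen=True)
class DriftSpec:
    """Slow tonic component: sinusoids at ≤ 0.01 Hz plus a random walk."""

    sinusoids: tuple[tuple[float, float], ...] = ()  # (amplitude μS, freq Hz)
    random_walk_sd: float = 0.0                      # μS / sqrt(s)

    def __post_init__(self) -> None:
        for amp, freq in self.sinusoids:
            if freq > 0.01:
                raise ValueError("drift sinusoids must stay at or below 0.01 Hz")
        if self.random_walk_sd < 0:
            raise ValueError("random_walk_sd must be >= 0")


DEFAULT_DRIFT = DriftSpec(sinusoids=((0.5, 0.002), (0.3, 0.006), (0.2, 0.01)))


@dataclass(frozen=True)
class RFJitter:
    """Per-subject response-function perturbation."""

    latency_shift_sd: float = 0.0     # s, added to the SCRF peak time
    dispersion_scale_sd: float = 0.0  # fractional


@dataclass(frozen=True)
class SimConfig:
    """Full generative description of a synthetic cohort."""

    conditions: tuple[ConditionSpec, ...]
    n_trials_per_condition: int
    schedule: ScheduleSpec = ScheduleSpec()
    n_subjects: int = 20
    habituation_slope: float = 0.007   # fractional amplitude decline per trial
    habituation_kind: str = "linear"   # or "exponential"
    rf_jitter: RFJitter = RFJitter()
    neural_latency_jitter_sd: float = 0.0  # s per trial; 0 = strict linear model
    drift: DriftSpec = DriftSpec()
    noise_sd: float = 0.05             # μS white measurement noise
    sampling_rate: float = 10.0        # Hz (model rate; simulated directly)
    scrf: SCRFParams = SCRFParams()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.habituation_kind not in ("linear", "exponential"):
            raise ValueError(f"unknown habituation kind {self.habituation_kind!r}")
        if self.noise_sd < 0 or self.neural_latency_jitter_sd < 0:
            raise ValueError("noise and jitter SDs must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_condition * len(self.conditions)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth emitted alongside each simulated subject."""

    subject: int
    scrf: SCRFParams                       # the subject's perturbed RF
    trial_condition: tuple[str, ...]
    trial_amplitude: np.ndarray            # μS, post-habituation, floored at 0
    trial_latency: np.ndarray              # s, actual burst time


def exp1_config(**overrides) -> SimConfig:
    """Picture-viewing paradigm 1: neutral vs aversive, 45 trials each."""
    cfg = SimConfig(
        conditions=(
            ConditionSpec("neutral", 0.3),
            ConditionSpec("negative", 0.6),
        ),
        n_trials_per_condition=45,
        schedule=ScheduleSpec(
            stimulus_dur=1.0, isi_set=(7.65, 9.0, 10.35),
            n_blocks=3, block_gap=45.0,
        ),
    )
    return replace(cfg, **overrides)


def exp2_config(**overrides) -> SimConfig:
    """Picture-viewing paradigm 2: neutral / aversive / positive, 16 trials
    each at a rapid fixed 4.4 s ISI."""
    cfg = SimConfig(
        conditions=(
            ConditionSpec("neutral", 0.3),
            ConditionSpec("negative", 0.6),
            ConditionSpec("positive", 0.5),
        ),
        n_trials_per_condition=16,
        schedule=ScheduleSpec(
            stimulus_dur=1.0, isi_set=(4.4,), n_blocks=1,
        ),
    )
    return replace(cfg, **overrides)


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject_index,))
    )


def _make_schedule(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Random condition order and onset times honouring blocks and ISI set."""
    labels = [c.name for c in cfg.conditions for _ in range(cfg.n_trials_per_condition)]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    sched = cfg.schedule
    n = len(labels)
    per_block = int(np.ceil(n / sched.n_blocks))
    onsets = np.empty(n)
    t = sched.lead_in
    for i in range(n):
        if i > 0 and i % per_block == 0:
            t += sched.block_gap
        onsets[i] = t
        isi = rng.choice(sched.isi_set) if len(sched.isi_set) > 1 else sched.isi_set[0]
        t += sched.stimulus_dur + isi
    return onsets, labels


def simulate_subject(
    cfg: SimConfig, subject_index: int
) -> tuple[SCTimeSeries, EventModel, SimTruth]:
    """Simulate one subject's recording, events and ground truth.

    Trial amplitude = condition mean × habituation(trial rank within
    condition) + Normal(0, trial_sd), floored at 0; a unit-mass delta (with
    optional per-trial latency jitter) is convolved with the subject's
    perturbed canonical response function; drift and white noise are added.
    Deterministic given ``(cfg.seed, subject_index)``.
    """
    rng = _subject_rng(cfg.seed, subject_index)
    sr = cfg.sampling_rate
    onsets, labels = _make_schedule(cfg, rng)

    # subject-specific response function
    jit = cfg.rf_jitter
    peak = cfg.scrf.peak_time + rng.normal(0, jit.latency_shift_sd)
    peak = max(peak, 1.0)
    disp = cfg.scrf.dispersion * (1 + rng.normal(0, jit.dispersion_scale_sd))
    disp = max(disp, 0.2)
    subj_params = replace(cfg.scrf, peak_time=peak, dispersion=disp)
    rf = canonical_scrf(subj_params, sr, duration=30.0).columns[:, 0]

    n_samples = int(round((onsets[-1] + cfg.schedule.lead_out) * sr))
    by_cond = {c.name: c for c in cfg.conditions}
    rank = {c.name: 0 for c in cfg.conditions}
    amplitudes = np.empty(len(labels))
    latencies = np.empty(len(labels))
    train = np.zeros(n_samples)
    for i, (onset, name) in enumerate(zip(onsets, labels)):
        spec = by_cond[name]
        r = rank[name]
        rank[name] += 1
        if cfg.habituation_kind == "linear":
            hab = max(1.0 - cfg.habituation_slope * r, 0.0)
        else:
            hab = float(np.exp(-cfg.habituation_slope * r))
        amp = spec.mean_amplitude * hab + rng.normal(0, spec.trial_sd)
        amp = max(amp, 0.0)
        lat = onset + rng.normal(0, cfg.neural_latency_jitter_sd)
        idx = int(np.round(lat * sr))
        idx = min(max(idx, 0), n_samples - 1)
        train[idx] += amp
        amplitudes[i] = amp
        latencies[i] = lat

    values = np.convolve(train, rf)[:n_samples]

    t = np.arange(n_samples) / sr
    for amp, freq in cfg.drift.sinusoids:
        phase = rng.uniform(0, 2 * np.pi)
        values += amp * np.sin(2 * np.pi * freq * t + phase)
    if cfg.drift.random_walk_sd > 0:
        steps = rng.normal(0, cfg.drift.random_walk_sd / np.sqrt(sr), n_samples)
        values += np.cumsum(steps)
    if cfg.noise_sd > 0:
        values += rng.normal(0, cfg.noise_sd, n_samples)

    conditions = []
    for c in cfg.conditions:
        mask = [i for i, name in enumerate(labels) if name == c.name]
        conditions.append(Condition(c.name, onsets[mask]))
    events = EventModel(tuple(conditions))
    truth = SimTruth(
        subject=subject_index,
        scrf=subj_params,
        trial_condition=tuple(labels),
        trial_amplitude=amplitudes,
        trial_latency=latencies,
    )
    return SCTimeSeries(values, sr), events, truth


def simulate_cohort(cfg: SimConfig, outdir, force: bool = False) -> list[str]:
    """Simulate all subjects and write CSV triples plus a YAML manifest.

    Each subject yields ``sub-XX_ts.csv``, ``sub-XX_events.csv`` and
    ``sub-XX_truth.csv``; ``manifest.yaml`` records the full config so the
    cohort regenerates bit-identically.
    """
    import pathlib

    import pandas as pd

    out = pathlib.Path(outdir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for s in range(cfg.n_subjects):
        ts, events, truth = simulate_subject(cfg, s)
        stem = f"sub-{s:02d}"
        write_timeseries(ts, out / f"{stem}_ts.csv")
        write_events(events, out / f"{stem}_events.csv")
        pd.DataFrame(
            {
                "condition": truth.trial_condition,
                "amplitude_us": truth.trial_amplitude,
                "latency_s": truth.trial_latency,
            }
        ).to_csv(out / f"{stem}_truth.csv", index=False)
        written.append(stem)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
    return written
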