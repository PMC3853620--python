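"""End-to-end conveniences: from a (simulated or recorded) subject to
condition-wise SNA estimates, and from a cohort to a predictive-validity
statistic.  Thin glue over :mod:`preprocess`, :mod:`basis`, :mod:`glm` and
:mod:`modelcomp`."""

from __future__ import annotations

import pandas as pd

from . import glm
from .basis import BasisSet, SCRFParams, make_basis
from .core_io import EventModel, SCTimeSeries
from .modelcomp import ModelStat, predictive_validity
from .preprocess import FilterSpec, apply_filter
from .synth import SimConfig, simulate_subject

__all__ = [
    "subject_sna",
    "simulated_cohort_estimates",
    "cohort_predictive_validity",
]


def subject_sna(
    ts: SCTimeSeries,
    events: EventModel,
    basis: BasisSet | str,
    hp: FilterSpec | None,
    scrf_params: SCRFParams = SCRFParams(),
) -> tuple[dict[str, float], glm.GLMFit, BasisSet]:
    """High-pass the trace, build the matched-filter design, fit, and read
    out one SNA amplitude per condition."""
    if isinstance(basis, str):
        basis = make_basis(basis, scrf_params, ts.sampling_rate)
    data = apply_filter(ts, hp) if hp is not None else ts
    design = glm.build_design(
        events, basis, data.n_samples, data.sampling_rate, filter_spec=hp,
        start_time=data.start_time,
    )
    fitres = glm.fit(data, design)
    amps = {
        cond.name: glm.sna_amplitude(fitres, cond.name, basis)
        for cond in events.conditions
    }
    return amps, fitres, basis


def simulated_cohort_estimates(
    cfg: SimConfig,
    basis: str | BasisSet,
    hp: FilterSpec | None,
) -> pd.DataFrame:
    """Simulate every subject of a cohort and estimate condition SNA.

    Returns a tidy frame with columns ``subject``, ``condition``, ``sna``.
    The analysis always uses the cohort's *canonical* response function —
    the subject-specific perturbations are exactly the misfit the derivative
    regressors are meant to absorb.
    """
    rows = []
    for s in range(cfg.n_subjects):
        ts, events, _ = simulate_subject(cfg, s)
        amps, _, _ = subject_sna(ts, events, basis, hp, cfg.scrf)
        for cond, amp in amps.items():
            rows.append({"subject": s, "condition": cond, "sna": amp})
    return pd.DataFrame(rows)


def cohort_predictive_validity(
    estimates: pd.DataFrame,
    contrast: dict[str, float],
    label: str = "model",
) -> ModelStat:
    """Predictive-validity statistic of a cohort's estimates (see
    :func:`scrglm.modelcomp.predictive_validity`)."""
    return predictive_validity(estimates, contrast, label=label)
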