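"""Peristimulus response-function basis sets.

The canonical skin conductance response function (SCRF) is a stereotyped,
single-peaked impulse response from a sudomotor nerve burst to palmar
conductance.  It is implemented here as a gamma-type curve

    h(t) = (t / tp)^a * exp(a * (1 - t / tp)),    a = (tp / d)^2

which peaks at exactly ``tp`` seconds with unit amplitude; ``d`` controls the
width (dispersion).  Informed basis sets augment the SCRF with its temporal
derivative (sensitive to latency shifts) and a dispersion derivative
(sensitive to width changes), serially orthogonalized so the canonical column
keeps its amplitude interpretation.  Uninformed alternatives — boxcar FIR
bins and a constant-plus-sine/cosine Fourier set — estimate the response
shape nonparametrically.  A subject-specific response function (SRF) can be
estimated from pooled peristimulus epochs via PCA and a second-order
linear-ODE impulse-response fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .core_io import SCTimeSeries

__all__ = [
    "SCRFParams",
    "BasisSet",
    "SRFFit",
    "canonical_scrf",
    "scrf_with_derivatives",
    "fir_basis",
    "fourier_basis",
    "gram_schmidt_serial",
    "make_basis",
    "estimate_srf",
    "BASIS_NAMES",
]

BASIS_NAMES = (
    "scrf",
    "scrf-td",
    "scrf-tdd",
    "fir15",
    "fir30",
    "fourier4",
    "fourier8",
)


@dataclass(frozen=True)
class SCRFParams:
    """Shape parameters of the canonical response function.

    peak_time
        Latency of the (unit) peak in seconds; default 3.5 s.
    dispersion
        Width parameter in seconds; the gamma shape is (peak_time/dispersion)².
    dispersion_step
        Fractional step used for the finite-difference dispersion derivative.
    """

    peak_time: float = 3.5
    dispersion: float = 1.5
    dispersion_step: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.peak_time):
            raise ValueError("peak_time must be positive")
        if not (0 < self.dispersion):
            raise ValueError("dispersion must be positive")
        if not (0 < self.dispersion_step < 1):
            raise ValueError("dispersion_step must be a fraction in (0, 1)")

    @property
    def shape(self) -> float:
        return (self.peak_time / self.dispersion) ** 2


@dataclass(frozen=True)
class BasisSet:
    """Peristimulus basis functions sampled at the model rate.

    ``columns`` has shape (n_samples, bf); unit is shape-per-μS-of-SNA, so a
    GLM coefficient on the (unit-peak) canonical column reads directly as an
    SNA amplitude in μS.
    """

    columns: np.ndarray
    sampling_rate: float
    names: tuple[str, ...]
    orthogonalized: bool = False

    def __post_init__(self) -> None:
        cols = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if cols.shape[1] != len(self.names):
            raise ValueError("names must match column count")
        object.__setattr__(self, "columns", cols)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def bf(self) -> int:
        """Number of basis functions."""
        return self.columns.shape[1]

    @property
    def n_samples(self) -> int:
        return self.columns.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.columns, columns=list(self.names)
        ).assign(time_s=self.times).set_index("time_s")


def _scrf_curve(t: np.ndarray, params: SCRFParams) -> np.ndarray:
    a = params.shape
    tp = params.peak_time
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(t > 0, np.exp(a * (np.log(np.maximum(t, 1e-300) / tp) + 1 - t / tp)), 0.0)
    return h


def canonical_scrf(
    params: SCRFParams = SCRFParams(),
    sampling_rate: float = 10.0,
    duration: float = 30.0,
) -> BasisSet:
    """Sample the canonical SCRF; unit peak by construction, h(0) = 0."""
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    h = _scrf_curve(t, params)
    peak = h.argmax()
    if peak == 0 or h[peak] <= 0 or (n > peak + 1 and h[-1] >= h[peak]):
        raise ValueError("degenerate SCRF parameters: curve does not peak and decay")
    # unit-peak on the sampled grid (analytic peak may fall between samples)
    h = h / h[peak]
    return BasisSet(h[:, None], sampling_rate, ("scrf",))


def scrf_with_derivatives(
    params: SCRFParams = SCRFParams(),
    n_derivs: int = 1,
    sampling_rate: float = 10.0,
    duration: float = 30.0,
) -> BasisSet:
    """Canonical SCRF plus temporal (and optionally dispersion) derivative.

    Derivative columns are serially orthogonalized to their predecessors;
    the canonical column is returned unchanged.
    """
    if n_derivs not in (1, 2):
        raise ValueError("n_derivs must be 1 or 2")
    base = canonical_scrf(params, sampling_rate, duration)
    scrf = base.columns[:, 0]
    cols = [scrf]
    names = ["scrf", "scrf_time_deriv"]
    cols.append(np.gradient(scrf) * sampling_rate)
    if n_derivs == 2:
        step = params.dispersion_step * params.dispersion
        hi = canonical_scrf(replace(params, dispersion=params.dispersion + step),
                            sampling_rate, duration).columns[:, 0]
        lo = canonical_scrf(replace(params, dispersion=params.dispersion - step),
                            sampling_rate, duration).columns[:, 0]
        cols.append((hi - lo) / (2 * step))
        names.append("scrf_disp_deriv")
    ortho = gram_schmidt_serial(np.column_stack(cols))
    return BasisSet(ortho, sampling_rate, tuple(names), orthogonalized=True)


def fir_basis(
    n_bins: int = 15, bin_width: float = 1.0, sampling_rate: float = 10.0
) -> BasisSet:
    """Finite-impulse-response basis: contiguous peristimulus boxcar bins."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    samples_per_bin = int(round(bin_width * sampling_rate))
    n = n_bins * samples_per_bin
    cols = np.zeros((n, n_bins))
    for i in range(n_bins):
        cols[i * samples_per_bin:(i + 1) * samples_per_bin, i] = 1.0
    names = tuple(f"fir_{i}" for i in range(n_bins))
    # boxcars are disjoint, hence orthogonal by construction
    return BasisSet(cols, sampling_rate, names, orthogonalized=True)


def fourier_basis(
    order: int = 4, duration: float = 60.0, sampling_rate: float = 10.0
) -> BasisSet:
    """Cosine/Fourier set: constant plus sine and cosine pairs.

    The set has 2·order + 1 columns over [0, duration): a constant and, for
    m = 1..order, sin and cos at m cycles per window.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    cols = [np.ones(n)]
    names = ["const"]
    for m in range(1, order + 1):
        w = 2 * np.pi * m / duration
        cols.append(np.sin(w * t))
        cols.append(np.cos(w * t))
        names += [f"sin_{m}", f"cos_{m}"]
    return BasisSet(np.column_stack(cols), sampling_rate, tuple(names),
                    orthogonalized=True)


def gram_schmidt_serial(columns: np.ndarray) -> np.ndarray:
    """Serial Gram-Schmidt: residualize each column on its predecessors.

    The first column is returned bit-exactly; later columns are replaced by
    their residual after projection onto the span of the already-processed
    columns, without renormalization (so the first column's scale, and hence
    the interpretability of its coefficient, is preserved).  A column lying
    in the span of its predecessors becomes a zero column with a warning.
    """
    cols = np.atleast_2d(np.asarray(columns, dtype=float)).copy()
    if cols.shape[1] < 1:
        raise ValueError("need at least one column")
    scale = np.linalg.norm(cols[:, 0])
    if scale == 0:
        raise ValueError("first column is all-zero")
    for i in range(1, cols.shape[1]):
        for m in range(i):
            denom = cols[:, m] @ cols[:, m]
            if denom > 0:
                cols[:, i] -= (cols[:, m] @ cols[:, i]) / denom * cols[:, m]
        if np.linalg.norm(cols[:, i]) <= 1e-12 * scale:
            warnings.warn(
                f"column {i} lies in the span of its predecessors; kept as zero",
                stacklevel=2,
            )
            cols[:, i] = 0.0
    return cols


def make_basis(
    name: str,
    params: SCRFParams = SCRFParams(),
    sampling_rate: float = 10.0,
    duration: float = 30.0,
) -> BasisSet:
    """Construct a named basis set (``scrf``, ``scrf-td``, ``scrf-tdd``,
    ``fir15``, ``fir30``, ``fourier4``, ``fourier8``)."""
    if name == "scrf":
        return canonical_scrf(params, sampling_rate, duration)
    if name == "scrf-td":
        return scrf_with_derivatives(params, 1, sampling_rate, duration)
    if name == "scrf-tdd":
        return scrf_with_derivatives(params, 2, sampling_rate, duration)
    if name == "fir15":
        return fir_basis(15, 1.0, sampling_rate)
    if name == "fir30":
        return fir_basis(30, 1.0, sampling_rate)
    if name == "fourier4":
        return fourier_basis(4, 60.0, sampling_rate)
    if name == "fourier8":
        return fourier_basis(8, 60.0, sampling_rate)
    raise ValueError(f"unknown basis set {name!r}; choose from {BASIS_NAMES}")


@dataclass(frozen=True)
class SRFFit:
    """Subject-specific response function estimated from pooled epochs.

    ``params`` are the 3 coefficients (a1, a0, gain) of the second-order
    linear ODE  h'' + a1 h' + a0 h = gain·δ(t)  whose impulse response was
    fitted to the first principal component of the peristimulus epochs.
    """

    params: tuple[float, float, float]
    component: np.ndarray
    fitted: np.ndarray
    r2: float
    n_epochs: int

    @property
    def k(self) -> int:
        """Free parameters of the response-function fit."""
        return 3


def _ode2_impulse(t: np.ndarray, a1: float, a0: float, gain: float) -> np.ndarray:
    """Impulse response of h'' + a1 h' + a0 h = gain δ(t), evaluated stably."""
    disc = a1 * a1 / 4.0 - a0
    half = a1 / 2.0
    if disc >= 0:
        w = np.sqrt(disc)
        if w < 1e-12:
            h = t * np.exp(-half * t)
        else:
            h = np.exp(-half * t) * np.sinh(np.minimum(w * t, 700.0)) / w
    else:
        w = np.sqrt(-disc)
        h = np.exp(-half * t) * np.sin(w * t) / w
    return gain * h


def estimate_srf(
    ts: SCTimeSeries,
    all_onsets: np.ndarray,
    epoch_duration: float,
    min_epochs: int = 10,
) -> tuple[SRFFit, BasisSet]:
    """Estimate a subject-specific RF from peristimulus epochs.

    Epochs of ``epoch_duration`` seconds (conventionally the minimum stimulus
    onset asynchrony) after every onset are stacked, column-mean centered and
    decomposed by PCA; the first component over peristimulus time is sign
    flipped so its extreme value is positive, then a 3-parameter second-order
    ODE impulse response is fitted by bounded nonlinear least squares.  The
    fitted curve, normalized to unit peak, is returned as a 1-column basis.
    """
    sr = ts.sampling_rate
    n_t = int(round(epoch_duration * sr))
    onsets = np.asarray(all_onsets, dtype=float)
    rows = []
    for onset in onsets:
        i0 = int(np.round((onset - ts.start_time) * sr))
        if i0 >= 0 and i0 + n_t <= ts.n_samples:
            rows.append(ts.values[i0:i0 + n_t])
    if len(rows) < min_epochs:
        raise ValueError(
            f"only {len(rows)} complete epochs; need at least {min_epochs}"
        )
    epochs = np.asarray(rows)
    centered = epochs - epochs.mean(axis=0)
    # first right singular vector = first PC over peristimulus time
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pc = vt[0]
    if np.abs(pc.min()) > np.abs(pc.max()):
        pc = -pc
    pc = pc / np.abs(pc).max()

    t = np.arange(n_t) / sr

    def resid(theta):
        return _ode2_impulse(t, *theta) - pc

    t_peak = max(t[pc.argmax()], 1.0 / sr)
    x0 = np.array([2.0 / t_peak, 1.0 / t_peak**2, pc.max() / max(t_peak, 1e-3)])
    sol = optimize.least_squares(
        resid, x0, bounds=([1e-6, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12,
    )
    a1, a0, gain = sol.x
    if a1 <= 0 or a0 <= 0:
        raise ValueError(
            f"fitted ODE impulse response is unstable (a1={a1:.4g}, a0={a0:.4g})"
        )
    fitted = _ode2_impulse(t, a1, a0, gain)
    ss_res = float(np.sum((fitted - pc) ** 2))
    ss_tot = float(np.sum((pc - pc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    fit = SRFFit((float(a1), float(a0), float(gain)), pc, fitted, r2, len(rows))
    peak = np.abs(fitted).max()
    if peak == 0:
        raise ValueError("fitted SRF is identically zero")
    col = fitted / peak
    return fit, BasisSet(col[:, None], sr, ("srf",))
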