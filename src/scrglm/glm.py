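"""General linear convolution model for evoked skin conductance responses.

Event onsets are modelled as Dirac delta functions, convolved with a
response-function basis set, and passed through the same filter as the data,
giving one regressor per condition × basis function (plus optional
parametric-modulator regressors and a constant).  Ordinary least squares then
yields coefficients, from which a per-condition response is reconstructed and
the sympathetic nerve activity (SNA) amplitude read off as the peak of
largest modulus.

Orthogonalization happens at the regressor level: every non-primary regressor
(derivative / higher basis functions, parametric modulators) is serially
residualized against the constant, all primary regressors, and previously
processed columns.  This guarantees that adding derivative regressors leaves
the canonical-SCRF coefficients exactly unchanged — the property that makes
the canonical coefficient a valid SNA estimate in the first place.  The
unit-triangular mixing matrix of that residualization is retained, so
coefficients can be mapped back to basis coordinates for exact response
reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .basis import BasisSet
from .core_io import EventModel, SCTimeSeries
from .preprocess import FilterSpec, filter_array

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "build_design",
    "add_parametric_modulators",
    "single_trial_design",
    "fit",
    "reconstruct_response",
    "sna_amplitude",
    "delta_train",
]


@dataclass(frozen=True)
class ColumnLabel:
    kind: str        # {"cond", "pmod", "const"}
    condition: str   # condition (or trial) name; "" for const
    basis: str       # basis-function name; "" for const
    pmod: str = ""   # modulator name for kind == "pmod"


@dataclass(frozen=True)
class DesignMatrix:
    """A filtered, serially orthogonalized convolution design.

    ``X`` holds the columns actually used for fitting (constant last);
    ``to_basis`` maps fitted coefficients back to raw (basis-coordinate)
    coefficients so that per-condition responses reconstruct exactly.
    """

    X: np.ndarray
    labels: tuple[ColumnLabel, ...]
    to_basis: np.ndarray
    filter_spec: FilterSpec | None
    bf: int

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        """Free parameters: every column except the constant."""
        return self.X.shape[1] - 1

    def column_indices(self, kind: str, condition: str, pmod: str = "") -> list[int]:
        return [
            i
            for i, lab in enumerate(self.labels)
            if lab.kind == kind and lab.condition == condition and lab.pmod == pmod
        ]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab.kind == "cond" and lab.condition not in seen:
                seen.append(lab.condition)
        return seen


@dataclass(frozen=True)
class GLMFit:
    """OLS estimates for one design: coefficients, RSS, bookkeeping."""

    design: DesignMatrix
    betas: np.ndarray        # coefficients of the orthogonalized columns
    betas_basis: np.ndarray  # same fit expressed in basis coordinates
    rss: float
    n: int
    k: int
    rank: int

    @property
    def labels(self) -> tuple[ColumnLabel, ...]:
        return self.design.labels


def delta_train(
    onsets: np.ndarray,
    n_samples: int,
    sampling_rate: float,
    masses: np.ndarray | None = None,
    start_time: float = 0.0,
) -> np.ndarray:
    """Unit-mass (or weighted) Dirac delta train on the sample grid.

    Onset seconds map to sample indices by nearest-sample rounding
    (ties to even).  Onsets beyond the recording raise, listing the trials.
    """
    onsets = np.asarray(onsets, dtype=float)
    idx = np.round((onsets - start_time) * sampling_rate).astype(int)
    bad = np.flatnonzero((idx < 0) | (idx >= n_samples))
    if bad.size:
        raise ValueError(
            f"onsets outside the recording for trial indices {bad.tolist()}"
        )
    train = np.zeros(n_samples)
    if masses is None:
        masses = np.ones(onsets.size)
    np.add.at(train, idx, masses)
    return train


def _convolve_regressors(
    train: np.ndarray, basis: BasisSet, n_samples: int
) -> np.ndarray:
    out = np.empty((n_samples, basis.bf))
    for i in range(basis.bf):
        out[:, i] = np.convolve(train, basis.columns[:, i])[:n_samples]
    return out


def _assemble(
    blocks: list[tuple[ColumnLabel, np.ndarray]],
    n_samples: int,
    sampling_rate: float,
    filter_spec: FilterSpec | None,
    bf: int,
    orthogonalize: bool,
) -> DesignMatrix:
    cols = []
    labels = []
    for lab, col in blocks:
        if filter_spec is not None:
            col = filter_array(col, filter_spec, sampling_rate)
        cols.append(col)
        labels.append(lab)
    labels.append(ColumnLabel("const", "", ""))
    cols.append(np.ones(n_samples))
    X = np.column_stack(cols)
    p = X.shape[1]
    const_idx = p - 1

    # Primary columns: the first basis function of each unmodulated condition
    # block.  They and the constant are never touched; every other column is
    # serially residualized against them and previously processed columns.
    mixing = np.eye(p)
    if orthogonalize:
        # primary = first column of each condition block
        primaries = []
        seen_cond: set[str] = set()
        for i, lab in enumerate(labels[:-1]):
            if lab.kind == "cond" and lab.condition not in seen_cond:
                primaries.append(i)
                seen_cond.add(lab.condition)
        proj = [const_idx] + primaries
        for j in range(p - 1):
            if j in primaries:
                continue
            P = X[:, proj]
            # project onto the span of the processed columns (they are not
            # mutually orthogonal, so a joint least-squares projection is
            # required for the residual to be orthogonal to all of them)
            coef, _, _, _ = np.linalg.lstsq(P, X[:, j], rcond=None)
            X[:, j] = X[:, j] - P @ coef
            mixing[proj, j] = coef
            proj.append(j)

    return DesignMatrix(X, tuple(labels), mixing, filter_spec, bf)


def build_design(
    events: EventModel,
    basis: BasisSet,
    n_samples: int,
    sampling_rate: float,
    filter_spec: FilterSpec | None = None,
    with_pmods: bool = False,
    orthogonalize: bool = True,
    start_time: float = 0.0,
) -> DesignMatrix:
    """Convolve condition delta trains with the basis set into a design.

    Per condition, a unit-mass delta train is convolved with each basis
    column and truncated to ``n_samples``; every regressor is then passed
    through ``filter_spec`` (the identical filter as the data) and the
    result serially orthogonalized (see module docstring).  A constant
    column is always appended but excluded from the parameter count ``k``.
    """
    if not np.isclose(basis.sampling_rate, sampling_rate):
        raise ValueError(
            f"basis sampled at {basis.sampling_rate} Hz but data at {sampling_rate} Hz"
        )
    blocks: list[tuple[ColumnLabel, np.ndarray]] = []
    for cond in events.conditions:
        train = delta_train(cond.onsets, n_samples, sampling_rate, start_time=start_time)
        reg = _convolve_regressors(train, basis, n_samples)
        for i in range(basis.bf):
            blocks.append(
                (ColumnLabel("cond", cond.name, basis.names[i]), reg[:, i])
            )
    if with_pmods:
        for cond in events.conditions:
            for pname, vals in cond.pmods.items():
                centered = vals - vals.mean()
                if np.allclose(centered, 0):
                    raise ValueError(
                        f"pmod {pname!r} of condition {cond.name!r} is constant "
                        "(zero variance after centering)"
                    )
                train = delta_train(
                    cond.onsets, n_samples, sampling_rate,
                    masses=centered, start_time=start_time,
                )
                reg = _convolve_regressors(train, basis, n_samples)
                for i in range(basis.bf):
                    blocks.append(
                        (ColumnLabel("pmod", cond.name, basis.names[i], pname),
                         reg[:, i])
                    )
    return _assemble(blocks, n_samples, sampling_rate, filter_spec, basis.bf,
                     orthogonalize)


def add_parametric_modulators(
    events: EventModel,
    basis: BasisSet,
    n_samples: int,
    sampling_rate: float,
    filter_spec: FilterSpec | None = None,
    orthogonalize: bool = True,
    start_time: float = 0.0,
) -> DesignMatrix:
    """Design with parametric-modulator regressors appended.

    Each modulator is mean-centered within its condition, multiplied onto the
    delta masses, convolved, filtered, and appended after the unmodulated
    regressors.  A per-trial index modulator encodes linear habituation.
    """
    return build_design(
        events, basis, n_samples, sampling_rate, filter_spec,
        with_pmods=True, orthogonalize=orthogonalize, start_time=start_time,
    )


def single_trial_design(
    events: EventModel,
    basis: BasisSet,
    n_samples: int,
    sampling_rate: float,
    filter_spec: FilterSpec | None = None,
    orthogonalize: bool = True,
    start_time: float = 0.0,
) -> DesignMatrix:
    """One regressor set per trial (k = bf × N), for trial-wise SNA estimates.

    Trials are labelled ``{condition}#{trial_index}`` with the index counting
    within condition; amplitudes are read out with :func:`sna_amplitude` on
    these labels.
    """
    from .core_io import Condition

    singles = []
    for cond in events.conditions:
        for i, onset in enumerate(cond.onsets):
            singles.append(Condition(f"{cond.name}#{i}", np.array([onset])))
    trial_events = EventModel(tuple(singles))
    return build_design(
        trial_events, basis, n_samples, sampling_rate, filter_spec,
        orthogonalize=orthogonalize, start_time=start_time,
    )


def fit(ts: SCTimeSeries, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares via pseudoinverse (rank-deficiency tolerant)."""
    X = design.X
    if X.shape[1] == 0:
        raise ValueError("design has no columns")
    if X.shape[0] != ts.n_samples:
        raise ValueError(
            f"design has {X.shape[0]} rows but data has {ts.n_samples} samples"
        )
    y = ts.values
    betas, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            "minimum-norm solution returned",
            stacklevel=2,
        )
    resid = y - X @ betas
    rss = float(resid @ resid)
    betas_basis = np.linalg.solve(design.to_basis, betas)
    return GLMFit(design, betas, betas_basis, rss, ts.n_samples, design.k, int(rank))


def reconstruct_response(
    fitres: GLMFit, condition: str, basis: BasisSet, pmod: str = ""
) -> np.ndarray:
    """Peristimulus response for one condition: Σ_i β_i · basis column i.

    Uses the basis-coordinate coefficients of the unmodulated regressors
    (or, with ``pmod`` given, of that modulator's regressors).
    """
    kind = "pmod" if pmod else "cond"
    idx = fitres.design.column_indices(kind, condition, pmod)
    if not idx:
        raise KeyError(
            f"no {kind} regressors for condition {condition!r}"
            + (f" pmod {pmod!r}" if pmod else "")
        )
    if len(idx) != basis.bf:
        raise ValueError(
            f"basis has {basis.bf} columns but condition {condition!r} "
            f"has {len(idx)} regressors"
        )
    return basis.columns @ fitres.betas_basis[idx]


def sna_amplitude(
    fitres: GLMFit, condition: str, basis: BasisSet, pmod: str = ""
) -> float:
    """SNA amplitude: value at the peak of largest modulus of the
    reconstructed response (sign retained).

    For a single-column unit-peak SCRF basis this equals the coefficient.
    """
    wave = reconstruct_response(fitres, condition, basis, pmod)
    return float(wave[np.argmax(np.abs(wave))])
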