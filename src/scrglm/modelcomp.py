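"""Model comparison: log likelihood, AIC, log Bayes factors, predictive
validity and trial-wise explained variance.

Two complementary yardsticks are used.  *Within-subject fit*: the residual
sum of squares of a fitted time series converts to a negative log likelihood

    LL = n · log(RSS / n)

(natural log), penalized for complexity by AIC = LL + 2k.  *Predictive
validity*: how well estimated sympathetic amplitudes predict the known
stimulus class, assessed by a second-level GLM with the contrast code as
response, the estimates as predictor and subject effects in the design;
its RSS converts to LL by the same relation.  Model differences are reported
as log Bayes factors (LBF); negative LBF favours the model over the
reference, and |LBF| > 3 is conventionally decisive.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
import pandas as pd

__all__ = [
    "ModelStat",
    "ComparisonTable",
    "neg_log_likelihood",
    "aic",
    "log_bayes_factor",
    "compare_models",
    "predictive_validity",
    "explained_variance",
    "DECISIVE_LBF",
]

DECISIVE_LBF = 3.0


def neg_log_likelihood(rss: float, n: int) -> float:
    """Negative log likelihood of a Gaussian fit: n·log(RSS/n), natural log."""
    if not rss > 0:
        raise ValueError(
            "RSS must be positive (a perfect fit has undefined likelihood here)"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * log(rss / n)


def aic(ll: float, k: int) -> float:
    """Akaike information criterion: LL + 2k."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    return ll + 2 * k


@dataclass(frozen=True)
class ModelStat:
    """One model's evidence summary on a fixed dataset."""

    label: str
    rss: float
    n: int
    k: int = 0

    @property
    def ll(self) -> float:
        return neg_log_likelihood(self.rss, self.n)

    @property
    def aic(self) -> float:
        return aic(self.ll, self.k)


def log_bayes_factor(
    model: ModelStat, reference: ModelStat, penalize: bool = False
) -> tuple[float, bool]:
    """LBF of ``model`` against ``reference`` (model − reference).

    Both must be computed on identical response data (checked via n).
    With ``penalize=True`` the difference is taken on AIC instead of LL.
    Returns ``(lbf, decisive)``; decisiveness is strict (|LBF| > 3).
    """
    if model.n != reference.n:
        raise ValueError(
            f"models fitted to different data (n={model.n} vs n={reference.n})"
        )
    if penalize:
        lbf = model.aic - reference.aic
    else:
        lbf = model.ll - reference.ll
    return lbf, abs(lbf) > DECISIVE_LBF


def compare_models(
    models: list[ModelStat], reference: str, penalize: bool = False
) -> pd.DataFrame:
    """ComparisonTable: LL, k, AIC and LBF-vs-reference for each model."""
    ref = next((m for m in models if m.label == reference), None)
    if ref is None:
        raise KeyError(f"reference model {reference!r} not in the list")
    rows = []
    for m in models:
        lbf, decisive = log_bayes_factor(m, ref, penalize=penalize)
        rows.append(
            {"model": m.label, "LL": m.ll, "k": m.k, "AIC": m.aic,
             "n": m.n, "LBF": lbf, "decisive": decisive}
        )
    return pd.DataFrame(rows)


ComparisonTable = pd.DataFrame  # alias: the table is a plain DataFrame


def predictive_validity(
    estimates: pd.DataFrame,
    contrast: dict[str, float],
    label: str = "model",
) -> ModelStat:
    """Second-level GLM: can the estimates predict the stimulus class?

    ``estimates`` needs columns ``subject``, ``condition``, ``sna``;
    ``contrast`` maps condition names to codes (e.g. {"neutral": -1,
    "negative": 1}).  Observations are the (subject, condition) pairs of the
    contrast's conditions; the contrast code is regressed on the SNA estimate
    plus subject indicator columns, and the RSS converted to LL.
    """
    conds = list(contrast)
    if len(conds) < 2:
        raise ValueError("contrast needs at least 2 conditions")
    sub = estimates[estimates["condition"].isin(conds)].copy()
    subjects = sub["subject"].unique()
    if subjects.size < 2:
        raise ValueError("need at least 2 subjects")
    y = sub["condition"].map(contrast).to_numpy(dtype=float)
    x = sub["sna"].to_numpy(dtype=float)
    dummies = (sub["subject"].to_numpy()[:, None] == subjects[None, :]).astype(float)
    within = x - dummies @ (np.linalg.lstsq(dummies, x, rcond=None)[0])
    if np.allclose(within, 0):
        import warnings

        warnings.warn(
            "estimates are constant within every subject; predictor is "
            "collinear with subject effects",
            stacklevel=2,
        )
    X = np.column_stack([x, dummies])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    return ModelStat(label, rss, n=y.size, k=1)


def explained_variance(
    trial_estimates: pd.DataFrame,
    predictor_cols: list[str],
    estimate_col: str = "sna",
    subject_col: str = "subject",
) -> tuple[pd.Series, float]:
    """Per-subject R² of trial-wise estimates on per-trial predictors.

    For each subject, OLS of the trial estimates on the predictors plus an
    intercept gives R²; the group summary converts each subject's relative
    residual variance RSS/TSS into a log likelihood n·log(RSS/TSS) and sums
    across subjects.  Returns ``(r2_per_subject, summed_ll)``.
    """
    r2s = {}
    ll_sum = 0.0
    for subject, grp in trial_estimates.groupby(subject_col, sort=False):
        y = grp[estimate_col].to_numpy(dtype=float)
        P = grp[predictor_cols].to_numpy(dtype=float)
        if y.size < P.shape[1] + 2:
            raise ValueError(
                f"subject {subject!r}: {y.size} trials for {P.shape[1]} predictors"
            )
        X = np.column_stack([np.ones(y.size), P])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss <= 0:
            raise ValueError(f"subject {subject!r}: estimates have zero variance")
        r2s[subject] = 1.0 - rss / tss
        if rss > 0:
            ll_sum += y.size * log(rss / tss)
        else:
            ll_sum += -np.inf
    return pd.Series(r2s, name="r2"), ll_sum
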