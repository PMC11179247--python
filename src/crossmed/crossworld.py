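r"""Cross-world mediation weights and sampling-weight strategies.

To estimate the mean counterfactual outcome E[Y(a, M_{a'})] from the
A = a arm alone, each unit receives a cross-world weight

    w_{aa'} = p(A = a' | M, C) / p(A = a | M, C)  *  1 / p(A = a' | C)
              \_________ odds weight _________/     \_____ IPW _____/

which collapses to the familiar 1 / p(A = a | C) when a = a'.  The two
conditional exposure probabilities come from two separate logistic
fits — ``A ~ C`` and ``A ~ M + C`` — whose products form the final
weight.  When the sample was drawn with unequal probabilities, sampling
weights can enter at two places: as observation weights in the logistic
fits (first stage) and/or as a factor multiplying the cross-world
weights in the outcome analysis (second stage).  The four combinations
are the four :class:`WeightStrategy` members.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .popgen import COVARIATES

__all__ = [
    "WeightStrategy",
    "PropensityFit",
    "CrossWorldWeights",
    "FitError",
    "fit_weighted_logistic",
    "fit_propensity_models",
    "cross_world_weight",
    "build_weights",
]

#: Lower floor applied to fitted probabilities before inversion.
PROB_FLOOR = 1e-6


class FitError(RuntimeError):
    """A propensity model failed to converge (e.g. separation)."""


class WeightStrategy(enum.Enum):
    """Where the sampling weights enter the two-stage estimation."""

    NEITHER = (False, False)
    FIRST_ONLY = (True, False)
    SECOND_ONLY = (False, True)
    BOTH = (True, True)

    @property
    def use_sw_in_fits(self) -> bool:
        return self.value[0]

    @property
    def use_sw_in_outcome(self) -> bool:
        return self.value[1]


@dataclass(frozen=True)
class PropensityFit:
    """A converged weighted-logistic fit and its per-unit probabilities."""

    coef: np.ndarray
    fitted: np.ndarray
    converged: bool
    n_iter: int
    max_coef_change: float

    def __post_init__(self) -> None:
        if np.any(self.fitted <= 0.0) or np.any(self.fitted >= 1.0):
            raise FitError("fitted probabilities must lie strictly in (0, 1)")


def fit_weighted_logistic(
    y: np.ndarray,
    design_matrix: np.ndarray,
    obs_weights: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> PropensityFit:
    """Maximize the weighted Bernoulli log-likelihood by IRLS.

    Convergence: max absolute coefficient change < ``tol`` within
    ``max_iter`` Newton steps.  Separation or non-convergence raises
    :class:`FitError` so callers can drop (and log) the replicate.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design_matrix, dtype=float)
    n, p = X.shape
    if obs_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(obs_weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("observation weights must be positive")

    beta = np.zeros(p)
    change = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        v = np.maximum(mu * (1.0 - mu), 1e-12)
        ww = w * v
        # Newton step: solve (X' W V X) delta = X' W (y - mu)
        XtWX = X.T @ (X * ww[:, None])
        score = X.T @ (w * (y - mu))
        try:
            delta = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix at iteration {it}") from exc
        beta = beta + delta
        change = float(np.max(np.abs(delta)))
        if not np.isfinite(change):
            raise FitError(f"diverging coefficients at iteration {it} (separation?)")
        if change < tol:
            break
    else:
        raise FitError(
            f"IRLS did not converge in {max_iter} iterations (last change {change:.3g})"
        )
    fitted = expit(X @ beta)
    eps = np.finfo(float).tiny
    fitted = np.clip(fitted, eps, 1.0 - 1e-16)
    return PropensityFit(coef=beta, fitted=fitted, converged=True,
                         n_iter=it, max_coef_change=change)


def _design(sample: pd.DataFrame, with_mediator: bool) -> np.ndarray:
    cols = [sample[c].to_numpy(dtype=float) for c in COVARIATES]
    if with_mediator:
        cols = [sample["M"].to_numpy(dtype=float)] + cols
    return np.column_stack([np.ones(len(sample))] + cols)


def fit_propensity_models(
    sample: pd.DataFrame, use_sampling_weights: bool
) -> tuple[PropensityFit, PropensityFit]:
    """Fit the two exposure models ``A ~ C`` and ``A ~ M + C``.

    Observation weights are the sampling weights when
    ``use_sampling_weights`` is true, else uniform.
    """
    y = sample["A"].to_numpy(dtype=float)
    w = sample["s_weight"].to_numpy(dtype=float) if use_sampling_weights else None
    fit_ax = fit_weighted_logistic(y, _design(sample, with_mediator=False), w)
    fit_amx = fit_weighted_logistic(y, _design(sample, with_mediator=True), w)
    return fit_ax, fit_amx


def cross_world_weight(
    fit_ax: PropensityFit,
    fit_amx: PropensityFit,
    A: np.ndarray,
    a: int,
    a_prime: int,
    floor: float = PROB_FLOOR,
) -> tuple[np.ndarray, int]:
    """Per-unit cross-world weight w_{a a'}, defined on the A = a arm.

    For a = a' the odds weight is identically 1 and the weight is the
    plain inverse probability 1 / p(A = a | C).  Probabilities below
    ``floor`` are truncated before inversion; the truncation count is
    returned alongside the weights.  Entries for units with A != a are
    NaN (the weight has no meaning off-arm).
    """
    A = np.asarray(A)
    p_a_prime_x = fit_ax.fitted if a_prime == 1 else 1.0 - fit_ax.fitted
    n_trunc = int(np.sum(p_a_prime_x < floor))
    ipw = 1.0 / np.maximum(p_a_prime_x, floor)
    if a == a_prime:
        w = ipw
    else:
        p_ap_mx = fit_amx.fitted if a_prime == 1 else 1.0 - fit_amx.fitted
        p_a_mx = fit_amx.fitted if a == 1 else 1.0 - fit_amx.fitted
        n_trunc += int(np.sum(p_a_mx < floor))
        odds = p_ap_mx / np.maximum(p_a_mx, floor)
        w = odds * ipw
    return np.where(A == a, w, np.nan), n_trunc


@dataclass
class CrossWorldWeights:
    """All four cross-world weights for one sample under one strategy.

    ``raw`` holds w11, w00, w10, w01 (NaN off-arm); ``final`` is the
    weight actually used in the outcome stage — ``raw * s_weight`` when
    the strategy puts sampling weights in the outcome model, else
    ``raw`` itself.
    """

    strategy: WeightStrategy
    raw: pd.DataFrame
    final: pd.DataFrame
    fit_ax: PropensityFit
    fit_amx: PropensityFit
    n_truncated: int = 0

    def to_frame(self, sample: pd.DataFrame) -> pd.DataFrame:
        out = sample[["A"]].copy()
        for c in self.raw.columns:
            out[c] = self.raw[c]
        for c in self.final.columns:
            out[f"composite_{c}"] = self.final[c]
        out["n_truncated"] = self.n_truncated
        return out


def build_weights(
    sample: pd.DataFrame,
    strategy: WeightStrategy,
    fits: tuple[PropensityFit, PropensityFit] | None = None,
    floor: float = PROB_FLOOR,
) -> CrossWorldWeights:
    """Construct cross-world weights for a sample under one strategy.

    ``fits`` may supply precomputed propensity fits (they must have been
    fit with observation weights matching ``strategy.use_sw_in_fits``);
    the simulation harness uses this to share fits between strategies
    that differ only in the outcome stage.
    """
    if fits is None:
        fits = fit_propensity_models(sample, strategy.use_sw_in_fits)
    fit_ax, fit_amx = fits
    A = sample["A"].to_numpy()
    raw = {}
    n_trunc = 0
    for a, ap in ((1, 1), (0, 0), (1, 0), (0, 1)):
        w, t = cross_world_weight(fit_ax, fit_amx, A, a, ap, floor=floor)
        raw[f"w{a}{ap}"] = w
        n_trunc += t
    raw = pd.DataFrame(raw, index=sample.index)
    if strategy.use_sw_in_outcome:
        final = raw.mul(sample["s_weight"], axis=0)
    else:
        final = raw.copy()
    return CrossWorldWeights(strategy=strategy, raw=raw, final=final,
                             fit_ax=fit_ax, fit_amx=fit_amx, n_truncated=n_trunc)
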