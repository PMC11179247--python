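"""Fixed-size unequal-probability sampling from a generated population.

Four sampling methods are supported, mirroring common survey situations:
selection driven by design covariates only (``S ~ U``), by covariates
plus the mediator (``S ~ U + M``), by covariates plus the exposure
(``S ~ U + A``), and simple random sampling (``S ~ 1``).  Selection
propensities are logistic in the design variables; inclusion
probabilities are obtained by scaling propensities to sum to the target
sample size (capping at 1 where needed), and an exact-size sample is
drawn by systematic probability-proportional-to-size sampling on a
randomly permuted frame.  Sampling weights are the inverse inclusion
probabilities; all downstream estimators are of Hajek (ratio) form, so
weights matter only up to scale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SamplingMethod",
    "SamplingDesign",
    "DesignError",
    "selection_propensity",
    "inclusion_probabilities",
    "draw_sample",
    "normalize_weights",
]


class DesignError(ValueError):
    """The sampling design is inconsistent or produces extreme probabilities."""


class SamplingMethod(enum.Enum):
    COV = "cov"          # S ~ U
    COV_MED = "cov_med"  # S ~ U + M
    COV_TRT = "cov_trt"  # S ~ U + A
    SRS = "srs"          # S ~ 1

    @property
    def extra_column(self) -> str | None:
        return {"cov_med": "M", "cov_trt": "A"}.get(self.value)


# Default selection-logit coefficients: informative sampling with
# realized sampling weights spanning roughly a 15x range around the 0.1
# sampling fraction — strong enough for one-stage weighting strategies
# to show their bias against the Monte-Carlo noise floor, without the
# extreme weight tails of the largest national surveys.
DEFAULT_GAMMA_U = {"intercept": -2.4, "U1": 1.0, "U2": -0.8, "U3": 1.0}
DEFAULT_GAMMA_EXTRA = 1.2


@dataclass(frozen=True)
class SamplingDesign:
    """One of the four sampling methods plus its selection-logit coefficients."""

    method: SamplingMethod
    target_n: int
    gamma: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.target_n < 1:
            raise DesignError("target_n must be positive")
        method = self.method
        if method is SamplingMethod.SRS:
            extra = set(self.gamma) - {"intercept"}
            if extra:
                raise DesignError(f"SRS design takes no selection coefficients: {sorted(extra)}")
            return
        allowed = {"intercept", "U1", "U2", "U3"}
        if method.extra_column:
            allowed.add(method.extra_column)
        unknown = set(self.gamma) - allowed
        if unknown:
            raise DesignError(
                f"{method.name} design got coefficients {sorted(unknown)}; allowed {sorted(allowed)}"
            )

    @classmethod
    def default(cls, method: SamplingMethod, target_n: int) -> "SamplingDesign":
        if method is SamplingMethod.SRS:
            return cls(method, target_n)
        gamma = dict(DEFAULT_GAMMA_U)
        if method.extra_column:
            gamma[method.extra_column] = DEFAULT_GAMMA_EXTRA
        return cls(method, target_n, gamma)


def selection_propensity(data: pd.DataFrame, design: SamplingDesign) -> np.ndarray:
    """Per-unit selection propensity (up to the target-size normalization).

    Logistic in (U1, U2, U3) plus M or A where the method requires; a
    constant ``target_n / N`` for simple random sampling.
    """
    n_rows = len(data)
    if design.method is SamplingMethod.SRS:
        return np.full(n_rows, design.target_n / n_rows)
    eta = np.full(n_rows, design.gamma.get("intercept", 0.0))
    cols = ["U1", "U2", "U3"]
    if design.method.extra_column:
        cols.append(design.method.extra_column)
    for col in cols:
        coef = design.gamma.get(col, 0.0)
        if coef:
            if col not in data.columns:
                raise DesignError(
                    f"method {design.method.name} needs column {col!r}, absent from data"
                )
            eta = eta + coef * data[col].to_numpy(dtype=float)
    p = expit(eta)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise DesignError("selection propensities must lie strictly in (0, 1)")
    return p


def inclusion_probabilities(propensity: np.ndarray, target_n: int, max_iter: int = 100) -> np.ndarray:
    """Scale propensities to inclusion probabilities summing to ``target_n``.

    pi_i = target_n * p_i / sum(p); any pi > 1 is capped at 1 and the
    remainder re-scaled over the uncapped units, iterating to
    convergence (at most ``max_iter`` rounds).
    """
    p = np.asarray(propensity, dtype=float)
    if target_n > len(p):
        raise DesignError("target_n exceeds population size")
    pi = np.minimum(target_n * p / p.sum(), 1.0)
    for _ in range(max_iter):
        capped = pi >= 1.0
        deficit = target_n - capped.sum()
        if deficit < 0:
            raise DesignError("propensities too extreme: more capped units than target_n")
        free = ~capped
        scale_target = deficit
        current = pi[free].sum()
        if np.isclose(current, scale_target, rtol=0, atol=1e-10):
            break
        pi[free] = np.minimum(pi[free] * scale_target / current, 1.0)
    else:
        raise DesignError("inclusion-probability capping failed to converge")
    return pi


def draw_sample(pop: pd.DataFrame, design: SamplingDesign, rng_seed=None) -> pd.DataFrame:
    """Draw exactly ``design.target_n`` units without replacement.

    Systematic PPS on a randomly permuted frame: with inclusion
    probabilities summing to n, the cumulative-total grid ``u, u+1, ...,
    u+n-1`` (u uniform) selects each unit with probability pi_i exactly.
    Returns the sampled rows with ``pi`` and ``s_weight = 1/pi`` columns.
    """
    n = design.target_n
    if n > len(pop):
        raise DesignError("target_n exceeds population size")
    rng = np.random.default_rng(rng_seed)
    p = selection_propensity(pop, design)
    pi = inclusion_probabilities(p, n)

    perm = rng.permutation(len(pop))
    cum = np.cumsum(pi[perm])
    # guard rounding so the last grid point stays inside the cumulative range
    cum[-1] = n
    points = rng.random() + np.arange(n)
    chosen = np.searchsorted(cum, points, side="left")
    idx = perm[chosen]
    if len(np.unique(idx)) != n:  # pragma: no cover - pi <= 1 precludes this
        raise DesignError("systematic PPS selected a unit twice")

    sample = pop.iloc[idx].copy()
    sample["pi"] = pi[idx]
    sample["s_weight"] = 1.0 / pi[idx]
    return sample.reset_index(drop=True)


def normalize_weights(s_weight) -> np.ndarray:
    """Rescale weights to mean 1 (a no-op for every Hajek-type estimator)."""
    w = np.asarray(s_weight, dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    return w / w.mean()
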