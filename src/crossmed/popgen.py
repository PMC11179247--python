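"""Population generation for the mediation simulation study.

A population of ``N`` individuals is split into three equal strata that
differ only in the distribution of six binary covariates
``C = (U1, U2, U3, X1, X2, X3)``.  The ``U`` covariates may later drive
sample selection; the ``X`` covariates never do.  On top of the
covariates the generator draws a binary exposure ``A``, a binary
mediator ``M`` and a binary outcome ``Y`` such that *both* the marginal
exposure model ``A | C`` and the mediator-conditional exposure model
``A | M, C`` are exactly logistic:

    P(A = 1 | C)        = expit(a),        a = 0.68 + alpha' [1, C]
    P(A = 1 | M = 0, C) = expit(b),        b = 0.80 + beta'  [1, C]
    P(A = 1 | M = 1, C) = expit(b + d),    d = -1.52 + delta * X2

The mediator law ``P(M = 1 | A, C)`` is then *derived* from these three
logits (it is the unique law compatible with them), and the outcome is
logistic in ``A``, ``M``, ``C`` plus at most one scenario-specific
interaction.  Because every variable is binary, true natural
direct/indirect effects are available in closed form by enumerating the
3 x 64 stratum-covariate cells (:func:`true_effects_exact`) as well as
by Monte-Carlo pseudo-populations carrying all four potential outcomes
(:func:`true_effects_mc`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "COVARIATES",
    "StratumSpec",
    "ScenarioSpec",
    "TrueEffects",
    "ConfigurationError",
    "GenerativeValidityError",
    "default_strata",
    "generate_covariates",
    "linear_predictors",
    "prob_A",
    "prob_A_given_M",
    "prob_M_given_A",
    "outcome_probability",
    "generate_population",
    "true_effects_mc",
    "true_effects_exact",
    "write_population_csv",
    "read_population_csv",
]

COVARIATES = ("U1", "U2", "U3", "X1", "X2", "X3")

#: Potential-outcome columns; ``Y11`` is Y(1, M1), ``Y10`` is Y(1, M0), etc.
PO_COLUMNS = ("Y11", "Y00", "Y10", "Y01")

A_INTERCEPT = 0.68
B_INTERCEPT = 0.80
D_INTERCEPT = -1.52
DELTA_INTERACTION = -0.5

#: Interaction term (if any) in each scenario's outcome model.
SCENARIO_Y_INTERACTION = {
    1: None, 2: "A:M", 3: "A:X2", 4: "M:X2",
    5: None, 6: "A:M", 7: "A:X2", 8: "M:X2",
}
#: Scenarios whose A | M, C model carries the M x X2 interaction (delta != 0).
SCENARIOS_WITH_M_X2_IN_D = frozenset({5, 6, 7, 8})

# Default generative coefficients.  Magnitudes 0.2-0.45 with alternating
# signs; the gap alpha - beta is uniformly negative so that b + d < a < b
# holds on every covariate cell (margin >= 0.12 on the logit scale), which
# keeps the derived mediator law strictly inside (0, 1).
DEFAULT_ALPHA = (0.0, 0.25, -0.20, 0.20, -0.25, 0.30, -0.20)
DEFAULT_BETA = (0.0, 0.40, -0.10, 0.30, -0.10, 0.45, -0.05)
DEFAULT_Y_MODEL = {
    "intercept": -1.2,
    "A": 0.5,
    "M": 0.5,
    "U1": 0.5, "U2": -0.35, "U3": 0.45,
    "X1": -0.35, "X2": 0.4, "X3": -0.3,
}
DEFAULT_Y_INTERACTION_COEF = 0.4

# Stratum-specific latent covariate parameters (logit scale by default).
DEFAULT_STRATUM_PARAMS = {
    1: (0.3, -0.4, -0.2, 0.25, 0.2, -0.3),
    2: (0.5, 0.0, 0.1, 0.6, 0.4, -0.1),
    3: (0.7, 0.4, 0.2, 0.75, 0.8, 0.3),
}

_LINKS = {
    "logistic": expit,
    "probit": norm.cdf,
}


class ConfigurationError(ValueError):
    """A scenario/stratum/design specification violates its contract."""


class GenerativeValidityError(ValueError):
    """The (a, b, d) logits imply an impossible mediator law somewhere."""


def _seed_seq(rng_seed) -> np.random.SeedSequence:
    if isinstance(rng_seed, np.random.SeedSequence):
        return rng_seed
    return np.random.SeedSequence(rng_seed)


def _link_fn(link: str):
    try:
        return _LINKS[link]
    except KeyError:
        raise ConfigurationError(
            f"unknown link {link!r}; choose from {sorted(_LINKS)}"
        ) from None


@dataclass(frozen=True)
class StratumSpec:
    """Covariate distribution of one population stratum.

    ``latent_params`` are on a latent (default: logit) scale; the printed
    per-stratum values include negatives, so they cannot be probabilities
    themselves.  They are mapped to Bernoulli probabilities by ``link``.
    """

    stratum_id: int
    latent_params: tuple[float, ...]
    link: str = "logistic"

    def __post_init__(self) -> None:
        if self.stratum_id not in (1, 2, 3):
            raise ConfigurationError("stratum_id must be 1, 2 or 3")
        if len(self.latent_params) != len(COVARIATES):
            raise ConfigurationError(
                f"need {len(COVARIATES)} latent params, got {len(self.latent_params)}"
            )
        if not np.all(np.isfinite(self.latent_params)):
            raise ConfigurationError("latent params must be finite")
        p = self.probabilities()
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ConfigurationError(
                f"stratum {self.stratum_id}: covariate probabilities must lie "
                f"strictly in (0, 1); got {p}"
            )

    def probabilities(self) -> np.ndarray:
        """Bernoulli probabilities for (U1, U2, U3, X1, X2, X3)."""
        return _link_fn(self.link)(np.asarray(self.latent_params, dtype=float))


def default_strata(link: str = "logistic") -> tuple[StratumSpec, StratumSpec, StratumSpec]:
    """The three study strata, each 1/3 of the population."""
    return tuple(
        StratumSpec(k, DEFAULT_STRATUM_PARAMS[k], link=link) for k in (1, 2, 3)
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """All generative parameters for one of the eight population scenarios.

    ``alpha``/``beta`` are 7-vectors (constant + six covariate
    coefficients) entering ``a``/``b`` on top of the fixed intercepts
    0.68 / 0.80; ``delta`` is the M x X2 coefficient in ``d``; ``y_model``
    maps term names (``intercept``, ``A``, ``M``, the six covariates and
    at most one of ``A:M``, ``A:X2``, ``M:X2``) to logit coefficients.
    Construction enumerates all covariate cells and fails fast if any
    implies a mediator probability outside [0, 1].
    """

    scenario_id: int
    alpha: tuple[float, ...]
    beta: tuple[float, ...]
    delta: float
    y_model: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario_id not in range(1, 9):
            raise ConfigurationError("scenario_id must be in 1..8")
        for name, vec in (("alpha", self.alpha), ("beta", self.beta)):
            if len(vec) != 7:
                raise ConfigurationError(f"{name} must have length 7")
            if not np.all(np.isfinite(vec)):
                raise ConfigurationError(f"{name} must be finite")
        allowed = {"intercept", "A", "M", *COVARIATES, "A:M", "A:X2", "M:X2"}
        unknown = set(self.y_model) - allowed
        if unknown:
            raise ConfigurationError(f"unknown y_model terms: {sorted(unknown)}")
        inters = [t for t in ("A:M", "A:X2", "M:X2") if self.y_model.get(t, 0.0) != 0.0]
        expected = SCENARIO_Y_INTERACTION[self.scenario_id]
        if expected is None and inters:
            raise ConfigurationError(
                f"scenario {self.scenario_id} has no Y interaction, got {inters}"
            )
        if expected is not None and inters != [expected]:
            raise ConfigurationError(
                f"scenario {self.scenario_id} requires Y interaction {expected}, got {inters}"
            )
        if self.delta != 0.0 and self.scenario_id not in SCENARIOS_WITH_M_X2_IN_D:
            raise ConfigurationError(
                f"delta != 0 only allowed for scenarios {sorted(SCENARIOS_WITH_M_X2_IN_D)}"
            )
        if self.delta == 0.0 and self.scenario_id in SCENARIOS_WITH_M_X2_IN_D:
            raise ConfigurationError(
                f"scenario {self.scenario_id} requires a nonzero delta (A x X2 in the M model)"
            )
        self.validate_feasibility()

    @classmethod
    def default(cls, scenario_id: int) -> "ScenarioSpec":
        """Scenario with the package's documented default coefficients."""
        y_model = dict(DEFAULT_Y_MODEL)
        inter = SCENARIO_Y_INTERACTION[scenario_id]
        if inter is not None:
            y_model[inter] = DEFAULT_Y_INTERACTION_COEF
        delta = DELTA_INTERACTION if scenario_id in SCENARIOS_WITH_M_X2_IN_D else 0.0
        return cls(scenario_id, DEFAULT_ALPHA, DEFAULT_BETA, delta, y_model)

    def validate_feasibility(self) -> None:
        """Check every covariate pattern yields a valid mediator law."""
        cells = _all_covariate_patterns()
        a, b, d = linear_predictors(cells, self)
        for a_level in (0, 1):
            prob_M_given_A(a, b, d, a_level)  # raises on violation


def _all_covariate_patterns() -> pd.DataFrame:
    rows = list(itertools.product((0, 1), repeat=len(COVARIATES)))
    return pd.DataFrame(rows, columns=list(COVARIATES), dtype=np.int64)


def generate_covariates(
    n: int,
    strata: tuple[StratumSpec, ...] = None,
    rng_seed=None,
) -> pd.DataFrame:
    """Draw the stratified covariate table (columns: stratum, U1..X3).

    Each stratum receives ``n // 3`` units, with the remainder (at most
    two units) spread over the first strata.  Covariates are independent
    Bernoulli draws within stratum; per-stratum RNG substreams make the
    result reproducible even if strata are generated in parallel.
    """
    if strata is None:
        strata = default_strata()
    if len(strata) != 3:
        raise ConfigurationError("exactly three strata are required")
    if n < 3:
        raise ConfigurationError("population size must be at least 3")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    streams = _seed_seq(rng_seed).spawn(3)
    frames = []
    for spec, size, ss in zip(strata, sizes, streams):
        rng = np.random.default_rng(ss)
        draws = rng.random((size, len(COVARIATES))) < spec.probabilities()
        df = pd.DataFrame(draws.astype(np.int64), columns=list(COVARIATES))
        df.insert(0, "stratum", spec.stratum_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def linear_predictors(C: pd.DataFrame, spec: ScenarioSpec):
    """Return the (a, b, d) logits for each covariate row.

    a = 0.68 + alpha'[1, C];  b = 0.80 + beta'[1, C];  d = -1.52 + delta * X2.
    """
    X = C[list(COVARIATES)].to_numpy(dtype=float)
    alpha = np.asarray(spec.alpha, dtype=float)
    beta = np.asarray(spec.beta, dtype=float)
    a = A_INTERCEPT + alpha[0] + X @ alpha[1:]
    b = B_INTERCEPT + beta[0] + X @ beta[1:]
    d = D_INTERCEPT + spec.delta * X[:, COVARIATES.index("X2")]
    return a, b, d


def prob_A(a):
    """Marginal exposure probability P(A = 1 | C) = expit(a)."""
    return expit(np.asarray(a, dtype=float))


def prob_A_given_M(b, d, m):
    """P(A = 1 | M = m, C): expit(b) for m = 0, expit(b + d) for m = 1."""
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    return expit(b + d * np.asarray(m, dtype=float))


def prob_M_given_A(a, b, d, a_level: int):
    """Mediator law P(M = 1 | A = a_level, C) implied by the three logits.

    Derived from the compatibility of the marginal and the
    mediator-conditional exposure models:

        P(M=1|A=1) = (e^{-b} - e^{-a}) / (e^{-b} - e^{-b-d})
        P(M=1|A=0) = (e^{-b} - e^{-a}) / (e^{d-a} - e^{-a})

    Raises :class:`GenerativeValidityError` when a covariate pattern
    makes this fall outside [0, 1] (the three logits are then mutually
    inconsistent), including the degenerate d = 0, a != b case.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    d = np.atleast_1d(np.asarray(d, dtype=float))
    a, b, d = np.broadcast_arrays(a, b, d)
    if a_level not in (0, 1):
        raise ValueError("a_level must be 0 or 1")

    num = np.exp(-b) - np.exp(-a)
    if a_level == 1:
        den = np.exp(-b) - np.exp(-b - d)
    else:
        den = np.exp(d - a) - np.exp(-a)

    degenerate = (den == 0.0) & (num != 0.0)
    if np.any(degenerate):
        i = int(np.argmax(degenerate))
        raise GenerativeValidityError(
            f"infeasible logits at cell {i}: d = 0 with a != b "
            f"(a={a.flat[i]:.4g}, b={b.flat[i]:.4g}) leaves the mediator law undefined"
        )
    with np.errstate(invalid="ignore"):
        p = np.where((den == 0.0) & (num == 0.0), 0.0, num / np.where(den == 0.0, 1.0, den))
    bad = (p < 0.0) | (p > 1.0) | ~np.isfinite(p)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise GenerativeValidityError(
            f"P(M=1|A={a_level}) = {p.flat[i]:.4g} outside [0, 1] at cell {i} "
            f"(a={a.flat[i]:.4g}, b={b.flat[i]:.4g}, d={d.flat[i]:.4g})"
        )
    return p if p.shape != () else float(p)


def outcome_probability(A, M, C: pd.DataFrame, y_model: dict[str, float]):
    """P(Y = 1 | A, M, C) under the scenario's logistic outcome model."""
    A = np.asarray(A, dtype=float)
    M = np.asarray(M, dtype=float)
    eta = np.full(len(C), float(y_model.get("intercept", 0.0)))
    eta = eta + y_model.get("A", 0.0) * A + y_model.get("M", 0.0) * M
    for cov in COVARIATES:
        coef = y_model.get(cov, 0.0)
        if coef:
            eta = eta + coef * C[cov].to_numpy(dtype=float)
    x2 = C["X2"].to_numpy(dtype=float)
    if y_model.get("A:M", 0.0):
        eta = eta + y_model["A:M"] * A * M
    if y_model.get("A:X2", 0.0):
        eta = eta + y_model["A:X2"] * A * x2
    if y_model.get("M:X2", 0.0):
        eta = eta + y_model["M:X2"] * M * x2
    return expit(eta)


def generate_population(
    n: int,
    strata=None,
    spec: ScenarioSpec = None,
    rng_seed=None,
) -> pd.DataFrame:
    """Generate a full pseudo-population carrying all potential outcomes.

    Columns: stratum, U1..X3, A, M, Y, M1, M0, Y11, Y00, Y10, Y01 where
    Mk is the potential mediator under A = k and Yab is Y(a, M_b).
    Observed M and Y satisfy consistency: M = M_A, Y = Y(A, M_A).
    Potential outcomes are drawn independently per (a, m) pair; only
    their means feed any downstream quantity, so the (unidentified)
    cross-world coupling is irrelevant.
    """
    if spec is None:
        spec = ScenarioSpec.default(1)
    ss = _seed_seq(rng_seed).spawn(2)
    pop = generate_covariates(n, strata, rng_seed=ss[0])
    rng = np.random.default_rng(ss[1])

    a, b, d = linear_predictors(pop, spec)
    pA = prob_A(a)
    pM1_A1 = prob_M_given_A(a, b, d, 1)
    pM1_A0 = prob_M_given_A(a, b, d, 0)

    A = (rng.random(n) < pA).astype(np.int64)
    M1 = (rng.random(n) < pM1_A1).astype(np.int64)
    M0 = (rng.random(n) < pM1_A0).astype(np.int64)
    pop["A"] = A
    pop["M1"] = M1
    pop["M0"] = M0
    pop["M"] = np.where(A == 1, M1, M0)

    for col, (a_lvl, m_src) in {
        "Y11": (1, M1), "Y00": (0, M0), "Y10": (1, M0), "Y01": (0, M1),
    }.items():
        p = outcome_probability(a_lvl, m_src, pop, spec.y_model)
        pop[col] = (rng.random(n) < p).astype(np.int64)
    pop["Y"] = np.where(A == 1, pop["Y11"], pop["Y00"])
    return pop


@dataclass(frozen=True)
class TrueEffects:
    """Potential-outcome means and the five effects they imply.

    te = po11 - po00 with the two exact decompositions
    te = nde0 + nie1 = nde1 + nie0 holding by construction.
    """

    po11: float
    po00: float
    po10: float
    po01: float

    @property
    def te(self) -> float:
        return self.po11 - self.po00

    @property
    def nde0(self) -> float:
        return self.po10 - self.po00

    @property
    def nie1(self) -> float:
        return self.po11 - self.po10

    @property
    def nde1(self) -> float:
        return self.po11 - self.po01

    @property
    def nie0(self) -> float:
        return self.po01 - self.po00

    def effect(self, name: str) -> float:
        return getattr(self, name.lower())

    def po_mean(self, a: int, a_prime: int) -> float:
        return getattr(self, f"po{a}{a_prime}")

    def as_dict(self) -> dict[str, float]:
        return {
            "po11": self.po11, "po00": self.po00,
            "po10": self.po10, "po01": self.po01,
            "TE": self.te, "NDE0": self.nde0, "NIE1": self.nie1,
            "NDE1": self.nde1, "NIE0": self.nie0,
        }


def true_effects_mc(pop: pd.DataFrame) -> TrueEffects:
    """True effects from a pseudo-population's potential-outcome means."""
    missing = [c for c in PO_COLUMNS if c not in pop.columns]
    if missing:
        raise ValueError(f"population lacks potential-outcome columns {missing}")
    return TrueEffects(
        po11=float(pop["Y11"].mean()),
        po00=float(pop["Y00"].mean()),
        po10=float(pop["Y10"].mean()),
        po01=float(pop["Y01"].mean()),
    )


def true_effects_exact(strata=None, spec: ScenarioSpec = None) -> TrueEffects:
    """Closed-form true effects by enumerating all stratum-covariate cells.

    E[Y(a, M_{a'})] = sum_strata (1/3) sum_{C in {0,1}^6} P(C | stratum)
        * sum_m P(M = m | A = a', C) * P(Y = 1 | A = a, M = m, C).

    Deterministic; serves as the oracle for the Monte-Carlo route.
    """
    if strata is None:
        strata = default_strata()
    if spec is None:
        spec = ScenarioSpec.default(1)
    cells = _all_covariate_patterns()
    X = cells.to_numpy(dtype=float)
    a, b, d = linear_predictors(cells, spec)
    pM1 = {1: prob_M_given_A(a, b, d, 1), 0: prob_M_given_A(a, b, d, 0)}

    # P(C | stratum) for each of the 64 cells, averaged over strata.
    cell_w = np.zeros(len(cells))
    for s in strata:
        p = s.probabilities()
        w = np.prod(np.where(X == 1, p, 1 - p), axis=1)
        cell_w += w / len(strata)

    po = {}
    for a_lvl, ap in ((1, 1), (0, 0), (1, 0), (0, 1)):
        total = 0.0
        for m in (0, 1):
            pm = pM1[ap] if m == 1 else 1.0 - pM1[ap]
            py = outcome_probability(a_lvl, m, cells, spec.y_model)
            total += float(np.sum(cell_w * pm * py))
        po[(a_lvl, ap)] = total
    return TrueEffects(po11=po[(1, 1)], po00=po[(0, 0)], po10=po[(1, 0)], po01=po[(0, 1)])


def write_population_csv(pop: pd.DataFrame, path) -> None:
    """Write a population (or sample) table to CSV, stable column order."""
    lead = ["stratum", *COVARIATES, "A", "M", "Y"]
    rest = [c for c in pop.columns if c not in lead]
    pop[lead + rest].to_csv(path, index=False)


def read_population_csv(path) -> pd.DataFrame:
    """Read a population table written by :func:`write_population_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in ("stratum", *COVARIATES, "A", "M", "Y") if c not in df.columns]
    if missing:
        raise ValueError(f"population file lacks required columns {missing}")
    return df
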