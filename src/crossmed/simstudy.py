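"""Replication harness: scenarios x sampling methods x weighting strategies.

One population per scenario is generated once and held fixed; each
replicate redraws the sample, refits the propensity models, rebuilds
cross-world weights under every requested strategy (strategies that
share the first stage share fits), and records the estimates.  Metrics
per condition follow the usual simulation-study conventions: mean,
bias against the exact truth, relative bias, MSE, mean estimated SE,
SD across replicates (denominator R - 1), and the mean-SE/SD ratio.

Seed schedule: every RNG stream is derived from
``SeedSequence([master_seed, scenario_id, method_code, replicate])``,
so any subset of the grid reproduces the full-grid numbers exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import crossworld, effects, popgen, sampler
from .crossworld import FitError, WeightStrategy
from .effects import EFFECT_NAMES, PO_NAMES
from .popgen import ScenarioSpec, TrueEffects
from .sampler import SamplingDesign, SamplingMethod

__all__ = [
    "ConditionResult",
    "run_replicate",
    "run_condition",
    "summarize",
    "run_grid",
    "ALL_STRATEGIES",
    "ALL_METHODS",
]

ALL_STRATEGIES = (
    WeightStrategy.NEITHER,
    WeightStrategy.FIRST_ONLY,
    WeightStrategy.SECOND_ONLY,
    WeightStrategy.BOTH,
)
ALL_METHODS = (
    SamplingMethod.COV,
    SamplingMethod.COV_MED,
    SamplingMethod.COV_TRT,
    SamplingMethod.SRS,
)

_METHOD_CODE = {m: i + 1 for i, m in enumerate(ALL_METHODS)}

#: Conditions with more than this fraction of failed replicates are invalid.
MAX_FAILURE_RATE = 0.05


class ConditionInvalidError(RuntimeError):
    """Too many replicates failed for the condition to be summarized."""


@dataclass
class ConditionResult:
    """Per-replicate estimates plus bookkeeping for one (scenario, design)."""

    scenario_id: int
    method: SamplingMethod
    estimates: pd.DataFrame  # long format: one row per (replicate, strategy)
    truth: TrueEffects
    n_replicates: int
    n_failed: int


def run_replicate(
    pop: pd.DataFrame,
    design: SamplingDesign,
    strategies,
    rng_seed,
) -> list[dict]:
    """Draw one sample and estimate under each strategy on that same sample."""
    sample = sampler.draw_sample(pop, design, rng_seed=rng_seed)
    # Strategies differing only in the outcome stage share propensity fits.
    fits_cache: dict[bool, tuple] = {}
    rows = []
    for strat in strategies:
        key = strat.use_sw_in_fits
        if key not in fits_cache:
            fits_cache[key] = crossworld.fit_propensity_models(sample, key)
        cw = crossworld.build_weights(sample, strat, fits=fits_cache[key])
        est = effects.estimate_effects(sample, cw)
        row = {"strategy": strat.name, "n_truncated": cw.n_truncated}
        row.update(est.as_row())
        rows.append(row)
    return rows


def run_condition(
    scenario,
    design: SamplingDesign,
    R: int,
    base_seed: int = 0,
    strategies=ALL_STRATEGIES,
    population: pd.DataFrame | None = None,
    N: int = 90_000,
    regenerate_population: bool = False,
) -> ConditionResult:
    """Run ``R`` replicate samples for one scenario x sampling method.

    ``scenario`` may be a scenario id (default coefficients) or a full
    :class:`ScenarioSpec`.  A failed propensity fit drops the replicate
    for *all* strategies, keeping strategy comparisons replicate-matched;
    more than 5% failures invalidates the condition.
    """
    if isinstance(scenario, int):
        spec = ScenarioSpec.default(scenario)
    else:
        spec = scenario
    if R < 2:
        raise ValueError("need at least 2 replicates")
    if isinstance(strategies, WeightStrategy):
        strategies = (strategies,)
    mcode = _METHOD_CODE[design.method]
    if population is None and not regenerate_population:
        population = popgen.generate_population(
            N, spec=spec, rng_seed=np.random.SeedSequence([base_seed, spec.scenario_id])
        )
    truth = popgen.true_effects_exact(spec=spec)

    records = []
    n_failed = 0
    for rep in range(R):
        seed = np.random.SeedSequence([base_seed, spec.scenario_id, mcode, rep])
        pop = population
        if regenerate_population:
            pop_seed, seed = seed.spawn(2)
            pop = popgen.generate_population(N, spec=spec, rng_seed=pop_seed)
        try:
            rows = run_replicate(pop, design, strategies, rng_seed=seed)
        except (FitError, effects.EstimationError):
            n_failed += 1
            continue
        for row in rows:
            row["replicate"] = rep
            records.append(row)
    if n_failed > MAX_FAILURE_RATE * R:
        raise ConditionInvalidError(
            f"{n_failed}/{R} replicates failed for scenario {spec.scenario_id}, "
            f"method {design.method.name}"
        )
    est = pd.DataFrame.from_records(records)
    est.insert(0, "scenario", spec.scenario_id)
    est.insert(1, "method", design.method.name)
    return ConditionResult(
        scenario_id=spec.scenario_id,
        method=design.method,
        estimates=est,
        truth=truth,
        n_replicates=R - n_failed,
        n_failed=n_failed,
    )


def summarize(estimates: pd.DataFrame, truth: TrueEffects) -> pd.DataFrame:
    """Replication metrics per (strategy, quantity).

    Columns: mean, bias, relative_bias (NaN when the truth is zero),
    mse, mean_se, sd (ddof = 1) and se_sd_ratio.  The arithmetic
    identity MSE = bias^2 + SD^2 (R-1)/R is asserted for every row.
    """
    truths = truth.as_dict()
    rows = []
    for strat, grp in estimates.groupby("strategy", sort=False):
        if len(grp) < 2:
            raise ValueError("need at least 2 retained replicates per strategy")
        for q in (*EFFECT_NAMES, *PO_NAMES):
            vals = grp[q].to_numpy(dtype=float)
            tv = truths[q]
            r = len(vals)
            mean = vals.mean()
            bias = mean - tv
            sd = vals.std(ddof=1)
            mse = float(np.mean((vals - tv) ** 2))
            np.testing.assert_allclose(
                mse, bias**2 + sd**2 * (r - 1) / r, rtol=1e-10, atol=1e-14
            )
            mean_se = grp[f"se_{q}"].mean()
            rows.append({
                "strategy": strat,
                "quantity": q,
                "truth": tv,
                "mean": mean,
                "bias": bias,
                "relative_bias": bias / tv if tv != 0 else np.nan,
                "mse": mse,
                "mean_se": mean_se,
                "sd": sd,
                "se_sd_ratio": mean_se / sd if sd > 0 else np.nan,
                "n_replicates": r,
            })
    return pd.DataFrame(rows)


def run_grid(
    scenarios=range(1, 9),
    methods=ALL_METHODS,
    strategies=ALL_STRATEGIES,
    R: int = 1000,
    base_seed: int = 0,
    N: int = 90_000,
    n: int = 9_000,
    keep_estimates: bool = False,
):
    """Fully crossed study: scenarios x sampling methods (x strategies).

    Returns the long-format summary table (one row per scenario, method,
    strategy, quantity); with ``keep_estimates`` also a dict of
    per-condition :class:`ConditionResult`.
    """
    summaries = []
    results: dict[tuple[int, str], ConditionResult] = {}
    for sid in scenarios:
        spec = ScenarioSpec.default(sid) if isinstance(sid, int) else sid
        population = popgen.generate_population(
            N, spec=spec, rng_seed=np.random.SeedSequence([base_seed, spec.scenario_id])
        )
        for method in methods:
            design = SamplingDesign.default(method, n)
            res = run_condition(
                spec, design, R, base_seed=base_seed,
                strategies=strategies, population=population, N=N,
            )
            summ = summarize(res.estimates, res.truth)
            summ.insert(0, "scenario", spec.scenario_id)
            summ.insert(1, "method", method.name)
            summ["n_failed"] = res.n_failed
            summaries.append(summ)
            if keep_estimates:
                results[(spec.scenario_id, method.name)] = res
    summary = pd.concat(summaries, ignore_index=True)
    if keep_estimates:
        return summary, results
    return summary
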