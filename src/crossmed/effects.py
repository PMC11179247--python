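"""Weighted potential-outcome means, effect estimates and linearized SEs.

Each counterfactual mean E[Y(a, M_{a'})] is estimated as a Hajek ratio
mean of the observed outcome over the A = a arm, with the strategy's
final (possibly composite) weight.  The five effects — total effect and
the two natural direct / indirect decompositions — are plug-in
differences of those means, so the identities TE = NDE0 + NIE1 and
TE = NDE1 + NIE0 hold at machine precision by construction.

Standard errors use Taylor linearization of the ratio mean, treating
all weights as known and the four means as independent.  Both choices
are deliberate: ignoring the propensity-estimation step and the
between-mean covariance makes these "sandwich-style" SEs conservative,
which is the behavior under study in the replication metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossworld import CrossWorldWeights, WeightStrategy

__all__ = [
    "EstimationError",
    "EffectEstimates",
    "po_mean",
    "estimate_effects",
    "sandwich_se_diagnostic",
    "EFFECT_NAMES",
    "PO_NAMES",
    "EFFECT_COMPONENTS",
]

EFFECT_NAMES = ("TE", "NDE0", "NIE1", "NDE1", "NIE0")
PO_NAMES = ("po11", "po00", "po10", "po01")

#: Each effect as (positive po term, negative po term).
EFFECT_COMPONENTS = {
    "TE": ("po11", "po00"),
    "NDE0": ("po10", "po00"),
    "NIE1": ("po11", "po10"),
    "NDE1": ("po11", "po01"),
    "NIE0": ("po01", "po00"),
}


class EstimationError(RuntimeError):
    """Estimation impossible on this sample (empty arm, no positive weight)."""


def po_mean(Y, A, final_weights, a: int, a_prime: int) -> tuple[float, float]:
    """Hajek mean of Y over the A = a arm and its linearized variance term.

    estimate = sum_{i: A_i = a} w_i Y_i / sum w_i
    se_component = sum w_i^2 (Y_i - estimate)^2 / (sum w_i)^2

    ``se_component`` is a *variance* contribution; effect SEs add two of
    them and take the square root.
    """
    Y = np.asarray(Y, dtype=float)
    A = np.asarray(A)
    w = np.asarray(final_weights, dtype=float)
    mask = (A == a) & np.isfinite(w) & (w > 0)
    if mask.sum() < 2:
        raise EstimationError(
            f"fewer than 2 units with A={a} and positive weight (positivity violation?)"
        )
    wa, ya = w[mask], Y[mask]
    total = wa.sum()
    est = float(np.dot(wa, ya) / total)
    se_comp = float(np.dot(wa**2, (ya - est) ** 2) / total**2)
    return est, se_comp


@dataclass(frozen=True)
class EffectEstimates:
    """Four counterfactual means, five effects, and their SEs for one sample."""

    po_hat: dict[str, float]
    se_po: dict[str, float]
    effects: dict[str, float]
    se: dict[str, float]
    n_by_arm: dict[int, int]
    strategy: WeightStrategy | None = None

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        row.update(self.po_hat)
        row.update(self.effects)
        row.update({f"se_{k}": v for k, v in self.se_po.items()})
        row.update({f"se_{k}": v for k, v in self.se.items()})
        return row


def estimate_effects(sample: pd.DataFrame, cw: CrossWorldWeights) -> EffectEstimates:
    """Estimates and SEs from a sample and its cross-world weights."""
    Y = sample["Y"].to_numpy(dtype=float)
    A = sample["A"].to_numpy()
    po_hat: dict[str, float] = {}
    var_comp: dict[str, float] = {}
    for a, ap in ((1, 1), (0, 0), (1, 0), (0, 1)):
        name = f"po{a}{ap}"
        est, comp = po_mean(Y, A, cw.final[f"w{a}{ap}"].to_numpy(), a, ap)
        po_hat[name] = est
        var_comp[name] = comp
    effects = {
        e: po_hat[pos] - po_hat[neg] for e, (pos, neg) in EFFECT_COMPONENTS.items()
    }
    se = {
        e: float(np.sqrt(var_comp[pos] + var_comp[neg]))
        for e, (pos, neg) in EFFECT_COMPONENTS.items()
    }
    se_po = {k: float(np.sqrt(v)) for k, v in var_comp.items()}
    n_by_arm = {1: int((A == 1).sum()), 0: int((A == 0).sum())}
    return EffectEstimates(po_hat=po_hat, se_po=se_po, effects=effects, se=se,
                           n_by_arm=n_by_arm, strategy=cw.strategy)


def sandwich_se_diagnostic(estimates: pd.DataFrame, quantities=EFFECT_NAMES) -> pd.Series:
    """Per-quantity ratio mean(estimated SE) / SD(estimates) across replicates.

    A ratio above 1 means the analytic SE overstates the true replication
    variability.  Requires columns ``<q>`` and ``se_<q>``; a zero SD
    yields NaN (ratio undefined), not an error.
    """
    if len(estimates) < 2:
        raise ValueError("need at least 2 replicates")
    out = {}
    for q in quantities:
        sd = estimates[q].std(ddof=1)
        mean_se = estimates[f"se_{q}"].mean()
        out[q] = mean_se / sd if sd > 0 else np.nan
    return pd.Series(out, name="se_sd_ratio")
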