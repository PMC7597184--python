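"""Stochastic oracle: simulate unreliable submodules task by task.

The closed-form benefits and utilities in :mod:`neurodup.model_core` are
expectations over two layers of randomness: whether a task's submodule is
active in each structure copy (Bernoulli with probability kappa), and whether
an active module computes correctly (fails with probability epsilon).  This
module samples that process directly and reports empirical means with
standard errors, providing an implementation-independent check of the
algebra.

Costs are applied as their deterministic expected values (they are written
directly in kappa), which affects only the variance of the simulated utility,
never its mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    Activation,
    ModelParams,
    Scenario,
    activation_cost,
    benefit_coop,
    benefit_uncoop,
    coordination_cost,
    utility,
)

__all__ = ["SimResult", "simulate_benefit", "simulate_utility"]

_RNG_NAME = "numpy.random.Generator(PCG64)"


@dataclass(frozen=True)
class SimResult:
    """A seeded Monte Carlo estimate.

    ``mean`` and ``std_error`` summarize ``n_reps`` independent replicates;
    identical inputs and seed reproduce the result bit-for-bit.  ``closed_form``
    carries the analytic expectation for the same inputs, and ``rep_range``
    the width of the interval a single replicate can occupy.
    """

    mean: float
    std_error: float
    n_reps: int
    seed: int
    quantity: str
    scenario: Scenario
    closed_form: float
    rep_range: float = float("nan")
    rng: str = _RNG_NAME

    def zscore(self) -> float:
        """(mean - closed form) / SE.

        When every replicate came out identical the empirical SE is 0 and the
        ratio is undefined; common with rare all-or-nothing rewards, where an
        all-zero sample is perfectly consistent with a tiny positive
        expectation.  The fallback reports the smallest |z| attainable by any
        per-replicate distribution that is supported on an interval of width
        ``rep_range``, has the closed-form expectation, and could have
        produced the constant sample: its variance is at most
        |diff| * (rep_range - |diff|), giving z = sqrt(n * q / (1 - q)) with
        q = |diff| / rep_range.  A diff at or beyond rep_range is impossible
        for a correct implementation and reported as signed infinity.
        """
        diff = self.mean - self.closed_form
        if self.std_error > 0.0:
            return float(diff / self.std_error)
        if diff == 0.0:
            return 0.0
        q = abs(diff) / self.rep_range
        if not q < 1.0:
            return float("inf") * float(np.sign(diff))
        return float(np.sign(diff)) * float(np.sqrt(self.n_reps * q / (1.0 - q)))

    def to_tsv_record(self) -> str:
        """One-line TSV record of all fields, for audit logs."""
        fields = [
            self.quantity, self.scenario.value, repr(self.mean),
            repr(self.std_error), str(self.n_reps), str(self.seed),
            repr(self.closed_form), repr(self.rep_range), self.rng,
        ]
        return "\t".join(fields)


def _simulate_task_success(params: ModelParams, act: Activation,
                           n_reps: int, rng: np.random.Generator,
                           deterministic_activation: bool) -> np.ndarray:
    """Boolean (n_reps, K0) matrix: did each task of each replicate succeed?"""
    K0 = params.K0
    shape = (n_reps, K0)
    if deterministic_activation:
        # exactly round(kappa*K0) modules active, same pattern every replicate
        n_left = int(round(act.kappa_L * K0))
        n_right = int(round(act.kappa_R * K0))
        active_l = np.zeros(shape, dtype=bool)
        active_r = np.zeros(shape, dtype=bool)
        active_l[:, :n_left] = True
        active_r[:, :n_right] = True
    else:
        active_l = rng.random(shape) < act.kappa_L
        active_r = rng.random(shape) < act.kappa_R
    ok_l = active_l & (rng.random(shape) >= params.epsilon)
    ok_r = active_r & (rng.random(shape) >= params.epsilon)
    return ok_l | ok_r


def _summarize(values: np.ndarray) -> tuple:
    mean = float(values.mean())
    # a constant sample has SE exactly 0; np.std would report summation noise
    if values.size > 1 and np.ptp(values) > 0.0:
        se = float(values.std(ddof=1) / np.sqrt(values.size))
    else:
        se = 0.0
    return mean, se


def simulate_benefit(params: ModelParams, act: Activation, scenario: Scenario,
                     n_reps: int, seed: int,
                     deterministic_activation: bool = False) -> SimResult:
    """Empirical mean benefit over ``n_reps`` replicates.

    Per replicate: each of the K0 tasks has its left (right) submodule active
    with probability kappa_L (kappa_R); each active module fails independently
    with probability epsilon; the task succeeds iff at least one active module
    succeeds.  The uncooperative benefit is b times the number of successful
    tasks; the cooperative benefit is b*K0 if every task succeeded, else 0.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    scenario = Scenario.from_string(scenario)
    rng = np.random.default_rng(seed)
    success = _simulate_task_success(params, act, n_reps, rng,
                                     deterministic_activation)
    if scenario is Scenario.UNCOOPERATIVE:
        per_rep = params.b * success.sum(axis=1)
        closed = float(benefit_uncoop(params, act))
    else:
        per_rep = params.b * params.K0 * success.all(axis=1).astype(float)
        closed = float(benefit_coop(params, act))
    mean, se = _summarize(per_rep)
    return SimResult(mean=mean, std_error=se, n_reps=n_reps, seed=seed,
                     quantity="benefit", scenario=scenario, closed_form=closed,
                     rep_range=params.b * params.K0)


def simulate_utility(params: ModelParams, act: Activation, scenario: Scenario,
                     n_reps: int, seed: int,
                     deterministic_activation: bool = False) -> SimResult:
    """Empirical mean normalized utility: (realized benefit - C - Chat) / K0.

    The benefit is stochastic as in :func:`simulate_benefit`; the coordination
    and activation costs are the deterministic functions of kappa.  The mean
    converges to the closed-form utility rho (uncooperative) or rho~
    (cooperative).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    scenario = Scenario.from_string(scenario)
    rng = np.random.default_rng(seed)
    success = _simulate_task_success(params, act, n_reps, rng,
                                     deterministic_activation)
    if scenario is Scenario.UNCOOPERATIVE:
        per_rep_benefit = params.b * success.sum(axis=1)
    else:
        per_rep_benefit = params.b * params.K0 * success.all(axis=1).astype(float)
    costs = float(coordination_cost(params, act) + activation_cost(params, act))
    per_rep = (per_rep_benefit - costs) / params.K0
    closed = float(utility(params, act, scenario))
    mean, se = _summarize(per_rep)
    return SimResult(mean=mean, std_error=se, n_reps=n_reps, seed=seed,
                     quantity="utility", scenario=scenario, closed_form=closed,
                     rep_range=params.b)
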