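"""Costs, benefits and utilities of duplicated neural structures.

A complex neural structure consists of ``K0`` submodules, each solving one
task and each failing independently with probability ``epsilon``.  The
structure may be duplicated into a left and a right copy (bilateral
counterparts, or any arbitrary pair of duplicates); ``kappa_L`` and
``kappa_R`` are the fractions of submodules kept active in each copy.
Active modules pay costs and contribute benefit; inactive ones do neither.

Two fitness scenarios are modelled:

* **uncooperative** — each task pays benefit ``b`` on its own when at least
  one active copy of its submodule computes correctly;
* **cooperative** — an emergent phenotype pays ``b * K0``, but only when all
  ``K0`` tasks succeed simultaneously.

In both scenarios activating a task's submodule in *both* copies incurs a
per-task coordination cost ``c``, and every active module pays a baseline
cost ``c_hat * (1 - epsilon)`` that grows with the module's reliability.

All functions here are pure and numpy-broadcastable: activation fractions
may be scalars or arrays of matching shape.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "Activation",
    "Scenario",
    "per_task_success",
    "benefit_uncoop",
    "coordination_cost",
    "activation_cost",
    "utility_uncoop",
    "benefit_coop",
    "utility_coop",
    "utility",
    "utility_surface",
]


class Scenario(enum.Enum):
    """How task successes convert into fitness benefit."""

    UNCOOPERATIVE = "uncoop"
    COOPERATIVE = "coop"

    @classmethod
    def from_string(cls, s: "str | Scenario") -> "Scenario":
        if isinstance(s, Scenario):
            return s
        key = s.strip().lower()
        aliases = {
            "uncoop": cls.UNCOOPERATIVE,
            "uncooperative": cls.UNCOOPERATIVE,
            "coop": cls.COOPERATIVE,
            "cooperative": cls.COOPERATIVE,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown scenario {s!r}") from None


@dataclass(frozen=True)
class ModelParams:
    """The five scalar model parameters.

    Parameters
    ----------
    b : float
        Fitness benefit per successfully implemented task; must be > 0.
    c : float
        Coordination cost per task with both module copies active; >= 0.
    c_hat : float
        Baseline cost scale per active module; >= 0.
    epsilon : float
        Per-module failure probability, in [0, 1].
    K0 : int
        Number of tasks (equivalently submodules per structure); >= 1.
    """

    b: float
    c: float
    c_hat: float
    epsilon: float
    K0: int = 1

    def __post_init__(self) -> None:
        if not (self.b > 0) or not math.isfinite(self.b):
            raise ValueError(f"b must be a positive finite number, got {self.b}")
        if not (self.c >= 0) or not math.isfinite(self.c):
            raise ValueError(f"c must be non-negative and finite, got {self.c}")
        if not (self.c_hat >= 0) or not math.isfinite(self.c_hat):
            raise ValueError(f"c_hat must be non-negative and finite, got {self.c_hat}")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if int(self.K0) != self.K0 or self.K0 < 1:
            raise ValueError(f"K0 must be an integer >= 1, got {self.K0}")
        object.__setattr__(self, "K0", int(self.K0))

    def replace(self, **kwargs) -> "ModelParams":
        fields = dict(b=self.b, c=self.c, c_hat=self.c_hat,
                      epsilon=self.epsilon, K0=self.K0)
        fields.update(kwargs)
        return ModelParams(**fields)


@dataclass(frozen=True)
class Activation:
    """Activation fractions (kappa_L, kappa_R) of the two structure copies.

    Each fraction lies in [0, 1].  With ``discrete=True`` the fractions are
    additionally required to be integer multiples of ``1/K0`` (the model's
    underlying count of active submodules, K = kappa * K0, is then integral).
    """

    kappa_L: float
    kappa_R: float

    def __post_init__(self) -> None:
        for name, k in (("kappa_L", self.kappa_L), ("kappa_R", self.kappa_R)):
            if not (0.0 <= k <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {k}")

    def validate_discrete(self, K0: int, tol: float = 1e-9) -> None:
        """Check both fractions are multiples of 1/K0 (discrete mode)."""
        for name, k in (("kappa_L", self.kappa_L), ("kappa_R", self.kappa_R)):
            if abs(round(k * K0) - k * K0) > tol * K0:
                raise ValueError(
                    f"{name}={k} is not an integer multiple of 1/K0 (K0={K0})"
                )

    def swapped(self) -> "Activation":
        return Activation(self.kappa_R, self.kappa_L)


def _check_unit_interval(x, name: str) -> None:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0) or np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} must lie in [0, 1]")


def per_task_success(act: Activation, epsilon: float):
    """Probability that one task is successfully implemented.

    A task succeeds if exactly one copy of its submodule is active and that
    module computes correctly, or if both copies are active and at least one
    computes correctly:

        p = (1-eps) * [kL(1-kR) + (1-kL)kR] + (1-eps^2) * kL*kR
    """
    kl, kr = act.kappa_L, act.kappa_R
    _check_unit_interval(kl, "kappa_L")
    _check_unit_interval(kr, "kappa_R")
    _check_unit_interval(epsilon, "epsilon")
    one_active = kl * (1.0 - kr) + (1.0 - kl) * kr
    both_active = kl * kr
    return (1.0 - epsilon) * one_active + (1.0 - epsilon**2) * both_active


def benefit_uncoop(params: ModelParams, act: Activation):
    """Expected total benefit when each task pays b independently: B = b*p*K0."""
    return params.b * per_task_success(act, params.epsilon) * params.K0


def coordination_cost(params: ModelParams, act: Activation):
    """Cost of integrating duplicated outputs: C = c * kL * kR * K0.

    Vanishes whenever either structure is fully inactive.
    """
    return params.c * act.kappa_L * act.kappa_R * params.K0


def activation_cost(params: ModelParams, act: Activation):
    """Baseline cost of keeping modules active: Chat = c_hat*(1-eps)*(kL+kR)*K0.

    The cost scales with module reliability (1 - epsilon): a more reliable
    module is assumed to be metabolically more expensive, linearly so.
    """
    return params.c_hat * (1.0 - params.epsilon) * (act.kappa_L + act.kappa_R) * params.K0


def utility_uncoop(params: ModelParams, act: Activation):
    """Normalized uncooperative utility rho = (B - C - Chat) / K0.

    Expanded form (equal to the assembled form to machine precision):

        rho = b(1-eps)[kL(1-kR) + (1-kL)kR + (1+eps) kL kR]
              - c kL kR - c_hat (1-eps)(kL + kR)
    """
    kl, kr = act.kappa_L, act.kappa_R
    eps = params.epsilon
    bracket = kl * (1.0 - kr) + (1.0 - kl) * kr + (1.0 + eps) * kl * kr
    return (
        params.b * (1.0 - eps) * bracket
        - params.c * kl * kr
        - params.c_hat * (1.0 - eps) * (kl + kr)
    )


def benefit_coop(params: ModelParams, act: Activation):
    """Expected benefit of the emergent phenotype: Btilde = b * K0 * p**K0.

    The phenotype pays b*K0 only when all K0 tasks succeed simultaneously,
    which happens with probability p**K0 for independent tasks.
    """
    p = per_task_success(act, params.epsilon)
    return params.b * params.K0 * p**params.K0


def utility_coop(params: ModelParams, act: Activation):
    """Normalized cooperative utility rho~ = b*p**K0 - c kL kR - c_hat(1-eps)(kL+kR).

    Costs are identical to the uncooperative scenario; only the benefit
    changes.  At K0 = 1 this coincides with :func:`utility_uncoop`.
    """
    kl, kr = act.kappa_L, act.kappa_R
    eps = params.epsilon
    p = per_task_success(act, eps)
    return (
        params.b * p**params.K0
        - params.c * kl * kr
        - params.c_hat * (1.0 - eps) * (kl + kr)
    )


def utility(params: ModelParams, act: Activation, scenario: Scenario):
    """Dispatch to the scenario's normalized utility."""
    scenario = Scenario.from_string(scenario)
    if scenario is Scenario.UNCOOPERATIVE:
        return utility_uncoop(params, act)
    return utility_coop(params, act)


def utility_surface(params: ModelParams, scenario: Scenario,
                    kappa_L: np.ndarray, kappa_R: np.ndarray) -> np.ndarray:
    """Vectorized utility over arrays of activation fractions.

    ``kappa_L`` and ``kappa_R`` must broadcast against each other; values
    outside [0, 1] raise.  Used by the grid optimizer and the diagrams.
    """
    kl = np.asarray(kappa_L, dtype=float)
    kr = np.asarray(kappa_R, dtype=float)
    _check_unit_interval(kl, "kappa_L")
    _check_unit_interval(kr, "kappa_R")
    eps = params.epsilon
    scenario = Scenario.from_string(scenario)
    cost = (params.c * kl * kr
            + params.c_hat * (1.0 - eps) * (kl + kr))
    if scenario is Scenario.UNCOOPERATIVE:
        bracket = kl * (1.0 - kr) + (1.0 - kl) * kr + (1.0 + eps) * kl * kr
        return params.b * (1.0 - eps) * bracket - cost
    p = ((1.0 - eps) * (kl * (1.0 - kr) + (1.0 - kl) * kr)
         + (1.0 - eps**2) * kl * kr)
    return params.b * p**params.K0 - cost
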