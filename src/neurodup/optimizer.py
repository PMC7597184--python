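"""Optimal activation configurations and phase classification.

The utilities in :mod:`neurodup.model_core` are smooth, low-degree surfaces
over the unit square of activation fractions.  Their maxima sit at corners of
the square — no graded (fractional) optimum exists — so the optimal design is
always one of three *phases*: build nothing, build one structure
(lateralized), or build both (bilateral / duplicated).  This module evaluates
the corner utilities, classifies the phase, and provides a brute-force grid
optimizer that verifies corner optimality numerically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .model_core import Activation, ModelParams, Scenario, utility, utility_surface

__all__ = [
    "PhaseLabel",
    "Optimum",
    "corner_utilities",
    "classify_phase",
    "optimize_grid",
    "verify_corner_optimality",
    "DEFAULT_TOL",
]

#: Absolute tolerance for utility ties; ties break toward fewer structures.
DEFAULT_TOL = 1e-12

_CORNERS = ((0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0))


class PhaseLabel(enum.IntEnum):
    """Optimal configuration class.

    ``SINGLE`` collapses the exactly degenerate pair (1,0)/(0,1): left and
    right are arbitrary labels, so only the number of structures matters.
    The integer values are the on-disk grid encoding.
    """

    NONE = 0
    SINGLE = 1
    DUPLICATED = 2

    @property
    def n_active_structures(self) -> int:
        return int(self)


@dataclass(frozen=True)
class Optimum:
    """Argmax of a scenario utility over activation fractions."""

    kappa_L: float
    kappa_R: float
    utility: float
    label: PhaseLabel
    at_corner: bool


def corner_utilities(params: ModelParams, scenario: Scenario) -> dict:
    """Utilities at the four activation corners (0,0), (1,0), (0,1), (1,1).

    The (1,0) and (0,1) values are equal by left/right symmetry; the (0,0)
    value is always exactly 0.
    """
    return {
        (kl, kr): float(utility(params, Activation(kl, kr), scenario))
        for (kl, kr) in _CORNERS
    }


def _label_of_corner(kl: float, kr: float) -> PhaseLabel:
    n = int(kl >= 0.5) + int(kr >= 0.5)
    return PhaseLabel(n)


def classify_phase(params: ModelParams, scenario: Scenario,
                   tol: float = DEFAULT_TOL) -> PhaseLabel:
    """Phase of the utility-maximizing corner.

    Ties within ``tol`` break toward fewer active structures (parsimony: a
    structure with zero net advantage is not built), so the preference order
    under a tie is NONE > SINGLE > DUPLICATED.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    corners = corner_utilities(params, scenario)
    u_none = corners[(0.0, 0.0)]
    u_single = corners[(1.0, 0.0)]
    u_dup = corners[(1.0, 1.0)]
    best = max(u_none, u_single, u_dup)
    for label, u in ((PhaseLabel.NONE, u_none),
                     (PhaseLabel.SINGLE, u_single),
                     (PhaseLabel.DUPLICATED, u_dup)):
        if u >= best - tol:
            return label
    raise AssertionError("unreachable")


def optimize_grid(params: ModelParams, scenario: Scenario,
                  resolution: int = 101, tol: float = DEFAULT_TOL) -> Optimum:
    """Brute-force argmax of the scenario utility over a kappa grid.

    The grid is ``resolution x resolution`` over [0,1]^2 and always contains
    the corners.  Ties within ``tol`` resolve toward corners first, then
    toward fewer active structures.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    axis = np.linspace(0.0, 1.0, resolution)
    kl, kr = np.meshgrid(axis, axis, indexing="ij")
    surf = utility_surface(params, scenario, kl, kr)
    u_max = float(surf.max())

    # candidates within tol of the max; prefer corners, then parsimony
    ii, jj = np.nonzero(surf >= u_max - tol)
    best = None
    for i, j in zip(ii.tolist(), jj.tolist()):
        x, y = float(axis[i]), float(axis[j])
        is_corner = (x in (0.0, 1.0)) and (y in (0.0, 1.0))
        n_active = (x > 0.0) + (y > 0.0)
        key = (not is_corner, n_active, x + y)
        if best is None or key < best[0]:
            best = (key, x, y, float(surf[i, j]), is_corner)
    _, x, y, u, is_corner = best
    label = _label_of_corner(x, y) if is_corner else _label_of_corner(round(x), round(y))
    return Optimum(kappa_L=x, kappa_R=y, utility=u, label=label, at_corner=is_corner)


def verify_corner_optimality(params: ModelParams, scenario: Scenario,
                             resolution: int = 101, tol: float = 1e-9) -> bool:
    """True iff no interior grid point beats the best corner by more than tol.

    Numerical check of the claim that the utilities admit no graded optimum:
    the maximum over the full ``resolution x resolution`` grid must not exceed
    the maximum over the four corners plus ``tol``.
    """
    if resolution < 3:
        raise ValueError("resolution must be >= 3")
    axis = np.linspace(0.0, 1.0, resolution)
    kl, kr = np.meshgrid(axis, axis, indexing="ij")
    surf = utility_surface(params, scenario, kl, kr)
    best_corner = max(corner_utilities(params, scenario).values())
    return float(surf.max()) <= best_corner + tol
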