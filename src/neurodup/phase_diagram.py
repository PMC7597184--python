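"""Phase diagrams over the (epsilon, c) plane and evolutionary-transition maps.

A *phase diagram* labels every point of a (failure probability, coordination
cost) grid with the optimal configuration — none, single, or duplicated — for
one scenario at fixed ``b``, ``c_hat`` and ``K0``.  Superposing the
uncooperative diagram (evolutionary precondition) with the cooperative one
(emergent phenotype) yields a *transition map*: each cell is labeled with the
evolutionary path it implies, e.g. a single lateralized structure becoming a
duplicated bilateral one.

Closed-form phase boundaries are derived from the corner-utility comparisons
and cross-checked against the swept grids.  Grids round-trip losslessly
through a '#'-header TSV format.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .model_core import ModelParams, Scenario
from .optimizer import DEFAULT_TOL, PhaseLabel

__all__ = [
    "PhaseGrid",
    "TransitionGrid",
    "TransitionLabel",
    "sweep",
    "boundary_uncoop",
    "boundaries_coop",
    "CoopBoundaries",
    "phase_uncoop_closed_form",
    "phase_coop_closed_form",
    "superpose",
    "region_census",
    "trace_path",
    "write_grid_tsv",
    "read_grid_tsv",
    "default_epsilon_axis",
    "default_c_axis",
]


class TransitionLabel(enum.IntEnum):
    """Evolutionary path implied by a (pre-phase, post-phase) pair.

    The integer values are the on-disk encoding.  ``DENOVO`` (nothing optimal
    before, something after) never occurs for b > c_hat and epsilon < 1; it is
    this package's label for an extrapolated corner of parameter space.
    """

    NO_EMERGENCE = 0
    LATERAL_TO_LATERAL = 1
    LATERAL_TO_BILATERAL = 2
    BILATERAL_TO_BILATERAL = 3
    BILATERAL_TO_LATERAL = 4
    DENOVO = 5


def default_epsilon_axis(n: int = 199) -> np.ndarray:
    """Default failure-probability axis: [0.005, 0.995], avoiding the
    degenerate endpoints (which remain supported explicitly)."""
    return np.linspace(0.005, 0.995, n)


def default_c_axis(n: int = 201) -> np.ndarray:
    """Default coordination-cost axis: [0, 1]."""
    return np.linspace(0.0, 1.0, n)


def _check_axes(epsilon_axis: np.ndarray, c_axis: np.ndarray) -> tuple:
    eps = np.asarray(epsilon_axis, dtype=float)
    c = np.asarray(c_axis, dtype=float)
    if eps.ndim != 1 or eps.size == 0 or c.ndim != 1 or c.size == 0:
        raise ValueError("axes must be non-empty 1-D arrays")
    if np.any(np.diff(eps) <= 0) or np.any(np.diff(c) <= 0):
        if eps.size > 1 and np.any(np.diff(eps) <= 0):
            raise ValueError("epsilon_axis must be strictly ascending")
        if c.size > 1 and np.any(np.diff(c) <= 0):
            raise ValueError("c_axis must be strictly ascending")
    if np.any(eps < 0) or np.any(eps > 1):
        raise ValueError("epsilon_axis values must lie in [0, 1]")
    if np.any(c < 0):
        raise ValueError("c_axis values must be >= 0")
    return eps, c


@dataclass
class PhaseGrid:
    """Phase labels over an (epsilon, c) grid for one scenario.

    ``labels[i, j]`` is the :class:`~neurodup.optimizer.PhaseLabel` (stored as
    a small integer) at ``epsilon_axis[i]``, ``c_axis[j]``.  ``meta`` records
    everything needed to reproduce the grid: scenario, b, c_hat, K0, tol.
    """

    epsilon_axis: np.ndarray
    c_axis: np.ndarray
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epsilon_axis = np.asarray(self.epsilon_axis, dtype=float)
        self.c_axis = np.asarray(self.c_axis, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (self.epsilon_axis.size, self.c_axis.size):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match axes "
                f"({self.epsilon_axis.size}, {self.c_axis.size})"
            )
        valid = {int(l) for l in PhaseLabel}
        if not set(np.unique(self.labels).tolist()) <= valid:
            raise ValueError("labels contain values outside the PhaseLabel encoding")

    @property
    def kind(self) -> str:
        return "phase"


@dataclass
class TransitionGrid:
    """Evolutionary-path labels from superposing two phase diagrams."""

    epsilon_axis: np.ndarray
    c_axis: np.ndarray
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epsilon_axis = np.asarray(self.epsilon_axis, dtype=float)
        self.c_axis = np.asarray(self.c_axis, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (self.epsilon_axis.size, self.c_axis.size):
            raise ValueError("labels shape does not match axes")
        valid = {int(l) for l in TransitionLabel}
        if not set(np.unique(self.labels).tolist()) <= valid:
            raise ValueError("labels contain values outside the TransitionLabel encoding")

    @property
    def kind(self) -> str:
        return "transition"


def _corner_utility_arrays(b: float, c_hat: float, K0: int,
                           scenario: Scenario,
                           eps: np.ndarray, c: np.ndarray):
    """Utilities of the single and duplicated corners over a meshgrid.

    Same algebra as evaluating the scenario utility at (1,0) and (1,1); the
    (0,0) corner is identically 0 and (0,1) equals (1,0) by symmetry.
    """
    E, C = np.meshgrid(eps, c, indexing="ij")
    if scenario is Scenario.UNCOOPERATIVE:
        u_single = (b - c_hat) * (1.0 - E)
        u_dup = b * (1.0 - E**2) - C - 2.0 * c_hat * (1.0 - E)
    else:
        u_single = b * (1.0 - E) ** K0 - c_hat * (1.0 - E)
        u_dup = b * (1.0 - E**2) ** K0 - C - 2.0 * c_hat * (1.0 - E)
    return u_single, u_dup


def sweep(b: float, c_hat: float, K0: int, scenario: Scenario,
          epsilon_axis: np.ndarray | None = None,
          c_axis: np.ndarray | None = None,
          tol: float = DEFAULT_TOL) -> PhaseGrid:
    """Classify the optimal phase at every (epsilon, c) of the grid.

    Vectorized corner comparison, cell-for-cell identical to calling
    :func:`neurodup.optimizer.classify_phase` with the same tolerance and
    tie-break (ties go to fewer structures).
    """
    scenario = Scenario.from_string(scenario)
    eps = default_epsilon_axis() if epsilon_axis is None else epsilon_axis
    c = default_c_axis() if c_axis is None else c_axis
    eps, c = _check_axes(eps, c)
    # validate fixed params once (c placeholder 0, epsilon placeholder 0)
    ModelParams(b=b, c=0.0, c_hat=c_hat, epsilon=0.0, K0=K0)

    u_single, u_dup = _corner_utility_arrays(b, c_hat, K0, scenario, eps, c)
    u_none = np.zeros_like(u_single)
    best = np.maximum(u_none, np.maximum(u_single, u_dup))
    labels = np.full(best.shape, int(PhaseLabel.DUPLICATED), dtype=np.int8)
    labels[u_single >= best - tol] = int(PhaseLabel.SINGLE)
    labels[u_none >= best - tol] = int(PhaseLabel.NONE)

    meta = {
        "scenario": scenario.value,
        "b": b,
        "c_hat": c_hat,
        "K0": int(K0),
        "tol": tol,
    }
    return PhaseGrid(epsilon_axis=eps, c_axis=c, labels=labels, meta=meta)


def boundary_uncoop(epsilon, b: float, c_hat: float):
    """Critical coordination cost below which duplication wins (uncooperative).

        c* = max(0, (1 - eps) (b eps - c_hat))

    From the corner comparison rho(1,1) > rho(1,0):
    b(1-eps^2) - c - 2 c_hat (1-eps) > (b - c_hat)(1-eps).  Accepts scalar or
    array epsilon.
    """
    eps = np.asarray(epsilon, dtype=float)
    if np.any(eps < 0) or np.any(eps > 1):
        raise ValueError("epsilon must lie in [0, 1]")
    c_star = np.maximum(0.0, (1.0 - eps) * (b * eps - c_hat))
    return float(c_star) if np.isscalar(epsilon) else c_star


@dataclass(frozen=True)
class CoopBoundaries:
    """Closed-form thresholds of the cooperative corner comparison.

    ``single_viable`` — a lone structure beats building nothing,
    b(1-eps)^K0 > c_hat(1-eps).
    ``c_dup_vs_single`` — duplicated beats single below this cost.
    ``c_dup_vs_none`` — duplicated beats nothing below this cost.
    """

    single_viable: bool
    c_dup_vs_single: float
    c_dup_vs_none: float


def boundaries_coop(epsilon: float, b: float, c_hat: float, K0: int) -> CoopBoundaries:
    """Cooperative-scenario thresholds at one epsilon.

        c1 = b[(1-eps^2)^K0 - (1-eps)^K0] - c_hat (1-eps)   (duplicated vs single)
        c2 = b (1-eps^2)^K0 - 2 c_hat (1-eps)               (duplicated vs none)
    """
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError("epsilon must lie in [0, 1]")
    if K0 < 1 or int(K0) != K0:
        raise ValueError("K0 must be an integer >= 1")
    q_single = (1.0 - epsilon) ** K0
    q_dup = (1.0 - epsilon**2) ** K0
    single_viable = b * q_single > c_hat * (1.0 - epsilon)
    c1 = b * (q_dup - q_single) - c_hat * (1.0 - epsilon)
    c2 = b * q_dup - 2.0 * c_hat * (1.0 - epsilon)
    return CoopBoundaries(single_viable=bool(single_viable),
                          c_dup_vs_single=float(c1), c_dup_vs_none=float(c2))


def _phase_from_corner_values(u_single: float, u_dup: float,
                              tol: float) -> PhaseLabel:
    """Tie-break identical to the grid classifier: NONE > SINGLE > DUPLICATED
    whenever corner utilities tie within tol."""
    best = max(0.0, u_single, u_dup)
    if 0.0 >= best - tol:
        return PhaseLabel.NONE
    if u_single >= best - tol:
        return PhaseLabel.SINGLE
    return PhaseLabel.DUPLICATED


def phase_uncoop_closed_form(epsilon: float, c: float, b: float, c_hat: float,
                             tol: float = DEFAULT_TOL) -> PhaseLabel:
    """Uncooperative phase from the closed-form corner utilities
    (no grid search)."""
    u_single = (b - c_hat) * (1.0 - epsilon)
    u_dup = b * (1.0 - epsilon**2) - c - 2.0 * c_hat * (1.0 - epsilon)
    return _phase_from_corner_values(u_single, u_dup, tol)


def phase_coop_closed_form(epsilon: float, c: float, b: float, c_hat: float,
                           K0: int, tol: float = DEFAULT_TOL) -> PhaseLabel:
    """Cooperative phase from the closed-form corner utilities
    (no grid search)."""
    if K0 < 1 or int(K0) != K0:
        raise ValueError("K0 must be an integer >= 1")
    u_single = b * (1.0 - epsilon) ** K0 - c_hat * (1.0 - epsilon)
    u_dup = b * (1.0 - epsilon**2) ** K0 - c - 2.0 * c_hat * (1.0 - epsilon)
    return _phase_from_corner_values(u_single, u_dup, tol)


_TRANSITION_MAP = {
    (PhaseLabel.SINGLE, PhaseLabel.SINGLE): TransitionLabel.LATERAL_TO_LATERAL,
    (PhaseLabel.SINGLE, PhaseLabel.DUPLICATED): TransitionLabel.LATERAL_TO_BILATERAL,
    (PhaseLabel.DUPLICATED, PhaseLabel.DUPLICATED): TransitionLabel.BILATERAL_TO_BILATERAL,
    (PhaseLabel.DUPLICATED, PhaseLabel.SINGLE): TransitionLabel.BILATERAL_TO_LATERAL,
}


def superpose(pre: PhaseGrid, post: PhaseGrid) -> TransitionGrid:
    """Superpose a precondition diagram with an emergent-phenotype diagram.

    Per-cell mapping: if the post-phase is NONE the phenotype cannot emerge
    (``NO_EMERGENCE``) regardless of the precondition; otherwise the
    (pre, post) pair names the path, with a pre-phase of NONE mapped to
    ``DENOVO``.  Grids must share axes and fixed parameters b, c_hat exactly
    (K0 may differ: the cooperative diagram's K0 is a property of the
    emergent phenotype).
    """
    if (pre.epsilon_axis.shape != post.epsilon_axis.shape
            or pre.c_axis.shape != post.c_axis.shape
            or not np.array_equal(pre.epsilon_axis, post.epsilon_axis)
            or not np.array_equal(pre.c_axis, post.c_axis)):
        raise ValueError("grids do not share identical axes")
    for key in ("b", "c_hat"):
        if pre.meta.get(key) != post.meta.get(key):
            raise ValueError(f"grids disagree on fixed parameter {key!r}")

    out = np.empty_like(pre.labels)
    pre_l, post_l = pre.labels, post.labels
    out[:] = int(TransitionLabel.NO_EMERGENCE)
    emerged = post_l != int(PhaseLabel.NONE)
    denovo = emerged & (pre_l == int(PhaseLabel.NONE))
    out[denovo] = int(TransitionLabel.DENOVO)
    for (a, b_), t in _TRANSITION_MAP.items():
        out[emerged & (pre_l == int(a)) & (post_l == int(b_))] = int(t)

    meta = {
        "b": pre.meta.get("b"),
        "c_hat": pre.meta.get("c_hat"),
        "K0_pre": pre.meta.get("K0"),
        "K0_post": post.meta.get("K0"),
        "scenario_pre": pre.meta.get("scenario"),
        "scenario_post": post.meta.get("scenario"),
        "tol": max(pre.meta.get("tol", DEFAULT_TOL), post.meta.get("tol", DEFAULT_TOL)),
    }
    return TransitionGrid(epsilon_axis=pre.epsilon_axis.copy(),
                          c_axis=pre.c_axis.copy(), labels=out, meta=meta)


def region_census(grid) -> dict:
    """Cell counts per label name; counts sum to the total number of cells."""
    enum_cls = PhaseLabel if grid.kind == "phase" else TransitionLabel
    values, counts = np.unique(grid.labels, return_counts=True)
    return {enum_cls(int(v)).name: int(n) for v, n in zip(values, counts)}


def trace_path(grid, points) -> list:
    """Label sequence along an (epsilon, c) polyline, deduplicated.

    ``points`` is a sequence of (epsilon, c) vertices; each segment is sampled
    at the grid's own resolution and every point snaps to the nearest cell.
    Consecutive repeats are collapsed, so the result is the ordered sequence
    of regions the path visits.  Illustrative only — no claim is made about
    any particular published trajectory.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("points must be a sequence of (epsilon, c) pairs")
    enum_cls = PhaseLabel if grid.kind == "phase" else TransitionLabel
    n_samples = max(grid.epsilon_axis.size, grid.c_axis.size)
    samples = [pts[0]]
    for a, b_ in zip(pts[:-1], pts[1:]):
        ts = np.linspace(0.0, 1.0, n_samples)[1:]
        samples.extend(a + (b_ - a) * t for t in ts)
    seq = []
    for e, cc in samples:
        i = int(np.argmin(np.abs(grid.epsilon_axis - e)))
        j = int(np.argmin(np.abs(grid.c_axis - cc)))
        lab = enum_cls(int(grid.labels[i, j]))
        if not seq or seq[-1] != lab:
            seq.append(lab)
    return seq


# ---------------------------------------------------------------------------
# TSV round-tripping
# ---------------------------------------------------------------------------

_PHASE_ENCODING = "0=NONE,1=SINGLE,2=DUPLICATED"
_TRANSITION_ENCODING = ("0=NO_EMERGENCE,1=LATERAL_TO_LATERAL,"
                        "2=LATERAL_TO_BILATERAL,3=BILATERAL_TO_BILATERAL,"
                        "4=BILATERAL_TO_LATERAL,5=DENOVO")


def _fmt_axis(ax: np.ndarray) -> str:
    return ",".join(np.format_float_positional(v, unique=True, trim="-") for v in ax)


def write_grid_tsv(grid, path_or_buf) -> None:
    """Write a grid as TSV: '#key<TAB>value' metadata header, then one row of
    integer labels per epsilon value (columns follow the c axis)."""
    buf = io.StringIO()
    buf.write(f"#grid_kind\t{grid.kind}\n")
    buf.write(f"#software_version\t{__version__}\n")
    for k, v in grid.meta.items():
        buf.write(f"#{k}\t{v}\n")
    buf.write(f"#label_encoding\t"
              f"{_PHASE_ENCODING if grid.kind == 'phase' else _TRANSITION_ENCODING}\n")
    buf.write(f"#epsilon_axis\t{_fmt_axis(grid.epsilon_axis)}\n")
    buf.write(f"#c_axis\t{_fmt_axis(grid.c_axis)}\n")
    for row in grid.labels:
        buf.write("\t".join(str(int(v)) for v in row) + "\n")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_grid_tsv(path_or_buf):
    """Read a grid written by :func:`write_grid_tsv`; the round trip is exact."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    meta: dict = {}
    rows = []
    kind = None
    eps_axis = c_axis = None
    for line in text.splitlines():
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("\t")
            if key == "grid_kind":
                kind = value
            elif key == "epsilon_axis":
                eps_axis = np.array([float(v) for v in value.split(",")])
            elif key == "c_axis":
                c_axis = np.array([float(v) for v in value.split(",")])
            elif key in ("label_encoding", "software_version"):
                pass
            else:
                meta[key] = _parse_meta_value(value)
        else:
            rows.append([int(v) for v in line.split("\t")])
    if kind not in ("phase", "transition") or eps_axis is None or c_axis is None:
        raise ValueError("not a recognizable grid TSV")
    labels = np.array(rows, dtype=np.int8)
    cls = PhaseGrid if kind == "phase" else TransitionGrid
    return cls(epsilon_axis=eps_axis, c_axis=c_axis, labels=labels, meta=meta)


def _parse_meta_value(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    if value in ("True", "False"):
        return value == "True"
    if value == "None":
        return None
    return value
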