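"""Tests for sweeps, closed-form boundaries, superposition and TSV I/O."""

import io

import numpy as np
import pytest

from neurodup import (
    ModelParams,
    PhaseLabel,
    Scenario,
    TransitionLabel,
    boundaries_coop,
    boundary_uncoop,
    classify_phase,
    read_grid_tsv,
    region_census,
    superpose,
    sweep,
    trace_path,
    write_grid_tsv,
)
from neurodup.phase_diagram import (
    PhaseGrid,
    default_c_axis,
    default_epsilon_axis,
    phase_coop_closed_form,
    phase_uncoop_closed_form,
)


@pytest.fixture(scope="module")
def default_grids():
    eps = default_epsilon_axis()
    c = default_c_axis()
    pre = sweep(1.0, 0.1, 10, Scenario.UNCOOPERATIVE, eps, c)
    post = sweep(1.0, 0.1, 10, Scenario.COOPERATIVE, eps, c)
    return pre, post


class TestSweep:
    def test_uncoop_has_exactly_two_phases(self, default_grids):
        pre, _ = default_grids
        assert set(region_census(pre)) == {"SINGLE", "DUPLICATED"}

    def test_coop_has_exactly_three_phases(self, default_grids):
        _, post = default_grids
        assert set(region_census(post)) == {"NONE", "SINGLE", "DUPLICATED"}

    def test_zero_cost_column_duplicated_iff_eps_above_chat_over_b(self):
        eps = np.linspace(0.01, 0.99, 50)
        grid = sweep(1.0, 0.1, 1, Scenario.UNCOOPERATIVE, eps, np.array([0.0]))
        for i, e in enumerate(eps):
            expected = (PhaseLabel.DUPLICATED if e > 0.1 / 1.0
                        else PhaseLabel.SINGLE)
            assert grid.labels[i, 0] == int(expected)

    def test_matches_scalar_classifier_on_random_cells(self, rng,
                                                       default_grids):
        for grid, scen in zip(default_grids, Scenario):
            for _ in range(100):
                i = int(rng.integers(grid.epsilon_axis.size))
                j = int(rng.integers(grid.c_axis.size))
                p = ModelParams(b=1.0, c=float(grid.c_axis[j]), c_hat=0.1,
                                epsilon=float(grid.epsilon_axis[i]), K0=10)
                assert grid.labels[i, j] == int(classify_phase(p, scen))

    def test_rejects_bad_axes(self):
        with pytest.raises(ValueError):
            sweep(1, 0.1, 1, "uncoop", np.array([0.5, 0.2]), np.array([0.0]))
        with pytest.raises(ValueError):
            sweep(1, 0.1, 1, "uncoop", np.array([0.5, 1.2]), np.array([0.0]))
        with pytest.raises(ValueError):
            sweep(1, 0.1, 1, "uncoop", np.array([0.5]), np.array([-0.1]))

    def test_labels_monotone_along_c(self, default_grids):
        """For fixed eps, raising c can only remove structures: labels along
        the c axis go DUPLICATED -> SINGLE or DUPLICATED -> NONE, never back."""
        order = {int(PhaseLabel.DUPLICATED): 0, int(PhaseLabel.SINGLE): 1,
                 int(PhaseLabel.NONE): 1}
        for grid in default_grids:
            for row in grid.labels:
                ranks = [order[int(v)] for v in row]
                assert all(a <= b for a, b in zip(ranks, ranks[1:]))

    def test_meta_records_reproducibility_inputs(self, default_grids):
        pre, _ = default_grids
        assert pre.meta["scenario"] == "uncoop"
        assert pre.meta["b"] == 1.0
        assert pre.meta["c_hat"] == 0.1
        assert pre.meta["K0"] == 10


class TestBoundaries:
    def test_uncoop_closed_form_values(self):
        assert boundary_uncoop(0.5, b=1.0, c_hat=0.1) == pytest.approx(0.2)
        assert boundary_uncoop(0.1, b=1.0, c_hat=0.1) == pytest.approx(0.0)
        assert boundary_uncoop(1.0, b=1.0, c_hat=0.1) == 0.0

    def test_uncoop_boundary_brackets_classifier_flip(self):
        p_lo = ModelParams(b=1, c=0.199, c_hat=0.1, epsilon=0.5, K0=1)
        p_hi = ModelParams(b=1, c=0.201, c_hat=0.1, epsilon=0.5, K0=1)
        assert classify_phase(p_lo, Scenario.UNCOOPERATIVE) is PhaseLabel.DUPLICATED
        assert classify_phase(p_hi, Scenario.UNCOOPERATIVE) is PhaseLabel.SINGLE

    def test_coop_reduces_to_uncoop_at_k0_one(self, rng):
        for _ in range(100):
            e, b, ch = rng.random(), rng.uniform(0.1, 2), rng.uniform(0, 1)
            bnd = boundaries_coop(e, b, ch, K0=1)
            if bnd.single_viable:
                assert max(0.0, bnd.c_dup_vs_single) == pytest.approx(
                    boundary_uncoop(e, b, ch), abs=1e-12)

    def test_coop_duplicated_without_viable_single(self):
        # eps=0.3, K0=10: one structure alone cannot deliver the phenotype
        # (0.7**10 < 0.07) yet a duplicated pair can
        bnd = boundaries_coop(0.3, b=1.0, c_hat=0.1, K0=10)
        assert not bnd.single_viable
        assert bnd.c_dup_vs_none > 0.1
        p = ModelParams(b=1, c=0.1, c_hat=0.1, epsilon=0.3, K0=10)
        assert classify_phase(p, Scenario.COOPERATIVE) is PhaseLabel.DUPLICATED

    def test_coop_none_region(self):
        p = ModelParams(b=1, c=0.5, c_hat=0.1, epsilon=0.5, K0=10)
        assert phase_coop_closed_form(0.5, 0.5, 1.0, 0.1, 10) is PhaseLabel.NONE
        assert classify_phase(p, Scenario.COOPERATIVE) is PhaseLabel.NONE

    @pytest.mark.parametrize("scenario", list(Scenario))
    def test_closed_form_brackets_swept_flip_everywhere(self, scenario,
                                                        default_grids):
        """At every eps, the c where the swept label flips must bracket the
        analytic threshold within one c-grid step."""
        grid = default_grids[0] if scenario is Scenario.UNCOOPERATIVE \
            else default_grids[1]
        c_axis = grid.c_axis
        step = c_axis[1] - c_axis[0]
        for i, e in enumerate(grid.epsilon_axis):
            row = grid.labels[i]
            dup = row == int(PhaseLabel.DUPLICATED)
            if scenario is Scenario.UNCOOPERATIVE:
                c_star = boundary_uncoop(float(e), 1.0, 0.1)
            else:
                bnd = boundaries_coop(float(e), 1.0, 0.1, 10)
                c_star = (bnd.c_dup_vs_single if bnd.single_viable
                          else bnd.c_dup_vs_none)
            n_dup = int(dup.sum())
            if n_dup == 0:
                assert c_star <= c_axis[0] + step
            elif n_dup == dup.size:
                assert c_star >= c_axis[-1] - step
            else:
                flip_c = c_axis[n_dup]  # first non-duplicated cell
                assert abs(flip_c - c_star) <= step + 1e-12
                # duplicated cells must be a prefix of the row
                assert dup[:n_dup].all() and not dup[n_dup:].any()

    def test_closed_form_phase_matches_classifier(self, rng):
        for _ in range(300):
            e = rng.uniform(0, 1)
            c = rng.uniform(0, 1)
            b = rng.uniform(0.1, 2)
            ch = rng.uniform(0, 1)
            K0 = int(rng.integers(1, 21))
            pu = ModelParams(b=b, c=c, c_hat=ch, epsilon=e, K0=K0)
            assert phase_uncoop_closed_form(e, c, b, ch) is \
                classify_phase(pu, Scenario.UNCOOPERATIVE)
            assert phase_coop_closed_form(e, c, b, ch, K0) is \
                classify_phase(pu, Scenario.COOPERATIVE)


class TestSuperpose:
    def test_default_transition_regions(self, default_grids):
        trans = superpose(*default_grids)
        census = region_census(trans)
        assert set(census) == {"NO_EMERGENCE", "LATERAL_TO_LATERAL",
                               "LATERAL_TO_BILATERAL", "BILATERAL_TO_BILATERAL"}
        assert census.get("BILATERAL_TO_LATERAL", 0) == 0
        assert census.get("DENOVO", 0) == 0
        assert sum(census.values()) == trans.labels.size

    def test_cell_mapping(self):
        eps = np.array([0.5])
        c = np.array([0.0])
        mk = lambda lab: PhaseGrid(eps, c, np.array([[int(lab)]]),
                                   {"b": 1.0, "c_hat": 0.1, "K0": 1})
        cases = [
            (PhaseLabel.SINGLE, PhaseLabel.DUPLICATED,
             TransitionLabel.LATERAL_TO_BILATERAL),
            (PhaseLabel.SINGLE, PhaseLabel.NONE, TransitionLabel.NO_EMERGENCE),
            (PhaseLabel.DUPLICATED, PhaseLabel.NONE, TransitionLabel.NO_EMERGENCE),
            (PhaseLabel.NONE, PhaseLabel.NONE, TransitionLabel.NO_EMERGENCE),
            (PhaseLabel.DUPLICATED, PhaseLabel.SINGLE,
             TransitionLabel.BILATERAL_TO_LATERAL),
            (PhaseLabel.NONE, PhaseLabel.SINGLE, TransitionLabel.DENOVO),
        ]
        for pre_l, post_l, expected in cases:
            trans = superpose(mk(pre_l), mk(post_l))
            assert trans.labels[0, 0] == int(expected)

    def test_self_superposition_only_same_phase_labels(self, default_grids):
        pre, _ = default_grids
        census = region_census(superpose(pre, pre))
        assert set(census) <= {"LATERAL_TO_LATERAL", "BILATERAL_TO_BILATERAL",
                               "NO_EMERGENCE"}

    def test_axis_mismatch_is_an_error(self, default_grids):
        pre, _ = default_grids
        other = sweep(1.0, 0.1, 10, Scenario.COOPERATIVE,
                      np.linspace(0.01, 0.99, 50), pre.c_axis)
        with pytest.raises(ValueError):
            superpose(pre, other)

    def test_parameter_mismatch_is_an_error(self, default_grids):
        pre, _ = default_grids
        other = sweep(1.0, 0.2, 10, Scenario.COOPERATIVE,
                      pre.epsilon_axis, pre.c_axis)
        with pytest.raises(ValueError):
            superpose(pre, other)

    def test_larger_k0_grows_no_emergence_region(self, default_grids):
        """Demanding more simultaneous task successes (p**K0) can only shrink
        the viable region of the emergent phenotype."""
        pre, post10 = default_grids
        post15 = sweep(1.0, 0.1, 15, Scenario.COOPERATIVE,
                       pre.epsilon_axis, pre.c_axis)
        c10 = region_census(superpose(pre, post10))
        c15 = region_census(superpose(pre, post15))
        assert c15["NO_EMERGENCE"] >= c10["NO_EMERGENCE"]


class TestPathTracing:
    def test_single_cell_path(self, default_grids):
        pre, _ = default_grids
        seq = trace_path(pre, [(0.9, 0.05)])
        assert seq == [PhaseLabel.DUPLICATED]

    def test_crossing_the_boundary_reports_both_phases(self, default_grids):
        pre, _ = default_grids
        # at c=0.1 the duplication threshold c*=(1-eps)(eps-0.1) is crossed
        # as eps falls from 0.5 toward 0
        seq = trace_path(pre, [(0.5, 0.1), (0.05, 0.1)])
        assert seq == [PhaseLabel.DUPLICATED, PhaseLabel.SINGLE]

    def test_transition_grid_path(self, default_grids):
        # eps=0.3: pre-phase is SINGLE for c > 0.14; the cooperative optimum
        # is DUPLICATED up to c ~ 0.249, NONE for large c
        trans = superpose(*default_grids)
        seq = trace_path(trans, [(0.3, 0.2), (0.3, 0.9)])
        assert seq[0] == TransitionLabel.LATERAL_TO_BILATERAL
        assert seq[-1] == TransitionLabel.NO_EMERGENCE


class TestTsvRoundTrip:
    @pytest.mark.parametrize("which", ["phase", "transition"])
    def test_lossless(self, which, default_grids):
        grid = default_grids[0] if which == "phase" \
            else superpose(*default_grids)
        buf = io.StringIO()
        write_grid_tsv(grid, buf)
        back = read_grid_tsv(io.StringIO(buf.getvalue()))
        assert np.array_equal(back.labels, grid.labels)
        assert np.array_equal(back.epsilon_axis, grid.epsilon_axis)
        assert np.array_equal(back.c_axis, grid.c_axis)
        assert back.meta == grid.meta
        assert back.kind == grid.kind

    def test_write_is_deterministic(self, default_grids):
        pre, _ = default_grids
        a, b = io.StringIO(), io.StringIO()
        write_grid_tsv(pre, a)
        write_grid_tsv(pre, b)
        assert a.getvalue() == b.getvalue()
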