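"""Lambda schedules and the Zwanzig free-energy estimator."""

import numpy as np
import pytest
from scipy.integrate import quad

from evbkit import (
    R_KCAL,
    LambdaSchedule,
    SamplerParams,
    accumulate_fep,
    make_schedule,
    sample_all_windows,
    zwanzig_from_work,
    zwanzig_increment,
)
from evbkit.errors import AlignmentError, DataError, ScheduleError

from conftest import marcus_topology

RT300 = R_KCAL * 300.0


class TestMakeSchedule:
    def test_uniform_dissociative_grid(self):
        sched = make_schedule("dissociative", 101)
        assert sched.n_windows == 101
        np.testing.assert_allclose(np.diff(sched.progress), 0.01, atol=1e-12)
        np.testing.assert_array_equal(sched.vectors[0], [1.0, 0.0])
        np.testing.assert_array_equal(sched.vectors[-1], [0.0, 1.0])

    def test_associative_densified_grid(self):
        sched = make_schedule("associative")
        assert sched.n_windows == 131
        prog = sched.progress
        assert (np.diff(prog) > 0).all()
        # 30 extra windows all lie strictly inside (0.3, 1.0)
        base = np.linspace(0, 1, 101)
        extra = np.setdiff1d(np.round(prog, 12), np.round(base, 12))
        assert extra.size == 30
        assert extra.min() > 0.3 and extra.max() < 1.0

    def test_minimal_schedule(self):
        sched = make_schedule("dissociative", 2)
        np.testing.assert_array_equal(sched.vectors, [[1.0, 0.0], [0.0, 1.0]])

    def test_duplicate_merge_rejected(self):
        with pytest.raises(ScheduleError):
            make_schedule("associative", 3, densify_after=0.0, n_extra=1)

    def test_endpoint_validation(self):
        with pytest.raises(ScheduleError):
            LambdaSchedule(vectors=np.array([[0.5, 0.5], [0.0, 1.0]]))
        with pytest.raises(ScheduleError):
            LambdaSchedule(vectors=np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))


class TestZwanzig:
    def test_identical_windows_give_zero(self, marcus_run):
        _, _, trajs, _ = marcus_run
        assert zwanzig_increment(trajs[10], trajs[10].lam) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_closed_form(self):
        """Normal work (mu, sigma^2) -> dG = mu - beta*sigma^2/2."""
        rng = np.random.default_rng(0)
        work = rng.normal(2.0, 1.0, size=1_000_000)
        beta = 1.0 / RT300
        expected = 2.0 - beta * 1.0 / 2.0  # ~1.161
        assert expected == pytest.approx(1.161, abs=2e-3)
        assert zwanzig_from_work(work, 300.0) == pytest.approx(expected, abs=0.02)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(DataError):
            zwanzig_from_work(np.array([]), 300.0)
        with pytest.raises(DataError):
            zwanzig_from_work(np.array([1.0, np.nan]), 300.0)

    def test_bias_shrinks_with_sample_size(self):
        """Median Zwanzig bias on the Gaussian benchmark decreases with n."""
        beta = 1.0 / RT300
        truth = -beta * 4.0 / 2.0  # mu=0, sigma^2=4
        rng = np.random.default_rng(42)
        med_bias = []
        for n in (100, 1_000, 10_000):
            est = [
                zwanzig_from_work(rng.normal(0.0, 2.0, size=n), 300.0)
                for _ in range(31)
            ]
            med_bias.append(np.median(est) - truth)
        assert med_bias[0] > med_bias[1] > med_bias[2] >= 0.0


def harmonic_shift_run(replicate, steps=2000):
    """Equal-f diabats, offsets c2=4 and alpha2=1: exact total dG = 5."""
    from evbkit import DiabaticState, EVBTopology

    topo = EVBTopology(
        states=(
            DiabaticState(id="a", role="reactant", x0=0.0, f=150.0),
            DiabaticState(id="b", role="product", x0=0.5, f=150.0, c=4.0),
        ),
        alpha=(0.0, 1.0),
        coupling=((0.0, 0.0), (0.0, 0.0)),
        temperature=300.0,
    )
    sched = make_schedule("dissociative", 101)
    p = SamplerParams(steps_per_window=steps)
    trajs = sample_all_windows(topo, sched, p, master_seed=99, replicate_index=replicate)
    return topo, sched, trajs


def test_harmonic_shift_exact_free_energy():
    """Partition functions of equal-f wells cancel: dG = (c2+alpha2) - c1."""
    beta = 1.0 / RT300
    # quadrature oracle for the same pair of shifted wells
    z1 = quad(lambda x: np.exp(-beta * (0.5 * 150 * x**2)), -1, 1)[0]
    z2 = quad(lambda x: np.exp(-beta * (0.5 * 150 * (x - 0.5) ** 2 + 5.0)), -0.5, 1.5)[0]
    oracle = -RT300 * np.log(z2 / z1)
    assert oracle == pytest.approx(5.0, abs=1e-6)

    totals = []
    for rep in range(6):
        topo, sched, trajs = harmonic_shift_run(rep)
        totals.append(accumulate_fep(trajs, sched, topo).total)
    totals = np.array(totals)
    sem = totals.std(ddof=1) / np.sqrt(len(totals))
    assert abs(totals.mean() - 5.0) <= 3 * sem + 0.02


def test_single_increment_equals_zwanzig(marcus_run):
    topo, _, trajs, _ = marcus_run
    sched2 = LambdaSchedule(vectors=np.array([[1.0, 0.0], [0.0, 1.0]]))
    res = accumulate_fep([trajs[0], trajs[-1].with_alpha([0.0, 0.0])], sched2, topo)
    assert res.increments[0] == zwanzig_increment(trajs[0], [0.0, 1.0], topo)
    assert res.cumulative[0] == 0.0
    assert res.total == res.increments[0]


def test_identical_diabats_give_exactly_zero():
    """Null perturbation: every increment vanishes identically."""
    topo = marcus_topology(d=0.0)  # both states are the same parabola
    sched = make_schedule("dissociative", 21)
    trajs = sample_all_windows(topo, sched, SamplerParams(steps_per_window=200), 5)
    res = accumulate_fep(trajs, sched, topo)
    assert res.total == pytest.approx(0.0, abs=1e-12)
    assert np.abs(res.increments).max() <= 1e-12


def test_posthoc_alpha_shift_is_exactly_linear(marcus_run):
    """Adding delta to the final state's alpha moves the total by delta."""
    topo, sched, trajs, fep = marcus_run
    delta = 3.7
    shifted = [t.with_alpha(np.array([0.0, delta])) for t in trajs]
    topo2 = topo.with_params(alpha=(0.0, delta))
    fep2 = accumulate_fep(shifted, sched, topo2)
    assert fep2.total - fep.total == pytest.approx(delta, abs=1e-10)


def test_window_insertion_telescopes(marcus_run):
    """Dropping to a coarser schedule agrees within stochastic error."""
    topo, sched, trajs, fep = marcus_run
    coarse_idx = list(range(0, 101, 2))
    coarse = LambdaSchedule(vectors=sched.vectors[coarse_idx])
    res = accumulate_fep([trajs[i] for i in coarse_idx], coarse, topo)
    assert res.total == pytest.approx(fep.total, abs=0.5)


def test_alignment_errors(marcus_run):
    topo, sched, trajs, _ = marcus_run
    with pytest.raises(AlignmentError):
        accumulate_fep(trajs[:-1], sched, topo)
    with pytest.raises(AlignmentError):
        accumulate_fep(list(reversed(trajs)), sched, topo)


def test_bidirectional_average_close_to_forward(marcus_run):
    topo, sched, trajs, fep = marcus_run
    bi = accumulate_fep(trajs, sched, topo, bidirectional=True)
    assert bi.total == pytest.approx(fep.total, abs=0.5)
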