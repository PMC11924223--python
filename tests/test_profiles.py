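"""Umbrella-sampling profiles: Marcus oracles, features, leg composition."""

import numpy as np
import pytest
from scipy.stats import norm

from evbkit import (
    R_KCAL,
    FreeEnergyProfile,
    LambdaSchedule,
    SamplerParams,
    WindowTrajectory,
    accumulate_fep,
    evb_us_profile,
    extract_features,
    join_legs,
    make_schedule,
    sample_all_windows,
)
from evbkit.calibrate import recalibrate_profile
from evbkit.errors import CompositionError, NoBarrierError, UndersamplingError

from conftest import marcus_topology, scan_features

RT300 = R_KCAL * 300.0


def toy_profile(dG, roles=("reactant", "product"), centers=None):
    dG = np.asarray(dG, dtype=float)
    centers = np.linspace(-2, 2, dG.size) if centers is None else np.asarray(centers)
    return FreeEnergyProfile(
        bin_centers=centers, dG=dG, counts=np.full(dG.size, 100), roles=roles
    )


class TestExtractFeatures:
    def test_toy_array(self):
        f = extract_features(toy_profile([0, 5, 25, 5, -2]))
        assert f.dG_ddagger == 25.0
        assert f.dG0 == -2.0
        assert f.reactant_min_index < f.barrier_index < f.product_min_index

    def test_symmetric_toy(self):
        f = extract_features(toy_profile([0, 10, 0]))
        assert f.dG_ddagger == 10.0
        assert f.dG0 == 0.0

    def test_monotone_profile_raises(self):
        with pytest.raises(NoBarrierError):
            extract_features(toy_profile([0, 1, 2, 3, 4]))
        with pytest.raises(NoBarrierError):
            extract_features(toy_profile([0, -1, -2, -3]))

    def test_barrier_tie_broken_toward_zero_gap(self):
        f = extract_features(
            toy_profile([0, 8, 3, 8, 0], centers=[-2, -1, 0, 1, 2])
        )
        # two equal maxima at centers -1 and +1; both are 1 away from 0 ->
        # earliest of the nearest wins deterministically
        assert f.dG_ddagger == 8.0


def marcus_replicates(dG0, H, n_reps, seed=202, bins=200, min_count=25):
    topo = marcus_topology(dG0=dG0, H=H)
    sched = make_schedule("dissociative", 101)
    p = SamplerParams()
    out = []
    for r in range(n_reps):
        trajs = sample_all_windows(topo, sched, p, master_seed=seed, replicate_index=r)
        fep = accumulate_fep(trajs, sched, topo)
        prof = evb_us_profile(trajs, fep, topo, bins=bins, min_count=min_count)
        out.append((prof, fep))
    return topo, out


class TestMarcusBenchmarks:
    def test_symmetric_uncoupled_barrier(self):
        """lambda_reorg/4 for two displaced parabolas (f=200, d=1 -> 25)."""
        _, runs = marcus_replicates(0.0, 0.0, 8)
        bars = np.array([p.features.dG_ddagger for p, _ in runs])
        sem = bars.std(ddof=1) / np.sqrt(len(bars))
        assert abs(bars.mean() - 25.0) <= 3 * sem + 0.05

    def test_exergonic_marcus_barrier(self):
        """(lambda_reorg + dG0)^2 / (4 lambda_reorg) with dG0 = -10 -> 20.25."""
        _, runs = marcus_replicates(-10.0, 0.0, 8)
        bars = np.array([p.features.dG_ddagger for p, _ in runs])
        sem = bars.std(ddof=1) / np.sqrt(len(bars))
        assert abs(bars.mean() - 20.25) <= 3 * sem + 0.05

    def test_coupling_lowers_barrier_monotonically(self, marcus_run):
        """Recalibrating the same frames with growing H lowers the barrier,
        by about H at the symmetric crossing."""
        topo, sched, trajs, fep = marcus_run
        bars = []
        for h in (0.0, 1.0, 2.0, 3.0, 5.0):
            prof, _ = recalibrate_profile(trajs, fep, topo, (0.0, 0.0), h)
            bars.append(prof.features.dG_ddagger)
        assert all(b1 >= b2 - 0.05 for b1, b2 in zip(bars, bars[1:]))
        scan0 = scan_features(topo.with_params(coupling=((0, 0), (0, 0))), -1, 2)[0]
        scan3 = scan_features(topo.with_params(coupling=((0, 3.0), (3.0, 0))), -1, 2)[0]
        assert (bars[0] - bars[3]) == pytest.approx(scan0 - scan3, abs=0.5)


def test_profile_gauge_invariance():
    """A constant added to every diabat leaves the profile untouched."""
    from evbkit import DiabaticState, EVBTopology

    sched = make_schedule("dissociative", 51)
    p = SamplerParams(steps_per_window=800)

    def run(offset):
        topo = EVBTopology(
            states=(
                DiabaticState(id="r", role="reactant", x0=0.0, f=200.0, c=offset),
                DiabaticState(id="p", role="product", x0=1.0, f=200.0, c=offset),
            ),
            alpha=(0.0, 0.0),
            coupling=((0.0, 2.0), (2.0, 0.0)),
            temperature=300.0,
        )
        trajs = sample_all_windows(topo, sched, p, master_seed=8)
        fep = accumulate_fep(trajs, sched, topo)
        return evb_us_profile(trajs, fep, topo)

    a, b = run(0.0), run(25.0)
    np.testing.assert_allclose(a.dG, b.dG, atol=1e-9)
    np.testing.assert_array_equal(a.counts, b.counts)


def test_profile_dg0_consistent_with_fep_total():
    """Endpoint consistency: profile dG0 tracks the end-to-end FEP total."""
    _, runs = marcus_replicates(-10.0, 2.0, 6, seed=11)
    diffs = [p.features.dG0 - f.total for p, f in runs]
    assert abs(np.mean(diffs)) < 1.0


def test_quadrature_pseudo_frames_match_boltzmann_inversion():
    """Deterministic stratified frames reproduce the ground-surface free
    energy (equal-f diabats: G(gap) = E_g(x(gap)) + const) to < 0.1."""
    topo = marcus_topology(dG0=-5.0, H=2.0)
    sched = make_schedule("dissociative", 101)
    f_eff = 200.0
    sigma = np.sqrt(RT300 / f_eff)
    n = 2000
    quantiles = norm.ppf((np.arange(n) + 0.5) / n)
    trajs = []
    for lam in sched.vectors:
        # mapping potential of equal-f harmonic states is harmonic with
        # minimum at the lambda-weighted centers
        m = lam[0] * 0.0 + lam[1] * 1.0
        x = m + sigma * quantiles
        eps = topo.shifted_energies(x)
        trajs.append(
            WindowTrajectory(
                lam=lam, x=x, eps=eps, e_map=eps @ lam,
                gap=eps[:, 0] - eps[:, 1], seed=0,
                sampling_alpha=np.array([0.0, -5.0]),
            )
        )
    fep = accumulate_fep(trajs, sched, topo)
    prof = evb_us_profile(trajs, fep, topo, bins=400, min_count=4)
    feats = prof.features
    scan_bar, scan_dg0 = scan_features(topo, -1.5, 2.5)
    assert feats.dG_ddagger == pytest.approx(scan_bar, abs=0.1)
    assert feats.dG0 == pytest.approx(scan_dg0, abs=0.1)


class TestJoinLegs:
    def test_shift_matches_first_leg_product(self):
        leg1 = toy_profile([0, 27.9, 27.4], roles=("reactant", "intermediate"))
        leg2 = toy_profile([0, 0.5, -26.8], roles=("intermediate", "product"))
        comp = join_legs(leg1, leg2)
        # leg 2 rigidly shifted by +27.4
        np.testing.assert_allclose(comp.dG, [0, 27.9, 27.4, 27.9, 0.6])
        assert comp.features.dG_ddagger == pytest.approx(27.9)
        assert comp.features.dG0 == pytest.approx(0.6)

    def test_downhill_first_leg(self):
        leg1 = toy_profile([0, 10.0, -4.0], roles=("reactant", "intermediate"))
        leg2 = toy_profile([0, 7.0, -1.0], roles=("intermediate", "product"))
        comp = join_legs(leg1, leg2)
        # composite second maximum at b - x = 7 - 4 = 3
        assert comp.dG[3] == pytest.approx(3.0)
        assert comp.features.dG_ddagger == pytest.approx(10.0)

    def test_identical_legs_zero_dg0_idempotent_offset(self):
        leg = toy_profile([0, 5.0, 0.0], roles=("reactant", "intermediate"))
        leg2 = toy_profile([0, 5.0, 0.0], roles=("intermediate", "product"))
        comp = join_legs(leg, leg2)
        assert comp.dG[comp.features.product_min_index] == pytest.approx(0.0)

    def test_role_mismatch_raises(self):
        leg1 = toy_profile([0, 5, -1], roles=("reactant", "intermediate"))
        bad = toy_profile([0, 5, -1], roles=("reactant", "product"))
        with pytest.raises(CompositionError):
            join_legs(leg1, bad)


class TestDegenerateAndUndersampled:
    def test_identical_diabats_collapse_to_flat_profile(self):
        topo = marcus_topology(d=0.0)
        sched = make_schedule("dissociative", 11)
        trajs = sample_all_windows(topo, sched, SamplerParams(steps_per_window=200), 3)
        fep = accumulate_fep(trajs, sched, topo)
        prof = evb_us_profile(trajs, fep, topo)
        assert prof.features.degenerate
        assert prof.features.dG_ddagger == 0.0
        assert prof.features.dG0 == 0.0

    def test_unsampled_crossing_raises(self):
        """A two-window jump schedule never samples the barrier region."""
        topo = marcus_topology()
        sched = LambdaSchedule(vectors=np.array([[1.0, 0.0], [0.0, 1.0]]))
        trajs = sample_all_windows(topo, sched, SamplerParams(), 5)
        fep = accumulate_fep(trajs, sched, topo)
        with pytest.raises(UndersamplingError):
            evb_us_profile(trajs, fep, topo)

    def test_all_bins_below_threshold(self):
        topo = marcus_topology()
        sched = make_schedule("dissociative", 11)
        trajs = sample_all_windows(topo, sched, SamplerParams(steps_per_window=100), 5)
        fep = accumulate_fep(trajs, sched, topo)
        with pytest.raises(UndersamplingError):
            evb_us_profile(trajs, fep, topo, min_count=10_000)


def test_counts_account_for_all_frames(marcus_run):
    topo, sched, trajs, fep = marcus_run
    prof = evb_us_profile(trajs, fep, topo)
    assert prof.counts.sum() == sum(t.n_frames for t in trajs)
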