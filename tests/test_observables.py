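import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from condenseq.affinity import AffinityProfile
from condenseq.detect import record_from_members
from condenseq.engine import InteractionTable
from condenseq.fixtures import make_bondlength_series, make_membership_series
from condenseq.observables import (OccupancyProfile, coarsening_kinetics,
                                   capillary_force, fit_growth_exponent,
                                   fit_persistence_length,
                                   force_from_bond_means, interfacial_affinity,
                                   kymograph, membership_matrix,
                                   monomer_potential_profile, occupancy,
                                   outside_bond_mean, tangent_correlation)
from condenseq.units import PN_PER_KBT_SIGMA


def occ_from_pm(pm, omega=10):
    pm = np.asarray(pm, dtype=float)
    s = np.zeros((omega, len(pm)), dtype=bool)
    for m, p in enumerate(pm):
        s[: int(round(p * omega)), m] = True
    return OccupancyProfile(pm, s, omega)


def profile_from_eps(eps):
    eps = np.asarray(eps, dtype=float)
    return AffinityProfile(eps, np.zeros(len(eps), dtype=int), "homogeneous")


def detections_from_membership(s, points=None):
    """Turn a (frames x monomers) membership matrix into detection output."""
    omega, nm = s.shape
    out = []
    for c in range(omega):
        members = np.flatnonzero(s[c])
        if len(members):
            pts = points if points is not None else np.zeros((nm, 3))
            out.append([record_from_members(pts, members, n_monomers=nm)])
        else:
            out.append([])
    return out


class TestOccupancy:
    def test_always_inside_gives_one(self):
        s = make_membership_series(np.ones(5, dtype=int), 30)
        occ = occupancy(detections_from_membership(s), 5)
        assert np.all(occ.pm == 1.0)

    def test_half_frames_gives_half(self):
        s = np.zeros((30, 4), dtype=bool)
        s[::2, 2] = True
        occ = occupancy(detections_from_membership(s), 4)
        assert occ.pm[2] == pytest.approx(0.5)
        assert occ.pm[0] == 0.0

    def test_conservation_identity(self, rng):
        s = rng.random((40, 12)) < 0.3
        det = detections_from_membership(s)
        occ = occupancy(det, 12)
        total_events = sum(r.n_monomers for recs in det for r in recs)
        assert np.sum(occ.pm) * occ.omega_c == pytest.approx(total_events)

    def test_zero_frames_error(self):
        with pytest.raises(ValueError):
            occupancy([], 5)


class TestInterfacialAffinity:
    def test_constant_affinity_gives_constant(self):
        occ = occ_from_pm([0.0, 0.4, 0.9, 1.0, 0.9, 0.4, 0.0], omega=20)
        prof = profile_from_eps([2.0] * 7)
        res = interfacial_affinity(occ, prof)
        assert res.ia_mean == pytest.approx(2.0)
        assert res.ia_global == pytest.approx(2.0)

    def test_equal_weights_average(self):
        occ = occ_from_pm([0.5, 0.5], omega=10)
        prof = profile_from_eps([1.75, 2.25])
        res = interfacial_affinity(occ, prof)
        assert res.ia_global == pytest.approx(2.0)

    def test_hand_worked_weighted_mean(self):
        # (1*0.2 + 3*0.6) / (0.2 + 0.6) = 2.5
        occ = occ_from_pm([0.2, 0.6], omega=10)
        prof = profile_from_eps([1.0, 3.0])
        res = interfacial_affinity(occ, prof)
        assert res.ia_global == pytest.approx(2.5)

    def test_empty_interface_reports_pm_summary(self):
        occ = occ_from_pm([0.0, 0.05, 0.0], omega=20)
        prof = profile_from_eps([2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="Pm summary"):
            interfacial_affinity(occ, prof)

    def test_strict_upper_bound_excludes_interior(self):
        occ = occ_from_pm([0.5, 1.0, 0.5], omega=10)
        prof = profile_from_eps([1.0, 4.0, 1.0])
        printed = interfacial_affinity(occ, prof)           # 0.1 < Pm <= 1
        strict = interfacial_affinity(occ, prof, upper=0.9)  # drops Pm = 1
        assert printed.n_interface == 3
        assert strict.n_interface == 2
        assert strict.ia_global == pytest.approx(1.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounds_between_min_and_max_eps(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 30)
        pm = rng.random(n)
        pm[rng.integers(0, n)] = 0.5  # guarantee a non-empty interface
        eps = rng.uniform(0.1, 4.0, n)
        occ = occ_from_pm(pm, omega=100)
        res = interfacial_affinity(occ, profile_from_eps(eps))
        sel = res.interface_monomers
        assert eps[sel].min() - 1e-9 <= res.ia_global <= eps[sel].max() + 1e-9
        for side in res.sides:
            assert eps[sel].min() - 1e-9 <= side.ia <= eps[sel].max() + 1e-9


class TestForcePipeline:
    def test_noiseless_series_reproduces_kb_shift(self):
        data = make_bondlength_series(1.0, 0.01, 0.0, 50, n_bonds=99, seed=0)
        res = force_from_bond_means(data["with_protein"].mean(),
                                    data["tethered"].mean(),
                                    data["free"].mean(), kb=100.0)
        assert res.f_dna == pytest.approx(1.0)
        assert res.f_dna_protein == pytest.approx(1.0)
        assert res.f == pytest.approx(0.0)
        assert res.f == res.f_dna_protein - res.f_dna

    def test_noisy_series_within_sampling_error(self):
        data = make_bondlength_series(1.0, 0.01, 0.1, 2000, n_bonds=499, seed=1)
        res = force_from_bond_means(data["with_protein"].mean(),
                                    data["tethered"].mean(),
                                    data["free"].mean(), kb=100.0)
        assert res.f_dna == pytest.approx(1.0, abs=0.1)

    def test_unit_conversion_to_piconewton(self):
        res = force_from_bond_means(1.02, 1.01, 1.0, kb=100.0)
        assert res.f_dna == pytest.approx(1.0)
        assert res.f_dna_pn == pytest.approx(1.209, abs=0.001)
        assert PN_PER_KBT_SIGMA == pytest.approx(4.11 / 3.4)

    def test_antisymmetry_under_swap(self):
        a = force_from_bond_means(1.03, 1.01, 1.0, kb=100.0)
        b = force_from_bond_means(1.01, 1.03, 1.0, kb=100.0)
        # swapping the roles of the two trajectories negates the
        # with-protein excess force
        assert a.f_dna_protein == pytest.approx(-b.f_dna_protein)

    def test_outside_bond_mean_excludes_condensate(self, trajectory_factory):
        # chain of 10 monomers along z; monomers 3..6 belong to a condensate
        nm, nf = 10, 12
        frames = np.zeros((nf, nm, 3))
        frames[:, :, 2] = np.arange(nm) * 1.0
        # stretch the bonds outside the condensate by delta
        delta = 0.05
        outside = np.array([0, 1, 2, 7, 8, 9])
        for rank, m in enumerate(outside):
            frames[:, m, 2] += delta * rank  # cumulative extra spacing
        traj = trajectory_factory(frames, nm)
        s = np.zeros((nf, nm), dtype=bool)
        s[:, 3:7] = True
        det = detections_from_membership(s, points=frames[0])
        # outside bonds: (0,1), (1,2), (7,8), (8,9), each of length 1+delta
        assert outside_bond_mean(traj, det) == pytest.approx(1.0 + delta)

    def test_all_bonds_inside_is_an_error(self, trajectory_factory):
        nm, nf = 6, 10
        frames = np.zeros((nf, nm, 3))
        frames[:, :, 2] = np.arange(nm)
        traj = trajectory_factory(frames, nm)
        s = np.ones((nf, nm), dtype=bool)
        det = detections_from_membership(s, points=frames[0])
        with pytest.raises(ValueError, match="outside"):
            outside_bond_mean(traj, det)


class TestMonomerPotentialProfile:
    def _table(self):
        prof = profile_from_eps([2.0, 2.0, 2.0, 2.0])
        return InteractionTable.from_profile(prof, eps_pp=2.0), prof

    def test_isolated_monomer_has_bonded_energy_only(self):
        table, _ = self._table()
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0],
                        [20.0, 20, 20]])
        types = np.array([0, 0, 0, 0, 1])
        prof = monomer_potential_profile(pos, types, table, 4,
                                         np.array([50.0, 50, 50]),
                                         kb=100.0, kappa=15.0)
        # straight chain at rest length: all bonded terms vanish
        assert np.allclose(prof, 0.0, atol=1e-12)

    def test_half_share_bookkeeping_identity(self, rng):
        from condenseq.potentials import LJ_CUTOFF, pair_energy
        table, _ = self._table()
        box = np.array([30.0, 30.0, 30.0])
        pos = np.zeros((9, 3))
        pos[:4, 2] = np.arange(4)
        pos[4:] = rng.uniform(0, 6, (5, 3))
        types = np.array([0] * 4 + [1] * 5)
        prof = monomer_potential_profile(pos, types, table, 4, box,
                                         kb=100.0, kappa=15.0)
        # independent tally of monomer-involved pair energies
        mm = mp = 0.0
        for i in range(9):
            for j in range(i + 1, 9):
                if i < 4 and j < 4 and j - i == 1:
                    continue
                d = pos[i] - pos[j]
                d -= box * np.round(d / box)
                r = np.linalg.norm(d)
                if i < 4 and j < 4:
                    mm += pair_energy(r, "repulsive", 1.0)
                elif i < 4 or j < 4:
                    if r < LJ_CUTOFF:
                        mp += pair_energy(r, "attractive", 2.0)
        from condenseq.potentials import bonded_energy_forces
        bonds = [[i, i + 1] for i in range(3)]
        angles = [[i - 1, i, i + 1] for i in range(1, 3)]
        eb, _ = bonded_energy_forces(pos[:4], bonds, angles, 100.0, 15.0)
        assert prof.sum() == pytest.approx(mm + 0.5 * mp + eb, rel=1e-9)


class TestKymograph:
    def test_constant_band(self):
        s = np.zeros((25, 300), dtype=bool)
        s[:, 100:201] = True
        kymo = kymograph(detections_from_membership(s), 300)
        assert kymo.shape == (300, 25)
        assert np.all(kymo[100:201] == 1)
        assert np.all(kymo[:100] == 0)

    def test_band_fusion_at_frame(self):
        s = np.zeros((20, 100), dtype=bool)
        s[:10, 20:35] = True
        s[:10, 60:75] = True
        s[10:, 20:75] = True  # fusion at frame 10
        kymo = kymograph(detections_from_membership(s), 100)
        assert kymo[40, 5] == 0 and kymo[40, 15] == 1

    def test_column_sums_are_condensed_fraction(self, rng):
        s = rng.random((15, 50)) < 0.4
        kymo = kymograph(detections_from_membership(s), 50)
        assert np.allclose(kymo.sum(axis=0) / 50, s.mean(axis=1))


class TestCoarsening:
    def _power_law_detections(self, times, exponent, n_members=30):
        out = []
        members = np.arange(n_members)
        pts = np.zeros((n_members, 3))
        for t in times:
            r = 0.5 * t ** exponent
            rec = record_from_members(pts, members)
            rec.volume = 4 / 3 * np.pi * r ** 3
            out.append([rec])
        return out

    def test_exact_half_power_law(self):
        times = np.linspace(1.0, 400.0, 200)
        det = self._power_law_detections(times, 0.5)
        res = coarsening_kinetics(times, det)
        assert res.exponent == pytest.approx(0.5, abs=1e-6)
        assert res.single_droplet

    def test_saturating_series_late_slope_near_zero(self):
        times = np.linspace(1.0, 400.0, 300)
        radii = 3.0 * (1 - np.exp(-times / 20.0))
        late = times > 150
        x, y = np.log(times[late]), np.log(radii[late])
        assert abs(np.polyfit(x, y, 1)[0]) < 0.02

    def test_growth_window_excludes_plateau(self):
        times = np.linspace(1.0, 1000.0, 500)
        radii = np.minimum(0.3 * times ** 0.5, 5.0)  # growth then arrest
        exp = fit_growth_exponent(times, radii)
        assert exp == pytest.approx(0.5, abs=0.02)

    def test_two_tracks_scaled_by_final_largest(self):
        times = np.arange(1.0, 41.0)
        det = []
        pts = np.zeros((60, 3))
        for t in times:
            a = record_from_members(pts, np.arange(30))
            a.volume = 4 / 3 * np.pi * (0.4 * t ** 0.5) ** 3
            b = record_from_members(pts, np.arange(30, 60))
            b.volume = 4 / 3 * np.pi * 1.0
            det.append([a, b])
        res = coarsening_kinetics(times, det)
        assert res.n_tracks == 2
        assert not res.single_droplet
        assert res.series["R_scaled"].max() == pytest.approx(1.0)


class TestPersistence:
    def test_rigid_rod_flags_unbounded(self, trajectory_factory):
        nm = 40
        frames = np.zeros((5, nm, 3))
        frames[:, :, 2] = np.arange(nm)
        traj = trajectory_factory(frames, nm)
        from condenseq.observables import persistence_length
        res = persistence_length(traj)
        assert res.unbounded and res.lp is None

    def test_freely_jointed_limit(self, trajectory_factory):
        # ideal chains sampled with zero bending stiffness: lp <= 2 monomers
        from condenseq.engine import _wlc_chain
        rng = np.random.default_rng(4)
        frames = np.array([_wlc_chain(60, 1.0, 0.0, rng, np.zeros(3))
                           for _ in range(200)])
        traj = trajectory_factory(frames, 60)
        from condenseq.observables import persistence_length
        res = persistence_length(traj, max_sep=6)
        assert not res.unbounded
        assert res.lp <= 2.0

    def test_ideal_wlc_sampler_matches_theory(self, trajectory_factory):
        # kappa = 15: <cos theta> = coth(k) - 1/k, lp = -1/ln<cos>
        from condenseq.engine import _wlc_chain
        rng = np.random.default_rng(9)
        frames = np.array([_wlc_chain(80, 1.0, 15.0, rng, np.zeros(3))
                           for _ in range(400)])
        traj = trajectory_factory(frames, 80)
        corr = tangent_correlation(traj, 20)
        expected = 1 / np.tanh(15.0) - 1 / 15.0
        assert corr[1] == pytest.approx(expected, abs=0.01)
        res = fit_persistence_length(corr, np.arange(21))
        assert res.lp == pytest.approx(-1 / np.log(expected), rel=0.1)
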