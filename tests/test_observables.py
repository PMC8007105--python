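import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from coevomc import fixtures
from coevomc.cgmodel import CA, SC
from coevomc.coevolution import CouplingMatrix
from coevomc.energetics import EnergyParams
from coevomc.observables import (
    WeightedEnsemble,
    box_concentration,
    calibrate_temperature,
    cluster_conformations,
    contact_probability,
    fraction_bound,
    fraction_from_kd,
    kd_from_fraction,
    pair_distance_distribution,
    per_residue_fluctuations,
    reweight_umbrella,
    rmsd,
    snapshot_is_bound,
    specific_heat,
)
from coevomc.sampling import Trajectory


def dimer_snapshot(sc_gap, n=2):
    """Two n-residue chains whose (0,0) SC pair sits `sc_gap` Å apart."""
    a = np.zeros((n, 4, 3))
    a[:, :, 0] = np.arange(n)[:, None] * 4.0
    a[:, SC, 2] = 1.0
    b = a.copy()
    b[:, :, 1] += 30.0
    b[0, SC] = a[0, SC] + np.array([0.0, 0.0, sc_gap])
    return [a, b]


def make_traj(states, trans_raw, T=1.0, k=0.5):
    traj = Trajectory(temperature=T, k_trans=k)
    traj.states = list(states)
    traj.steps = list(range(len(states)))
    traj.energies = [0.0] * len(states)
    traj.trans_raw = list(trans_raw)
    return traj


class TestReweighting:
    def test_k_one_gives_uniform_weights(self):
        traj = make_traj([None] * 5, [], k=1.0)
        ens = reweight_umbrella(traj)
        assert np.allclose(ens.weights, 0.2)
        assert ens.normalization == pytest.approx(1.0)

    def test_two_snapshot_hand_computed_ratio(self):
        # E_trans = 0 and -1, k = 0.5, beta = 1: weight ratio e^{-0.5*0}/e^{-0.5*-1}
        traj = make_traj([None, None], [0.0, -1.0], T=1.0, k=0.5)
        ens = reweight_umbrella(traj)
        assert ens.weights[1] / ens.weights[0] == pytest.approx(math.exp(0.5))

    def test_weights_normalized(self, rng):
        traj = make_traj([None] * 50, rng.normal(size=50), T=2.0, k=0.3)
        ens = reweight_umbrella(traj)
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_missing_trans_records_is_error(self):
        traj = make_traj([None] * 3, [], k=0.5)
        with pytest.raises(ValueError):
            reweight_umbrella(traj)


class TestFractionBound:
    params = EnergyParams()
    cm = CouplingMatrix(np.array([[2.0, 0.0], [0.0, 0.0]]))

    def test_separated_chains_are_unbound(self):
        ens = WeightedEnsemble.uniform([dimer_snapshot(20.0)] * 4)
        assert fraction_bound(ens, self.cm, self.params) == 0.0

    def test_contacting_chains_are_bound(self):
        ens = WeightedEnsemble.uniform([dimer_snapshot(5.0)] * 4)
        assert fraction_bound(ens, self.cm, self.params) == 1.0

    def test_repulsive_contact_does_not_bind(self):
        # positive energy contribution is not an attractive contact
        cm_rep = CouplingMatrix(np.array([[-2.0, 0.0], [0.0, 0.0]]))
        assert not snapshot_is_bound(dimer_snapshot(5.0), cm_rep, self.params)

    def test_weighted_mixture_matches_hand_count(self):
        snaps = [dimer_snapshot(5.0)] * 3 + [dimer_snapshot(20.0)] * 7
        w = np.arange(1.0, 11.0)
        w /= w.sum()
        ens = WeightedEnsemble(snaps, w)
        assert fraction_bound(ens, self.cm, self.params) == pytest.approx(
            w[:3].sum()
        )

    def test_single_chain_is_domain_error(self):
        snap = [np.zeros((2, 4, 3))]
        with pytest.raises(ValueError):
            snapshot_is_bound(snap, self.cm, self.params)


class TestDissociationConstant:
    V = 3.2e4  # nm^3

    def test_printed_triple_f03_gives_166_uM(self):
        kd = kd_from_fraction(0.3, self.V)
        assert kd * 1e6 == pytest.approx(166, rel=0.03)

    def test_direct_evaluation_at_f_half(self):
        kd = kd_from_fraction(0.5, self.V)
        assert kd * 1e6 == pytest.approx(51.9, rel=0.01)

    def test_strong_binding_limit(self):
        assert kd_from_fraction(0.999999, self.V) < 1e-12

    def test_roundtrip_identity_on_open_interval(self):
        for f in np.linspace(0.01, 0.99, 17):
            assert fraction_from_kd(
                kd_from_fraction(f, self.V), self.V
            ) == pytest.approx(f, abs=1e-12)

    def test_boundary_fractions_rejected(self):
        with pytest.raises(ValueError):
            kd_from_fraction(0.0, self.V)
        with pytest.raises(ValueError):
            kd_from_fraction(1.0, self.V)

    def test_two_molecules_in_reference_box_are_about_100_uM(self):
        c = box_concentration(2, self.V)
        assert c * 1e6 == pytest.approx(104, rel=0.01)

    def test_temperature_calibration_interpolates_crossing(self):
        T = [1.0, 2.0, 3.0, 4.0]
        f = [0.9, 0.7, 0.4, 0.2]
        t = calibrate_temperature(T, f, target_f=0.55)
        assert 2.0 < t < 3.0
        with pytest.raises(ValueError):
            calibrate_temperature(T, f, target_f=0.95)


class TestContactProbability:
    def test_single_snapshot_gives_binary_map(self):
        ens = WeightedEnsemble.uniform([dimer_snapshot(5.0)])
        cmap = contact_probability(ens, R=8.5)
        assert set(np.unique(cmap.probabilities)) <= {0.0, 1.0}

    def test_intra_quadrants_symmetric(self, rng):
        snaps = [
            [rng.normal(scale=5, size=(3, 4, 3)), rng.normal(scale=5, size=(3, 4, 3))]
            for _ in range(10)
        ]
        cmap = contact_probability(WeightedEnsemble.uniform(snaps), R=6.0)
        aa = cmap.quadrant(0, 0)
        bb = cmap.quadrant(1, 1)
        assert np.allclose(aa, aa.T) and np.allclose(bb, bb.T)
        assert np.allclose(cmap.quadrant(0, 1), cmap.quadrant(1, 0).T)

    def test_matches_brute_force_counting(self, rng):
        snaps = [
            [rng.normal(scale=4, size=(3, 4, 3)), rng.normal(scale=4, size=(3, 4, 3))]
            for _ in range(50)
        ]
        ens = WeightedEnsemble.uniform(snaps)
        cmap = contact_probability(ens, R=5.0)
        # oracle for one arbitrary inter-chain pair
        i, j = 1, 2
        count = sum(
            np.linalg.norm(s[0][i, SC] - s[1][j, SC]) <= 5.0 for s in snaps
        )
        assert cmap.quadrant(0, 1)[i, j] == pytest.approx(count / 50)

    def test_monotone_nonincreasing_in_R(self, rng):
        snaps = [
            [rng.normal(scale=4, size=(4, 4, 3))] for _ in range(20)
        ]
        ens = WeightedEnsemble.uniform(snaps)
        p_small = contact_probability(ens, R=4.0).probabilities
        p_large = contact_probability(ens, R=8.0).probabilities
        assert np.all(p_small <= p_large + 1e-12)


class TestRmsd:
    def test_identical_structures_give_zero(self, helix_chain):
        assert rmsd(helix_chain, helix_chain) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_gives_zero(self, helix_chain, rng):
        moved = helix_chain.copy()
        R = Rotation.random(random_state=rng).as_matrix()
        moved.coords = helix_chain.coords @ R.T + np.array([3.0, -2.0, 1.0])
        assert rmsd(moved, helix_chain) == pytest.approx(0.0, abs=1e-9)

    def test_hand_solvable_scaling_case(self):
        # y = 2x about the centroid: optimal rotation is identity, so
        # rmsd = sqrt(mean |x_i|^2) for centered x
        x = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], dtype=float)
        assert rmsd(x, 2 * x) == pytest.approx(1.0)

    def test_length_mismatch_raises(self, helix_chain):
        short = fixtures.make_toy_chain(4, "helix")
        with pytest.raises(ValueError):
            rmsd(helix_chain, short)


class TestFluctuations:
    def test_frozen_ensemble_has_zero_rmsf(self, helix_chain):
        snaps = [[helix_chain.coords.copy()] for _ in range(5)]
        rmsf = per_residue_fluctuations(WeightedEnsemble.uniform(snaps))
        assert np.allclose(rmsf, 0.0, atol=1e-9)

    def test_jittered_residue_shows_sqrt_variance(self):
        chain = fixtures.make_toy_chain(30, "strand")
        d = 0.4
        up, down = chain.coords.copy(), chain.coords.copy()
        up[15, CA, 2] += d
        down[15, CA, 2] -= d
        ens = WeightedEnsemble.uniform([[up], [down]])
        rmsf = per_residue_fluctuations(ens)
        assert rmsf[15] == pytest.approx(d, rel=0.05)
        assert rmsf[[0, 5, 25]].max() < 0.1 * d

    def test_global_translation_invisible_after_superposition(self, helix_chain):
        base = helix_chain.coords
        snaps = [[base + np.array([i * 5.0, 0, 0])] for i in range(4)]
        rmsf = per_residue_fluctuations(WeightedEnsemble.uniform(snaps))
        assert np.allclose(rmsf, 0.0, atol=1e-9)


class TestSpecificHeat:
    def test_constant_series_gives_zero(self):
        assert specific_heat(np.full(100, 3.3), T=2.0) == 0.0

    def test_two_level_closed_form(self):
        tl = fixtures.TwoLevelSystem()
        rng = np.random.default_rng(8)
        T = 0.9
        p = tl.exact_occupancy(T)
        e = tl.delta_e * (rng.random(200000) < p)
        c = specific_heat(e, T)
        assert c == pytest.approx(tl.exact_specific_heat(T), rel=0.05)

    def test_harmonic_equipartition(self):
        rng = np.random.default_rng(9)
        T = 1.7
        x = rng.normal(scale=math.sqrt(T), size=300000)
        c = specific_heat(0.5 * x * x, T)
        assert c == pytest.approx(0.5, rel=0.03)


class TestClustering:
    def test_two_copies_plus_outlier(self, helix_chain):
        far = fixtures.make_toy_chain(8, "strand")
        snaps = [[helix_chain.coords]] * 2 + [[far.coords]]
        ens = WeightedEnsemble.uniform(snaps)
        clusters = cluster_conformations(ens, cutoff=2.0)
        assert len(clusters) == 2
        assert clusters[0].population == pytest.approx(2 / 3)
        assert clusters[1].population == pytest.approx(1 / 3)

    def test_infinite_cutoff_gives_single_cluster(self, helix_chain):
        far = fixtures.make_toy_chain(8, "coil")
        ens = WeightedEnsemble.uniform([[helix_chain.coords], [far.coords]])
        clusters = cluster_conformations(ens, cutoff=1e9)
        assert len(clusters) == 1
        assert clusters[0].population == pytest.approx(1.0)

    def test_two_separated_basins_recovered(self, rng):
        helix = fixtures.make_toy_chain(8, "helix").coords
        strand = fixtures.make_toy_chain(8, "strand").coords
        snaps, labels = [], []
        for i in range(20):
            base = helix if i % 2 == 0 else strand
            snaps.append([base + rng.normal(scale=0.05, size=base.shape)])
            labels.append(i % 2)
        ens = WeightedEnsemble.uniform(snaps)
        clusters = cluster_conformations(ens, cutoff=3.0)
        assert len(clusters) == 2
        for c in clusters:
            member_labels = {labels[m] for m in c.members}
            assert len(member_labels) == 1

    def test_chain_relabeling_symmetry_for_identical_dimers(self):
        a = fixtures.make_toy_chain(5, "helix").coords
        b = a + np.array([12.0, 0, 0])
        snap_ab, snap_ba = [a, b], [b, a]
        ens = WeightedEnsemble.uniform([snap_ab, snap_ba])
        clusters = cluster_conformations(ens, cutoff=1.0, identical_chains=True)
        assert len(clusters) == 1


class TestDistanceDistribution:
    def test_frozen_snapshot_single_pair_is_delta(self):
        snap = dimer_snapshot(20.0)
        ens = WeightedEnsemble.uniform([snap])
        hist, edges = pair_distance_distribution(
            ens, [(0, 0)], [(1, 0)], bins=10, bead=CA, range_=(0.0, 50.0)
        )
        assert np.count_nonzero(hist) == 1

    def test_two_equal_weight_snapshots_two_equal_bins(self):
        s1, s2 = dimer_snapshot(20.0), dimer_snapshot(20.0)
        s2[1] = s2[1] + np.array([0.0, 5.0, 0.0])
        ens = WeightedEnsemble.uniform([s1, s2])
        hist, edges = pair_distance_distribution(
            ens, [(0, 0)], [(1, 0)], bins=50, bead=CA, range_=(0.0, 60.0)
        )
        nonzero = hist[hist > 0]
        assert len(nonzero) == 2
        assert nonzero[0] == pytest.approx(nonzero[1])

    def test_matches_direct_distance_computation(self, rng):
        snaps = [
            [rng.normal(size=(3, 4, 3)), rng.normal(size=(3, 4, 3))]
            for _ in range(30)
        ]
        ens = WeightedEnsemble.uniform(snaps)
        sel_a = [(0, 0), (0, 1)]
        sel_b = [(1, 2)]
        hist, edges = pair_distance_distribution(
            ens, sel_a, sel_b, bins=8, bead=SC
        )
        direct = [
            np.linalg.norm(s[ca][ra, SC] - s[cb][rb, SC])
            for s in snaps for ca, ra in sel_a for cb, rb in sel_b
        ]
        expected, _ = np.histogram(direct, bins=edges, density=True)
        assert np.allclose(hist, expected)
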