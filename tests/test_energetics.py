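import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from coevomc import fixtures
from coevomc.cgmodel import BoxSpec, CGChain, CGSystem, SC
from coevomc.coevolution import CouplingMatrix
from coevomc.energetics import (
    DihedralPropensity,
    EnergyModel,
    EnergyParams,
    Restraint,
    contact_energy,
    dihedral_energy,
    dihedral_energy_from_angles,
    hardcore_check,
    restraint_energy,
    total_energy,
)


def two_bead_dimer(distance, n=1, box=80.0):
    """Two 1-residue 'chains' whose SC beads sit `distance` apart."""
    coords_a = np.zeros((1, 4, 3))
    coords_a[0] = [[0, 0, 0], [1.5, 0, 0], [2.3, 1.2, 0], [1.5, -2.4, 0]]
    coords_b = coords_a.copy()
    coords_b[:, :, 1] += 30.0  # keep backbones apart
    coords_b[0, SC] = coords_a[0, SC] + np.array([0.0, 0.0, distance])
    a = CGChain("A", coords_a)
    b = CGChain("A", coords_b)
    return CGSystem([a, b], BoxSpec("cube", box / 10.0 * 10))


class TestContactEnergy:
    def test_pair_beyond_interaction_range_contributes_zero(self):
        system = two_bead_dimer(9.0)
        cis = CouplingMatrix(np.zeros((1, 1)))
        trans = CouplingMatrix(np.array([[-2.0]]))
        _, tr = contact_energy(system, cis, trans, EnergyParams())
        assert tr == 0.0

    def test_sign_convention_contribution_is_eps0_times_J(self):
        system = two_bead_dimer(8.0)
        cis = CouplingMatrix(np.zeros((1, 1)))
        trans = CouplingMatrix(np.array([[-2.0]]))
        _, tr = contact_energy(system, cis, trans, EnergyParams(eps0=-1.0))
        assert tr == pytest.approx(2.0)

    def test_step_function_boundary_inclusive(self):
        params = EnergyParams()
        at_R = two_bead_dimer(params.R)
        trans = CouplingMatrix(np.array([[1.0]]))
        cis = CouplingMatrix(np.zeros((1, 1)))
        _, tr = contact_energy(at_R, cis, trans, params)
        assert tr == pytest.approx(-1.0)

    def test_matches_all_pairs_brute_force(self, rng):
        n = 6
        chain_a = fixtures.make_toy_chain(n, "helix", "ACDEFG")
        chain_b = fixtures.make_toy_chain(n, "strand", "HIKLMN")
        chain_b.coords = chain_b.coords + np.array([8.0, 2.0, -3.0])
        system = CGSystem([chain_a, chain_b], BoxSpec("cube", 30.0))
        Jc = rng.normal(size=(n, n))
        Jc = (Jc + Jc.T) / 2
        Jt = rng.normal(size=(n, n))
        params = EnergyParams()
        cis, trans = contact_energy(
            system, CouplingMatrix(Jc), CouplingMatrix(Jt), params
        )
        # oracle: explicit double loop over residue pairs
        exp_cis = 0.0
        for ch in (chain_a, chain_b):
            for i in range(n):
                for j in range(i + 3, n):
                    if np.linalg.norm(ch.sc_coords[i] - ch.sc_coords[j]) <= params.R:
                        exp_cis += params.eps0 * Jc[i, j]
        exp_trans = 0.0
        for i in range(n):
            for j in range(n):
                d = np.linalg.norm(chain_a.sc_coords[i] - chain_b.sc_coords[j])
                if d <= params.R:
                    exp_trans += params.eps0 * Jt[i, j]
        assert cis == pytest.approx(exp_cis, abs=1e-9)
        assert trans == pytest.approx(exp_trans, abs=1e-9)


class TestHardCore:
    def test_nonbonded_overlap_detected(self):
        system = two_bead_dimer(1.9)
        assert not hardcore_check(system, EnergyParams())

    def test_bonded_and_same_residue_pairs_excluded(self, helix_chain, big_box):
        # N-CA bond (1.458 A) and intra-residue beads are below R_HC by design
        system = CGSystem([helix_chain], big_box)
        assert hardcore_check(system, EnergyParams())

    def test_wall_violation_detected(self, helix_chain):
        system = CGSystem([helix_chain], BoxSpec("cube", 1.0))
        assert not hardcore_check(system, EnergyParams())

    def test_matches_brute_force_scan(self, rng):
        chain = fixtures.make_toy_chain(6, "coil")
        other = fixtures.make_toy_chain(6, "coil")
        other.coords = other.coords + rng.uniform(3, 6, size=3)
        system = CGSystem([chain, other], BoxSpec("cube", 40.0))
        params = EnergyParams()
        a, b = chain.flat_coords(), other.flat_coords()
        inter_ok = np.min(
            np.linalg.norm(a[:, None] - b[None], axis=-1)
        ) >= params.R_HC

        def intra_ok(c):
            n = len(c) // 4
            for i in range(len(c)):
                for j in range(i + 1, len(c)):
                    ri, rj = i // 4, j // 4
                    if ri == rj:
                        continue
                    if rj == ri + 1 and i % 4 == 2 and j % 4 == 0:
                        continue
                    if np.linalg.norm(c[i] - c[j]) < params.R_HC:
                        return False
            return True

        expected = inter_ok and intra_ok(a) and intra_ok(b)
        assert hardcore_check(system, params) == expected


class TestDihedralEnergy:
    def test_zero_propensity_gives_zero(self, helix_chain):
        prop = DihedralPropensity.uniform(8)
        assert dihedral_energy(helix_chain, prop, EnergyParams()) == 0.0

    def test_helix_at_alpha_centers_reaches_full_well_depth(self):
        # interior residues sit exactly at (-63, -44): factor exp(0) = 1 per dihedral
        chain = fixtures.make_toy_chain(4, "helix")
        prop = DihedralPropensity.uniform(4, w_alpha=1.0)
        params = EnergyParams()
        e = dihedral_energy(chain, prop, params)
        n_defined = 2 * 4 - 2  # phi for 1..3, psi for 0..2
        # beta wells overlap a little, so e is at least as deep as -eps_dih * n
        assert e <= -params.eps_dih * n_defined
        beta_extra = (
            math.exp(-((63 - 105) ** 2) / (2 * 40**2) / 1)  # placeholder guard
        )
        assert e == pytest.approx(
            -params.eps_dih * n_defined, rel=0.05
        )

    def test_matches_independent_scalar_reimplementation(self, rng):
        params = EnergyParams()
        n = 5
        prop = DihedralPropensity(rng.random(n), rng.random(n))
        angles = np.column_stack([
            rng.uniform(-180, 180, n), rng.uniform(-180, 180, n)
        ])
        angles[0, 0] = np.nan
        angles[-1, 1] = np.nan

        def wrap(x):
            return (x + 180.0) % 360.0 - 180.0

        expected = 0.0
        for i in range(n):
            for col, (c_a, c_b) in enumerate(
                [(params.phi0_alpha, params.phi0_beta),
                 (params.psi0_alpha, params.psi0_beta)]
            ):
                x = angles[i, col]
                if not np.isfinite(x):
                    continue
                expected -= params.eps_dih * (
                    prop.w_alpha[i] * math.exp(-wrap(x - c_a) ** 2 / (2 * 30**2))
                    + prop.w_beta[i] * math.exp(-wrap(x - c_b) ** 2 / (2 * 40**2))
                )
        got = dihedral_energy_from_angles(angles, prop, params)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_periodicity_in_every_angle(self, rng):
        params = EnergyParams()
        prop = DihedralPropensity(rng.random(3), rng.random(3))
        angles = np.column_stack([
            rng.uniform(-180, 180, 3), rng.uniform(-180, 180, 3)
        ])
        shifted = angles + 360.0
        assert dihedral_energy_from_angles(
            shifted, prop, params
        ) == pytest.approx(
            dihedral_energy_from_angles(angles, prop, params), abs=1e-10
        )

    def test_length_mismatch_raises(self, helix_chain):
        with pytest.raises(ValueError):
            dihedral_energy(helix_chain, DihedralPropensity.uniform(5),
                            EnergyParams())


class TestRestraints:
    def test_inside_well_is_zero(self, helix_chain, big_box):
        system = CGSystem([helix_chain], big_box)
        d = np.linalg.norm(
            helix_chain.ca_coords[0] - helix_chain.ca_coords[5]
        )
        r = Restraint(0, 0, 0, 5, d - 1.0, d + 1.0)
        assert restraint_energy(system, [r]) == 0.0

    def test_outside_well_is_infinite(self, helix_chain, big_box):
        system = CGSystem([helix_chain], big_box)
        d = np.linalg.norm(
            helix_chain.ca_coords[0] - helix_chain.ca_coords[5]
        )
        r = Restraint(0, 0, 0, 5, d + 0.01, d + 2.0)
        assert restraint_energy(system, [r]) == math.inf

    def test_multiwell_decisions_match_per_pair_oracle(self, rng, big_box):
        chain = fixtures.make_toy_chain(10, "coil")
        system = CGSystem([chain], big_box)
        restraints = []
        for _ in range(3):
            i, j = rng.choice(10, 2, replace=False)
            d = np.linalg.norm(chain.ca_coords[i] - chain.ca_coords[j])
            lo = d - 1.0 + rng.uniform(0, 2)  # some wells will be violated
            restraints.append(Restraint(0, int(i), 0, int(j), lo, lo + 1.5))
        expected_ok = all(
            r.r_min
            <= np.linalg.norm(chain.ca_coords[r.res_i] - chain.ca_coords[r.res_j])
            <= r.r_max
            for r in restraints
        )
        got = restraint_energy(system, restraints)
        assert (got == 0.0) == expected_ok


class TestTotalEnergy:
    def test_vacuum_chain_scores_zero(self, big_box):
        chain = fixtures.make_toy_chain(4, "strand")
        system = CGSystem([chain], big_box)
        b = total_energy(system, CouplingMatrix(np.zeros((4, 4))))
        assert b.total == 0.0 and not b.forbidden

    def test_k_zero_silences_trans_term(self):
        system, cis, trans = fixtures.make_toy_dimer(
            n_residues=3, separation=5.0, trans_coupling=4.0, pattern="uniform"
        )
        params = EnergyParams(k_trans=0.0)
        b = total_energy(system, cis, trans, params=params)
        assert b.contact_trans == 0.0
        assert b.contact_trans_raw != 0.0
        assert b.total == b.contact_cis + b.dihedral

    def test_breakdown_components_sum_to_total(self, rng):
        system, cis, trans = fixtures.make_toy_dimer(
            n_residues=4, separation=7.0, trans_coupling=2.0, pattern="uniform"
        )
        prop = DihedralPropensity(rng.random(4), rng.random(4))
        params = EnergyParams(k_trans=0.5)
        b = total_energy(system, cis, trans, prop, (), params)
        assert b.total == pytest.approx(
            b.contact_cis + 0.5 * b.contact_trans_raw + b.dihedral
        )

    def test_invariance_under_rigid_motion_of_whole_system(self, rng):
        system, cis, trans = fixtures.make_toy_dimer(
            n_residues=4, separation=6.0, trans_coupling=1.5, pattern="uniform"
        )
        prop = DihedralPropensity(rng.random(4), rng.random(4))
        model = EnergyModel(cm_cis=cis, cm_trans=trans, prop=prop)
        e1 = model.breakdown(system)
        R = Rotation.random(random_state=rng).as_matrix()
        shift = rng.uniform(-2, 2, 3)
        moved = system.copy()
        for c in moved.chains:
            c.coords = c.coords @ R.T + shift
        e2 = model.breakdown(moved)
        for field in ("contact_cis", "contact_trans_raw", "dihedral"):
            assert getattr(e2, field) == pytest.approx(
                getattr(e1, field), rel=1e-9, abs=1e-12
            )
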