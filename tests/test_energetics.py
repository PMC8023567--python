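"""Reference-state geometry, nonbonded energies and rotamer placement."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mutfep import (
    AtomRecord,
    Frame,
    NonbondedParams,
    ReferenceStateSpec,
    RotamerConformer,
    build_reference_state,
    crf_constant,
    fit_rotamer,
    lj_energy,
    perturbation_energy,
    rf_coulomb_energy,
    softcore_lj_energy,
)
from mutfep.energetics import (
    COULOMB_PREFACTOR,
    REFERENCE_C6_SQRT,
    REFERENCE_C12_SQRT,
    combine_lj,
    effective_vdw_radius,
    group_energy,
    pair_energy,
    system_energy,
)


class TestReactionField:
    def test_crf_limits(self):
        assert crf_constant(1.0) == 0.0
        assert crf_constant(61.0) == pytest.approx(120.0 / 123.0)
        assert crf_constant(1e9) == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(ValueError):
            crf_constant(0.5)

    def test_zero_at_cutoff(self):
        nb = NonbondedParams()
        assert rf_coulomb_energy(1.0, -1.0, 1.4, nb) == pytest.approx(0.0, abs=1e-12)

    def test_vacuum_limit_is_shifted_coulomb(self):
        nb = NonbondedParams(eps_rf=1.0)
        expected = COULOMB_PREFACTOR * (1.0 / 0.5 - 1.0 / 1.4)
        assert rf_coulomb_energy(1.0, 1.0, 0.5, nb) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(178.6, abs=0.2)

    def test_double_implementation_agreement(self):
        """Independent scalar transcription of the Barker-Watts form."""
        nb = NonbondedParams()
        crf = 2 * (nb.eps_rf - 1) / (2 * nb.eps_rf + 1)
        rng = np.random.default_rng(0)
        for _ in range(50):
            q1, q2 = rng.uniform(-1, 1, 2)
            r = rng.uniform(0.05, 1.4)
            independent = (
                138.9354 * q1 * q2
                * (1 / r + crf * r**2 / (2 * 1.4**3) - (1 + crf / 2) / 1.4)
            )
            assert rf_coulomb_energy(q1, q2, r, nb) == pytest.approx(independent, abs=1e-10)

    def test_beyond_cutoff_is_zero_and_bad_r_rejected(self):
        nb = NonbondedParams()
        assert rf_coulomb_energy(1.0, 1.0, 2.0, nb) == 0.0
        with pytest.raises(ValueError):
            rf_coulomb_energy(1.0, 1.0, 0.0, nb)

    def test_continuity_near_cutoff(self):
        nb = NonbondedParams()
        just_inside = rf_coulomb_energy(1.0, 1.0, 1.4 - 1e-9, nb)
        assert abs(just_inside) < 1e-6


class TestLennardJones:
    def test_dummy_atom_is_non_interacting(self):
        assert lj_energy(0.0, 0.0, 0.3) == 0.0

    def test_minimum_depth(self):
        c6 = REFERENCE_C6_SQRT**2
        c12 = REFERENCE_C12_SQRT**2
        r_min = (2 * c12 / c6) ** (1 / 6)
        assert lj_energy(c6, c12, r_min) == pytest.approx(-(c6**2) / (4 * c12), rel=1e-12)
        # minimum: derivative changes sign
        assert lj_energy(c6, c12, r_min * 0.99) > lj_energy(c6, c12, r_min)
        assert lj_energy(c6, c12, r_min * 1.01) > lj_energy(c6, c12, r_min)

    def test_effective_vdw_radius_of_reference_atom(self):
        assert effective_vdw_radius() == pytest.approx(0.662, abs=5e-4)


class TestSoftCore:
    def test_hard_limit_recovers_plain_lj(self):
        c6, c12 = 1e-3, 1e-6
        for r in (0.1, 0.3, 0.7, 1.2):
            assert softcore_lj_energy(c6, c12, r, alpha_sc=0.0) == pytest.approx(
                lj_energy(c6, c12, r), rel=1e-12
            )
            # vanishing softness converges uniformly on r >= 0.1
            soft = softcore_lj_energy(c6, c12, r, alpha_sc=1.51, lambda_sc=1e-6)
            assert soft == pytest.approx(lj_energy(c6, c12, r), rel=1e-6)

    def test_finite_at_origin(self):
        c6, c12 = 1e-3, 1e-6
        s = 1.51 * (c12 / c6)
        expected = c12 / s**2 - c6 / s
        assert softcore_lj_energy(c6, c12, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_double_implementation_agreement(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            c6 = rng.uniform(1e-4, 1e-2)
            c12 = rng.uniform(1e-7, 1e-5)
            r = rng.uniform(0.0, 1.2)
            s = 1.51 * c12 / c6
            independent = c12 / (s + r**6) ** 2 - c6 / (s + r**6)
            assert softcore_lj_energy(c6, c12, r) == pytest.approx(independent, abs=1e-10)

    def test_c12_without_c6_rejected(self):
        with pytest.raises(ValueError, match="without C6"):
            softcore_lj_energy(0.0, 1e-6, 0.5)


class TestReferenceStateGeometry:
    def test_rdr_placement(self):
        atoms = build_reference_state(ReferenceStateSpec("RDR"), (0, 0, 0), (1, 0, 0))
        assert [a.name for a in atoms] == ["D", "A"]
        np.testing.assert_allclose(atoms[0].position, [0.153, 0, 0], atol=1e-12)
        np.testing.assert_allclose(atoms[1].position, [0.306, 0, 0], atol=1e-12)
        assert not atoms[0].soft and atoms[0].c6_sqrt == 0.0  # dummy
        assert atoms[1].soft

    def test_r2r_placement(self):
        atoms = build_reference_state(ReferenceStateSpec("R2R"), (0, 0, 0), (1, 0, 0))
        np.testing.assert_allclose(atoms[0].position, [0.252, 0, 0], atol=1e-12)
        np.testing.assert_allclose(atoms[1].position, [0.603, 0, 0], atol=1e-12)
        assert all(a.soft for a in atoms)

    def test_bond_lengths_preserved_for_arbitrary_directions(self):
        rng = np.random.default_rng(2)
        for variant in ("RDR", "R2R"):
            spec = ReferenceStateSpec(variant)
            ca = rng.normal(size=3)
            d = rng.normal(size=3)
            atoms = build_reference_state(spec, ca, d / np.linalg.norm(d))
            assert np.linalg.norm(atoms[0].position - ca) == pytest.approx(
                spec.bond_lengths[0], abs=1e-12
            )
            assert np.linalg.norm(atoms[1].position - atoms[0].position) == pytest.approx(
                spec.bond_lengths[1], abs=1e-12
            )

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError, match="zero direction"):
            build_reference_state(ReferenceStateSpec("RDR"), (0, 0, 0), (0, 0, 0))


def _make_rotamer(side_positions, ca=(0.0, 0.0, 0.0)):
    atoms = [AtomRecord("CA", np.asarray(ca, dtype=float))]
    for i, p in enumerate(side_positions):
        atoms.append(AtomRecord(f"C{i+1}", np.asarray(p, dtype=float)))
    return RotamerConformer(atoms=atoms, side_chain_indices=list(range(1, len(atoms))))


class TestRotamerFit:
    def test_already_aligned_is_identity(self):
        ref = build_reference_state(ReferenceStateSpec("RDR"), (0, 0, 0), (1, 0, 0))
        rot = _make_rotamer([(0.2, 0.0, 0.0), (0.4, 0.0, 0.0)])
        placed = fit_rotamer((0, 0, 0), ref, rot)
        for orig, new in zip(rot.atoms, placed):
            np.testing.assert_allclose(new, orig.position, atol=1e-12)

    def test_closed_form_alignment(self):
        """After fitting, the COG sits at distance d along the soft-centroid axis."""
        ref = build_reference_state(ReferenceStateSpec("RDR"), (0, 0, 0), (1, 0, 0))
        rot = _make_rotamer([(0.0, 0.3, 0.0)])
        d = 0.3
        placed = fit_rotamer((0, 0, 0), ref, rot)
        cog = np.mean(placed[1:], axis=0)
        np.testing.assert_allclose(cog, [d, 0, 0], atol=1e-12)

    def test_rigidity(self):
        rng = np.random.default_rng(3)
        rot = _make_rotamer(rng.normal(scale=0.2, size=(4, 3)), ca=rng.normal(size=3))
        ref = build_reference_state(ReferenceStateSpec("R2R"), (1, 1, 1), (0, 0, 1))
        placed = fit_rotamer((1, 1, 1), ref, rot)
        orig = np.array([a.position for a in rot.atoms])
        new = np.array(placed)
        for i, j in itertools.combinations(range(len(orig)), 2):
            assert np.linalg.norm(orig[i] - orig[j]) == pytest.approx(
                np.linalg.norm(new[i] - new[j]), abs=1e-12
            )

    def test_objective_improves_and_matches_rotation_grid_search(self):
        rng = np.random.default_rng(4)
        ref = build_reference_state(ReferenceStateSpec("RDR"), (0, 0, 0), (0.6, 0.8, 0.0))
        centroid = np.mean([a.position for a in ref if a.soft], axis=0)
        best_overall = True
        for _ in range(25):
            rot = _make_rotamer(rng.normal(scale=0.25, size=(3, 3)))
            pre = np.linalg.norm(rot.side_chain_cog() - centroid)
            placed = fit_rotamer((0, 0, 0), ref, rot)
            cog = np.mean([placed[i] for i in rot.side_chain_indices], axis=0)
            post = float(np.linalg.norm(cog - centroid))
            assert post <= pre + 1e-12
            # brute-force SO(3) search over random rotations
            grid = Rotation.random(2000, random_state=12345)
            arm = rot.side_chain_cog() - rot.ca_position
            candidates = np.linalg.norm(grid.apply(arm) - centroid, axis=1)
            assert post <= candidates.min() + 1e-6
        assert best_overall

    def test_degenerate_rotamer_rejected(self):
        ref = build_reference_state(ReferenceStateSpec("RDR"), (0, 0, 0), (1, 0, 0))
        rot = _make_rotamer([(0.0, 0.0, 0.0)])
        with pytest.raises(ValueError, match="undefined orientation"):
            fit_rotamer((0, 0, 0), ref, rot)


class TestPerturbationEnergy:
    nb = NonbondedParams()

    def _frame(self, env_atoms):
        return Frame(atoms=env_atoms, selections={"environment": list(range(len(env_atoms)))})

    def test_identical_rotamer_and_reference_cancel(self):
        env = [AtomRecord("O", (0.9, 0, 0), charge=0.0, c6_sqrt=0.05, c12_sqrt=0.01)]
        ref = build_reference_state(ReferenceStateSpec("RDR"), (0, 0, 0), (1, 0, 0))
        frame = self._frame(env)
        assert perturbation_energy(frame, ref, ref, self.nb) == pytest.approx(0.0, abs=1e-12)

    def test_empty_environment_gives_zero(self):
        frame = Frame(atoms=[], selections={"environment": []})
        ref = build_reference_state(ReferenceStateSpec("RDR"), (0, 0, 0), (1, 0, 0))
        side = [AtomRecord("CB", (0.2, 0, 0), c6_sqrt=0.05, c12_sqrt=0.01)]
        assert perturbation_energy(frame, side, ref, self.nb) == 0.0

    def test_three_particle_hand_sum(self):
        env = [
            AtomRecord("O1", (0.5, 0.0, 0.0), charge=-0.5, c6_sqrt=0.04, c12_sqrt=0.002),
            AtomRecord("O2", (0.0, 0.6, 0.0), charge=0.25, c6_sqrt=0.05, c12_sqrt=0.003),
        ]
        side = [AtomRecord("CB", (0.1, 0.1, 0.0), charge=0.2, c6_sqrt=0.06, c12_sqrt=0.004)]
        ref = build_reference_state(ReferenceStateSpec("RDR"), (0, 0, 0), (1, 0, 0))
        frame = self._frame(env)

        def hand_pair(a, b, soft):
            r = float(np.linalg.norm(a.position - b.position))
            c6 = a.c6_sqrt * b.c6_sqrt
            c12 = a.c12_sqrt * b.c12_sqrt
            if soft:
                s = 1.51 * c12 / c6 if c6 else 0.0
                e = c12 / (s + r**6) ** 2 - c6 / (s + r**6) if c6 else 0.0
            else:
                e = c12 / r**12 - c6 / r**6
            if a.charge and b.charge:
                crf = 2 * (61 - 1) / (2 * 61 + 1)
                e += 138.9354 * a.charge * b.charge * (
                    1 / r + crf * r**2 / (2 * 1.4**3) - (1 + crf / 2) / 1.4
                )
            return e

        expected = sum(hand_pair(side[0], e, soft=False) for e in env)
        expected -= sum(hand_pair(a, e, soft=True) for a in ref if a.soft for e in env)
        assert perturbation_energy(frame, side, ref, self.nb) == pytest.approx(
            expected, abs=1e-9
        )

    def test_overlapping_physical_atoms_rejected(self):
        a = AtomRecord("C1", (0, 0, 0), c6_sqrt=0.05, c12_sqrt=0.01)
        b = AtomRecord("C2", (0, 0, 1e-6), c6_sqrt=0.05, c12_sqrt=0.01)
        with pytest.raises(ValueError, match="overlapping physical atoms"):
            pair_energy(a, b, self.nb)

    def test_permutation_invariance_and_additivity(self):
        rng = np.random.default_rng(5)
        atoms = [
            AtomRecord(f"X{i}", rng.uniform(0, 1.0, 3), charge=rng.uniform(-0.3, 0.3),
                       c6_sqrt=0.04, c12_sqrt=0.005)
            for i in range(6)
        ]
        probe = [AtomRecord("P", (0.5, 0.5, 0.5), charge=0.1, c6_sqrt=0.04, c12_sqrt=0.005)]
        total = group_energy(probe, atoms, self.nb)
        shuffled = group_energy(probe, atoms[::-1], self.nb)
        split = group_energy(probe, atoms[:3], self.nb) + group_energy(probe, atoms[3:], self.nb)
        assert total == pytest.approx(shuffled, abs=1e-12)
        assert total == pytest.approx(split, abs=1e-12)

    def test_system_energy_matches_independent_pair_loop(self):
        rng = np.random.default_rng(6)
        atoms = [
            AtomRecord(f"X{i}", rng.uniform(0, 1.2, 3), charge=rng.uniform(-0.2, 0.2),
                       c6_sqrt=0.05, c12_sqrt=0.006)
            for i in range(5)
        ]
        expected = 0.0
        for i in range(5):
            for j in range(5):
                if i < j:
                    expected += pair_energy(atoms[i], atoms[j], self.nb)
        assert system_energy(atoms, self.nb) == pytest.approx(expected, abs=1e-12)
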