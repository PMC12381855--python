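"""Coulomb energies and interaction-energy assembly against brute-force oracles."""

import math

import numpy as np
import pytest

from chdamp.damping import DampingScheme, PointCharge, apply_damping
from chdamp.electrostatics import (
    COULOMB_K,
    InteractionRecord,
    assemble_ch_interaction,
    assemble_qm_interaction,
    ch_columns,
    charge_self_energy,
    coulomb_cross_energy,
    frame_to_records,
    records_to_frame,
)
from chdamp.errors import DataError
from chdamp.synthetic import SurrogateParams, surrogate_self_energy


def random_charges(rng, n, center=(0.0, 0.0, 0.0), spread=5.0):
    out = []
    for _ in range(n):
        pos = tuple(np.asarray(center) + rng.uniform(-spread, spread, 3))
        out.append(PointCharge(pos, float(rng.uniform(-1, 1))))
    return out


def brute_cross(a, b):
    return sum(
        COULOMB_K * ca.charge * cb.charge / math.dist(ca.position, cb.position)
        for ca in a
        for cb in b
    )


def brute_self(charges):
    return sum(
        COULOMB_K * charges[i].charge * charges[j].charge
        / math.dist(charges[i].position, charges[j].position)
        for i in range(len(charges))
        for j in range(i + 1, len(charges))
    )


class TestCoulombCross:
    def test_empty_set_is_zero(self):
        assert coulomb_cross_energy([], [PointCharge((0, 0, 0), 1.0)]) == 0.0

    def test_unit_pair_gives_coulomb_constant(self):
        a = [PointCharge((0.0, 0.0, 0.0), 1.0)]
        b = [PointCharge((1.0, 0.0, 0.0), -1.0)]
        assert coulomb_cross_energy(a, b) == pytest.approx(-332.0637, abs=1e-12)

    def test_matches_brute_force(self, rng):
        a = random_charges(rng, 30)
        b = random_charges(rng, 40, center=(20.0, 0.0, 0.0))
        assert coulomb_cross_energy(a, b) == pytest.approx(brute_cross(a, b), rel=1e-9)

    def test_coincident_charges_rejected(self):
        a = [PointCharge((0.0, 0.0, 0.0), 1.0)]
        with pytest.raises(DataError):
            coulomb_cross_energy(a, [PointCharge((0.0, 0.0, 0.0), -1.0)])

    def test_symmetry_under_swap_and_rigid_motion(self, rng):
        a = random_charges(rng, 10)
        b = random_charges(rng, 12, center=(15.0, 0.0, 0.0))
        e = coulomb_cross_energy(a, b)
        assert coulomb_cross_energy(b, a) == pytest.approx(e, rel=1e-12)
        # random rotation + translation of the whole system
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        rot = q * np.sign(np.diag(r))
        shift = rng.uniform(-30, 30, 3)

        def move(cs):
            return [
                PointCharge(tuple(rot @ np.array(c.position) + shift), c.charge) for c in cs
            ]

        assert coulomb_cross_energy(move(a), move(b)) == pytest.approx(e, rel=1e-9)

    def test_bilinearity_in_one_set(self, rng):
        a = random_charges(rng, 8)
        b = random_charges(rng, 9, center=(12.0, 0.0, 0.0))
        e = coulomb_cross_energy(a, b)
        scaled = [PointCharge(c.position, 0.37 * c.charge) for c in b]
        assert coulomb_cross_energy(a, scaled) == pytest.approx(0.37 * e, rel=1e-12)

    def test_damped_energy_equals_per_charge_scaling(self, rng):
        """apply_damping then Coulomb = scaling each charge's undamped
        contribution by its own attenuation factor (exact bilinearity)."""
        kernel = random_charges(rng, 5)
        kern_coords = [c.position for c in kernel]
        env = random_charges(rng, 15, center=(6.0, 0.0, 0.0))
        scheme = DampingScheme(3.0)
        damped = apply_damping(env, kern_coords, scheme)
        e_damped = coulomb_cross_energy(kernel, damped)
        per_charge = sum(
            (d.charge / c.charge) * coulomb_cross_energy(kernel, [c])
            for c, d in zip(env, damped)
        )
        assert e_damped == pytest.approx(per_charge, rel=1e-9)


class TestSelfEnergy:
    def test_single_charge_is_zero(self):
        assert charge_self_energy([PointCharge((0, 0, 0), 2.0)]) == 0.0

    def test_equilateral_triangle(self):
        h = math.sqrt(3) / 2
        charges = [
            PointCharge((0.0, 0.0, 0.0), 1.0),
            PointCharge((1.0, 0.0, 0.0), 1.0),
            PointCharge((0.5, h, 0.0), 1.0),
        ]
        assert charge_self_energy(charges) == pytest.approx(3 * 332.0637, rel=1e-12)

    def test_matches_brute_force(self, rng):
        charges = random_charges(rng, 25)
        assert charge_self_energy(charges) == pytest.approx(brute_self(charges), rel=1e-9)

    def test_union_decomposition(self, rng):
        """self(A ∪ B) = self(A) + self(B) + cross(A, B)."""
        a = random_charges(rng, 10)
        b = random_charges(rng, 12, center=(14.0, 0.0, 0.0))
        assert charge_self_energy(a + b) == pytest.approx(
            charge_self_energy(a) + charge_self_energy(b) + coulomb_cross_energy(a, b),
            rel=1e-9,
        )


class TestAssembly:
    def test_qm_noninteracting_limit(self):
        assert assemble_qm_interaction(-90.0, -60.0, -30.0) == 0.0

    def test_qm_arithmetic(self):
        assert assemble_qm_interaction(-100.0, -60.0, -30.0) == pytest.approx(-10.0)

    def test_ch_zero_charges(self):
        assert assemble_ch_interaction(-50.0, -50.0, []) == 0.0

    def test_recovers_planted_cross_term_from_surrogate_totals(self, rng):
        """Totals built as intra + cross + self must give back the cross term."""
        params = SurrogateParams(noise_sigma=0.0)
        kernel = random_charges(rng, 8)
        env = random_charges(rng, 12, center=(8.0, 0.0, 0.0))
        planted_cross = coulomb_cross_energy(kernel, env)
        e_kern = surrogate_self_energy(kernel, params)
        e_in = e_kern + planted_cross + charge_self_energy(env)
        assert assemble_ch_interaction(e_in, e_kern, env) == pytest.approx(
            planted_cross, rel=1e-9
        )
        # QM branch: dimer total minus monomer totals
        e_pair = surrogate_self_energy(kernel + env, params)
        e_res = surrogate_self_energy(env, params)
        from chdamp.synthetic import surrogate_reference_energy

        assert assemble_qm_interaction(e_pair, e_kern, e_res) == pytest.approx(
            surrogate_reference_energy(kernel, env, params), rel=1e-9
        )

    def test_distant_charge_interaction_vanishes(self):
        """A single charge 50 Å from a neutral, dipole-free kernel interacts
        below 1e-3 kcal/mol."""
        kernel = [
            PointCharge((-0.5, 0.0, 0.0), 0.4),
            PointCharge((0.0, 0.0, 0.0), -0.8),
            PointCharge((0.5, 0.0, 0.0), 0.4),
        ]
        env = [PointCharge((50.0, 0.0, 0.0), 1.0)]
        params = SurrogateParams(noise_sigma=0.0)
        e_kern = surrogate_self_energy(kernel, params)
        e_in = e_kern + coulomb_cross_energy(kernel, env) + charge_self_energy(env)
        assert abs(assemble_ch_interaction(e_in, e_kern, env)) < 1e-3

    def test_chd_approaches_ch_as_r0_vanishes(self, rng):
        kernel = random_charges(rng, 5)
        kern_coords = [c.position for c in kernel]
        env = random_charges(rng, 10, center=(5.0, 0.0, 0.0))
        e_ch = coulomb_cross_energy(kernel, env)
        diffs = []
        for r0 in (2.0, 1.0, 0.1, 0.01):
            damped = apply_damping(env, kern_coords, DampingScheme(r0))
            diffs.append(abs(coulomb_cross_energy(kernel, damped) - e_ch))
        assert all(b <= a for a, b in zip(diffs, diffs[1:]))
        assert diffs[-1] < 1e-9 * abs(e_ch)


class TestRecordTable:
    def _records(self):
        return [
            InteractionRecord("rep1", "R", "res001", -3.0, {0.0: -3.5, 2.5: -3.2}, 2.4),
            InteractionRecord("rep1", "R", "res002", 1.0, {0.0: 1.1, 2.5: 1.05}, 7.0),
        ]

    def test_round_trip(self):
        frame = records_to_frame(self._records())
        assert ch_columns(frame) == {0.0: "E_CH@0", 2.5: "E_CH@2.5"}
        back = frame_to_records(frame)
        assert back == self._records()

    def test_plain_ch_entry_required(self):
        with pytest.raises(ValueError):
            InteractionRecord("rep1", "R", "res001", -3.0, {2.5: -3.2}, 2.4)

    def test_inconsistent_grids_rejected(self):
        recs = self._records()
        recs[1] = InteractionRecord("rep1", "R", "res002", 1.0, {0.0: 1.1}, 7.0)
        with pytest.raises(DataError):
            records_to_frame(recs)
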