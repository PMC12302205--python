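import math

import numpy as np
import pytest

from deltasolv.dataset_io import MoleculeRecord
from deltasolv.gb_physics import (
    GBParameters,
    GBSystem,
    assign_partial_charges,
    effective_born_radii,
    electrostatic_size,
    gb_pair_function,
    gb_polar_energy,
)
from deltasolv.synthetic import make_toy_gb_system


def _rotate(coords, seed=0):
    rng = np.random.default_rng(seed)
    # random rotation via QR of a Gaussian matrix
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return coords @ Q.T + rng.normal(size=3)


class TestPartialCharges:
    def test_methanol_neutral(self):
        rec = MoleculeRecord(id="x", smiles="CO")
        q = assign_partial_charges(rec)
        assert abs(q.sum()) < 1e-6
        assert len(q) == 2

    def test_ethane_symmetry(self):
        rec = MoleculeRecord(id="x", smiles="CC")
        q = assign_partial_charges(rec)
        np.testing.assert_allclose(q[0], q[1], atol=1e-9)

    def test_from_structure_passthrough(self):
        rec = MoleculeRecord(id="x", smiles="CO", charges=[0.1, -0.1])
        q = assign_partial_charges(rec, method="from_structure")
        np.testing.assert_allclose(q, [0.1, -0.1])

    def test_from_structure_missing_raises(self):
        from deltasolv.dataset_io import ValidationError

        with pytest.raises(ValidationError):
            assign_partial_charges(MoleculeRecord(id="x", smiles="CO"),
                                   method="from_structure")


class TestBornRadii:
    def test_isolated_atom_intrinsic(self):
        system = make_toy_gb_system("single_ion", R=1.5)
        np.testing.assert_allclose(effective_born_radii(system), [1.5])

    def test_diatomic_symmetry(self):
        system = make_toy_gb_system("diatomic", d=3.0, R=1.5)
        R = effective_born_radii(system)
        np.testing.assert_allclose(R[0], R[1])
        assert np.all(R >= 1.5)

    def test_rigid_motion_invariance(self):
        system = make_toy_gb_system("linear_chain", n=4, d=2.0, R=1.4)
        R0 = effective_born_radii(system)
        moved = GBSystem(coords=_rotate(system.coords, seed=3), charges=system.charges,
                         intrinsic_radii=system.intrinsic_radii)
        np.testing.assert_allclose(effective_born_radii(moved), R0, rtol=1e-9)

    def test_burial_monotonicity(self):
        base = make_toy_gb_system("diatomic", d=4.0, R=1.5)
        R2 = effective_born_radii(base)
        more = GBSystem(
            coords=np.vstack([base.coords, [[0.0, 4.0, 0.0]]]),
            charges=np.append(base.charges, 0.0),
            intrinsic_radii=np.append(base.intrinsic_radii, 1.5),
        )
        R3 = effective_born_radii(more)
        assert np.all(R3[:2] >= R2 - 1e-12)

    def test_overlapping_identical_coords_raise(self):
        system = GBSystem(coords=[[0, 0, 0], [0, 0, 0]], charges=[0.1, 0.1],
                          intrinsic_radii=[1.5, 1.5])
        with pytest.raises(ValueError):
            effective_born_radii(system)

    def test_linear_chain_vs_grid_oracle(self):
        """Inverse-radius descreening against dense numerical integration.

        Geometry chosen so neighbor spheres do not overlap each other or
        the central sphere, where the pairwise sum is the exact union.
        """
        d, rho = 4.0, 1.5
        system = make_toy_gb_system("linear_chain", n=3, d=d, R=rho)
        R = effective_born_radii(system)

        def oracle_inv_radius(i):
            xyz = system.coords
            total = 1.0 / rho
            h = 0.05
            for j in range(3):
                if j == i:
                    continue
                center = xyz[j]
                grid = np.arange(-rho + h / 2, rho, h)
                gx, gy, gz = np.meshgrid(grid, grid, grid, indexing="ij")
                pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) + center
                inside = np.linalg.norm(pts - center, axis=1) <= rho
                r = np.linalg.norm(pts[inside] - xyz[i], axis=1)
                keep = r > rho  # outside atom i's own sphere
                total -= (h ** 3 / (4 * np.pi)) * np.sum(1.0 / r[keep] ** 4)
            return total

        for i in range(3):
            np.testing.assert_allclose(1.0 / R[i], oracle_inv_radius(i), rtol=0.05)


class TestElectrostaticSize:
    def test_single_atom_equals_radius(self):
        system = make_toy_gb_system("single_ion", R=2.0)
        assert electrostatic_size(system) == pytest.approx(2.0)

    def test_scaling_increases(self):
        system = make_toy_gb_system("linear_chain", n=3, d=2.5, R=1.2)
        A1 = electrostatic_size(system)
        scaled = GBSystem(coords=system.coords * 2.0, charges=system.charges,
                          intrinsic_radii=system.intrinsic_radii)
        assert electrostatic_size(scaled) > A1

    def test_rigid_motion_invariance(self):
        system = make_toy_gb_system("linear_chain", n=4, d=2.0, R=1.3)
        A0 = electrostatic_size(system)
        moved = GBSystem(coords=_rotate(system.coords, seed=11), charges=system.charges,
                         intrinsic_radii=system.intrinsic_radii)
        assert electrostatic_size(moved) == pytest.approx(A0, rel=1e-9)

    def test_two_spheres_vs_capacitance_oracle(self):
        """Boundary-element capacitance of the two-sphere conductor."""
        d = 10.0
        system = GBSystem(coords=[[0, 0, 0], [d, 0, 0]], charges=[0.0, 0.0],
                          intrinsic_radii=[1.0, 1.0])

        def fibonacci_sphere(n, radius, center):
            k = np.arange(n) + 0.5
            phi = np.arccos(1 - 2 * k / n)
            theta = np.pi * (1 + 5 ** 0.5) * k
            pts = radius * np.stack(
                [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
                axis=1,
            )
            return pts + center

        n = 400
        pts = np.vstack([fibonacci_sphere(n, 1.0, np.zeros(3)),
                         fibonacci_sphere(n, 1.0, np.array([d, 0, 0]))])
        area = 4 * np.pi / n  # per patch, unit sphere
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        patch_radius = math.sqrt(area / math.pi)
        P = np.where(dist > 0, 1.0 / np.maximum(dist, 1e-12), 2.0 / patch_radius)
        # constant potential 1 on the conductor: solve P q = 1, C = sum q
        q = np.linalg.solve(P, np.ones(2 * n))
        oracle_C = q.sum()
        assert electrostatic_size(system) == pytest.approx(oracle_C, rel=0.10)

    def test_empty_raises(self):
        system = GBSystem(coords=np.zeros((0, 3)), charges=[], intrinsic_radii=[])
        with pytest.raises(ValueError):
            electrostatic_size(system)


class TestPairFunction:
    def test_self_term_limit(self):
        assert gb_pair_function(0.0, 2.0, 2.0) == pytest.approx(2.0)

    def test_coulomb_limit(self):
        assert gb_pair_function(100.0, 1.0, 1.0) == pytest.approx(100.0, abs=1e-3)

    def test_against_independent_evaluation(self):
        r, Ri, Rj = 3.0, 1.5, 2.0
        expected = math.sqrt(r * r + Ri * Rj * math.exp(-(r * r) / (4 * Ri * Rj)))
        assert gb_pair_function(r, Ri, Rj) == pytest.approx(expected, rel=1e-12)

    def test_symmetry_and_monotonicity(self):
        assert gb_pair_function(2.0, 1.0, 3.0) == gb_pair_function(2.0, 3.0, 1.0)
        rs = np.linspace(0, 10, 200)
        fs = gb_pair_function(rs, 1.5, 2.5)
        assert np.all(np.diff(fs) >= 0)

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            gb_pair_function(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            gb_pair_function(1.0, -1.0, 1.0)


class TestPolarEnergy:
    def test_born_ion_closed_form(self):
        system = make_toy_gb_system("single_ion", q=1.0, R=2.0)
        system.born_radii = np.array([2.0])
        system.electrostatic_size = 2.0
        params = GBParameters(eps_in=1.0, eps_out=78.5)
        energy = gb_polar_energy(system, params)
        born = -(332.06 / 2) * (1.0 - 1.0 / 78.5) * 1.0 / 2.0
        assert energy.total == pytest.approx(born, rel=1e-9)
        assert energy.total == pytest.approx(-81.96, abs=0.01)

    def test_born_limit_many_radii(self):
        for R in (0.8, 1.5, 3.1):
            for q in (0.3, -1.2):
                system = make_toy_gb_system("single_ion", q=q, R=R)
                system.populate()
                energy = gb_polar_energy(system, GBParameters())
                born = -(332.06 / 2) * (1 - 1 / 78.5) * q * q / R
                assert energy.total == pytest.approx(born, rel=1e-9)

    def test_charge_inversion_invariance(self):
        system = make_toy_gb_system("linear_chain", n=3, d=2.0, R=1.4).populate()
        e1 = gb_polar_energy(system).total
        flipped = GBSystem(coords=system.coords, charges=-system.charges,
                           intrinsic_radii=system.intrinsic_radii,
                           born_radii=system.born_radii,
                           electrostatic_size=system.electrostatic_size)
        assert gb_polar_energy(flipped).total == pytest.approx(e1, rel=1e-12)

    def test_two_atom_brute_force_sum(self):
        system = make_toy_gb_system("diatomic", d=3.0, q=0.4, R=1.5).populate()
        params = GBParameters()
        energy = gb_polar_energy(system, params)
        # literal term-by-term oracle over the four (i, j) pairs
        q = system.charges
        R = system.born_radii
        A = system.electrostatic_size
        ab = params.alpha * params.beta
        pref = -0.5 * 332.06 * (1 / params.eps_in - 1 / params.eps_out) / (1 + ab)
        total = 0.0
        for i in range(2):
            for j in range(2):
                r = np.linalg.norm(system.coords[i] - system.coords[j])
                f = math.sqrt(r * r + R[i] * R[j] * math.exp(-(r * r) / (4 * R[i] * R[j])))
                total += pref * q[i] * q[j] * (1 / f + ab / A)
        assert energy.total == pytest.approx(total, rel=1e-12)

    def test_pair_decomposition_sums_to_total(self):
        system = make_toy_gb_system("linear_chain", n=5, d=1.8, R=1.5).populate()
        energy = gb_polar_energy(system)
        assert energy.total == pytest.approx(energy.pair_terms.sum(), rel=1e-9)

    def test_rigid_motion_invariance(self):
        base = make_toy_gb_system("linear_chain", n=4, d=2.0, R=1.5)
        base.populate()
        e0 = gb_polar_energy(base).total
        moved = GBSystem(coords=_rotate(base.coords, seed=5), charges=base.charges,
                         intrinsic_radii=base.intrinsic_radii).populate()
        assert gb_polar_energy(moved).total == pytest.approx(e0, rel=1e-9)

    def test_dielectric_limit(self):
        system = make_toy_gb_system("diatomic", d=3.0, q=0.5).populate()
        e = gb_polar_energy(system, GBParameters(eps_in=1.0, eps_out=1.0 + 1e-9)).total
        assert abs(e) < 1e-6

    def test_energy_nonpositive_random_charges(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(2, 6))
            coords = rng.normal(scale=3.0, size=(n, 3))
            system = GBSystem(coords=coords, charges=rng.normal(size=n),
                              intrinsic_radii=np.full(n, 1.5))
            try:
                system.populate()
            except ValueError:
                continue
            assert gb_polar_energy(system).total <= 1e-9

    def test_missing_born_radii_raises(self):
        system = make_toy_gb_system("diatomic")
        with pytest.raises(ValueError):
            gb_polar_energy(system)
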