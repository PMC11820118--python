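"""Mpipi energy terms: closed forms, oracles, and invariances."""

import math

import numpy as np
import pytest
import yaml

from pldscale import (
    BeadConfiguration,
    bond_energy,
    debye_kappa,
    electrostatic_energy,
    example_param_table,
    load_params,
    total_energy,
    wang_frenkel_energy,
)
from pldscale.mpipi_potential import (
    COULOMB_CONSTANT_KCAL_A_E2,
    ParamTableError,
    read_configuration,
)


@pytest.fixture(scope="module")
def params():
    return load_params(example_param_table())


class TestBond:
    def test_zero_at_equilibrium(self):
        assert bond_energy(3.81) == 0.0

    def test_one_angstrom_stretch(self):
        assert bond_energy(4.81, k=19.1, r0=3.81) == pytest.approx(9.55)

    def test_parabola_symmetry(self):
        for delta in (0.1, 0.5, 1.3):
            assert bond_energy(3.81 + delta) == pytest.approx(bond_energy(3.81 - delta))


class TestDebyeKappa:
    def test_zero_ionic_strength(self):
        assert debye_kappa(0.0) == 0.0

    def test_physiological_salt(self):
        assert debye_kappa(0.150, 80.0, 300.0) == pytest.approx(0.126, abs=5e-4)

    def test_square_root_scaling(self):
        assert debye_kappa(0.6) == pytest.approx(2 * debye_kappa(0.15))


class TestElectrostatics:
    def test_neutral_pair_zero(self):
        assert electrostatic_energy(0.0, 1.0, 5.0) == 0.0

    def test_screened_value_at_debye_length(self):
        r = 1.0 / 0.126
        expected = COULOMB_CONSTANT_KCAL_A_E2 / (80.0 * r) * math.exp(-1.0)
        assert electrostatic_energy(1.0, 1.0, r, kappa=0.126, eps_r=80.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.192, abs=5e-4)

    def test_monotone_decay(self):
        rs = np.linspace(2.0, 30.0, 50)
        es = [electrostatic_energy(1, 1, r) for r in rs]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_contact_rejected(self):
        with pytest.raises(ValueError):
            electrostatic_energy(1, 1, 0.0)


class TestWangFrenkel:
    def test_zero_at_sigma_and_cutoff(self):
        assert wang_frenkel_energy(1.0, 1.0, 1.0, 1.0, 1.0, 3.0) == pytest.approx(0.0)
        assert wang_frenkel_energy(3.0, 1.0, 1.0, 1.0, 1.0, 3.0) == 0.0
        assert wang_frenkel_energy(5.0, 1.0, 1.0, 1.0, 1.0, 3.0) == 0.0

    @pytest.mark.parametrize("eps, sigma", [(1.0, 1.0), (0.3, 6.2), (2.5, 4.0)])
    def test_minimum_depth_equals_minus_eps(self, eps, sigma):
        """Grid + golden-section refinement locates a minimum of exactly -eps
        for mu = nu = 1, rc = 3 sigma."""
        from scipy.optimize import minimize_scalar

        rc = 3.0 * sigma
        grid = np.linspace(sigma * 1.001, rc * 0.999, 2000)
        vals = [wang_frenkel_energy(r, eps, sigma, 1.0, 1.0, rc) for r in grid]
        r0 = grid[int(np.argmin(vals))]
        res = minimize_scalar(
            lambda r: wang_frenkel_energy(r, eps, sigma, 1.0, 1.0, rc),
            bracket=(r0 - sigma * 1e-3, r0, r0 + sigma * 1e-3),
        )
        assert res.fun == pytest.approx(-eps, abs=1e-6)

    def test_continuous_at_cutoff(self):
        rc = 3.0
        just_inside = wang_frenkel_energy(rc * (1 - 1e-12), 1.0, 1.0, 2.0, 1.0, rc)
        assert abs(just_inside) < 1e-9


class TestParamTable:
    def test_fixture_table_complete(self, params):
        residues = sorted(params.residues)
        assert len(residues) == 6
        # all unordered pairs present, symmetric access
        for i in residues:
            for j in residues:
                assert params.pair(i, j) == params.pair(j, i)
        assert params.bond_k == 19.1 and params.bond_r0 == 3.81
        assert params.eps_r == 80.0 and params.kappa == 0.126

    def test_symmetric_completion_single_listing(self, tmp_path):
        doc = {
            "residues": {"A": {"mass": 71.0, "charge": 0.0, "sigma": 5.0},
                         "B": {"mass": 99.0, "charge": 0.0, "sigma": 5.2}},
            "pairs": [{"i": "A", "j": "B", "eps": 0.2, "sigma": 5.1, "mu": 2, "nu": 1},
                      {"i": "A", "j": "A", "eps": 0.1, "sigma": 5.0, "mu": 2, "nu": 1},
                      {"i": "B", "j": "B", "eps": 0.3, "sigma": 5.2, "mu": 2, "nu": 1}],
        }
        path = tmp_path / "t.yaml"
        path.write_text(yaml.safe_dump(doc))
        table = load_params(path)
        assert table.pair("B", "A").eps == 0.2

    def test_conflicting_duplicate_rejected(self, tmp_path):
        doc = {
            "residues": {"A": {"mass": 71.0, "charge": 0.0, "sigma": 5.0}},
            "pairs": [{"i": "A", "j": "A", "eps": 0.2, "sigma": 5.0, "mu": 2, "nu": 1},
                      {"i": "A", "j": "A", "eps": 0.9, "sigma": 5.0, "mu": 2, "nu": 1}],
        }
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(ParamTableError, match="conflicting"):
            load_params(path)

    def test_missing_keys_reported(self, tmp_path):
        path = tmp_path / "bad2.yaml"
        path.write_text(yaml.safe_dump({
            "residues": {"A": {"mass": 71.0}}, "pairs": [],
        }))
        with pytest.raises(ParamTableError, match="charge"):
            load_params(path)


class TestTotalEnergy:
    def test_two_neutral_beads_at_sigma(self, params):
        sigma = params.pair("G", "G").sigma
        config = BeadConfiguration(["G", "G"], [[0, 0, 0], [sigma, 0, 0]])
        e = total_energy(config, params)
        assert e.bond == 0.0 and e.electrostatic == 0.0
        assert e.pair == pytest.approx(0.0, abs=1e-12)

    def test_bonded_pair_at_equilibrium_excluded_from_nonbonded(self, params):
        config = BeadConfiguration(["G", "G"], [[0, 0, 0], [3.81, 0, 0]],
                                   bonds=[(0, 1)])
        e = total_energy(config, params)
        assert e.bond == 0.0
        assert e.pair == 0.0 and e.electrostatic == 0.0  # 1-2 exclusion

    def test_three_bead_chain_decomposes_into_unit_ops(self, params):
        from pldscale import bond_energy as be

        pos = np.array([[0.0, 0, 0], [3.9, 0, 0], [7.5, 1.0, 0]])
        config = BeadConfiguration(["R", "G", "D"], pos, bonds=[(0, 1), (1, 2)])
        e = total_energy(config, params)
        r01 = np.linalg.norm(pos[1] - pos[0])
        r12 = np.linalg.norm(pos[2] - pos[1])
        r02 = np.linalg.norm(pos[2] - pos[0])
        assert e.bond == pytest.approx(
            be(r01, params.bond_k, params.bond_r0) + be(r12, params.bond_k, params.bond_r0),
            abs=1e-12,
        )
        pp = params.pair("R", "D")
        assert e.pair == pytest.approx(
            wang_frenkel_energy(r02, pp.eps, pp.sigma, pp.mu, pp.nu, pp.rc), abs=1e-12
        )
        assert e.electrostatic == pytest.approx(
            electrostatic_energy(1.0, -1.0, r02, params.kappa, params.eps_r), abs=1e-12
        )
        assert e.total == pytest.approx(e.bond + e.electrostatic + e.pair)

    def test_rigid_motion_invariance(self, params):
        rng = np.random.default_rng(11)
        pos = rng.uniform(0, 20, size=(5, 3))
        residues = ["R", "K", "D", "Y", "S"]
        bonds = [(0, 1), (1, 2), (2, 3), (3, 4)]
        base = total_energy(BeadConfiguration(residues, pos, bonds), params)
        for _ in range(5):
            q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            moved = pos @ q.T + rng.uniform(-50, 50, size=3)
            e = total_energy(BeadConfiguration(residues, moved, bonds), params)
            assert e.total == pytest.approx(base.total, rel=1e-9, abs=1e-9)

    def test_unknown_residue_rejected(self, params):
        config = BeadConfiguration(["Z"], [[0, 0, 0]])
        with pytest.raises(ParamTableError, match="Z"):
            total_energy(config, params)


def test_configuration_round_trip(tmp_path, params):
    text = (
        "# bead table\n"
        "0 R 0.0 0.0 0.0\n"
        "1 G 3.9 0.0 0.0\n"
        "2 D 7.5 1.0 0.0\n"
        "bonds\n"
        "0 1\n"
        "1 2\n"
    )
    path = tmp_path / "conf.txt"
    path.write_text(text)
    config = read_configuration(path)
    assert config.residues == ["R", "G", "D"]
    assert config.bonds == [(0, 1), (1, 2)]
    assert total_energy(config, params).total == pytest.approx(
        total_energy(BeadConfiguration(
            ["R", "G", "D"],
            [[0, 0, 0], [3.9, 0, 0], [7.5, 1.0, 0]], [(0, 1), (1, 2)]), params).total
    )
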