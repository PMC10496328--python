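import math

import numpy as np
import pytest

from oracles import BRUTE, contact_keys
from rinkit import BondParams, PrepOptions, annotate_chemistry, prepare_model
from rinkit.detectors import (
    Contact,
    DETECTORS,
    apply_policy,
    bond_energy,
    detect_contacts,
)
from rinkit.fixtures import FixtureSpec, make_fixture, random_structure
from rinkit.params import SPECIFIC_BONDS
from rinkit.structure import Atom, Model, Residue


def _contact(bond_type, distance, angle=None, extra=None):
    return Contact(bond_type=bond_type, idx_a=0, idx_b=1,
                   res_a=("A", 1, "", "ALA"), res_b=("A", 2, "", "ALA"),
                   atoms_a=("X",), atoms_b=("Y",), distance=distance,
                   angle=angle, extra=extra or {})


class TestHydrogenBonds:
    def test_collinear_positive(self, run_detector):
        s = make_fixture(FixtureSpec("HBOND_PAIR", {"d": 2.9, "angle": 180.0}))
        (c,) = run_detector(s, "HBOND")
        assert c.distance == pytest.approx(2.9, abs=1e-9)
        assert c.angle == pytest.approx(180.0, abs=0.1)
        assert c.extra["role_a"] == "donor" and c.extra["role_b"] == "acceptor"
        assert c.energy < 0

    def test_stretched_negative(self, run_detector):
        s = make_fixture(FixtureSpec("HBOND_PAIR", {"d": 4.2, "angle": 180.0}))
        assert run_detector(s, "HBOND") == []

    def test_angle_gate_only_with_require_h(self, run_detector, params):
        s = make_fixture(FixtureSpec("HBOND_PAIR", {"d": 2.9, "angle": 100.0}))
        assert run_detector(s, "HBOND") == []
        relaxed = BondParams()
        relaxed.hbond.require_h = False
        (c,) = run_detector(s, "HBOND", use_params=relaxed)
        assert c.angle is None  # distance-only mode records no angle

    def test_donor_without_h_skipped_when_required(self, prepared_and_chem, params):
        s = make_fixture(FixtureSpec("HBOND_PAIR", {"d": 2.9, "angle": 180.0}))
        # drop the hydrogen
        s.models[0].chains[0][1][0].atoms = [
            a for a in s.models[0].chains[0][1][0].atoms if a.name != "H"]
        pm, chem = prepared_and_chem(s)
        assert DETECTORS["HBOND"](pm, chem, params) == []
        relaxed = BondParams()
        relaxed.hbond.require_h = False
        assert len(DETECTORS["HBOND"](pm, chem, relaxed)) == 1


class TestVdw:
    def test_surface_distance_gate(self, run_detector):
        (c,) = run_detector(make_fixture(FixtureSpec("VDW_PAIR", {"d": 3.6})), "VDW")
        assert c.distance == pytest.approx(3.6)
        assert run_detector(make_fixture(FixtureSpec("VDW_PAIR", {"d": 4.2})), "VDW") == []

    def test_layering_with_hbond(self, prepared_and_chem, params):
        # an H-bonded pair is still reported as VDW: types are independent layers
        s = make_fixture(FixtureSpec("HBOND_PAIR", {"d": 2.9, "angle": 180.0}))
        pm, chem = prepared_and_chem(s)
        assert len(DETECTORS["HBOND"](pm, chem, params)) == 1
        vdw_pairs = {(c.atoms_a, c.atoms_b) for c in DETECTORS["VDW"](pm, chem, params)}
        assert (("N",), ("O",)) in vdw_pairs

    def test_lattice_matches_brute_force(self, prepared_and_chem, params):
        rng = np.random.default_rng(3)
        residues = [
            Residue(chain_id="A", seq_num=i + 1, icode="", name="GLY",
                    atoms=[Atom(serial=i, name="CA", element="C", altloc="",
                                coords=rng.uniform(0, 8, 3))])
            for i in range(10)
        ]
        s = make_fixture(FixtureSpec("CHAIN", {"n": 1}))
        s.models[0].chains = [("A", residues)]
        pm, chem = prepared_and_chem(s)
        got = contact_keys(DETECTORS["VDW"](pm, chem, params))
        assert got == BRUTE["VDW"](pm, chem, params)


class TestIonic:
    @pytest.mark.parametrize("d,count", [(3.5, 1), (6.0, 0), (4.5, 1)])
    def test_centroid_gate(self, run_detector, d, count):
        s = make_fixture(FixtureSpec("IONIC_PAIR", {"d": d}))
        contacts = run_detector(s, "IONIC")
        assert len(contacts) == count
        if contacts:
            assert contacts[0].distance == pytest.approx(d, abs=1e-9)


class TestPiPi:
    def test_parallel_stack(self, run_detector):
        (c,) = run_detector(make_fixture(FixtureSpec("PIPI_PAIR", {"d": 4.0, "gamma": 0.0})), "PIPI")
        assert c.angle == pytest.approx(0.0, abs=0.1)
        assert c.extra["stack"] == "parallel"

    def test_tshaped(self, run_detector):
        (c,) = run_detector(make_fixture(FixtureSpec("PIPI_PAIR", {"d": 5.0, "gamma": 90.0})), "PIPI")
        assert c.angle == pytest.approx(90.0, abs=0.1)
        assert c.extra["stack"] == "t-shaped"

    def test_too_far(self, run_detector):
        assert run_detector(make_fixture(FixtureSpec("PIPI_PAIR", {"d": 8.5, "gamma": 0.0})), "PIPI") == []


class TestPiCation:
    def test_on_axis(self, run_detector):
        (c,) = run_detector(make_fixture(FixtureSpec("PICATION_PAIR", {"d": 4.0, "alpha": 0.0})), "PICATION")
        assert c.angle == pytest.approx(0.0, abs=0.1)

    def test_in_plane_rejected(self, run_detector):
        s = make_fixture(FixtureSpec("PICATION_PAIR", {"d": 4.0, "alpha": 90.0}))
        assert run_detector(s, "PICATION") == []

    def test_thirty_degrees_off_normal(self, run_detector):
        (c,) = run_detector(make_fixture(FixtureSpec("PICATION_PAIR", {"d": 4.0, "alpha": 30.0})), "PICATION")
        assert c.angle == pytest.approx(30.0, abs=0.1)
        assert c.distance == pytest.approx(4.0, abs=1e-9)


class TestHydrophobic:
    def test_pair(self, run_detector):
        (c,) = run_detector(make_fixture(FixtureSpec("HYDROPHOBIC_PAIR", {"d": 4.0})), "HYDROPHOBIC")
        assert c.distance == pytest.approx(4.0)
        assert run_detector(make_fixture(FixtureSpec("HYDROPHOBIC_PAIR", {"d": 6.0})), "HYDROPHOBIC") == []

    def test_three_mutually_close_leucines(self, prepared_and_chem, params):
        centers = [(0.0, 0.0, 0.0), (4.0, 0.0, 0.0), (2.0, 3.5, 0.0)]
        residues = []
        for i, ctr in enumerate(centers):
            residues.append(Residue(
                chain_id="A", seq_num=i + 1, icode="", name="LEU",
                atoms=[Atom(serial=1, name="CD1", element="C", altloc="", coords=ctr),
                       Atom(serial=2, name="CD2", element="C", altloc="",
                            coords=np.asarray(ctr) + [0.4, 0.3, 0.0])]))
        s = make_fixture(FixtureSpec("CHAIN", {"n": 1}))
        s.models[0].chains = [("A", residues)]
        pm, chem = prepared_and_chem(s)
        contacts = DETECTORS["HYDROPHOBIC"](pm, chem, params)
        assert len(contacts) == 3  # one edge per residue pair
        got = contact_keys(contacts)
        assert got == BRUTE["HYDROPHOBIC"](pm, chem, params)


class TestCalpha:
    def test_helix_matches_scan(self, prepared_and_chem, params):
        s = make_fixture(FixtureSpec("CHAIN", {"n": 10, "conformation": "helix"}))
        pm, chem = prepared_and_chem(s)
        got = contact_keys(DETECTORS["CA_CONTACT"](pm, chem, params))
        assert got == BRUTE["CA_CONTACT"](pm, chem, params)
        seps = {abs(pm.residues[i].seq_num - pm.residues[j].seq_num)
                for i, j, _, _ in got}
        assert seps == {3, 4}

    def test_extended_chain_no_contacts(self, run_detector):
        s = make_fixture(FixtureSpec("CHAIN", {"n": 8, "conformation": "extended"}))
        assert run_detector(s, "CA_CONTACT") == []

    def test_interchain_pair_no_seq_gate(self, run_detector):
        (c,) = run_detector(make_fixture(FixtureSpec("CA_PAIR", {"d": 5.0})), "CA_CONTACT")
        assert c.distance == pytest.approx(5.0)
        assert c.energy == 0.0


class TestEnergies:
    def test_hbond_minimum(self, params):
        c = _contact("HBOND", distance=2.8, angle=180.0)
        assert bond_energy(c, params) == pytest.approx(-9.0, abs=1e-9)

    def test_vdw_minimum(self, params):
        c = _contact("VDW", distance=3.40, extra={"sigma": 3.40})
        assert bond_energy(c, params) == pytest.approx(-params.vdw.epsilon, abs=1e-9)

    def test_ionic_screened_coulomb(self, params):
        c = _contact("IONIC", distance=4.0)
        assert bond_energy(c, params) == pytest.approx(-5.1875, abs=1e-9)

    def test_hbond_missing_angle_factor_one(self, params):
        with_angle = bond_energy(_contact("HBOND", 2.8, angle=180.0), params)
        without = bond_energy(_contact("HBOND", 2.8, angle=None), params)
        assert without == pytest.approx(with_angle)

    @pytest.mark.parametrize("bond_type,extra", [
        ("HBOND", {}), ("VDW", {"sigma": 3.4}), ("IONIC", {}),
        ("PIPI", {}), ("PICATION", {}), ("HYDROPHOBIC", {}),
    ])
    def test_decay_to_zero(self, params, bond_type, extra):
        far = bond_energy(_contact(bond_type, 500.0, angle=0.0, extra=extra), params)
        assert -1e-3 < far <= 0.0
        nearer = bond_energy(_contact(bond_type, 250.0, angle=0.0, extra=extra), params)
        assert abs(far) <= abs(nearer)  # magnitude shrinks with distance

    def test_hbond_angle_dependence_monotone(self, params):
        energies = [bond_energy(_contact("HBOND", 2.8, angle=t), params)
                    for t in (180, 170, 150, 130, 120)]
        mags = [abs(e) for e in energies]
        assert mags == sorted(mags, reverse=True)

    def test_hydrophobic_clamped(self, params):
        e_close = bond_energy(_contact("HYDROPHOBIC", 3.0), params)
        assert e_close == pytest.approx(-params.hydrophobic.e0)
        e_far = bond_energy(_contact("HYDROPHOBIC", 4.5), params)
        assert e_far == pytest.approx(0.0)

    def test_ca_energy_zero(self, params):
        assert bond_energy(_contact("CA_CONTACT", 6.0), params) == 0.0


class TestPolicy:
    @staticmethod
    def _trio():
        a = _contact("HBOND", 2.8, angle=180.0)
        a.energy = -9.0
        b = _contact("HBOND", 3.2, angle=150.0)
        b.energy = -4.0
        c = _contact("VDW", 3.3, extra={"sigma": 3.4})
        c.energy = -0.2
        return [a, b, c]

    def test_all(self):
        assert len(apply_policy(self._trio(), "all")) == 3

    def test_best_per_type(self):
        kept = apply_policy(self._trio(), "best-per-type")
        assert sorted(c.bond_type for c in kept) == ["HBOND", "VDW"]
        assert min(c.energy for c in kept) == -9.0

    def test_best_overall(self):
        (kept,) = apply_policy(self._trio(), "best-overall")
        assert kept.bond_type == "HBOND" and kept.energy == -9.0


class TestProperties:
    def test_oracle_equivalence_random_models(self, prep, params):
        for seed in range(6):
            s = random_structure(18, seed=seed)
            pm = prepare_model(s.models[0], prep)
            chem = annotate_chemistry(pm)
            for bond_type in DETECTORS:
                got = contact_keys(DETECTORS[bond_type](pm, chem, params))
                ref = BRUTE[bond_type](pm, chem, params)
                assert got == ref, f"{bond_type} mismatch at seed {seed}"

    def test_rigid_motion_invariance(self, prep, params):
        s = random_structure(14, seed=42)
        pm = prepare_model(s.models[0], prep)
        chem = annotate_chemistry(pm)
        before = {t: DETECTORS[t](pm, chem, params) for t in DETECTORS}

        rng = np.random.default_rng(7)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q = q * np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        shift = rng.uniform(-30, 30, 3)
        for _, atom in pm.atoms:
            atom.coords = q @ atom.coords + shift
        pm2 = prepare_model(pm.to_model(), prep)
        chem2 = annotate_chemistry(pm2)
        for t in DETECTORS:
            after = DETECTORS[t](pm2, chem2, params)
            assert contact_keys(after) == contact_keys(before[t]), t
            d_before = sorted(c.distance for c in before[t])
            d_after = sorted(c.distance for c in after)
            np.testing.assert_allclose(d_after, d_before, atol=1e-6)

    def test_threshold_monotonicity(self, prep):
        s = random_structure(18, seed=5)
        pm = prepare_model(s.models[0], prep)
        chem = annotate_chemistry(pm)
        tight = BondParams()
        loose = BondParams()
        loose.hbond.d_max += 1.0
        loose.hbond.angle_min_deg -= 30.0
        loose.vdw.surface_tol += 0.8
        loose.ionic.d_max += 2.0
        loose.pipi.d_max += 2.0
        loose.pipi.parallel_max_deg += 20.0
        loose.pication.d_max += 2.0
        loose.pication.alpha_max_deg += 30.0
        loose.hydrophobic.d_max += 1.5
        loose.ca_contact.d_max += 3.0
        for t in DETECTORS:
            small = contact_keys(DETECTORS[t](pm, chem, tight))
            big = contact_keys(DETECTORS[t](pm, chem, loose))
            assert small <= big, t

    def test_canonical_edge_ordering(self, prep, params):
        s = random_structure(15, seed=1)
        pm = prepare_model(s.models[0], prep)
        chem = annotate_chemistry(pm)
        for c in detect_contacts(pm, chem, params, which=SPECIFIC_BONDS + ("CA_CONTACT",)):
            assert c.idx_a < c.idx_b
            assert c.res_a[:3] < c.res_b[:3]
            assert c.distance > 0
            assert math.isfinite(c.energy)
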