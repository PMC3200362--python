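"""Statistical mechanics of coupled titratable sites, and the electrostatics
that feeds it: intrinsic pKs, couplings, sampling, bias titration, redox."""

import itertools
import math

import numpy as np
import pytest

from protpka.solver import DielectricEnvironment, bjerrum_length_vacuum, pk_to_mv
from protpka.synth import ToySpec, make_model_compound, make_toy_multisite
from protpka.titration import (
    LN10,
    MicrostateModel,
    TitrationSystem,
    exact_populations,
    mc_sample,
    microstate_energy,
    redox_midpoint,
    titrate_pka,
    titration_curve,
)

from conftest import CHEAP


def simple_model(pk, W=None, kinds=None, pH=7.0):
    """Hand-built model: kinds is a string of 'a' (acid) / 'b' (base)."""
    n = len(pk)
    kinds = kinds or "a" * n
    return MicrostateModel(
        site_ids=[f"s{i}" for i in range(n)],
        pk_intr=np.asarray(pk, dtype=float),
        W=np.zeros((n, n)) if W is None else np.asarray(W, dtype=float),
        driv=np.full(n, float(pH)),
        charged_is_bound=np.array([k == "b" for k in kinds]),
    )


def random_model(rng, n):
    pk = rng.uniform(3.0, 11.0, n)
    W = rng.uniform(-2.5, 2.5, (n, n))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    kinds = "".join(rng.choice(["a", "b"]) for _ in range(n))
    return simple_model(pk, W, kinds)


class TestMicrostateEnergy:
    def test_single_acid_degenerate_at_its_pk(self):
        m = simple_model([7.0])
        e0 = microstate_energy(m, [0])
        e1 = microstate_energy(m, [1])
        assert e0 == pytest.approx(e1)

    def test_bias_shifts_gap_by_ln10_kT(self):
        m = simple_model([5.0])
        gap0 = microstate_energy(m, [1]) - microstate_energy(m, [0])
        gap1 = microstate_energy(m, [1], bias=[1.0]) - microstate_energy(m, [0], bias=[1.0])
        assert gap0 - gap1 == pytest.approx(LN10)

    def test_three_site_energies_match_hand_sums(self):
        """All 8 microstates against an independent sum over the definition."""
        pk = [4.5, 7.2, 10.0]
        W = [[0.0, 1.2, -0.4], [1.2, 0.0, 0.7], [-0.4, 0.7, 0.0]]
        kinds = "aab"
        m = simple_model(pk, W, kinds, pH=6.5)
        for x in itertools.product((0, 1), repeat=3):
            t = [1 - x[0], 1 - x[1], x[2]]  # charged indicators
            e = sum(x[i] * (6.5 - pk[i]) for i in range(3))
            e += 0.5 * sum(
                W[i][j] * t[i] * t[j] for i in range(3) for j in range(3) if i != j
            )
            assert microstate_energy(m, x) == pytest.approx(LN10 * e, abs=1e-12)


class TestExactPopulations:
    def test_single_site_is_henderson_hasselbalch(self):
        m = simple_model([6.0])
        for ph in (4.0, 6.0, 8.5):
            m.driv[:] = ph
            assert exact_populations(m)[0] == pytest.approx(
                1.0 / (1.0 + 10 ** (ph - 6.0)), abs=1e-12
            )

    def test_uncoupled_pair_is_product_of_sigmoids(self):
        m = simple_model([5.0, 9.0], kinds="ab", pH=7.0)
        p = exact_populations(m)
        assert p[0] == pytest.approx(1.0 / (1.0 + 10 ** (7.0 - 5.0)))
        assert p[1] == pytest.approx(1.0 / (1.0 + 10 ** (7.0 - 9.0)))

    def test_coupled_pair_matches_hand_partition_function(self):
        W = 3.0
        m = simple_model([6.0, 8.0], [[0, W], [W, 0]], "aa", pH=7.0)
        Z, mean = 0.0, np.zeros(2)
        for xa, xb in itertools.product((0, 1), repeat=2):
            e = xa * (7.0 - 6.0) + xb * (7.0 - 8.0) + W * (1 - xa) * (1 - xb)
            w = 10.0 ** (-e)
            Z += w
            mean += w * np.array([xa, xb])
        np.testing.assert_allclose(exact_populations(m), mean / Z, atol=1e-12)

    def test_enumeration_limit_enforced(self):
        m = random_model(np.random.default_rng(0), 8)
        with pytest.raises(ValueError, match="enumeration limit"):
            exact_populations(m, max_sites=4)

    def test_his_exclusion_penalty_suppresses_double_deprotonation(self):
        m = simple_model([6.6, 7.0], kinds="ab", pH=12.0)
        m.excluded_pairs = [(0, 1)]
        p = exact_populations(m)
        # at very high pH both sites would deprotonate; the penalty keeps
        # at least one proton on the pair
        assert p[0] + p[1] >= 0.999


class TestMonteCarlo:
    def test_single_site_half_protonated_at_its_pk(self):
        m = simple_model([7.0])
        means, diag = mc_sample(m, n_sweeps=10000, seed=11)
        assert means[0] == pytest.approx(0.5, abs=0.02)
        assert 0 < diag["acceptance_rate"] <= 1

    @pytest.mark.parametrize("n,seed", [(2, 1), (5, 2), (10, 3), (12, 4)])
    def test_converges_to_exact_populations(self, n, seed):
        """Seeded toys of 2-12 sites: MC means within 3 MC standard errors of
        the exact enumeration (SE estimated from independent replicates)."""
        rng = np.random.default_rng(seed)
        m = random_model(rng, n)
        exact = exact_populations(m)
        reps = np.array(
            [mc_sample(m, n_sweeps=8000, seed=1000 * seed + k)[0] for k in range(4)]
        )
        mean = reps.mean(axis=0)
        se = np.maximum(reps.std(axis=0, ddof=1) / 2.0, 0.004)
        assert np.all(np.abs(mean - exact) < 3.0 * se)

    def test_henderson_hasselbalch_limit(self):
        m = simple_model([9.0], pH=4.0)
        means, _ = mc_sample(m, n_sweeps=5000, seed=5)
        assert means[0] > 0.999

    def test_fixed_seed_bit_identical(self):
        m = random_model(np.random.default_rng(7), 6)
        a, _ = mc_sample(m, n_sweeps=3000, seed=42)
        b, _ = mc_sample(m, n_sweeps=3000, seed=42)
        np.testing.assert_array_equal(a, b)
        c, _ = mc_sample(m, n_sweeps=3000, seed=43)
        assert not np.array_equal(a, c)


class TestTitratePka:
    def test_isolated_site_recovers_intrinsic(self):
        m = simple_model([9.6])
        res = titrate_pka(m, 0, pH=7.0, engine="exact")
        assert res.pka == pytest.approx(9.6, abs=0.05)

    def test_two_site_mc_agrees_with_exact_root(self):
        m = simple_model([6.0, 7.5], [[0, 2.0], [2.0, 0]], "aa")
        exact = titrate_pka(m, 0, pH=7.0, engine="exact").pka
        mc = titrate_pka(m, 0, pH=7.0, engine="mc", n_sweeps=20000, seed=9).pka
        assert mc == pytest.approx(exact, abs=0.1)

    def test_unbracketed_root_errors(self):
        m = simple_model([80.0])
        with pytest.raises(ValueError, match="not bracketed"):
            titrate_pka(m, 0, pH=7.0, engine="exact", bias_limit=10.0)

    def test_relabeling_invariance(self):
        pk = [5.0, 8.0, 10.0]
        W = [[0, 1.0, 0.5], [1.0, 0, -0.8], [0.5, -0.8, 0]]
        m = simple_model(pk, W, "aab")
        perm = [2, 0, 1]
        m2 = simple_model(
            [pk[i] for i in perm],
            np.asarray(W)[np.ix_(perm, perm)],
            "".join("aab"[i] for i in perm),
        )
        assert titrate_pka(m, 0, engine="exact").pka == pytest.approx(
            titrate_pka(m2, 1, engine="exact").pka, abs=1e-9
        )

    def test_curve_monotone_decreasing_in_pH(self):
        m = simple_model([7.5])
        curve = titration_curve(m, 0, np.linspace(4, 11, 10))
        vals = list(curve.values())
        assert all(a > b for a, b in zip(vals, vals[1:]))


@pytest.fixture(scope="module")
def water_env():
    return DielectricEnvironment()


class TestModelCompoundReferences:
    """Model compounds alone in water: the protein and model contexts are the
    same system, so the machinery must return the reference pKa exactly."""

    @pytest.mark.parametrize(
        "kind,site,expected",
        [
            ("ASP", "A:1", 4.0),
            ("ARG", "A:1", 12.0),
            ("TYR", "A:1", 9.6),
            ("HIS", "A:1:ND1", 6.6),
            ("HIS", "A:1:NE2", 7.0),
        ],
    )
    def test_reference_recovery(self, water_env, kind, site, expected):
        system = TitrationSystem(make_model_compound(kind), env=water_env, **CHEAP)
        model = system.build_model(pH=7.0)
        res = titrate_pka(model, site, pH=7.0, engine="exact")
        assert res.pka == pytest.approx(expected, abs=0.05)

    def test_intrinsic_equals_reference_exactly(self, water_env):
        system = TitrationSystem(make_model_compound("GLU"), env=water_env, **CHEAP)
        assert system.intrinsic_pka(0) == pytest.approx(4.4, abs=1e-9)


class TestInteractionMatrix:
    def test_coulomb_closed_form_at_10A(self):
        spec = ToySpec(n_sites=2, site_kinds=["acid", "acid"], geometry=10.0, seed=0)
        s, exp = make_toy_multisite(spec)
        env = DielectricEnvironment(eps_protein=80, eps_water=80, ionic_strength=0.0)
        system = TitrationSystem(s, env=env, **CHEAP)
        W = system.interaction_matrix()
        d = float(np.linalg.norm(system.sites[0].positions - system.sites[1].positions))
        expected = bjerrum_length_vacuum(300.0) / (80.0 * d * LN10)
        assert W.W[0, 1] == pytest.approx(expected, rel=0.05)
        assert W.W[0, 1] > 0  # two acids: mutual deprotonation disfavored
        assert W.max_asymmetry < 0.05

    def test_far_separated_sites_decouple(self):
        spec = ToySpec(n_sites=2, site_kinds=["acid", "acid"], geometry=60.0, seed=0)
        s, _ = make_toy_multisite(spec)
        system = TitrationSystem(
            s,
            env=DielectricEnvironment(eps_protein=80, eps_water=80),
            levels=[2.5, 1.0],
            npoints_cap=55,
            tol=1e-6,
        )
        with pytest.warns(UserWarning, match="coarser"):
            W = system.interaction_matrix()
        assert abs(W.W[0, 1]) < 0.02

    def test_acid_base_coupling_is_negative(self):
        spec = ToySpec(n_sites=2, site_kinds=["acid", "base"], geometry=8.0, seed=1)
        s, _ = make_toy_multisite(spec)
        system = TitrationSystem(
            s, env=DielectricEnvironment(eps_protein=80, eps_water=80, ionic_strength=0.0), **CHEAP
        )
        assert system.interaction_matrix().W[0, 1] < 0


class TestSignConsistency:
    def _pka_with_neighbor(self, neighbor_state):
        spec = ToySpec(n_sites=2, site_kinds=["acid", "acid"], geometry=5.0, seed=2)
        s, _ = make_toy_multisite(spec)
        env = DielectricEnvironment(eps_protein=4, eps_water=4, ionic_strength=0.0)
        assignment = {"T:2": neighbor_state} if neighbor_state else {}
        system = TitrationSystem(s, env=env, assignment=assignment, exclude=["T:2"], **CHEAP)
        model = system.build_model(pH=7.0)
        return titrate_pka(model, "T:1", pH=7.0, engine="exact").pka

    def test_fixed_negative_charge_raises_acid_pka(self):
        assert self._pka_with_neighbor("TTA_deprot") > self._pka_with_neighbor("TTA_prot") + 1.0

    def test_buried_acid_pka_rises_by_kirkwood_shift(self):
        """Desolvation in an ideal low-dielectric sphere penalizes the anion;
        the magnitude must match the two-dielectric closed form: the reaction
        field of a centered charge changes by (l_B/2)(1/80 - 1/4)(1/R - 1/a)."""
        from conftest import atom
        from protpka.structure import Structure

        spec = ToySpec(n_sites=1, site_kinds=["acid"], geometry=[], seed=3)
        s, _ = make_toy_multisite(spec)
        site_pos = s.atoms[0].xyz.copy()
        sphere = atom("C1", site_pos, resname="MAT", chain="Z", resseq=99)
        s.atoms.append(sphere)
        system = TitrationSystem(
            s, env=DielectricEnvironment(ionic_strength=0.0), levels=[1.0, 0.4],
            npoints_cap=61, tol=1e-7,
        )
        R = 8.0
        next(a for a in system.structure.atoms if a.resseq == 99).radius = R
        pk = system.intrinsic_pka(0)
        a0 = 1.4  # oxygen radius: the model-compound cavity
        lb = bjerrum_length_vacuum(300.0)
        expected = 5.0 + lb / (2 * LN10) * (1 / 80.0 - 1 / 4.0) * (1 / R - 1 / a0)
        assert pk > 5.0  # burial must raise the acid's pKa
        assert pk == pytest.approx(expected, abs=0.3)


class TestRedox:
    def test_isolated_redox_site_returns_reference_midpoint(self, water_env):
        spec = ToySpec(n_sites=1, site_kinds=["redox"], geometry=[], seed=4)
        s, _ = make_toy_multisite(spec)
        system = TitrationSystem(s, env=water_env, **CHEAP)
        model = system.build_model(pH=7.0, Eh=0.0)
        res = redox_midpoint(model, 0, Eh=0.0, engine="exact")
        assert res.pka == pytest.approx(100.0, abs=1.0)  # mV

    def test_midpoint_shift_from_fixed_charge_matches_coulomb(self):
        spec = ToySpec(n_sites=2, site_kinds=["redox", "acid"], geometry=5.0, seed=5)
        s, _ = make_toy_multisite(spec)
        env = DielectricEnvironment(eps_protein=4, eps_water=4, ionic_strength=0.0)
        base = TitrationSystem(s, env=env, assignment={"T:2": "TTA_prot"}, exclude=["T:2"], **CHEAP)
        shifted = TitrationSystem(s, env=env, assignment={"T:2": "TTA_deprot"}, exclude=["T:2"], **CHEAP)
        em0 = redox_midpoint(base.build_model(), 0, engine="exact").pka
        em1 = redox_midpoint(shifted.build_model(), 0, engine="exact").pka
        d = float(np.linalg.norm(base.sites[0].positions[0] - np.array([5.0, 0, 0])))
        d = float(
            np.linalg.norm(
                base.sites[0].positions[0]
                - next(a for a in base.structure.atoms if a.resseq == 2).xyz
            )
        )
        expected_mV = -bjerrum_length_vacuum(300.0) / (4.0 * d) / LN10 * pk_to_mv(300.0)
        assert em1 - em0 == pytest.approx(expected_mV, rel=0.05)


class TestRigidMotionInvariance:
    def test_titration_invariant_under_translation_rotation(self):
        from scipy.spatial.transform import Rotation

        spec = ToySpec(n_sites=2, site_kinds=["acid", "base"], geometry=6.0, seed=6)
        s, _ = make_toy_multisite(spec)
        env = DielectricEnvironment(eps_protein=80, eps_water=80)
        pka0 = titrate_pka(
            TitrationSystem(s, env=env, **CHEAP).build_model(), "T:1", engine="exact"
        ).pka
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True)
        moved = s.copy()
        for a in moved.atoms:
            a.xyz = rot.apply(a.xyz) + np.array([3.3, -7.1, 11.9])
        pka1 = titrate_pka(
            TitrationSystem(moved, env=env, **CHEAP).build_model(), "T:1", engine="exact"
        ).pka
        assert pka1 == pytest.approx(pka0, abs=0.15)
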