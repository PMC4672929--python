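"""Species enumeration, free energies, and ensemble evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemoclust import (
    ComplexSpecies,
    EnsembleParameters,
    EnsembleSystem,
    ExpressionCondition,
    LigandBinding,
    LinkerScheme,
    ModificationState,
    RestGroup,
    dimer_free_energies,
    ensemble_state,
    enumerate_species,
    linker_potentials,
    species_table,
)
from conftest import random_parameter_draw


class TestDimerFreeEnergies:
    def test_zero_concentration_leaves_only_offset_and_potential(self):
        mod = ModificationState(-2.42)
        b = LigandBinding(kd_on=2.18, kd_off=0.002)
        f_on, f_off = dimer_free_energies(0.0, mod, b, mu=0.0)
        assert f_on == pytest.approx(-2.42)
        assert f_off == pytest.approx(0.0)

    def test_hand_evaluated_values(self):
        mod = ModificationState(-1.12)
        b = LigandBinding(kd_on=2.18, kd_off=0.001)
        f_on, f_off = dimer_free_energies(0.1, mod, b, mu=0.0)
        assert f_on == pytest.approx(-1.1648505661653519, abs=1e-12)
        assert f_off == pytest.approx(-math.log(101), abs=1e-12)

    def test_large_concentration_gap_approaches_offset_plus_kd_ratio(self):
        mod = ModificationState(-1.5)
        b = LigandBinding(kd_on=2.0, kd_off=0.001)
        f_on, f_off = dimer_free_energies(1e9, mod, b, mu=0.3)
        assert f_on - f_off == pytest.approx(-1.5 + math.log(2.0 / 0.001), rel=1e-6)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            dimer_free_energies(-1.0, ModificationState(-1.0),
                                LigandBinding(kd_on=1.0, kd_off=0.1), 0.0)


class TestLinkerPotentials:
    def test_wild_type_identity(self, tsr_params, wildtype):
        mu_w, mu_a2, _ = linker_potentials(wildtype, tsr_params)
        assert mu_w == pytest.approx(tsr_params.mu_w0)
        assert mu_a2 == pytest.approx(tsr_params.mu_a2_0)

    @pytest.mark.parametrize(
        "i, j, expect_w, expect_a",
        [
            (10.0, 1.0, -2.972585092994046, -1.68),
            (1.0, 0.25, -0.67, -0.29370563888010937),
        ],
    )
    def test_expression_scaling(self, tsr_params, i, j, expect_w, expect_a):
        mu_w, mu_a2, _ = linker_potentials(
            ExpressionCondition(w_mult=i, a_mult=j), tsr_params
        )
        assert mu_w == pytest.approx(expect_w, abs=1e-12)
        assert mu_a2 == pytest.approx(expect_a, abs=1e-12)

    def test_no_chea_gives_infinite_potential(self, tsr_params):
        _, mu_a2, _ = linker_potentials(
            ExpressionCondition(w_mult=1.0, a_mult=0.0), tsr_params
        )
        assert mu_a2 == math.inf

    def test_w2_unit_scales_as_two_monomers(self, wonly_params):
        _, _, mu_w2 = linker_potentials(
            ExpressionCondition(w_mult=10.0), wonly_params
        )
        assert mu_w2 == pytest.approx(wonly_params.mu_w2_0 - 2 * math.log(10))

    def test_nonpositive_w_rejected(self):
        with pytest.raises(ValueError):
            ExpressionCondition(w_mult=0.0)


class TestEnumeration:
    @pytest.mark.parametrize(
        "x_max, scheme, expected",
        [
            (4, LinkerScheme.BRIDGED, 12),
            (1, LinkerScheme.BRIDGED, 3),
            (4, LinkerScheme.BRIDGED_PLUS_WONLY, 30),
            (4, LinkerScheme.SYMMETRIC, 12),
            (4, LinkerScheme.SYMMETRIC_PLUS_WONLY, 30),
        ],
    )
    def test_species_counts(self, x_max, scheme, expected):
        species = enumerate_species(x_max, scheme)
        assert len(species) == expected
        assert len(set(species)) == expected  # duplicate-free

    def test_single_trimer_complexes_have_no_linkers(self):
        for sp in enumerate_species(1, LinkerScheme.BRIDGED):
            assert sp.n_linkers_a == 0 and sp.n_linkers_w == 0

    def test_species_invariants(self):
        for sp in enumerate_species(4, LinkerScheme.BRIDGED_PLUS_WONLY):
            assert sp.n_linkers_a + sp.n_linkers_w == sp.x - 1
            assert sp.multiplicity == math.comb(sp.x - 1, sp.n_linkers_a)
            assert sp.n_dimers == 3 * sp.x <= 12
            expect_a2 = sp.n_linkers_a + ((sp.x + 2) if sp.rest is RestGroup.R3 else 0)
            assert sp.n_a2 == expect_a2

    def test_invalid_x_max_rejected(self):
        with pytest.raises(ValueError):
            enumerate_species(0)

    def test_species_table_csv_roundtrip(self, tmp_path):
        df = species_table(enumerate_species(4, LinkerScheme.BRIDGED_PLUS_WONLY))
        assert list(df.columns) == [
            "x", "rest", "n_linkers_a", "n_linkers_w", "multiplicity", "n_w", "n_a2",
        ]
        path = tmp_path / "species.csv"
        df.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(df, back)


class TestEnsembleState:
    def test_zero_energy_hand_enumeration(self, zero_energy_params, wildtype):
        """With every energy zero each of the 12 species has weight 2,
        so Z = 25, rho = 7.2 and the activity is 36/25."""
        st_ = ensemble_state(zero_energy_params, wildtype, c=0.0, mu=0.0)
        assert np.allclose(st_.p_species, 2.0 / 25.0, atol=1e-14)
        assert np.allclose(st_.p_on, 0.5, atol=1e-14)
        assert st_.p_empty == pytest.approx(1.0 / 25.0, abs=1e-14)
        assert st_.rho == pytest.approx(7.2, abs=1e-12)
        assert st_.activity == pytest.approx(36.0 / 25.0, abs=1e-12)

    def test_no_chea_means_no_activity(self, tsr_params):
        st_ = ensemble_state(
            tsr_params, ExpressionCondition(w_mult=1.0, a_mult=0.0), c=0.01, mu=0.0
        )
        assert st_.activity == 0.0
        assert st_.rho > 0  # CheA-free species still populate the membrane

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_normalization_for_random_parameters(self, seed):
        rng = np.random.default_rng(seed)
        scheme = list(LinkerScheme)[int(rng.integers(4))]
        params = random_parameter_draw(rng, scheme)
        cond = ExpressionCondition(
            w_mult=float(rng.uniform(0.05, 20.0)), a_mult=float(rng.uniform(0.05, 20.0))
        )
        st_ = ensemble_state(params, cond,
                             c=float(rng.uniform(0.0, 10.0)),
                             mu=float(rng.uniform(-10.0, 10.0)))
        assert st_.p_species.sum() + st_.p_empty == pytest.approx(1.0, abs=1e-12)
        assert np.all((st_.p_on >= 0) & (st_.p_on <= 1))
        assert 0.0 <= st_.rho <= 3 * params.x_max + 1e-9
        assert st_.activity >= 0.0

    def test_log_space_matches_naive_exponentials(self, tsr_params, wildtype):
        system = EnsembleSystem(tsr_params, wildtype)
        c, mu = 0.05, 1.3
        F_on, F_off = system.free_energies(c, mu)
        mult = np.exp(system.log_mult)
        w_naive = mult * (np.exp(-F_on) + np.exp(-F_off))
        z_naive = 1.0 + w_naive.sum()
        st_ = system.state(c, mu)
        assert np.allclose(st_.p_species, w_naive / z_naive, rtol=1e-10)
        assert st_.p_empty == pytest.approx(1.0 / z_naive, rel=1e-10)

    def test_extreme_energies_do_not_overflow(self, tsr_params):
        st_ = ensemble_state(tsr_params, ExpressionCondition(w_mult=1e4), 1e3, -200.0)
        assert np.isfinite(st_.activity)
        assert st_.p_species.sum() + st_.p_empty == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_linker_factorization_closed_form(self, seed):
        """Summing the mixed-linker species with binomial multiplicity
        must reproduce the closed form in which each of the x - 1 linker
        slots contributes (e^-e_A + e^-e_W) independently."""
        rng = np.random.default_rng(seed)
        params = random_parameter_draw(rng, LinkerScheme.BRIDGED_PLUS_WONLY)
        cond = ExpressionCondition(
            w_mult=float(rng.uniform(0.2, 5.0)), a_mult=float(rng.uniform(0.2, 5.0))
        )
        c, mu = float(rng.uniform(0.0, 2.0)), float(rng.uniform(-3.0, 3.0))
        system = EnsembleSystem(params, cond)
        F_on, F_off = system.free_energies(c, mu)
        mult = np.exp(system.log_mult)

        mu_w, mu_a2, mu_w2 = linker_potentials(cond, params)
        e_a = mu_a2 + 2 * mu_w
        e_w = mu_w2 + 2 * mu_w
        f_on, f_off = dimer_free_energies(c, params.mod, params.binding, mu)
        for x in range(1, params.x_max + 1):
            for rest in RestGroup:
                sel = [k for k, sp in enumerate(system.species)
                       if sp.x == x and sp.rest is rest]
                rest_e = {"R1": 0.0, "R2": (x + 2) * mu_w,
                          "R3": (x + 2) * (mu_w + mu_a2)}[rest.value]
                link_on = (math.exp(-(e_a + params.j_coupling))
                           + math.exp(-(e_w + params.j_coupling))) ** (x - 1)
                link_off = (math.exp(-e_a) + math.exp(-e_w)) ** (x - 1)
                closed_on = math.exp(-(3 * x * f_on + rest_e)) * link_on
                closed_off = math.exp(-(3 * x * f_off + rest_e)) * link_off
                assert np.sum(mult[sel] * np.exp(-F_on[sel])) == pytest.approx(
                    closed_on, rel=1e-10
                )
                assert np.sum(mult[sel] * np.exp(-F_off[sel])) == pytest.approx(
                    closed_off, rel=1e-10
                )

    @pytest.mark.parametrize("base, extended", [
        (LinkerScheme.BRIDGED, LinkerScheme.BRIDGED_PLUS_WONLY),
        (LinkerScheme.SYMMETRIC, LinkerScheme.SYMMETRIC_PLUS_WONLY),
    ])
    def test_infinite_w2_potential_reduces_to_base_scheme(self, base, extended):
        common = dict(delta_eps=-1.8, kd_on=3.5, kd_off=0.003, J=-4.0,
                      mu_w0=-0.8, mu_a2_0=-1.6, rho=3.5)
        p_base = EnsembleParameters.from_dict({**common, "scheme": base.value})
        p_ext = EnsembleParameters.from_dict(
            {**common, "scheme": extended.value, "mu_w2_0": math.inf}
        )
        cond = ExpressionCondition(w_mult=2.0, a_mult=0.5)
        for c, mu in [(0.0, 0.0), (0.05, 1.0), (0.5, -2.0)]:
            s_base = ensemble_state(p_base, cond, c, mu)
            s_ext = ensemble_state(p_ext, cond, c, mu)
            assert s_ext.activity == pytest.approx(s_base.activity, rel=1e-12)
            assert s_ext.rho == pytest.approx(s_base.rho, rel=1e-12)
            assert s_ext.p_empty == pytest.approx(s_base.p_empty, rel=1e-12)

    def test_invalid_linker_split_rejected(self):
        with pytest.raises(ValueError):
            ComplexSpecies(x=3, rest=RestGroup.R1, n_linkers_a=1, n_linkers_w=0)
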