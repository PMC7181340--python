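import pytest
from hypothesis import given, settings, strategies as st

from antioxkit.fixtures import FixtureSpec, make_species_set, random_fixture_spec
from antioxkit.mechanisms import (
    Mechanism,
    MechanismPolicy,
    SiteThermo,
    aip,
    bde,
    ete,
    pa,
    pde,
    preferred_mechanism,
    site_table,
    substituent_effect,
)
from antioxkit.species import Form, Phase, PhaseReferences, ReferenceEnthalpies, SpeciesRecord
from antioxkit.units import HARTREE_TO_KCAL

REFS = PhaseReferences(h_atom=-0.495, proton=0.0024, electron=0.0012)


class TestElementaryParameters:
    def test_bde_null_reaction(self):
        assert bde(-100.0, -100.0 - REFS.h_atom, REFS) == pytest.approx(0.0, abs=1e-9)

    def test_aip_null_reaction(self):
        assert aip(-100.0, -100.0, REFS) == 0.0

    def test_aip_electron_term_is_additive(self):
        base = aip(-100.0, -99.6, REFS)
        full = aip(-100.0, -99.6, REFS, include_electron=True)
        assert full - base == pytest.approx(REFS.electron * HARTREE_TO_KCAL, rel=1e-12)

    def test_pde_null_reaction_gives_proton_enthalpy(self):
        assert pde(-99.5, -99.5, REFS) == pytest.approx(REFS.proton * HARTREE_TO_KCAL)

    def test_pa_null_reaction_gives_proton_enthalpy(self):
        assert pa(-100.0, -100.0, REFS) == pytest.approx(REFS.proton * HARTREE_TO_KCAL)

    def test_ete_equal_enthalpies(self):
        assert ete(-99.7, -99.7) == 0.0

    def test_record_pair_phase_mismatch(self):
        gas = SpeciesRecord("m", Form.NEUTRAL, Phase.GAS, -100.0)
        wat = SpeciesRecord("m", Form.RADICAL, Phase.WATER, -99.5, site="3")
        with pytest.raises(ValueError, match="phase mismatch"):
            bde(gas, wat, ReferenceEnthalpies(gas=REFS, water=REFS))

    def test_record_pair_molecule_mismatch(self):
        a = SpeciesRecord("a", Form.NEUTRAL, Phase.GAS, -100.0)
        b = SpeciesRecord("b", Form.RADICAL, Phase.GAS, -99.5, site="3")
        with pytest.raises(ValueError, match="molecule mismatch"):
            bde(a, b, ReferenceEnthalpies(gas=REFS))


class TestPetunidinSiteTable:
    def test_gas_bdes_recovered(self, gas_site_table):
        bdes = {t.site: t.bde for t in gas_site_table}
        expected = {"3": 78.72, "5": 85.06, "7": 88.94, "3'": 90.25, "4'": 79.84}
        for site, value in expected.items():
            assert bdes[site] == pytest.approx(value, abs=1e-9)

    def test_water_bde_site3(self, water_site_table):
        bdes = {t.site: t.bde for t in water_site_table}
        assert bdes["3"] == pytest.approx(77.02, abs=1e-9)

    def test_gas_two_step_parameters(self, gas_site_table):
        row = next(t for t in gas_site_table if t.site == "3")
        assert row.aip == pytest.approx(229.91, abs=1e-9)
        assert row.pde == pytest.approx(162.56, abs=1e-9)
        assert row.pa == pytest.approx(-112.68, abs=1e-9)
        assert row.ete == pytest.approx(505.15, abs=1e-9)

    def test_two_step_sums_close_the_cycle(self, gas_site_table):
        for row in gas_site_table:
            assert row.aip + row.pde == pytest.approx(row.pa + row.ete, abs=1e-6)

    def test_missing_neutral_is_an_error(self, petunidin, fixture_refs):
        gas = [r for r in petunidin.species_for(Phase.GAS) if r.form is not Form.NEUTRAL]
        with pytest.raises(ValueError, match="neutral"):
            site_table(gas, fixture_refs, phase=Phase.GAS)

    def test_single_site_input(self, fixture_refs):
        records = make_species_set(
            FixtureSpec(molecule_id="m", refs=fixture_refs.gas, bde={"7": 92.4})
        )
        table = site_table(records, fixture_refs)
        assert len(table) == 1
        assert table[0].site == "7"
        assert table[0].bde == pytest.approx(92.4, abs=1e-9)
        assert table[0].aip is None and table[0].pa is None


class TestPreferredMechanism:
    @staticmethod
    def _table(bde_val, aip_val, pa_val):
        return [
            SiteThermo("m", "3", Phase.GAS, bde=bde_val, aip=aip_val, pa=pa_val)
        ]

    def test_published_parameters_select_hat(self):
        verdict = preferred_mechanism(self._table(78.72, 229.91, -112.68))
        assert verdict.mechanism is Mechanism.HAT
        assert verdict.first_step_parameter == 78.72
        assert [m for m, _ in verdict.excluded] == [Mechanism.SPLET]

    @pytest.mark.parametrize("params, winner", [
        ((50.0, 200.0, 80.0), Mechanism.HAT),
        ((90.0, 60.0, 75.0), Mechanism.SET_PT),
        ((90.0, 85.0, 75.0), Mechanism.SPLET),
    ])
    def test_strict_minimum_wins(self, params, winner):
        assert preferred_mechanism(self._table(*params)).mechanism is winner

    def test_tie_breaks_in_fixed_order(self):
        verdict = preferred_mechanism(self._table(70.0, 70.0, 70.0))
        assert verdict.mechanism is Mechanism.HAT

    def test_all_excluded_demands_explicit_policy(self):
        with pytest.raises(ValueError, match="MechanismPolicy"):
            preferred_mechanism(self._table(-5.0, -1.0, -2.0))
        relaxed = MechanismPolicy(exclude_nonpositive=False)
        assert preferred_mechanism(self._table(-5.0, -1.0, -2.0), relaxed).mechanism \
            is Mechanism.HAT

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            preferred_mechanism([])


class TestSubstituentEffect:
    def test_amino_variant_lowers_every_site(self, gas_site_table, petunidin, fixture_refs):
        variant = site_table(list(petunidin.amino_species), fixture_refs)
        effect = substituent_effect(gas_site_table, variant)
        assert effect.verdict.value == "all_lower"
        assert len(effect.delta_bde) == 5
        assert effect.not_comparable == ()

    def test_glucoside_lacks_site3(self, gas_site_table, petunidin, fixture_refs):
        variant = site_table(list(petunidin.glucoside_species), fixture_refs)
        effect = substituent_effect(gas_site_table, variant)
        assert effect.verdict.value == "all_lower"
        assert len(effect.delta_bde) == 4
        assert effect.not_comparable == ("3",)

    def test_identical_tables_report_none(self, gas_site_table):
        effect = substituent_effect(gas_site_table, gas_site_table)
        assert effect.verdict.value == "none"
        assert all(d == 0 for d in effect.delta_bde.values())

    def test_disjoint_site_sets_rejected(self):
        a = [SiteThermo("m", "3", Phase.GAS, bde=80.0)]
        b = [SiteThermo("m", "5", Phase.GAS, bde=70.0)]
        with pytest.raises(ValueError, match="no sites"):
            substituent_effect(a, b)


class TestInvariants:
    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_cycle_closure_on_random_fixtures(self, seed):
        """AIP+PDE = PA+ETE = BDE + H(H+) − H(H•) for any consistent set."""
        spec = random_fixture_spec(seed, n_sites=3)
        table = site_table(
            make_species_set(spec), ReferenceEnthalpies(gas=spec.refs)
        )
        shift = (spec.refs.proton - spec.refs.h_atom) * HARTREE_TO_KCAL
        for row in table:
            assert row.aip + row.pde == pytest.approx(row.bde + shift, abs=1e-6)
            assert row.pa + row.ete == pytest.approx(row.bde + shift, abs=1e-6)

    @given(
        seed=st.integers(0, 2**31 - 1),
        shift=st.floats(-5.0, 5.0, allow_nan=False),
    )
    @settings(max_examples=40, deadline=None)
    def test_uniform_enthalpy_shift_leaves_parameters_unchanged(self, seed, shift):
        """Every mechanism equation balances species counts, so adding a
        constant to all enthalpies of one molecule changes nothing."""
        spec = random_fixture_spec(seed, n_sites=2)
        refs = ReferenceEnthalpies(gas=spec.refs)
        base = site_table(make_species_set(spec), refs)
        shifted_records = [
            SpeciesRecord(
                molecule_id=r.molecule_id, form=r.form, site=r.site, phase=r.phase,
                enthalpy=r.enthalpy + shift,
            )
            for r in make_species_set(spec)
        ]
        shifted = site_table(shifted_records, refs)
        for a, b in zip(base, shifted):
            for name in ("bde", "aip", "pde", "pa", "ete"):
                assert getattr(b, name) == pytest.approx(
                    getattr(a, name), rel=1e-9, abs=2e-6
                )
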