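import itertools

import pytest

from sideroforge.assembly import (
    CAPS,
    EnumerationConfig,
    NotASubstrateError,
    ent_oligomer,
    enumerate_ent_series,
    enumerate_products,
    make_full_analog,
    make_intermediate,
)
from sideroforge.chemcore import Formula, monoisotopic_mass

CH2_MASS = monoisotopic_mass(Formula.parse("CH2"))
WATER_MASS = monoisotopic_mass(Formula.parse("H2O"))


class TestIntermediates:
    def test_putrescine(self, registry_by_id):
        product = make_intermediate(registry_by_id[5])
        assert product.id == "M5"
        assert round(product.mz, 4) == 225.1234

    def test_diaminooctane(self, registry_by_id):
        product = make_intermediate(registry_by_id[21])
        assert product.id == "M21"
        assert round(product.mz, 4) == 281.1860

    def test_urea_is_not_a_substrate(self, registry_by_id):
        with pytest.raises(NotASubstrateError):
            make_intermediate(registry_by_id[18])

    def test_single_amide_provenance(self, registry_by_id):
        product = make_intermediate(registry_by_id[1])
        assert [s.bond for s in product.provenance] == ["root", "amide"]
        assert product.waters_lost == 1


class TestFullAnalogs:
    def test_m1tc(self, registry_by_id):
        inter = make_intermediate(registry_by_id[1])
        product = make_full_analog(inter, CAPS["Tc"])
        assert product.id == "M1Tc"
        assert round(product.mz, 4) == 430.1609

    def test_m2so(self, registry_by_id):
        product = make_full_analog(make_intermediate(registry_by_id[2]), CAPS["So"])
        assert product.id == "M2So"
        assert round(product.mz, 4) == 505.2293

    def test_m9sc_uses_secondary_amine(self, registry_by_id):
        product = make_full_analog(make_intermediate(registry_by_id[9]), CAPS["Sc"])
        assert round(product.mz, 4) == 492.1765

    def test_single_site_precursor_rejected(self, registry_by_id):
        inter = make_intermediate(registry_by_id[17])  # one aromatic amine
        with pytest.raises(NotASubstrateError):
            make_full_analog(inter, CAPS["Tc"])

    def test_secondary_amines_can_be_disabled(self, registry_by_id):
        inter = make_intermediate(registry_by_id[9], allow_secondary=False)
        with pytest.raises(NotASubstrateError):
            make_full_analog(inter, CAPS["Tc"])

    @pytest.mark.parametrize(
        "code,delta",
        [("Tc", 219.0532), ("To", 237.0637), ("Sc", 205.0375), ("So", 223.0481)],
    )
    def test_cap_compositions(self, code, delta):
        assert round(monoisotopic_mass(CAPS[code].composition), 4) == delta


class TestEnumeration:
    def test_two_entry_registry(self, registry_by_id):
        products = enumerate_products(
            [registry_by_id[1]], EnumerationConfig(caps=("Tc",))
        )
        assert [p.id for p in products] == ["M1", "M1Tc"]

    def test_mass_identical_intermediates(self, registry_by_id):
        products = enumerate_products(
            [registry_by_id[7], registry_by_id[11]], EnumerationConfig(caps=())
        )
        assert len(products) == 2
        assert round(products[0].mz, 4) == round(products[1].mz, 4) == 273.1234

    def test_empty_registry(self):
        assert enumerate_products([]) == []

    def test_count_law_brute_force(self, registry):
        # oracle: expected count computed directly from amine arithmetic
        cfg = EnumerationConfig()
        for subset in itertools.combinations(registry[:10], 3):
            expected = 0
            for p in subset:
                sites = p.n_primary_amines + p.n_secondary_amines
                if sites >= 1:
                    expected += 1
                if sites >= 2:
                    expected += len(cfg.caps)
            assert len(enumerate_products(subset, cfg)) == expected

    def test_regioisomers_collapsed_with_multiplicity(self, candidates):
        ids = [p.id for p in candidates]
        assert len(ids) == len(set(ids))
        by_id = {p.id: p for p in candidates}
        assert by_id["M2"].multiplicity == 3  # two primary + one secondary site

    def test_deterministic_order(self, registry):
        products = enumerate_products(registry)
        again = enumerate_products(registry)
        assert [p.id for p in products] == [p.id for p in again]
        ref_nos = [p.precursor_id for p in products]
        assert ref_nos == sorted(ref_nos)

    def test_vibriobactin_never_emitted(self, candidates):
        # vibriobactin = norspermidine + one DHB amide + two oxazoline caps;
        # mono-capping means its formula can never be produced
        vibriobactin = Formula.parse("C35H39N5O11")
        for product in candidates:
            assert product.formula != vibriobactin
            if product.kind == "analog":
                cap_steps = [s for s in product.provenance if s.block.startswith("DHB-")]
                assert len(cap_steps) == 1


class TestEntSeries:
    def test_cyclic_trilactone(self):
        product = ent_oligomer("Ser", 3, cyclic=True)
        assert product.id == "Ent"
        assert round(product.mz, 4) == 670.1515

    def test_monomer(self):
        product = ent_oligomer("Ser", 1)
        assert product.id == "Ent monomer"
        assert round(product.mz, 4) == 242.0659

    def test_thr_dimer(self):
        product = ent_oligomer("Thr", 2)
        assert product.id == "Thr-Ent dimer"
        assert round(product.mz, 4) == 493.1453

    def test_cyclic_requires_three_units(self):
        with pytest.raises(ValueError):
            ent_oligomer("Ser", 2, cyclic=True)

    def test_series_contents(self):
        ids = {p.id for p in enumerate_ent_series()}
        assert {"Ent", "Ent trimer", "Ent dimer", "Ent monomer", "Thr-Ent dimer"} <= ids

    def test_linear_trimer_exceeds_cyclic_by_one_water(self):
        linear = ent_oligomer("Ser", 3)
        cyclic = ent_oligomer("Ser", 3, cyclic=True)
        assert linear.neutral_mass - cyclic.neutral_mass == pytest.approx(
            WATER_MASS, abs=1e-9
        )


class TestIsobarProperties:
    def test_ser_thr_substitution_shifts_by_methylene(self, registry_by_id):
        for inter_id in (1, 2, 5, 6, 9):
            inter = make_intermediate(registry_by_id[inter_id])
            for ser_code, thr_code in (("Sc", "Tc"), ("So", "To")):
                ser = make_full_analog(inter, CAPS[ser_code])
                thr = make_full_analog(inter, CAPS[thr_code])
                assert thr.neutral_mass - ser.neutral_mass == pytest.approx(
                    CH2_MASS, abs=1e-9
                )
        for n in (1, 2, 3):
            shift = ent_oligomer("Thr", n).neutral_mass - ent_oligomer("Ser", n).neutral_mass
            assert shift == pytest.approx(n * CH2_MASS, abs=1e-9)
        assert CH2_MASS == pytest.approx(14.0157, abs=5e-5)

    def test_cyclization_shifts_by_water(self, registry_by_id):
        inter = make_intermediate(registry_by_id[1])
        for open_code, closed_code in (("So", "Sc"), ("To", "Tc")):
            open_cap = make_full_analog(inter, CAPS[open_code])
            closed = make_full_analog(inter, CAPS[closed_code])
            assert open_cap.neutral_mass - closed.neutral_mass == pytest.approx(
                WATER_MASS, abs=1e-9
            )

    def test_provenance_water_bookkeeping(self, candidates):
        # formula must equal the sum of its blocks minus the provenance waters
        for product in candidates:
            assert product.mz == pytest.approx(
                monoisotopic_mass(product.formula) + 1.00727646, abs=1e-12
            )
            assert product.waters_lost >= 1
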