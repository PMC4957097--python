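import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turgorkit.mixtures import (
    DEFAULT_SPECIES,
    AssociationEstimate,
    MixtureComposition,
    OsmolyteSpecies,
    OsmoticModelParams,
    anomer_fractions,
    association_degree,
    estimate_osmotic_potential,
    gamma_factor,
    mixture_from_ratio,
    osmotic_potential_ratio,
    round_half_up,
    rt_mpa_per_molar,
    table1_report,
)


class TestMixtureFromRatio:
    @pytest.mark.parametrize(
        "ratio,total,expected",
        [
            ("5:12:3", 1.00, {"KCl": 0.25, "D-Glc": 0.60, "L-Gln": 0.15}),
            ("15:12:3", 1.50, {"KCl": 0.75, "D-Glc": 0.60, "L-Gln": 0.15}),
            ("0:12:3", 0.75, {"D-Glc": 0.60, "L-Gln": 0.15}),
            ("25:12:3", 1.50, {"KCl": 0.9375, "D-Glc": 0.45, "L-Gln": 0.1125}),
        ],
    )
    def test_tabulated_compositions(self, ratio, total, expected):
        mix = mixture_from_ratio(ratio, total)
        assert set(mix.species_molarity) == set(expected)
        for sp, m in expected.items():
            assert mix.species_molarity[sp] == pytest.approx(m, rel=1e-12)

    def test_single_species_degenerate_ratio(self):
        mix = mixture_from_ratio("1:0:0", 0.42)
        assert mix.species_molarity == {"KCl": pytest.approx(0.42)}

    @pytest.mark.parametrize(
        "ratio,total",
        [("0:0:0", 1.0), ("-1:2:3", 1.0), ("1:2", 1.0), ("a:b:c", 1.0),
         ("1:1:1", 0.0), ("1:1:1", -1.0), ("", 1.0)],
    )
    def test_invalid_inputs(self, ratio, total):
        with pytest.raises(ValueError):
            mixture_from_ratio(ratio, total)

    @given(
        r1=st.integers(0, 50), r2=st.integers(0, 50), r3=st.integers(0, 50),
        total=st.floats(0.01, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_ratio_round_trip(self, r1, r2, r3, total):
        if r1 + r2 + r3 == 0:
            return
        g = math.gcd(r1, r2, r3)
        mix = mixture_from_ratio(f"{r1}:{r2}:{r3}", total)
        assert mix.ratio_ints() == (r1 // g, r2 // g, r3 // g)

    def test_molarity_sum_invariant(self):
        with pytest.raises(ValueError):
            MixtureComposition({"KCl": 0.5, "D-Glc": 0.6}, total_molarity=1.0)
        with pytest.raises(ValueError):
            MixtureComposition({"KCl": -0.1}, total_molarity=-0.1)


class TestGammaFactor:
    def test_ideal_glucose(self, params):
        assert gamma_factor(DEFAULT_SPECIES["D-Glc"], params) == 1.0

    def test_electrolyte_kcl(self, params):
        assert gamma_factor(DEFAULT_SPECIES["KCl"], params) == pytest.approx(1.8)

    def test_amino_acid_default_matches_back_calculation(self, params):
        # independent oracle: invert the two-component sugar+amino-acid row,
        # gamma = (Pi / (R T) - [Glc]) / [Gln] with Pi = 2.23 MPa
        rt = rt_mpa_per_molar(params)
        gamma_oracle = (2.23 / rt - 0.60) / 0.15
        assert gamma_factor(DEFAULT_SPECIES["L-Gln"], params) == pytest.approx(
            gamma_oracle, abs=0.005
        )

    def test_amino_acid_hook_overrides_constant(self):
        p = OsmoticModelParams(gamma_gln_hook=lambda pp: 1.5)
        assert gamma_factor(DEFAULT_SPECIES["L-Gln"], p) == 1.5

    def test_custom_constant(self, params):
        sp = OsmolyteSpecies(name="x", gamma_mode="custom-constant", custom_gamma=1.23)
        assert gamma_factor(sp, params) == 1.23

    def test_custom_constant_requires_value(self):
        with pytest.raises(ValueError):
            OsmolyteSpecies(name="x", gamma_mode="custom-constant")

    def test_species_validation(self):
        with pytest.raises(ValueError):
            OsmolyteSpecies(name="x", vant_hoff_i=0)
        with pytest.raises(ValueError):
            OsmolyteSpecies(name="x", phi=1.3)
        with pytest.raises(ValueError):
            OsmolyteSpecies(name="x", rejection_sigma=1.5)
        with pytest.raises(ValueError):
            OsmolyteSpecies(name="x", gamma_mode="bogus")


class TestEstimateOsmoticPotential:
    @pytest.mark.parametrize(
        "ratio,total,expected",
        [
            ("1:0:0", 1.50, 6.74),
            ("5:12:0", 0.85, 2.62),
            ("0:12:3", 0.75, 2.23),
            ("5:12:3", 1.00, 3.35),
        ],
    )
    def test_reference_rows_two_decimals(self, ratio, total, expected, params):
        mix = mixture_from_ratio(ratio, total)
        assert round_half_up(estimate_osmotic_potential(mix, params), 2) == expected

    def test_empty_mixture_is_zero(self, params):
        mix = MixtureComposition({}, total_molarity=0.0)
        assert estimate_osmotic_potential(mix, params) == 0.0

    def test_unknown_species_raises(self, params):
        mix = MixtureComposition({"urea": 1.0}, total_molarity=1.0)
        with pytest.raises(KeyError):
            estimate_osmotic_potential(mix, params)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            OsmoticModelParams(T=0.0)

    @given(
        m1=st.floats(0, 2), m2=st.floats(0, 2), m3=st.floats(0, 2),
        lam=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_molarity(self, m1, m2, m3, lam, params):
        mix = MixtureComposition(
            {"KCl": m1, "D-Glc": m2, "L-Gln": m3}, total_molarity=m1 + m2 + m3
        )
        pi = estimate_osmotic_potential(mix, params)
        pi_scaled = estimate_osmotic_potential(mix.scaled(lam), params)
        assert pi_scaled == pytest.approx(lam * pi, rel=1e-12, abs=1e-15)

    @given(a=st.floats(0, 2), b=st.floats(0, 2))
    @settings(max_examples=50, deadline=None)
    def test_additivity_over_disjoint_parts(self, a, b, params):
        part1 = MixtureComposition({"KCl": a}, total_molarity=a)
        part2 = MixtureComposition({"D-Glc": b}, total_molarity=b)
        union = MixtureComposition(
            {"KCl": a, "D-Glc": b}, total_molarity=a + b
        )
        assert estimate_osmotic_potential(union, params) == pytest.approx(
            estimate_osmotic_potential(part1, params)
            + estimate_osmotic_potential(part2, params),
            rel=1e-12, abs=1e-15,
        )


class TestRatioAndDegree:
    @pytest.mark.parametrize(
        "measured,estimated,expected",
        [(2.93, 3.35, 0.87), (4.83, 5.11, 0.95), (1.0, 1.0, 1.00)],
    )
    def test_ratio_two_decimals(self, measured, estimated, expected):
        assert round_half_up(
            osmotic_potential_ratio(measured, estimated), 2
        ) == expected

    def test_ratio_rejects_nonpositive_estimate(self):
        with pytest.raises(ValueError):
            osmotic_potential_ratio(1.0, 0.0)
        with pytest.raises(ValueError):
            osmotic_potential_ratio(-1.0, 1.0)

    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.87, 19.5), (0.88, 18.0), (0.85, 22.5), (0.95, 7.5),
         (1.00, 0.0), (1.01, 0.0), (1.2, 0.0)],
    )
    def test_degree_values(self, ratio, expected):
        assert association_degree(ratio) == pytest.approx(expected, abs=1e-12)

    def test_degree_rejects_nonpositive_ratio(self):
        with pytest.raises(ValueError):
            association_degree(0.0)

    @given(r=st.floats(0.01, 2.0), dr=st.floats(0.0, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_degree_non_increasing_in_ratio(self, r, dr):
        assert association_degree(r + dr) <= association_degree(r) + 1e-12

    def test_association_estimate_builder(self):
        est = AssociationEstimate.from_measurement(2.93, 3.35)
        assert est.ratio == pytest.approx(2.93 / 3.35)
        assert est.association_degree_percent == pytest.approx(19.5)
        assert est.n_members == 4
        assert est.deficit_multiplier == 1.5


class TestAnomerFractions:
    @pytest.mark.parametrize(
        "ia,ib,expected", [((36), 64, (36, 64)), (1, 1, (50, 50)), (77, 23, (77, 23))]
    )
    def test_values(self, ia, ib, expected):
        fa, fb = anomer_fractions(ia, ib)
        assert (fa, fb) == pytest.approx(expected)
        assert fa + fb == pytest.approx(100.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            anomer_fractions(0, 0)
        with pytest.raises(ValueError):
            anomer_fractions(-1, 1)


class TestTable1Report:
    def test_full_reproduction(self, fixture_entries, params):
        report = table1_report(
            [(e["mixture"], e["measured_MPa"], e["estimated_ref_MPa"])
             for e in fixture_entries],
            params,
        ).set_index("name")
        # estimated potentials for the internally consistent rows
        for name, pi in [("KCl", 6.74), ("M1", 3.35), ("M1a", 2.23), ("M1b", 2.62)]:
            assert report.loc[name, "estimated_MPa"] == pi
        for name, ratio in [
            ("M1", 0.87), ("M1a", 0.87), ("M1b", 1.01), ("M1c", 0.77),
            ("M2", 0.88), ("M2a", 0.85), ("M2b", 0.95), ("KCl", 0.95),
        ]:
            assert report.loc[name, "ratio"] == ratio
        for name, deg in [("M1", 19.5), ("M2", 18.0), ("M2a", 22.5), ("M2b", 7.5)]:
            assert report.loc[name, "assoc_degree_pct"] == deg
        # degree only proposed for three-component mixtures
        for name in ("M1a", "M1b", "M1c", "KCl"):
            assert math.isnan(report.loc[name, "assoc_degree_pct"])

    def test_ideal_single_species_row(self, params):
        mix = mixture_from_ratio("0:1:0", 0.5, name="glc")
        est = estimate_osmotic_potential(mix, params)
        report = table1_report([(mix, round_half_up(est, 2))], params)
        assert report.loc[0, "ratio"] == 1.00
        assert math.isnan(report.loc[0, "assoc_degree_pct"])

    def test_compositionality_against_elementwise_ops(self, params):
        mixes = [
            mixture_from_ratio("3:5:2", 0.9, name="a"),
            mixture_from_ratio("1:1:1", 1.2, name="b"),
        ]
        meas = [2.0, 2.5]
        report = table1_report([(m, v) for m, v in zip(mixes, meas)], params)
        for i, (mix, mv) in enumerate(zip(mixes, meas)):
            est = estimate_osmotic_potential(mix, params)
            ratio = osmotic_potential_ratio(mv, round_half_up(est, 2))
            assert report.loc[i, "estimated_MPa"] == round_half_up(est, 2)
            assert report.loc[i, "ratio"] == round_half_up(ratio, 2)
            assert report.loc[i, "assoc_degree_pct"] == pytest.approx(
                round_half_up(association_degree(ratio), 1)
            )

    def test_empty_entries_rejected(self, params):
        with pytest.raises(ValueError):
            table1_report([], params)
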