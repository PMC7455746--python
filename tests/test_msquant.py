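"""Calibration, isotope and stoichiometry bookkeeping vs closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from vesiquant.msquant import (
    DEFAULT_SPECIES,
    CalibrationFit,
    IsotopeLabel,
    average_injections,
    chain_composition_fractions,
    conversion_yield,
    counts_to_concentration,
    fit_calibration,
    isotope_mass_shift,
    normalize_to_reference_peptide,
    quantify_samples,
    random_incorporation_null,
)
from vesiquant.synthetic import MSSpec, generate_ms_tables


def peak_rows(entries):
    return pd.DataFrame(
        entries,
        columns=["sample_id", "transition_id", "injection", "counts", "block",
                 "concentration_uM"],
    )


class TestAverageInjections:
    def test_pair_averaged(self):
        table = peak_rows(
            [("s1", "DOPE", 1, 1000.0, "sample", np.nan),
             ("s1", "DOPE", 2, 1200.0, "sample", np.nan)]
        )
        out = average_injections(table)
        assert len(out) == 1
        assert out["counts"].iloc[0] == pytest.approx(1100.0)
        assert out["n_injections"].iloc[0] == 2

    def test_single_injection_flagged(self):
        table = peak_rows([("s1", "DOPE", 1, 900.0, "sample", np.nan)])
        out = average_injections(table)
        assert out["counts"].iloc[0] == 900.0
        assert out["n_injections"].iloc[0] == 1

    def test_fifty_pairs_match_group_mean_oracle(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(50):
            for inj in (1, 2):
                rows.append(
                    (f"s{i}", "DOPG", inj, float(rng.uniform(100, 5000)), "sample", np.nan)
                )
        table = peak_rows(rows)
        out = average_injections(table).set_index("sample_id")["counts"]
        expected = table.groupby("sample_id")["counts"].mean()
        for sid, val in expected.items():
            assert out[sid] == pytest.approx(val, rel=1e-12)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            average_injections(pd.DataFrame({"sample_id": [], "transition_id": [],
                                             "injection": []}))


class TestCalibration:
    def test_exact_line_recovered(self):
        rows = []
        for block in ("pre", "post"):
            for conc in (1.0, 5.0, 20.0):
                for inj in (1, 2):
                    rows.append(
                        (f"cal_{block}_{conc}", "DOPE", inj, 1000.0 * conc, block, conc)
                    )
        fit = fit_calibration(peak_rows(rows), "DOPE")
        assert fit.slope_counts_per_uM == pytest.approx(1000.0)
        assert fit.intercept_counts == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_pre_post_blocks_pooled(self):
        # slope 990 pre, 1010 post, same levels: pooled OLS slope is 1000
        rows = []
        for block, slope in (("pre", 990.0), ("post", 1010.0)):
            for conc in (1.0, 5.0, 20.0, 50.0):
                rows.append((f"cal_{block}_{conc}", "DOPG", 1, slope * conc + 7.0,
                             block, conc))
        fit = fit_calibration(peak_rows(rows), "DOPG")
        assert fit.slope_counts_per_uM == pytest.approx(1000.0)
        assert fit.intercept_counts == pytest.approx(7.0)

    def test_degenerate_levels_rejected(self):
        rows = [("c1", "DOPE", 1, 1000.0, "pre", 5.0),
                ("c2", "DOPE", 1, 1001.0, "post", 5.0)]
        with pytest.raises(ValueError):
            fit_calibration(peak_rows(rows), "DOPE")

    def test_inversion_examples(self):
        fit = CalibrationFit("DOPE", 1000.0, 0.0, 1.0, (1.0, 10.0))
        conc, clamped = counts_to_concentration(3000.0, fit)
        assert conc == pytest.approx(3.0) and not clamped
        fit2 = CalibrationFit("DOPE", 1000.0, 250.0, 1.0, (1.0, 10.0))
        conc2, _ = counts_to_concentration(250.0, fit2)
        assert conc2 == 0.0
        conc3, clamped3 = counts_to_concentration(100.0, fit2)
        assert conc3 == 0.0 and clamped3

    def test_nonpositive_slope_rejected(self):
        fit = CalibrationFit("DOPE", 0.0, 0.0, 1.0, (1.0, 10.0))
        with pytest.raises(ValueError):
            counts_to_concentration(100.0, fit)

    def test_noise_free_round_trip_exact(self):
        spec = MSSpec(
            count_noise_cv=0.0,
            true_concentrations_uM={"s1": {"DOPE": 12.0, "DOPG": 8.0}},
            seed=0,
        )
        cal, samples, truth = generate_ms_tables(spec)
        quant = quantify_samples(cal, samples)
        merged = quant.merge(truth, on=["sample_id", "transition_id"])
        np.testing.assert_allclose(
            merged["concentration_uM_x"], merged["concentration_uM_y"], rtol=1e-9
        )

    def test_five_percent_cv_median_error_bounded(self):
        concs = {f"s{i}": {"DOPE": 5.0 + i * 0.4, "DOPG": 2.0 + i * 0.3}
                 for i in range(50)}
        spec = MSSpec(true_concentrations_uM=concs, count_noise_cv=0.05, seed=23)
        cal, samples, truth = generate_ms_tables(spec)
        quant = quantify_samples(cal, samples)
        merged = quant.merge(truth, on=["sample_id", "transition_id"])
        rel_err = np.abs(
            merged["concentration_uM_x"] - merged["concentration_uM_y"]
        ) / merged["concentration_uM_y"]
        assert len(rel_err) == 100
        assert np.median(rel_err) <= 0.05


class TestNormalization:
    def test_examples(self):
        assert normalize_to_reference_peptide(2000.0, 2000.0) == 1.0
        assert normalize_to_reference_peptide(500.0, 2000.0) == 0.25

    def test_batch_matches_per_row_division(self):
        rng = np.random.default_rng(1)
        counts = rng.uniform(10, 1e5, 30)
        ref = 4321.0
        out = normalize_to_reference_peptide(counts, ref)
        np.testing.assert_allclose(out, [c / ref for c in counts], rtol=1e-15)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference_peptide(100.0, 0.0)


class TestIsotopeShift:
    def test_single_g3p_species_shift_three(self):
        assert isotope_mass_shift("DOPE") == 3.0
        assert isotope_mass_shift("DOPS") == 3.0
        assert isotope_mass_shift("LPA") == 3.0

    def test_pg_shift_six(self):
        assert isotope_mass_shift("DOPG") == 6.0
        assert isotope_mass_shift("PGP") == 6.0

    def test_unlabeled_precursor_zero_shift(self):
        label = IsotopeLabel(heavy_atoms_per_moiety=0)
        assert isotope_mass_shift("DOPE", label) == 0.0

    def test_exact_mode_uses_13c_mass_defect(self):
        shift = isotope_mass_shift("DOPG", rounding="exact")
        assert shift == pytest.approx(6 * 1.003355)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            isotope_mass_shift("PLASMALOGEN-X")


class TestChainComposition:
    def test_equimolar_null_is_half_mixed(self):
        null = random_incorporation_null(0.5)
        assert null["PO"] == pytest.approx(0.5)
        assert null["DP"] == pytest.approx(0.25) and null["DO"] == pytest.approx(0.25)

    def test_pure_palmitoyl_null(self):
        null = random_incorporation_null(1.0)
        assert null == {"DP": 1.0, "DO": 0.0, "PO": 0.0}

    @given(p=st.floats(0.0, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_null_matches_enumeration_and_sums_to_one(self, p):
        null = random_incorporation_null(p)
        ref = oracles.random_chain_pair_fractions(p)
        for key in ("DP", "DO", "PO"):
            assert null[key] == pytest.approx(ref[key], abs=1e-12)
        assert sum(null.values()) == pytest.approx(1.0, abs=1e-12)

    def test_p_030_hand_computed(self):
        null = random_incorporation_null(0.3)
        assert null["DP"] == pytest.approx(0.09)
        assert null["PO"] == pytest.approx(0.42)
        assert null["DO"] == pytest.approx(0.49)

    def test_observed_fractions_from_concentrations(self):
        observed, null = chain_composition_fractions(
            {"DOPE": 4.0, "DOPG": 4.0, "POPE": 8.0, "POPG": 2.0, "DPPE": 2.0}
        )
        assert observed["DO"] == pytest.approx(0.4)
        assert observed["PO"] == pytest.approx(0.5)
        assert observed["DP"] == pytest.approx(0.1)
        assert sum(observed.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            chain_composition_fractions({"DOPE": 0.0})


class TestConversionYield:
    def test_twenty_micromolar_products_is_forty_percent(self):
        products = {"DOPE": 12.0, "DOPG": 8.0}  # diacyl, 2 chains each
        assert conversion_yield(products, 100.0) == pytest.approx(40.0)

    def test_zero_products(self):
        assert conversion_yield({"DOPE": 0.0}, 100.0) == 0.0

    def test_mono_and_diacyl_chain_counting(self):
        # 10 uM LPA (1 chain) + 5 uM PA (2 chains) from 100 uM acyl-CoA
        products = {"LPA": 10.0, "DPPA": 5.0}
        assert conversion_yield(products, 100.0) == pytest.approx(20.0)

    @given(
        c1=st.floats(0.0, 25.0),
        c2=st.floats(0.0, 25.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity_and_bound(self, c1, c2):
        y = conversion_yield({"DOPE": c1, "DOPG": c2}, 100.0)
        assert y == pytest.approx(2 * (c1 + c2), rel=1e-12)
        assert 0.0 <= y <= 100.0

    def test_nonpositive_precursor_rejected(self):
        with pytest.raises(ValueError):
            conversion_yield({"DOPE": 1.0}, 0.0)


class TestSpeciesRegistry:
    def test_pg_class_carries_two_g3p_moieties(self):
        for sid, sp in DEFAULT_SPECIES.items():
            if sp.headgroup_class in ("PG", "PGP"):
                assert sp.n_g3p_moieties == 2
            else:
                assert sp.n_g3p_moieties == 1

    def test_lpa_is_monoacyl(self):
        assert DEFAULT_SPECIES["LPA"].n_acyl_chains == 1
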