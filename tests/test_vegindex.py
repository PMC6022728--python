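"""Registry, band-math parser, and the strict missing-wavelength rule."""

import numpy as np
import pandas as pd
import pytest

import proxispec as px
from proxispec.errors import FormulaSyntaxError, RegistryError

NDVI_TEXT = "(R800-R670)/(R800+R670)"


def _random_collection(rng, n=10, lo=400, hi=1000):
    wl = np.arange(lo, hi + 1, dtype=float)
    values = rng.uniform(0.01, 1.0, size=(n, wl.size))
    return px.build_collection(
        [px.Spectrum(f"s{i}", wl, values[i]) for i in range(n)]
    )


class TestRegistry:
    def test_bundle_holds_140_definitions(self, registry):
        assert len(registry) == 140

    def test_named_indices_present(self, registry):
        names = {d.name for d in registry}
        assert {"NDVI", "PSND", "TCARI", "BGI", "Gitelson", "EVI",
                "Vogelmann", "WI"} <= names

    def test_ndvi_requires_670_and_800(self, registry):
        ndvi = next(d for d in registry if d.name == "NDVI")
        assert ndvi.required_wavelengths == {670, 800}

    def test_all_bands_within_working_range(self, registry):
        for d in registry:
            assert all(400 <= b <= 1000 for b in d.required_wavelengths), d.name

    def test_duplicate_name_in_extra_registry_rejected(self, tmp_path):
        extra = tmp_path / "extra.tsv"
        extra.write_text("NDVI\tR800/R670\ty\tduplicate\n")
        with pytest.raises(RegistryError, match="NDVI"):
            px.load_registry(extra=[extra])

    def test_malformed_line_reports_line_number(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("OK\tR800/R670\ty\tref\nBROKEN LINE WITHOUT TABS\n")
        with pytest.raises(RegistryError, match=":2"):
            px.load_registry(path=bad)

    def test_extra_registry_appends_user_indices(self, tmp_path, registry):
        extra = tmp_path / "extra.tsv"
        extra.write_text("MyVI\t(R780-R680)/(R780+R680)\ty\tuser\n")
        defs = px.load_registry(extra=[extra])
        assert len(defs) == len(registry) + 1
        assert defs[-1].name == "MyVI"


class TestParser:
    def test_term_extraction(self):
        d = px.parse_formula(NDVI_TEXT)
        assert d.required_wavelengths == {670, 800}

    def test_single_band_identity(self, flat_spectrum):
        d = px.parse_formula("R800")
        c = px.build_collection([flat_spectrum])
        assert px.evaluate_index(c, d).values.iloc[0] == pytest.approx(0.3)

    def test_syntax_error_with_position(self):
        with pytest.raises(FormulaSyntaxError):
            px.parse_formula("R800-R670)/(")

    @pytest.mark.parametrize("bad", ["", "R800 +", "(R800", "R800 R670", "2 ** 3"])
    def test_malformed_expressions_rejected(self, bad):
        with pytest.raises(FormulaSyntaxError):
            px.parse_formula(bad)

    def test_out_of_range_band_warns_but_parses(self):
        with pytest.warns(UserWarning, match="1240"):
            d = px.parse_formula("(R860-R1240)/(R860+R1240)")
        assert 1240 in d.required_wavelengths

    def test_precedence_and_unary_minus(self, flat_spectrum):
        c = px.build_collection([flat_spectrum])
        v = px.evaluate_index(c, px.parse_formula("1+2*3-4/2")).values.iloc[0]
        assert v == pytest.approx(5.0)
        v = px.evaluate_index(c, px.parse_formula("-R800+1")).values.iloc[0]
        assert v == pytest.approx(0.7)

    def test_typographic_operator_aliases(self, flat_spectrum):
        c = px.build_collection([flat_spectrum])
        a = px.evaluate_index(c, px.parse_formula("(R800−R670)÷(R800+R670)"))
        b = px.evaluate_index(c, px.parse_formula(NDVI_TEXT))
        assert a.values.iloc[0] == b.values.iloc[0]


class TestEvaluation:
    def test_flat_spectrum_ndvi_zero(self, flat_spectrum):
        c = px.build_collection([flat_spectrum])
        v = px.evaluate_index(c, px.parse_formula(NDVI_TEXT, name="NDVI"))
        assert v.values.iloc[0] == pytest.approx(0.0, abs=1e-15)

    def test_direct_arithmetic_example(self):
        wl = np.array([670.0, 800.0])
        c = px.build_collection([px.Spectrum("s", wl, np.array([0.05, 0.50]))])
        v = px.evaluate_index(c, px.parse_formula(NDVI_TEXT))
        assert v.values.iloc[0] == pytest.approx(0.45 / 0.55)
        assert v.values.iloc[0] == pytest.approx(0.818182, abs=5e-7)

    def test_missing_band_yields_missing_for_all(self, trial, registry):
        collection, _, _ = trial
        ndvi = next(d for d in registry if d.name == "NDVI")
        trimmed = collection.trim(400, 750)  # 800 nm band gone
        v = px.evaluate_index(trimmed, ndvi)
        assert v.values.isna().all()

    def test_division_by_zero_is_missing(self):
        wl = np.array([670.0, 800.0])
        c = px.build_collection([
            px.Spectrum("zero", wl, np.array([0.0, 0.0])),
            px.Spectrum("ok", wl, np.array([0.05, 0.50])),
        ])
        v = px.evaluate_index(c, px.parse_formula(NDVI_TEXT))
        assert np.isnan(v.values["zero"])
        assert np.isfinite(v.values["ok"])

    def test_missing_operand_propagates(self):
        wl = np.array([670.0, 800.0])
        c = px.build_collection([
            px.Spectrum("nan670", wl, np.array([np.nan, 0.50])),
        ])
        v = px.evaluate_index(c, px.parse_formula(NDVI_TEXT))
        assert np.isnan(v.values.iloc[0])

    def test_full_resolution_collection_no_missing(self, trial, registry):
        collection, _, _ = trial
        table = px.evaluate_all(collection.trim(400, 1000), registry)
        assert table.shape == (40, 140)
        assert int(table.isna().sum().sum()) == 0

    def test_single_band_collection_mostly_missing(self, registry):
        wl = np.array([550.0])
        c = px.build_collection([px.Spectrum("s", wl, np.array([0.3]))])
        table = px.evaluate_all(c, registry)
        needs_other = [d.name for d in registry if d.required_wavelengths != {550}]
        assert table[needs_other].isna().all().all()
        # Carter6 is literally R550 and stays defined
        assert table["Carter6"].iloc[0] == pytest.approx(0.3)

    def test_evaluate_all_equals_stacked_single_calls(self, registry, rng):
        c = _random_collection(rng, n=5)
        subset = registry[:10]
        table = px.evaluate_all(c, subset)
        for d in subset:
            single = px.evaluate_index(c, d).values
            assert np.allclose(table[d.name], single, equal_nan=True)

    def test_column_order_follows_registry(self, registry, rng):
        c = _random_collection(rng, n=3)
        table = px.evaluate_all(c, registry)
        assert list(table.columns) == [d.name for d in registry]


class TestIndexProperties:
    def test_reentered_formulas_match_registry_evaluation(self, registry, rng):
        """Re-parsing every bundled formula from its text reproduces the
        registry evaluation to 1e-12 on 100 random spectra."""
        c = _random_collection(rng, n=100)
        for d in registry:
            reentered = px.parse_formula(d.formula, name=d.name)
            a = px.evaluate_index(c, d).values.to_numpy()
            b = px.evaluate_index(c, reentered).values.to_numpy()
            assert np.allclose(a, b, rtol=0, atol=1e-12, equal_nan=True), d.name

    def test_ndvi_matches_independent_numpy_oracle(self, rng):
        c = _random_collection(rng, n=50)
        r670 = c.band(670)
        r800 = c.band(800)
        oracle = (r800 - r670) / (r800 + r670)
        got = px.evaluate_index(c, px.parse_formula(NDVI_TEXT)).values.to_numpy()
        assert np.allclose(got, oracle, atol=1e-12, rtol=0)

    def test_flagged_ratio_indices_are_scale_invariant(self, registry, rng):
        wl = np.arange(400.0, 1001.0)
        base = rng.uniform(0.05, 0.9, wl.size)
        for factor in (0.5, 3.7):
            c = px.build_collection([
                px.Spectrum("x", wl, base),
                px.Spectrum("scaled", wl, factor * base),
            ])
            for d in registry:
                if not d.scale_invariant:
                    continue
                v = px.evaluate_index(c, d).values
                assert v["x"] == pytest.approx(v["scaled"], rel=1e-9, abs=1e-12), d.name

    def test_ndvi_monotone_in_nir(self):
        wl = np.array([670.0, 800.0])
        d = px.parse_formula(NDVI_TEXT)
        prev = -np.inf
        for nir in np.linspace(0.1, 0.9, 9):
            c = px.build_collection([px.Spectrum("s", wl, np.array([0.05, nir]))])
            v = px.evaluate_index(c, d).values.iloc[0]
            assert v > prev
            prev = v
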