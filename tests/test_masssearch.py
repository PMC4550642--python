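"""Adduct arithmetic, tolerance search, filters and peak-list I/O."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minekit.masssearch import (
    Peak,
    PeakListError,
    SearchConfig,
    adduct_table,
    get_adduct,
    neutral_candidates,
    read_peaklist,
    search_peaks,
    theoretical_mz,
    write_results,
)
from minekit.registry import ELECTRON_MASS, compound_id, exact_mass, formula_mass

GLUCOSE_MASS = 180.06339


class TestAdductTable:
    # shifts are exact consequences of CODATA particle masses and the
    # monoisotopic masses of Na and CH3COOH
    @pytest.mark.parametrize(
        "name,shift",
        [
            ("[M+H]+", 1.007276),
            ("[M+Na]+", 22.989218),
            ("[M+]+", -0.000549),
            ("[M-H]-", -1.007276),
            ("[M+CH3COO]-", 59.013853),
        ],
    )
    def test_shifts(self, name, shift):
        assert get_adduct(name).mass_shift == pytest.approx(shift, abs=1e-5)

    def test_shift_recomputable_from_mass_table(self):
        acetate = get_adduct("[M+CH3COO]-")
        assert acetate.mass_shift == pytest.approx(
            formula_mass("C2H4O2") - (formula_mass("H") - ELECTRON_MASS), abs=1e-5
        )

    def test_radical_cation_is_minus_one_electron(self):
        assert get_adduct("[M+]+").mass_shift == -ELECTRON_MASS

    def test_polarities(self):
        table = {a.name: a.polarity for a in adduct_table()}
        assert table["[M+H]+"] == "+" and table["[M-H]-"] == "-"


class TestMzArithmetic:
    def test_glucose_protonated(self):
        assert theoretical_mz(GLUCOSE_MASS, "[M+H]+") == pytest.approx(181.07067, abs=1e-4)

    def test_round_trip_inverse(self):
        for adduct in adduct_table():
            mz = theoretical_mz(250.1, adduct)
            pairs = dict(
                (a.name, m) for a, m in neutral_candidates(mz, [adduct])
            )
            assert pairs[adduct.name] == pytest.approx(250.1, abs=1e-9)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            theoretical_mz(0.0, "[M+H]+")


def _brute_force(bundle, peaks, config):
    """Independent oracle: exhaustive (compound x adduct) scan."""
    out = {}
    for peak in peaks:
        hits = []
        tol = config.tolerance_da(peak.mz)
        for cid in bundle.compounds:
            comp = bundle.compounds[cid]
            for name in config.adducts:
                adduct = get_adduct(name)
                if adduct.polarity != peak.polarity:
                    continue
                theo = adduct.mz(comp.exact_mass)
                if abs(peak.mz - theo) <= tol:
                    hits.append((cid, adduct.name, round((peak.mz - theo) * 1e3, 6)))
        hits.sort(key=lambda h: (abs(h[2]), h[0], h[1]))
        out[peak.peak_id] = hits
    return out


class TestSearchPeaks:
    def test_glucose_peak_annotated_within_half_mda(self, bundle):
        glucose_id = compound_id("OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O")
        mass = bundle.compounds[glucose_id].exact_mass
        peak = Peak("p1", round(theoretical_mz(mass, "[M+H]+"), 4), "+")
        hits = search_peaks(bundle, [peak], SearchConfig(tolerance_mda=2.0))
        ids = [h.compound_id for h in hits["p1"]]
        assert glucose_id in ids
        best = next(h for h in hits["p1"] if h.compound_id == glucose_id)
        assert abs(best.error_mda) < 0.5

    def test_shifted_peak_outside_window(self, bundle):
        glucose_id = compound_id("OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O")
        mass = bundle.compounds[glucose_id].exact_mass
        peak = Peak("p1", theoretical_mz(mass, "[M+H]+") + 0.0100, "+")
        hits = search_peaks(bundle, [peak], SearchConfig(tolerance_mda=2.0))
        assert all(h.compound_id != glucose_id for h in hits["p1"])

    def test_empty_bundle_annotates_nothing(self):
        from minekit.datastore import DatabaseBundle

        hits = search_peaks(DatabaseBundle(), [Peak("p", 100.0, "+")])
        assert hits == {"p": []}

    def test_polarity_must_match(self, bundle):
        glucose_id = compound_id("OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O")
        mass = bundle.compounds[glucose_id].exact_mass
        peak = Peak("p1", theoretical_mz(mass, "[M+H]+"), "-")
        hits = search_peaks(bundle, [peak], SearchConfig(tolerance_mda=2.0))
        assert all(h.adduct.endswith("-") for h in hits["p1"])

    def test_unparseable_polarity_skipped(self, bundle):
        hits = search_peaks(bundle, [Peak("p1", 100.0, "x")])
        assert hits == {}

    def test_matches_brute_force_oracle(self, big_bundle):
        adducts = adduct_table()
        peaks = []
        for i, cid in enumerate(sorted(big_bundle.compounds)[:100]):
            adduct = adducts[i % len(adducts)]
            mz = adduct.mz(big_bundle.compounds[cid].exact_mass) + (i % 3 - 1) * 4e-4
            peaks.append(Peak(f"p{i}", mz, adduct.polarity))
        for tol in (0.5, 2.0, 5.0):
            config = SearchConfig(tolerance_mda=tol)
            got = search_peaks(big_bundle, peaks, config)
            expected = _brute_force(big_bundle, peaks, config)
            simplified = {
                p: [(h.compound_id, h.adduct, round(h.error_mda, 6)) for h in hs]
                for p, hs in got.items()
            }
            assert simplified == expected

    def test_self_recall(self, big_bundle):
        # every compound is recovered from its own theoretical adduct mass
        adducts = adduct_table()
        for i, cid in enumerate(sorted(big_bundle.compounds)[:100]):
            adduct = adducts[i % len(adducts)]
            mz = adduct.mz(big_bundle.compounds[cid].exact_mass)
            hits = search_peaks(
                big_bundle, [Peak("p", mz, adduct.polarity)],
                SearchConfig(tolerance_mda=0.5, adducts=[adduct.name]),
            )
            assert cid in {h.compound_id for h in hits["p"]}

    def test_tolerance_monotonicity(self, big_bundle):
        peaks = [Peak(f"p{i}", 60.0 + 7.3 * i, "+") for i in range(20)]
        prev: dict[str, set] = {}
        for tol in (0.5, 2.0, 5.0):
            hits = search_peaks(big_bundle, peaks, SearchConfig(tolerance_mda=tol))
            current = {p: {(h.compound_id, h.adduct) for h in hs} for p, hs in hits.items()}
            for p in prev:
                assert prev[p] <= current[p]
            prev = current

    def test_property_filter_never_adds_hits(self, bundle):
        peaks = [Peak("p1", 181.0707, "+"), Peak("p2", 101.0233, "-")]
        base = search_peaks(bundle, peaks, SearchConfig(tolerance_mda=5.0))
        filtered = search_peaks(
            bundle, peaks, SearchConfig(tolerance_mda=5.0, logp_range=(-10.0, 10.0))
        )
        for p in base:
            assert {h.compound_id for h in filtered[p]} <= {h.compound_id for h in base[p]}

    def test_annotated_compound_outside_range_fails_filter(self, bundle):
        glucose_id = compound_id("OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O")
        bundle.compounds[glucose_id].properties["logp"] = -2.6
        mass = bundle.compounds[glucose_id].exact_mass
        peak = Peak("p1", theoretical_mz(mass, "[M+H]+"), "+")
        inside = search_peaks(
            bundle, [peak], SearchConfig(tolerance_mda=2.0, logp_range=(-5.0, 0.0))
        )
        outside = search_peaks(
            bundle, [peak], SearchConfig(tolerance_mda=2.0, logp_range=(0.0, 5.0))
        )
        assert glucose_id in {h.compound_id for h in inside["p1"]}
        assert glucose_id not in {h.compound_id for h in outside["p1"]}
        del bundle.compounds[glucose_id].properties["logp"]

    def test_organism_flag(self, bundle):
        glucose_id = compound_id("OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O")
        mass = bundle.compounds[glucose_id].exact_mass
        peak = Peak("p1", theoretical_mz(mass, "[M+H]+"), "+")
        hits = search_peaks(
            bundle, [peak], SearchConfig(tolerance_mda=2.0, organism_ids={glucose_id})
        )
        flags = {h.compound_id: h.in_organism for h in hits["p1"]}
        assert flags[glucose_id] is True
        assert all(not v for c, v in flags.items() if c != glucose_id)

    def test_ppm_tolerance_mode(self, bundle):
        with pytest.raises(ValueError):
            SearchConfig(tolerance_mda=2.0, tolerance_ppm=5.0)
        config = SearchConfig(tolerance_mda=None, tolerance_ppm=10.0)
        assert config.tolerance_da(500.0) == pytest.approx(0.005)


class TestPeakListIO:
    def test_round_trip(self, fixture_dir, tmp_path):
        peaks = read_peaklist(fixture_dir / "peaks.csv")
        assert len(peaks) >= 10
        assert all(p.mz > 0 and p.polarity in "+-" for p in peaks)

    def test_extra_columns_ignored(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("peak_id,mz,polarity,rt,comment\na,100.5,+,12.2,hello\n")
        peaks = read_peaklist(path)
        assert peaks[0].mz == 100.5

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("peak_id,mass,polarity\na,100.5,+\n")
        with pytest.raises(PeakListError, match="mz"):
            read_peaklist(path)

    def test_non_numeric_mz_reports_row(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("peak_id,mz,polarity\na,100.5,+\nb,oops,+\n")
        with pytest.raises(PeakListError, match="row 3"):
            read_peaklist(path)

    def test_write_results_columns(self, bundle, tmp_path):
        glucose_id = compound_id("OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O")
        mass = bundle.compounds[glucose_id].exact_mass
        peaks = [Peak("p1", theoretical_mz(mass, "[M+H]+"), "+")]
        hits = search_peaks(bundle, peaks, SearchConfig(tolerance_mda=2.0))
        out = tmp_path / "results.csv"
        write_results(hits, bundle, peaks, out)
        header = out.read_text().splitlines()[0]
        assert header == (
            "peak_id,mz,adduct,compound_id,mine_number,formula,"
            "theoretical_mz,error_mda,inchikey,smiles,in_organism"
        )


@settings(deadline=None, max_examples=50)
@given(st.floats(min_value=50.0, max_value=2000.0, allow_nan=False))
def test_mz_round_trip_property(neutral_mass):
    for adduct in adduct_table():
        mz = theoretical_mz(neutral_mass, adduct)
        assert adduct.neutral_mass(mz) == pytest.approx(neutral_mass, abs=1e-9)
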