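"""Library dereplication and analog annotation: self-match identity,
precursor gating, glycine-shift analog recovery, mass-shift localisation
and family-level propagation."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from actinonet import (
    ConsensusSpectrum,
    LibraryEntry,
    NetworkingParams,
    Spectrum,
    analog_library_search,
    exact_library_search,
    extract_families,
    build_graph,
    localize_mass_shift,
    prepare_library,
    propagate_family_annotations,
)
from actinonet.networking import NetworkEdge

from conftest import make_spectrum

GLYCINE = 57.02146


def as_consensus(spectra):
    return [ConsensusSpectrum(f"Q{i:03d}", s, members=((s.spectrum_id, "f.mgf"),))
            for i, s in enumerate(spectra)]


def library_from(spectra, pathway="Polyketides"):
    return [LibraryEntry(f"L{i:03d}", f"compound_{i}", s, pathway) for i, s in enumerate(spectra)]


@pytest.fixture
def lib_params():
    # generous windows so small hand-built spectra keep enough peaks
    return NetworkingParams(library_min_matched=3, min_matched_peaks=3)


def shifted_analog(entry: Spectrum, delta: float, n_shifted: int) -> Spectrum:
    """Copy of a spectrum with precursor and the n largest fragments
    shifted by delta."""
    mz = entry.mz.copy()
    mz[-n_shifted:] = mz[-n_shifted:] + delta
    return Spectrum.from_peaks("analog", entry.precursor_mz + delta, zip(mz, entry.intensity))


class TestExactSearch:
    def test_identical_query_scores_one(self, rng, lib_params):
        s = make_spectrum(rng, 10, spectrum_id="q")
        lib = library_from([s])
        (ann,) = exact_library_search(as_consensus([s]), lib, lib_params)
        assert ann.mode == "exact"
        assert ann.cosine == pytest.approx(1.0, abs=1e-9)
        assert ann.compound_name == "compound_0"

    def test_precursor_beyond_tolerance_rejected(self, rng, lib_params):
        s = make_spectrum(rng, 10, spectrum_id="q")
        off = dataclasses.replace(s, precursor_mz=s.precursor_mz + 0.05)
        lib = library_from([s])
        assert exact_library_search(as_consensus([off]), lib, lib_params) == []

    def test_empty_library_warns(self, rng, lib_params, caplog):
        with caplog.at_level("WARNING"):
            out = exact_library_search(as_consensus([make_spectrum(rng, 5)]), [], lib_params)
        assert out == []
        assert "empty library" in caplog.text

    def test_library_self_annotation_parity(self, rng):
        """Annotating a preprocessed library against itself yields a
        cosine-1 self match for every entry."""
        params = NetworkingParams()
        raw = [make_spectrum(rng, 30, mz_lo=50, mz_hi=700, precursor=900.0 + 10 * i,
                             spectrum_id=f"lib{i}") for i in range(8)]
        lib = prepare_library(library_from(raw), params)
        queries = [ConsensusSpectrum(e.entry_id, e.spectrum, ((e.entry_id, "lib.mgf"),)) for e in lib]
        anns = exact_library_search(queries, lib, params)
        assert len(anns) == len(lib)
        for a in anns:
            assert a.cosine == pytest.approx(1.0, abs=1e-9)
            assert a.consensus_id == a.entry_id


class TestAnalogSearch:
    def test_glycine_shift_recovered(self, rng, lib_params):
        entry = make_spectrum(rng, 12, mz_lo=100, mz_hi=380, precursor=400.0, spectrum_id="lib")
        analog = shifted_analog(entry, GLYCINE, n_shifted=2)
        lib = library_from([entry])
        (ann,) = analog_library_search(as_consensus([analog]), lib, lib_params)
        assert ann.mode == "analog"
        assert ann.precursor_delta == pytest.approx(GLYCINE, abs=1e-3)
        report = ann.shifted_fragment_report
        assert report is not None
        assert len(report.shifted_pairs) == 2
        assert report.smallest_shifted_mz == pytest.approx(float(entry.mz[-2] + GLYCINE), abs=1e-6)

    def test_delta_beyond_analog_window_rejected(self, rng, lib_params):
        entry = make_spectrum(rng, 12, precursor=400.0, spectrum_id="lib")
        analog = shifted_analog(entry, 250.0, n_shifted=2)
        assert analog_library_search(as_consensus([analog]), library_from([entry]), lib_params) == []

    def test_combined_count_at_least_exact_only(self, rng, lib_params):
        entries = [make_spectrum(rng, 12, precursor=400.0 + 30 * i, spectrum_id=f"l{i}")
                   for i in range(5)]
        queries = [entries[0], shifted_analog(entries[1], 14.01565, 3),
                   make_spectrum(rng, 8, spectrum_id="unrelated")]
        lib = library_from(entries)
        consensus = as_consensus(queries)
        exact = exact_library_search(consensus, lib, lib_params)
        analog = analog_library_search(consensus, lib, lib_params, exact)
        assert len(exact) + len(analog) >= len(exact)
        assert {a.consensus_id for a in exact}.isdisjoint({a.consensus_id for a in analog})

    def test_analog_skips_exactly_annotated_consensus(self, rng, lib_params):
        s = make_spectrum(rng, 12, spectrum_id="q")
        lib = library_from([s, shifted_analog(s, 28.0313, 2)])
        consensus = as_consensus([s])
        exact = exact_library_search(consensus, lib, lib_params)
        assert len(exact) == 1
        assert analog_library_search(consensus, lib, lib_params, exact) == []


class TestLocalization:
    def test_worked_example_partition(self, lib_params):
        lib = Spectrum.from_peaks("lib", 400.0, [(100, 1), (150, 2), (390, 1)])
        query = Spectrum.from_peaks("q", 457.02, [(100, 1), (207.02, 2), (447.02, 1)])
        report = localize_mass_shift(query, lib, 57.02, lib_params)
        assert [q for q, _ in report.direct_pairs] == [100.0]
        assert sorted(q for q, _ in report.shifted_pairs) == [207.02, 447.02]
        assert report.smallest_shifted_mz == 207.02

    def test_rejects_delta_within_precursor_tolerance(self, rng, lib_params):
        s = make_spectrum(rng, 6)
        with pytest.raises(ValueError, match="analog"):
            localize_mass_shift(s, s, 0.01, lib_params)

    def test_all_pairs_shifted_flags_smallest_fragment(self, lib_params):
        lib = Spectrum.from_peaks("lib", 400.0, [(120, 1), (200, 2), (300, 1)])
        query = Spectrum.from_peaks("q", 414.01565,
                                    [(134.01565, 1), (214.01565, 2), (314.01565, 1)])
        report = localize_mass_shift(query, lib, 14.01565, lib_params)
        assert report.all_shifted
        assert report.smallest_shifted_mz == pytest.approx(134.01565)

    def test_no_matches_gives_empty_report(self, lib_params):
        lib = Spectrum.from_peaks("lib", 400.0, [(100, 1)])
        query = Spectrum.from_peaks("q", 450.0, [(333.0, 1)])
        report = localize_mass_shift(query, lib, 50.0, lib_params)
        assert report.direct_pairs == () and report.shifted_pairs == ()
        assert report.smallest_shifted_mz is None


class TestFamilyPropagation:
    def _families(self):
        edges = [NetworkEdge("Q000", "Q001", 0.9, 8, 0.0)]
        g = build_graph([f"Q{i:03d}" for i in range(4)], edges)
        return extract_families(g)

    def test_one_annotated_node_labels_family(self, rng, lib_params):
        s = make_spectrum(rng, 10, spectrum_id="q")
        lib = library_from([s])
        anns = exact_library_search(as_consensus([s]), lib, lib_params)
        table = propagate_family_annotations(self._families(), anns)
        fam_of_q000 = table[table.family_id == "MF_0000"].iloc[0]
        assert bool(fam_of_q000.annotated)
        assert "compound_0" in fam_of_q000.compound_names

    def test_unannotated_families_flagged(self):
        table = propagate_family_annotations(self._families(), [])
        assert not table.annotated.any()

    def test_counts_match_bruteforce_recount(self, rng, lib_params):
        entries = [make_spectrum(rng, 12, precursor=350.0 + 40 * i, spectrum_id=f"l{i}")
                   for i in range(6)]
        queries = entries[:3] + [make_spectrum(rng, 8, spectrum_id=f"u{i}") for i in range(5)]
        consensus = as_consensus(queries)
        anns = exact_library_search(consensus, library_from(entries), lib_params)
        g = build_graph([c.consensus_id for c in consensus], [])
        fams = extract_families(g)
        table = propagate_family_annotations(fams, anns)
        annotated_nodes = {a.consensus_id for a in anns}
        expected = sum(1 for f in fams if any(n in annotated_nodes for n in f.nodes))
        assert int(table.annotated.sum()) == expected
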