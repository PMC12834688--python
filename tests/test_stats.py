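"""Incidence, rarefaction (closed form vs exhaustive orderings), media
overlap partition, annotation rates and the pathway x media matrix."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from actinonet import (
    Annotation,
    ConsensusSpectrum,
    IncidenceMatrix,
    MolecularFamily,
    Spectrum,
    annotation_rate_summary,
    build_incidence,
    expected_rarefaction,
    media_overlap_counts,
    pathway_media_matrix,
    rarefaction_curve,
)


def consensus_with(cid, strains=(), media=(), n_members=1):
    spec = Spectrum.from_peaks(cid, 500.0, [(100.0, 1.0)])
    return ConsensusSpectrum(
        cid, spec, members=tuple((f"{cid}:{i}", "f.mgf") for i in range(n_members)),
        strain_set=frozenset(strains), media_set=frozenset(media),
    )


def matrix_from(rows, units, annotated=None):
    ids = [f"I{i}" for i in range(len(rows))]
    m = pd.DataFrame(np.array(rows, dtype=bool), index=ids, columns=units)
    flags = pd.Series(annotated if annotated is not None else [False] * len(rows),
                      index=ids, dtype=bool)
    return IncidenceMatrix(m, flags)


class TestIncidence:
    def test_consensus_row(self):
        items = [consensus_with("C1", strains={"S1", "S3"})]
        m = build_incidence(items, ["S1", "S2", "S3"])
        assert m.matrix.loc["C1"].tolist() == [True, False, True]

    def test_family_union_rule(self):
        c1 = consensus_with("C1", strains={"S1"})
        c2 = consensus_with("C2", strains={"S2"})
        fam = MolecularFamily("MF_0000", ("C1", "C2"), ())
        m = build_incidence([fam], ["S1", "S2", "S3"], consensus_by_id={"C1": c1, "C2": c2})
        assert m.matrix.loc["MF_0000"].tolist() == [True, True, False]

    def test_column_sums_match_recount(self, rng):
        strains = [f"S{i}" for i in range(6)]
        items = []
        for i in range(40):
            chosen = set(np.array(strains)[rng.random(6) < 0.4])
            if chosen:
                items.append(consensus_with(f"C{i:02d}", strains=chosen))
        m = build_incidence(items, strains)
        for s in strains:
            expected = sum(1 for it in items if s in it.strain_set)
            assert int(m.matrix[s].sum()) == expected

    def test_unknown_strain_raises(self):
        with pytest.raises(KeyError, match="S9"):
            build_incidence([consensus_with("C1", strains={"S9"})], ["S1"])

    def test_all_zero_rows_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            matrix_from([[True, False], [False, False]], ["A", "B"])


class TestRarefaction:
    def test_saturating_units(self):
        m = matrix_from([[1, 1, 1], [1, 1, 1]], ["A", "B", "C"])
        curve = rarefaction_curve(m, n_permutations=5, seed=0)
        np.testing.assert_allclose(curve.mean, [2, 2, 2])
        np.testing.assert_allclose(curve.sd, 0)

    def test_single_unit(self):
        m = matrix_from([[1]] * 4, ["A"])
        curve = rarefaction_curve(m, n_permutations=3, seed=0)
        np.testing.assert_allclose(curve.mean, [4])

    def test_closed_form_small_example(self):
        # items present in 1, 2 and 3 of 3 units: E[S(1)] = 1/3 + 2/3 + 1 = 2
        m = matrix_from([[1, 0, 0], [1, 1, 0], [1, 1, 1]], ["A", "B", "C"])
        exp = expected_rarefaction(m.matrix.to_numpy())
        assert exp[0] == pytest.approx(2.0, abs=1e-12)
        assert exp[-1] == pytest.approx(3.0, abs=1e-12)

    @pytest.mark.parametrize("n_units", [2, 3, 4, 5])
    def test_all_orderings_mean_equals_closed_form(self, n_units):
        from oracles import brute_rarefaction_all_orderings

        rng = np.random.default_rng(n_units)
        rows = (rng.random((12, n_units)) < 0.5)
        rows = rows[rows.any(axis=1)]
        m = matrix_from(rows.tolist(), [f"U{i}" for i in range(n_units)])
        enumerated = brute_rarefaction_all_orderings(m.matrix.to_numpy())
        closed = expected_rarefaction(m.matrix.to_numpy())
        np.testing.assert_allclose(enumerated, closed, atol=1e-10)
        # permutation machinery agrees when fed every ordering explicitly
        perm_means = np.mean(
            [rarefaction_curve(m, 1, None, order=list(p)).mean
             for p in itertools.permutations(m.matrix.columns)], axis=0)
        np.testing.assert_allclose(perm_means, closed, atol=1e-10)

    def test_curves_monotone_and_conserving(self, rng):
        rows = (rng.random((30, 8)) < 0.3)
        rows = rows[rows.any(axis=1)]
        m = matrix_from(rows.tolist(), [f"U{i}" for i in range(8)])
        curve = rarefaction_curve(m, n_permutations=64, seed=3)
        assert (np.diff(curve.mean) >= -1e-12).all()
        assert curve.mean[-1] == pytest.approx(rows.shape[0])

    def test_stratum_additivity_under_shared_permutations(self, rng):
        rows = (rng.random((25, 6)) < 0.4)
        rows = rows[rows.any(axis=1)]
        annotated = (rng.random(rows.shape[0]) < 0.3).tolist()
        m = matrix_from(rows.tolist(), [f"U{i}" for i in range(6)], annotated)
        kw = dict(n_permutations=32, seed=11)
        total = rarefaction_curve(m, stratum="all", **kw)
        ann = rarefaction_curve(m, stratum="annotated", **kw)
        una = rarefaction_curve(m, stratum="unannotated", **kw)
        np.testing.assert_allclose(ann.mean + una.mean, total.mean, atol=1e-9)

    def test_deterministic_given_seed(self, rng):
        rows = (rng.random((15, 5)) < 0.5)
        rows = rows[rows.any(axis=1)]
        m = matrix_from(rows.tolist(), [f"U{i}" for i in range(5)])
        c1 = rarefaction_curve(m, 20, seed=7)
        c2 = rarefaction_curve(m, 20, seed=7)
        np.testing.assert_array_equal(c1.mean, c2.mean)


class TestMediaOverlap:
    def test_enumerated_example(self):
        all_five = {"ISP2", "ISP4", "TSA", "NSG", "CZP"}
        items = [
            consensus_with("C1", media={"ISP2"}),
            consensus_with("C2", media={"ISP2"}),
            consensus_with("C3", media={"ISP2", "TSA"}),
            consensus_with("C4", media=all_five),
        ]
        exclusive, set_sizes = media_overlap_counts(items)
        exc = dict(zip(exclusive.media_combination, exclusive.exclusive_count))
        assert exc["ISP2"] == 2
        assert exc["ISP2+TSA"] == 1
        assert exc["+".join(sorted(all_five))] == 1
        sizes = dict(zip(set_sizes.media, set_sizes.set_size))
        assert sizes["ISP2"] == 4 and sizes["TSA"] == 2

    def test_exclusive_counts_partition_items(self, rng):
        media = ["ISP2", "ISP4", "TSA", "NSG", "CZP"]
        items = []
        for i in range(60):
            chosen = set(np.array(media)[rng.random(5) < 0.4])
            if chosen:
                items.append(consensus_with(f"C{i:02d}", media=chosen))
        exclusive, set_sizes = media_overlap_counts(items)
        assert exclusive.exclusive_count.sum() == len(items)
        for m in media:
            singleton = exclusive[exclusive.media_combination == m]
            singleton_count = int(singleton.exclusive_count.iloc[0]) if len(singleton) else 0
            size_row = set_sizes[set_sizes.media == m]
            if len(size_row):
                assert int(size_row.set_size.iloc[0]) >= singleton_count

    def test_empty_media_set_raises(self):
        with pytest.raises(ValueError, match="empty media set"):
            media_overlap_counts([consensus_with("C1", media=())])


class TestSummaries:
    def _ann(self, cid, mode="exact", pathway=None):
        return Annotation(cid, "L0", "cmp", 0.9, 8, 0.0, mode, pathway)

    def test_consensus_rate(self):
        items = [consensus_with(f"C{i:03d}") for i in range(100)]
        anns = [self._ann(f"C{i:03d}") for i in range(13)]
        s = annotation_rate_summary(items, anns, [])
        assert s["annotation_rate_consensus"] == pytest.approx(0.13)

    def test_zero_annotations(self):
        items = [consensus_with("C1"), consensus_with("C2")]
        fams = [MolecularFamily("MF_0000", ("C1", "C2"), ())]
        s = annotation_rate_summary(items, [], fams)
        assert s["annotation_rate_consensus"] == 0.0
        assert s["annotated_families"] == 0
        assert s["unannotated_families"] == 1

    def test_raw_spectrum_rate_weighted_by_members(self):
        items = [consensus_with("C1", n_members=9), consensus_with("C2", n_members=1)]
        s = annotation_rate_summary(items, [self._ann("C1")], [])
        assert s["annotation_rate_raw_spectra"] == pytest.approx(0.9)
        assert s["annotation_rate_consensus"] == pytest.approx(0.5)


class TestPathwayMediaMatrix:
    def test_normalised_to_row_maximum(self):
        items = ([consensus_with(f"C{i:02d}", media={"ISP2"}) for i in range(10)]
                 + [consensus_with(f"D{i:02d}", media={"TSA"}) for i in range(5)])
        anns = [self._terp(c.consensus_id) for c in items]
        m = pathway_media_matrix(anns, items)
        assert m.loc["Terpenoids", "ISP2"] == pytest.approx(1.0)
        assert m.loc["Terpenoids", "TSA"] == pytest.approx(0.5)

    def _terp(self, cid):
        return Annotation(cid, "L0", "cmp", 0.9, 8, 0.0, "exact", "Terpenoids")

    def test_single_media_rows_all_one(self):
        items = [consensus_with(f"C{i}", media={"NSG"}) for i in range(4)]
        anns = [self._terp(c.consensus_id) for c in items]
        m = pathway_media_matrix(anns, items)
        assert (m.to_numpy() == 1.0).all()

    def test_matches_bruteforce_group_count(self, rng):
        media = ["ISP2", "TSA", "CZP"]
        pathways = ["Alkaloids", "Terpenoids", "Polyketides"]
        items, anns = [], []
        for i in range(50):
            chosen = set(np.array(media)[rng.random(3) < 0.5])
            if not chosen:
                continue
            c = consensus_with(f"C{i:02d}", media=chosen)
            items.append(c)
            if rng.random() < 0.6:
                anns.append(Annotation(c.consensus_id, "L0", "cmp", 0.9, 8, 0.0,
                                       "exact", str(rng.choice(pathways))))
        m = pathway_media_matrix(anns, items)
        by_id = {c.consensus_id: c for c in items}
        for pw in m.index:
            raw = {mm: 0 for mm in m.columns}
            for a in anns:
                if a.pathway == pw:
                    for mm in by_id[a.consensus_id].media_set:
                        raw[mm] += 1
            peak = max(raw.values())
            for mm in m.columns:
                assert m.loc[pw, mm] == pytest.approx(raw[mm] / peak)
        assert (m.max(axis=1) == 1.0).all()
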