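"""Transcript classification, naming, locus filtering and neighbourhood report."""

import numpy as np
import pandas as pd
import pytest

from lgatlas import transcripts as tr
from lgatlas.simulate import make_neighborhood_fixture, make_toy_annotation


@pytest.fixture(scope="module")
def pipeline(toy_dir):
    """Toy fixture pushed through classify -> name -> filter via file I/O."""
    ref = tr.read_annotation_gtf(toy_dir / "reference.gtf")
    novel = tr.read_transcripts_gtf(toy_dir / "novel.gtf")
    scores = tr.read_coding_scores(toy_dir / "coding_scores.tsv")
    tr.classify_transcripts(novel, ref)
    retained = [t for t in novel if t.class_code in tr.RETAINED_CLASSES]
    for t in retained:
        t.coding_score = float(scores[t.id])
    tr.assign_names(retained, ref)
    final, tally, n_loci = tr.dedupe_and_filter(retained)
    return ref, novel, retained, final, tally, n_loci


class TestClassification:
    def test_class_codes_match_truth(self, pipeline, toy):
        _, novel, _, _, _, _ = pipeline
        expected = dict(zip(toy.truth.transcript_id, toy.truth.class_code))
        got = {t.id: t.class_code for t in novel}
        assert got == expected

    def test_runon_two_kb_boundary(self, pipeline):
        _, novel, _, _, _, _ = pipeline
        codes = {t.id: t.class_code for t in novel}
        assert codes["N_P1"] == "p"   # gap exactly 2,000 bp: run-on
        assert codes["N_P2"] == "u"   # gap 2,001 bp: intergenic

    def test_discard_classes_absent_from_retained(self, pipeline):
        _, _, retained, final, _, _ = pipeline
        assert all(t.class_code in tr.RETAINED_CLASSES for t in retained)
        assert all(t.class_code not in tr.DISCARDED_CLASSES for t in final)

    def test_unknown_chromosome_classified_u(self, pipeline):
        ref, _, _, _, _, _ = pipeline
        orphan = tr.TranscriptModel("O1", "chrUn", "+", [(100, 400)])
        tr.classify_transcripts([orphan], ref)
        assert orphan.class_code == "u"


class TestNaming:
    def test_names_match_truth(self, pipeline, toy):
        _, _, retained, _, _, _ = pipeline
        truth = toy.truth.set_index("transcript_id")
        for t in retained:
            row = truth.loc[t.id]
            assert t.positional_class == row.positional_class, t.id
            assert t.name == row["name"], t.id
            assert t.tucp == row.tucp, t.id

    def test_bi_one_kb_boundary(self, pipeline):
        _, _, retained, _, _, _ = pipeline
        by_id = {t.id: t for t in retained}
        assert by_id["N_BI2"].positional_class == "BI"    # exactly 1,000 bp
        assert by_id["N_NB"].positional_class == "LINC"   # 1,001 bp

    def test_linc_numbering_is_coordinate_sorted(self, pipeline):
        _, _, retained, _, _, _ = pipeline
        by_id = {t.id: t for t in retained}
        # N_C9A was listed after N_C9B in the GTF but has the smaller TSS
        assert by_id["N_C9A"].name == "HE-LINC-C9T1"
        assert by_id["N_C9B"].name == "HE-LINC-C9T2"

    def test_dual_bi_tucp_keeps_positional_name(self, pipeline):
        _, _, retained, _, _, _ = pipeline
        dual = next(t for t in retained if t.id == "N_DUAL")
        assert dual.positional_class == "BI" and dual.tucp

    def test_naming_requires_retained_class(self, pipeline):
        ref, _, _, _, _, _ = pipeline
        bad = tr.TranscriptModel("B", "chr7", "+", [(1, 300)])
        bad.class_code = "j"
        bad.coding_score = 0.1
        with pytest.raises(ValueError, match="retained"):
            tr.assign_names([bad], ref)

    def test_naming_deterministic(self, toy_dir, toy):
        ref = tr.read_annotation_gtf(toy_dir / "reference.gtf")
        runs = []
        for _ in range(2):
            novel = tr.read_transcripts_gtf(toy_dir / "novel.gtf")
            scores = tr.read_coding_scores(toy_dir / "coding_scores.tsv")
            tr.classify_transcripts(novel, ref)
            retained = [t for t in novel if t.class_code in tr.RETAINED_CLASSES]
            for t in retained:
                t.coding_score = float(scores[t.id])
            tr.assign_names(retained, ref)
            runs.append({t.id: t.name for t in retained})
        assert runs[0] == runs[1]


class TestDedupeFilter:
    def test_final_membership_matches_truth(self, pipeline, toy):
        _, _, _, final, _, _ = pipeline
        expected = set(toy.truth[toy.truth.in_final].transcript_id)
        assert {t.id for t in final} == expected

    def test_longest_per_locus(self, pipeline):
        _, _, _, final, _, _ = pipeline
        ids = {t.id for t in final}
        assert "N_L2" in ids and "N_L1" not in ids

    def test_length_strictly_over_200(self, pipeline):
        _, _, _, final, _, _ = pipeline
        ids = {t.id for t in final}
        assert "N_201" in ids
        assert "N_200" not in ids and "N_SHORT" not in ids
        assert all(t.length > 200 for t in final)

    def test_opposite_strands_are_separate_loci(self, pipeline):
        _, _, _, final, _, _ = pipeline
        ids = {t.id for t in final}
        assert {"N_S1", "N_S2"} <= ids

    def test_final_nonoverlapping_per_strand(self, pipeline):
        _, _, _, final, _, _ = pipeline
        for a in final:
            for b in final:
                if a.id < b.id and a.chrom == b.chrom and a.strand == b.strand:
                    assert not tr._exonic_overlap(a, b)

    def test_gtf_roundtrip(self, pipeline, tmp_path):
        _, _, _, final, _, _ = pipeline
        p = tmp_path / "final.gtf"
        tr.write_transcripts_gtf(final, p)
        back = {t.id: t for t in tr.read_transcripts_gtf(p)}
        assert set(back) == {t.name for t in final}
        for t in final:
            rt = back[t.name]
            assert rt.exons == t.exons
            assert rt.strand == t.strand and rt.chrom == t.chrom


@pytest.fixture(scope="module")
def report():
    ann, nts, en, eg, truth = make_neighborhood_fixture(seed=0)
    return tr.neighborhood_correlation(nts, ann, en, eg), truth


class TestNeighborhood:
    def test_distant_planted_correlate_wins(self, report):
        rep, truth = report
        row = rep.summary.iloc[0]
        assert row.best_gene == truth["best_gene"]
        assert row.best_distance == truth["best_distance"]
        assert row.best_r > 0.9

    def test_window_boundary_exclusive_beyond_1mb(self, report):
        rep, truth = report
        listed = set(rep.neighbors.gene_id)
        assert "GN_edge_in" in listed       # exactly 1,000,000 bp: inside
        assert "GN_edge_out" not in listed  # 1,000,001 bp: outside
        assert rep.summary.iloc[0].n_neighbors == truth["n_neighbors"]

    def test_nearest_distance(self, report):
        rep, truth = report
        assert rep.summary.iloc[0].nearest_tss_distance == truth["nearest_distance"]

    def test_identical_profile_gives_r_one(self):
        ann, nts, en, eg, _ = make_neighborhood_fixture(seed=1)
        eg.loc["GN_near1"] = en.loc["NT1"].to_numpy()
        rep = tr.neighborhood_correlation(nts, ann, en, eg)
        pair = rep.neighbors.set_index("gene_id").loc["GN_near1"]
        assert pair.r == pytest.approx(1.0)

    def test_correlations_bounded(self, report):
        rep, _ = report
        r = rep.neighbors.r.dropna()
        assert (r.abs() <= 1 + 1e-12).all()


class TestFixtureContract:
    def test_byte_identical_regeneration(self):
        a = make_toy_annotation(seed=0)
        b = make_toy_annotation(seed=0)
        assert a.ref_gtf == b.ref_gtf and a.novel_gtf == b.novel_gtf
        assert a.scores_tsv == b.scores_tsv
        assert a.truth.equals(b.truth)

    def test_every_discard_class_present(self, toy):
        discarded = toy.truth[~toy.truth.retained]
        assert set(discarded.class_code) == {"j", "e", "p"}

    def test_every_positional_class_present(self, toy):
        kept = toy.truth[toy.truth.retained]
        assert {"BI", "AS", "OT", "LINC", "TUCP"} <= set(kept.positional_class)
        assert kept.tucp.any()
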