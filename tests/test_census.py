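"""Homolog identification, genome classification, census summaries, lengths."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from tfscan.census import (
    CensusSummary,
    FamilyHit,
    GenomeCensus,
    InsufficientDataError,
    ProteinRecord,
    TFHomolog,
    classify_cohort,
    classify_genome,
    compare_lengths,
    identify_tf_homologs,
    load_hits,
    load_proteomes,
    multi_tf_homologs,
    round_pct,
    summarize,
)
from tfscan.motif import RBSStatus


def hit(pid, fam="TIGR00115", score=250.0, evalue=1e-50):
    return FamilyHit(pid, fam, score, evalue)


def protein(pid, length, genome="G1", with_rbs=True):
    if with_rbs:
        seq = "GFRAGAAP" + "A" * (length - 8)
    else:
        seq = "A" * length
    return ProteinRecord(genome, pid, seq)


def homolog(genome, pid, length, present):
    rbs = RBSStatus(present, None, "degenerate-only" if present else "none")
    return TFHomolog(genome, pid, length, rbs, frozenset({"COG0544"}))


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

class TestLoadProteomes:
    def write(self, path, entries):
        with open(path, "w") as fh:
            for pid, seq in entries:
                fh.write(f">{pid}\n{seq}\n")

    def test_directory_ingestion_counts_and_genome_ids(self, tmp_path):
        self.write(tmp_path / "gA.fasta", [("p1", "MKTA"), ("p2", "MELV"), ("p3", "MAAA")])
        self.write(tmp_path / "gB.faa", [("p1", "MSSS")])
        recs = load_proteomes(tmp_path)
        assert len(recs) == 4
        assert {r.genome_id for r in recs} == {"gA", "gB"}
        # same protein id in different genomes is fine
        assert sum(r.protein_id == "p1" for r in recs) == 2

    def test_manifest_overrides_file_stem(self, tmp_path):
        self.write(tmp_path / "asm123.fasta", [("p1", "MKTA")])
        recs = load_proteomes(tmp_path, manifest={"asm123": "Escherichia_coli"})
        assert recs[0].genome_id == "Escherichia_coli"

    def test_stop_codon_sanitized_with_warning(self, tmp_path, caplog):
        self.write(tmp_path / "g.fasta", [("p1", "MKTA*")])
        with caplog.at_level("WARNING", logger="tfscan.motif"):
            recs = load_proteomes(tmp_path)
        assert recs[0].sequence == "MKTA" and recs[0].length == 4
        assert any("stripping" in r.message for r in caplog.records)

    def test_duplicate_protein_id_within_genome_is_error(self, tmp_path):
        self.write(tmp_path / "g.fasta", [("p1", "MKTA"), ("p1", "MELV")])
        with pytest.raises(ValueError, match="duplicate"):
            load_proteomes(tmp_path)

    def test_empty_sequence_is_error(self, tmp_path):
        self.write(tmp_path / "g.fasta", [("p1", "")])
        with pytest.raises(ValueError, match="empty"):
            load_proteomes(tmp_path)

    def test_missing_inputs_are_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_proteomes(tmp_path / "nowhere")
        (tmp_path / "empty").mkdir()
        with pytest.raises(FileNotFoundError):
            load_proteomes(tmp_path / "empty")


class TestLoadHits:
    def test_native_dialect_drops_off_family_rows(self, tmp_path):
        p = tmp_path / "hits.tsv"
        rows = [("p1", "TIGR00115"), ("p2", "COG0544"), ("p3", "PRK01490"),
                ("p4", "COG9999"), ("p5", "TIGR00115")]
        p.write_text("protein_id\tfamily_id\tscore\tevalue\n" +
                     "".join(f"{a}\t{b}\t200.0\t1e-60\n" for a, b in rows))
        hits = load_hits(p)
        assert len(hits) == 4
        assert all(h.family_id != "COG9999" for h in hits)

    def test_empty_table_with_header(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("protein_id\tfamily_id\tscore\tevalue\n")
        assert load_hits(p) == []

    def test_missing_column_is_error(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("protein_id\tscore\tevalue\np1\t1\t1e-5\n")
        with pytest.raises(ValueError, match="family_id"):
            load_hits(p)

    def test_outfmt6_dialect(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("p1\tTIGR00115\t98.0\t430\t5\t0\t1\t430\t1\t432\t1e-100\t350.5\n")
        (h,) = load_hits(p, dialect="outfmt6")
        assert (h.protein_id, h.family_id) == ("p1", "TIGR00115")
        assert h.score == 350.5 and h.evalue == 1e-100

    def test_hmmer_tblout_dialect(self, tmp_path):
        p = tmp_path / "hits.tbl"
        p.write_text(
            "# comment line\n"
            "COG0544  -  p7  -  1.2e-80  270.1  0.1  1.5e-80  269.8  0.1  1.0  1  0  0  1  1  1  1  -\n"
        )
        (h,) = load_hits(p, dialect="hmmer-tbl")
        assert (h.protein_id, h.family_id) == ("p7", "COG0544")
        assert h.score == 270.1 and h.evalue == 1.2e-80

    def test_unknown_dialect_is_error(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("protein_id\tfamily_id\tscore\tevalue\n")
        with pytest.raises(ValueError, match="dialect"):
            load_hits(p, dialect="csv")


# ---------------------------------------------------------------------------
# Identification and classification
# ---------------------------------------------------------------------------

class TestIdentifyHomologs:
    def test_length_filter_boundary(self):
        proteins = [protein("short", 119), protein("edge", 120), protein("long", 500)]
        hits = [hit("short"), hit("edge"), hit("long")]
        ids = {h.protein_id for h in identify_tf_homologs(proteins, hits)}
        assert ids == {"edge", "long"}

    def test_protein_without_hit_excluded(self):
        homs = identify_tf_homologs([protein("p1", 500)], [])
        assert homs == []

    def test_multi_family_hits_collapse_to_one_homolog(self):
        proteins = [protein("p1", 400)]
        hits = [hit("p1", "TIGR00115"), hit("p1", "COG0544"), hit("p1", "PRK01490")]
        (h,) = identify_tf_homologs(proteins, hits)
        assert h.families_hit == frozenset({"TIGR00115", "COG0544", "PRK01490"})

    def test_rbs_computed_from_sequence(self):
        homs = identify_tf_homologs(
            [protein("pos", 300, with_rbs=True), protein("neg", 300, with_rbs=False)],
            [hit("pos"), hit("neg")],
        )
        by_id = {h.protein_id: h for h in homs}
        assert by_id["pos"].rbs.present and by_id["pos"].rbs.variant_label == "canonical"
        assert not by_id["neg"].rbs.present

    def test_unresolved_hits_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="tfscan.census"):
            homs = identify_tf_homologs([protein("p1", 300)], [hit("ghost")])
        assert homs == []
        assert any("did not resolve" in r.message for r in caplog.records)

    def test_evalue_threshold_config(self):
        proteins = [protein("p1", 300), protein("p2", 300)]
        hits = [hit("p1", evalue=1e-80), hit("p2", evalue=1e-3)]
        homs = identify_tf_homologs(proteins, hits, max_evalue=1e-10)
        assert [h.protein_id for h in homs] == ["p1"]

    def test_raising_min_length_is_monotone(self, rng):
        proteins = [protein(f"p{i}", int(rng.integers(60, 600))) for i in range(40)]
        hits = [hit(p.protein_id) for p in proteins]
        counts = [len(identify_tf_homologs(proteins, hits, min_length=m))
                  for m in range(60, 620, 40)]
        assert counts == sorted(counts, reverse=True)


class TestClassifyGenome:
    def test_zero_homologs_is_none(self):
        c = classify_genome("g", [])
        assert (c.category, c.rbs_class, c.n_tf) == ("none", None, 0)

    def test_single(self):
        c = classify_genome("g", [homolog("g", "p1", 440, True)])
        assert (c.category, c.rbs_class, c.n_rbs) == ("single", None, 1)

    @pytest.mark.parametrize("flags,expected", [
        ((True, False, False), "one-RBS"),
        ((True, True), "multi-RBS"),
        ((False, False), "zero-RBS"),
    ])
    def test_multiple_rbs_classes(self, flags, expected):
        homs = [homolog("g", f"p{i}", 400, f) for i, f in enumerate(flags)]
        c = classify_genome("g", homs)
        assert c.category == "multiple" and c.rbs_class == expected

    def test_mixed_genome_ids_rejected(self):
        with pytest.raises(ValueError, match="belongs to"):
            classify_genome("g", [homolog("other", "p1", 400, True)])

    def test_cohort_counts_genomes_absent_from_hits_as_none(self):
        censuses = classify_cohort(["g1", "g2"], [homolog("g1", "p1", 400, True)])
        by_id = {c.genome_id: c.category for c in censuses}
        assert by_id == {"g1": "single", "g2": "none"}


class TestSummarize:
    def test_survey_scale_arithmetic(self):
        s = CensusSummary.from_counts(
            n_genomes=15575, n_none=334, n_single=14851,
            n_multi_oneRBS=367, n_multi_multiRBS=23,
        )
        assert s.n_with_tf == 15241 and s.n_multiple == 390
        assert (s.pct_with_tf, s.pct_single) == (97.86, 97.44)
        assert (s.pct_multi_oneRBS, s.pct_multi_multiRBS) == (2.41, 0.15)

    def test_four_genome_hand_count(self):
        censuses = [
            GenomeCensus("g1", 0, 0, "none", None),
            GenomeCensus("g2", 1, 1, "single", None),
            GenomeCensus("g3", 3, 1, "multiple", "one-RBS"),
            GenomeCensus("g4", 2, 2, "multiple", "multi-RBS"),
        ]
        s = summarize(censuses)
        assert (s.n_none, s.n_single, s.n_multiple) == (1, 1, 2)
        assert s.pct_single == 33.33
        assert s.pct_with_tf == 75.00

    def test_single_genome_cohort(self):
        s = summarize([GenomeCensus("g", 1, 1, "single", None)])
        assert s.pct_with_tf == 100.00 and s.pct_single == 100.00

    def test_zero_genomes_is_error(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_duplicate_genome_is_error(self):
        c = GenomeCensus("g", 1, 1, "single", None)
        with pytest.raises(ValueError, match="duplicate"):
            summarize([c, c])

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            CensusSummary.from_counts(10, 5, 3, 1, 1, n_multi_zeroRBS=5)

    def test_rounding_is_half_up(self):
        assert round_pct(1, 8) == 12.50
        assert round_pct(125, 1000) == 12.50
        assert round_pct(1, 16) == 6.25
        assert round_pct(1, 800) == 0.13  # 0.125 rounds up, not to even
        assert round_pct(49999, 100000) == 50.00


# ---------------------------------------------------------------------------
# Length comparison (Welch)
# ---------------------------------------------------------------------------

def welch_oracle(x, y):
    """Textbook Welch statistic and Welch-Satterthwaite p, written from the formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, p


def make_group(genome, lengths, present):
    return [homolog(genome, f"{genome}_{present}_{i}", L, present)
            for i, L in enumerate(lengths)]


class TestCompareLengths:
    def test_identical_groups_give_t_zero_p_one(self):
        homs = make_group("g", [400, 410, 420], True) + \
               make_group("g", [400, 410, 420], False)
        lc = compare_lengths(homs)
        assert lc.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert lc.p_value == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_welch_example(self):
        homs = make_group("g", [430, 440, 450], True) + \
               make_group("g", [300, 310, 320], False)
        lc = compare_lengths(homs)
        t, p = welch_oracle([430, 440, 450], [300, 310, 320])
        assert lc.t_statistic == pytest.approx(t, rel=1e-12)
        assert lc.p_value == pytest.approx(p, rel=1e-9)
        assert lc.mean_pos == 440 and lc.median_neg == 310
        # sign convention: positive t when RBS+ mean exceeds RBS- mean
        assert (lc.t_statistic > 0) == (lc.mean_pos > lc.mean_neg)

    def test_small_group_raises_insufficient_data(self):
        homs = make_group("g", [430, 440], True) + make_group("g", [300], False)
        with pytest.raises(InsufficientDataError):
            compare_lengths(homs)

    def test_agrees_with_formula_on_100_random_group_pairs(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(3, 40, size=2)
            x = rng.normal(440, rng.uniform(5, 60), size=n1).round()
            y = rng.normal(310, rng.uniform(5, 60), size=n2).round()
            homs = make_group("g", x.tolist(), True) + make_group("g", y.tolist(), False)
            lc = compare_lengths(homs)
            t, p = welch_oracle(x, y)
            assert lc.t_statistic == pytest.approx(t, rel=1e-6)
            assert lc.p_value == pytest.approx(p, rel=1e-6)

    def test_multi_tf_restriction_drops_single_tf_genomes(self):
        homs = (make_group("multi", [430, 420], True)
                + make_group("multi", [300], False)
                + make_group("solo", [440], True))
        censuses = classify_cohort(["multi", "solo"], homs)
        restricted = multi_tf_homologs(homs, censuses)
        assert {h.genome_id for h in restricted} == {"multi"}


def test_partition_property_summary_reconstructs_census(default_cohort):
    """Every genome lands in exactly one class and the summary counts add up."""
    from tfscan.pipeline import scan_cohort

    r = scan_cohort(default_cohort.proteins, default_cohort.hits,
                    genome_ids=default_cohort.genome_ids)
    s = r.summary
    assert s.n_genomes == len(r.censuses) == len(default_cohort.genome_ids)
    assert s.n_none + s.n_with_tf == s.n_genomes
    assert s.n_single + s.n_multiple == s.n_with_tf
    assert s.n_multi_oneRBS + s.n_multi_multiRBS + s.n_multi_zeroRBS == s.n_multiple
    from collections import Counter
    cats = Counter(c.category for c in r.censuses)
    assert cats["none"] == s.n_none and cats["single"] == s.n_single
    assert cats["multiple"] == s.n_multiple
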