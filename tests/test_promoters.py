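"""Promoter extraction, Rre1-consensus scanning, and gene categorisation."""

import re

import pytest
from Bio.Seq import Seq

from cyanokit.errors import ConfigError, CyanokitError
from cyanokit.genome_io import Contig, GeneFeature, GenomeRecord
from cyanokit.promoter_motifs import (
    DEFAULT_MOTIF_PATTERN,
    CategoryScheme,
    PromoterRegion,
    classify_genes,
    extract_promoters,
    motif_survey,
    scan_motif,
)


def gene(contig="c1", start=600, end=900, strand="+", **kw):
    kw.setdefault("locus_tag", f"g_{start}_{strand}")
    return GeneFeature(contig_id=contig, start=start, end=end, strand=strand, **kw)


@pytest.fixture
def contig2kb(random_dna):
    return GenomeRecord([Contig("c1", random_dna(2000, seed=42))])


class TestExtraction:
    def test_plus_strand_window(self, contig2kb):
        [region] = extract_promoters(contig2kb, [gene(start=600)])
        assert (region.window_start, region.window_end) == (100, 599)
        assert region.window_length == 500
        assert not region.truncated
        assert region.sequence == contig2kb.contigs[0].sequence[99:599]

    def test_plus_strand_clipped_at_contig_start(self, contig2kb):
        [region] = extract_promoters(contig2kb, [gene(start=200)])
        assert (region.window_start, region.window_end) == (1, 199)
        assert region.window_length == 199
        assert region.truncated

    def test_minus_strand_reverse_complemented(self, contig2kb):
        [region] = extract_promoters(contig2kb, [gene(start=700, end=1000, strand="-")])
        assert (region.window_start, region.window_end) == (1001, 1500)
        forward = contig2kb.contigs[0].sequence[1000:1500]
        # reverse-complementing the oriented window recovers the forward substring
        assert str(Seq(region.sequence).reverse_complement()) == forward

    def test_minus_strand_clipped_at_contig_end(self, contig2kb):
        [region] = extract_promoters(contig2kb, [gene(start=1500, end=1900, strand="-")])
        assert (region.window_start, region.window_end) == (1901, 2000)
        assert region.truncated and region.window_length == 100

    def test_gene_at_contig_edge_unscannable(self, contig2kb):
        [r_plus] = extract_promoters(contig2kb, [gene(start=1, end=300)])
        assert r_plus.window_length == 0 and r_plus.unscannable
        [r_short] = extract_promoters(contig2kb, [gene(start=5, end=300)])
        assert r_short.window_length == 4 and r_short.unscannable

    def test_unknown_contig_named_in_error(self, contig2kb):
        with pytest.raises(CyanokitError, match="cX"):
            extract_promoters(contig2kb, [gene(contig="cX", locus_tag="orphan")])


class TestScan:
    def region(self, seq, strand="+", start=1000):
        g = gene(start=start, end=start + 100, strand=strand)
        return PromoterRegion(g, seq, start - len(seq), start - 1, False)

    def test_minimal_match(self):
        hits = scan_motif([self.region("GTACGGT")])
        assert len(hits) == 1
        assert hits[0].offset == 1
        assert hits[0].matched == "GTACGGT"
        assert hits[0].distance_upstream == 7

    def test_case_insensitive(self):
        assert len(scan_motif([self.region("gtacggt")])) == 1

    def test_overlapping_matches_all_reported(self):
        # offsets 1 and 6 overlap by two bases
        hits = scan_motif([self.region("GTACG" + "GTACGGT")])
        assert [h.offset for h in hits] == [1, 6]

    def test_distance_upstream_convention(self):
        seq = "A" * 373 + "GTACGGT" + "A" * 120  # match start 374, window 500
        [hit] = scan_motif([self.region(seq)])
        assert hit.offset == 374
        assert hit.distance_upstream == 500 - 374 + 1 == 127

    def test_forward_coordinates_on_both_strands(self, contig2kb):
        seq = contig2kb.contigs[0].sequence
        plus = extract_promoters(contig2kb, [gene(start=600)])
        for hit in scan_motif(plus):
            s = hit.contig_position - 1
            assert re.fullmatch(
                DEFAULT_MOTIF_PATTERN, seq[s : s + 7], re.IGNORECASE
            ), "plus-strand hit coordinate must map onto the forward strand"
        minus = extract_promoters(contig2kb, [gene(start=700, end=1000, strand="-")])
        for hit in scan_motif(minus):
            s = hit.contig_position - 1
            rc = str(Seq(seq[s : s + 7]).reverse_complement())
            assert re.fullmatch(DEFAULT_MOTIF_PATTERN, rc, re.IGNORECASE)

    def test_strand_involution(self, contig2kb):
        """Scanning a minus-strand promoter equals scanning the reverse
        complement of the forward substring directly."""
        [region] = extract_promoters(contig2kb, [gene(start=700, end=1000, strand="-")])
        forward = contig2kb.contigs[0].sequence[1000:1500]
        direct = [
            m.start() + 1
            for m in re.finditer(
                f"(?=({DEFAULT_MOTIF_PATTERN}))",
                str(Seq(forward).reverse_complement()),
                re.IGNORECASE,
            )
        ]
        assert [h.offset for h in scan_motif([region])] == direct

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ConfigError):
            scan_motif([self.region("GTACGGT")], pattern="GT[ATCG")


class TestClassification:
    def test_keyword_categories(self):
        scheme = CategoryScheme()
        cases = {
            "hsp": gene(product="chaperonin GroEL", locus_tag="a"),
            "tca_cycle": gene(gene_name="sdhA", locus_tag="b"),
            "photosynthesis": gene(gene_name="psaC", locus_tag="c"),
            "respiration": gene(product="cytochrome c oxidase subunit 1", locus_tag="d"),
            "uncategorized": gene(product="hypothetical protein", locus_tag="e"),
        }
        out = classify_genes(list(cases.values()), scheme)
        for expected, feature in cases.items():
            assert out[feature] == expected

    def test_first_matching_category_wins(self):
        scheme = CategoryScheme({"first": ("alpha",), "second": ("alpha", "beta")})
        assert scheme.classify(gene(product="alpha beta", locus_tag="x")) == "first"
        assert scheme.classify(gene(product="beta only", locus_tag="y")) == "second"

    def test_matching_is_case_insensitive(self):
        scheme = CategoryScheme()
        assert scheme.classify(gene(product="CHAPERONIN GROEL", locus_tag="z")) == "hsp"


class TestSurvey:
    def test_no_occurrences_gives_empty_hits_full_summary(self, make_genome):
        genome = make_genome("A" * 3000)
        features = [gene(start=600, product="chaperonin GroEL")]
        hits, summary = motif_survey(genome, features)
        assert hits.empty
        assert summary.loc[summary.category == "hsp", "genes"].item() == 1
        assert summary["total_hits"].sum() == 0

    def test_survey_counts_and_order(self, random_dna, make_genome):
        genome = make_genome(random_dna(20000, seed=3))
        features = [
            gene(start=5000, end=5400, product="chaperonin GroEL", locus_tag="g1"),
            gene(start=1000, end=1300, product="hypothetical protein", locus_tag="g2"),
            gene(start=9000, end=9500, strand="-", gene_name="psaC", locus_tag="g3"),
        ]
        hits, summary = motif_survey(genome, features)
        if not hits.empty:
            starts = [features[["g1", "g2", "g3"].index(lt)].start for lt in hits["locus_tag"]]
            assert starts == sorted(starts)
        assert summary["genes"].sum() == 3
        assert summary["total_hits"].sum() == len(hits)
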