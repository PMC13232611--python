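"""Strand-aware promoter extraction and Rre1-consensus motif survey.

The Hik34-Rre1 two-component system is the canonical cyanobacterial
heat-stress regulator; Rre1 binds a short consensus written here as the
regular-expression character-class pattern ``GT[ATCG]CGG[TG]`` (7 bases).
This module extracts the 500-bp window upstream of each protein-coding
gene's translation start — upstream on the gene's own strand, so windows of
minus-strand genes are reverse-complemented and read 5'->3' on the coding
strand — scans the oriented windows for the consensus (case-insensitive,
overlapping matches all reported), and classifies target genes into four
functional categories by keyword lists over gene names and product
descriptions: photosynthesis light reactions / electron transport,
respiratory terminal and quinol oxidases, TCA cycle enzymes, and heat-shock
proteins.

Windows are clipped at contig edges (flagged ``truncated``) and are not
trimmed at upstream neighbouring genes. Only the oriented promoter strand
is scanned by default; the consensus is not palindromic, and scanning the
reverse complement as well is available via ``scan_motif(..., both_strands=True)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from cyanokit.errors import ConfigError, CyanokitError
from cyanokit.genome_io import GeneFeature, GenomeRecord

DEFAULT_MOTIF_PATTERN = "GT[ATCG]CGG[TG]"
DEFAULT_WINDOW = 500

#: The four functional categories of the survey, in classification order.
#: Keyword matching is case-insensitive substring over gene name and product.
DEFAULT_CATEGORIES: dict[str, tuple[str, ...]] = {
    "photosynthesis": (
        "psa", "psb", "photosystem", "pet", "ferredoxin", "plastocyanin",
        "cytochrome f", "cytochrome b6", "phycobilisome", "phycocyanin",
    ),
    "respiration": (
        "cox", "cyd", "cta", "quinol oxidase", "terminal oxidase",
        "cytochrome c oxidase", "cytochrome bd", "cytochrome oxidase",
    ),
    "tca_cycle": (
        "glta", "citrate synthase", "icd", "isocitrate dehydrogenase",
        "sdh", "succinate dehydrogenase", "frd", "fumarate reductase",
        "fumarase", "malate dehydrogenase", "aconitase",
    ),
    "hsp": (
        "clpb", "groel", "groes", "dnaj", "dnak", "hsp", "htpg", "grpe",
        "chaperon", "heat shock", "heat-shock",
    ),
}

MOTIF_LENGTH = 7


@dataclass
class CategoryScheme:
    """Ordered functional categories with editable keyword lists.

    The first category (in insertion order) with a keyword matching either
    the gene name or the product description wins; genes matching none are
    "uncategorized".
    """

    categories: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_CATEGORIES.items()}
    )

    def __post_init__(self) -> None:
        if not self.categories:
            raise ConfigError("category scheme must define at least one category")

    def classify(self, feature: GeneFeature) -> str:
        haystack = f"{feature.gene_name} {feature.product}".lower()
        for name, keywords in self.categories.items():
            for kw in keywords:
                if kw.lower() in haystack:
                    return name
        return "uncategorized"


@dataclass(frozen=True)
class PromoterRegion:
    """The upstream window of one gene, oriented 5'->3' on its coding strand.

    ``window_start``/``window_end`` are 1-based inclusive forward-strand
    contig coordinates; for minus-strand genes ``sequence`` is the reverse
    complement of that interval. ``unscannable`` marks windows shorter than
    the motif (including zero-length windows of genes at a contig edge).
    """

    gene: GeneFeature
    sequence: str
    window_start: int
    window_end: int
    truncated: bool

    @property
    def window_length(self) -> int:
        return len(self.sequence)

    @property
    def unscannable(self) -> bool:
        return self.window_length < MOTIF_LENGTH


@dataclass(frozen=True)
class MotifHit:
    """One consensus match inside an oriented promoter window.

    ``offset`` is the 1-based match start within the oriented promoter;
    ``distance_upstream`` counts bases from the match start back from the
    gene start (1 = immediately adjacent). ``contig_position`` is the
    1-based forward-strand coordinate of the match's 5'-most base on the
    forward strand (i.e. the lowest coordinate the match covers).
    """

    gene: GeneFeature
    offset: int
    distance_upstream: int
    matched: str
    contig_position: int
    category: str = "uncategorized"
    on_reverse_of_window: bool = False


def extract_promoters(
    genome: GenomeRecord,
    features: list[GeneFeature],
    window: int = DEFAULT_WINDOW,
) -> list[PromoterRegion]:
    """Extract the upstream window of every feature, strand-aware.

    Plus-strand genes get [start - window, start - 1]; minus-strand genes
    get [end + 1, end + window] reverse-complemented, so in both cases the
    returned sequence reads toward the gene start. Windows are clipped at
    contig boundaries and flagged ``truncated``.
    """
    contig_seqs = {c.id: c.sequence for c in genome}
    regions: list[PromoterRegion] = []
    for feature in features:
        if feature.contig_id not in contig_seqs:
            raise CyanokitError(
                f"feature {feature.locus_tag or feature.gene_name or feature.start} "
                f"references unknown contig {feature.contig_id!r}"
            )
        seq = contig_seqs[feature.contig_id]
        contig_len = len(seq)
        if feature.strand == "+":
            w_start = max(1, feature.start - window)
            w_end = feature.start - 1
            if w_end < w_start:  # gene starts at position 1: empty window
                regions.append(
                    PromoterRegion(feature, "", feature.start, feature.start - 1, True)
                )
                continue
            sub = seq[w_start - 1 : w_end]
            regions.append(
                PromoterRegion(feature, sub, w_start, w_end, w_end - w_start + 1 < window)
            )
        else:
            w_start = feature.end + 1
            w_end = min(contig_len, feature.end + window)
            if w_end < w_start:  # gene ends at the contig's last base
                regions.append(
                    PromoterRegion(feature, "", feature.end + 1, feature.end, True)
                )
                continue
            sub = str(Seq(seq[w_start - 1 : w_end]).reverse_complement())
            regions.append(
                PromoterRegion(feature, sub, w_start, w_end, w_end - w_start + 1 < window)
            )
    return regions


def _compile(pattern: str) -> "re.Pattern[str]":
    try:
        compiled = re.compile(f"(?=({pattern}))", re.IGNORECASE)
    except re.error as exc:
        raise ConfigError(f"invalid motif pattern {pattern!r}: {exc}")
    return compiled


def scan_motif(
    promoters: list[PromoterRegion],
    pattern: str = DEFAULT_MOTIF_PATTERN,
    scheme: CategoryScheme | None = None,
    both_strands: bool = False,
) -> list[MotifHit]:
    """Scan oriented promoter windows for the consensus pattern.

    Matching is case-insensitive and overlap-permitting (a lookahead wrapper
    reports every occurrence). By default only the oriented promoter strand
    is scanned; ``both_strands=True`` additionally scans each window's
    reverse complement (hits flagged ``on_reverse_of_window``).
    """
    compiled = _compile(pattern)
    scheme = scheme or CategoryScheme()
    hits: list[MotifHit] = []
    for region in promoters:
        if region.unscannable:
            continue
        category = scheme.classify(region.gene)
        for m in compiled.finditer(region.sequence):
            offset = m.start() + 1
            matched = m.group(1)
            hits.append(
                MotifHit(
                    gene=region.gene,
                    offset=offset,
                    distance_upstream=region.window_length - offset + 1,
                    matched=matched,
                    contig_position=_forward_position(region, offset, len(matched)),
                    category=category,
                )
            )
        if both_strands:
            rc = str(Seq(region.sequence).reverse_complement())
            for m in compiled.finditer(rc):
                offset_rc = m.start() + 1
                matched = m.group(1)
                # project back onto the oriented window
                offset = region.window_length - offset_rc - len(matched) + 2
                hits.append(
                    MotifHit(
                        gene=region.gene,
                        offset=offset,
                        distance_upstream=region.window_length - offset + 1,
                        matched=matched,
                        contig_position=_forward_position(region, offset, len(matched)),
                        category=category,
                        on_reverse_of_window=True,
                    )
                )
    return hits


def _forward_position(region: PromoterRegion, offset: int, match_len: int) -> int:
    """Forward-strand coordinate of the match's lowest-coordinate base."""
    if region.gene.strand == "+":
        return region.window_start + offset - 1
    return region.window_end - (offset - 1) - (match_len - 1)


def classify_genes(
    features: list[GeneFeature], scheme: CategoryScheme | None = None
) -> dict[GeneFeature, str]:
    """Map each feature to its functional category (or "uncategorized")."""
    scheme = scheme or CategoryScheme()
    return {f: scheme.classify(f) for f in features}


def motif_survey(
    genome: GenomeRecord,
    features: list[GeneFeature],
    scheme: CategoryScheme | None = None,
    window: int = DEFAULT_WINDOW,
    pattern: str = DEFAULT_MOTIF_PATTERN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full promoter-motif survey over a genome.

    Returns ``(hits, summary)``: a per-hit table sorted by (contig, gene
    start, offset) with gene identity, category, forward-strand coordinate
    and distance upstream; and a per-category summary counting genes with at
    least one hit and total hits.
    """
    scheme = scheme or CategoryScheme()
    promoters = extract_promoters(genome, features, window=window)
    hits = scan_motif(promoters, pattern=pattern, scheme=scheme)
    contig_order = {cid: i for i, cid in enumerate(genome.contig_ids())}
    hits.sort(key=lambda h: (contig_order[h.gene.contig_id], h.gene.start, h.offset))
    hit_rows = [
        {
            "gene": h.gene.gene_name,
            "locus_tag": h.gene.locus_tag,
            "category": h.category,
            "contig": h.gene.contig_id,
            "contig_position": h.contig_position,
            "strand": h.gene.strand,
            "offset": h.offset,
            "distance_upstream": h.distance_upstream,
            "matched": h.matched,
        }
        for h in hits
    ]
    hit_columns = [
        "gene", "locus_tag", "category", "contig", "contig_position",
        "strand", "offset", "distance_upstream", "matched",
    ]
    hits_df = pd.DataFrame(hit_rows, columns=hit_columns)

    categories = list(scheme.categories) + ["uncategorized"]
    by_gene: dict[tuple, int] = {}
    gene_category = {}
    for f in features:
        key = (f.contig_id, f.start, f.end, f.strand, f.locus_tag)
        by_gene[key] = 0
        gene_category[key] = scheme.classify(f)
    for h in hits:
        key = (h.gene.contig_id, h.gene.start, h.gene.end, h.gene.strand, h.gene.locus_tag)
        by_gene[key] += 1
    summary_rows = []
    for cat in categories:
        keys = [k for k, c in gene_category.items() if c == cat]
        summary_rows.append(
            {
                "category": cat,
                "genes": len(keys),
                "genes_with_hits": sum(1 for k in keys if by_gene[k] > 0),
                "total_hits": sum(by_gene[k] for k in keys),
            }
        )
    summary_df = pd.DataFrame(
        summary_rows, columns=["category", "genes", "genes_with_hits", "total_hits"]
    )
    return hits_df, summary_df
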