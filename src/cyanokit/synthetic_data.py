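"""Seed-deterministic synthetic data with machine-readable ground truth.

Every input the pipeline consumes can be generated here with known truth:

* multi-contig genomes with controlled GC and consensus motif instances
  planted at chosen distances upstream of chosen genes (plants substitute
  bases in place, never shifting coordinates);
* strand-mixed protein-coding features whose names/products are sampled
  from the functional-category vocabulary plus decoys, so classification
  has known labels;
* rapid light curves drawn from the Eilers-Peeters model with additive
  Gaussian noise on the study's irradiance ladder;
* exponential rereduction rises with known half-times;
* long-format Ct tables with a constant housekeeping gene and known true
  fold changes.

For motif fixtures the generator guarantees that the set of consensus
matches inside promoter windows equals the planted ground truth exactly:
background chance matches inside windows are disrupted by single-base
edits before planting, and matches induced at plant junctions are
disrupted afterwards (never touching planted bases). Genes are laid out in
non-overlapping blocks so no promoter window overlaps another window or a
gene body, keeping each plant attributable to exactly one gene.

Same seed, same spec => bit-identical outputs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from cyanokit.errors import SpecError
from cyanokit.expression import CtTable
from cyanokit.genome_io import Contig, GeneFeature, GenomeRecord
from cyanokit.photophys import LightResponseCurve, ep_model
from cyanokit.promoter_motifs import (
    DEFAULT_MOTIF_PATTERN,
    MOTIF_LENGTH,
    PromoterRegion,
    extract_promoters,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class Plant:
    """One motif instance to plant: which gene, how far upstream, which 7-mer."""

    gene_index: int
    distance_upstream: int
    motif: str

    def __post_init__(self) -> None:
        if not re.fullmatch(DEFAULT_MOTIF_PATTERN, self.motif, re.IGNORECASE):
            raise SpecError(
                f"planted 7-mer {self.motif!r} does not match the consensus "
                f"{DEFAULT_MOTIF_PATTERN}"
            )


@dataclass(frozen=True)
class GenomeSpec:
    """Genome + feature + plant layout for one synthetic fixture."""

    seed: int = 0
    contig_lengths: tuple[int, ...] = (60_000,)
    gc_percent: float = 42.09
    n_genes: int = 12
    gene_length: tuple[int, int] = (300, 900)
    minus_fraction: float = 0.5
    plants: tuple[Plant, ...] = ()
    promoter_window: int = 500
    leading_gap: int | None = None  # force a truncated first-gene window
    hsp_fraction: float = 0.5  # fraction of products drawn from category vocab


#: gene-name/product vocabulary per category, plus uncategorised decoys
_VOCAB = {
    "photosynthesis": [
        ("psaC", "photosystem I iron-sulfur center"),
        ("psbA", "photosystem II protein D1"),
        ("petA", "cytochrome f"),
        ("petJ", "cytochrome c6"),
        ("", "ferredoxin"),
    ],
    "respiration": [
        ("coxA", "cytochrome c oxidase subunit 1"),
        ("cydA", "cytochrome bd quinol oxidase subunit 1"),
    ],
    "tca_cycle": [
        ("gltA", "citrate synthase"),
        ("icd", "isocitrate dehydrogenase"),
        ("sdhA", "succinate dehydrogenase flavoprotein subunit"),
    ],
    "hsp": [
        ("groEL", "chaperonin GroEL"),
        ("groES", "co-chaperonin GroES"),
        ("clpB", "chaperone protein ClpB"),
        ("dnaK", "chaperone protein DnaK"),
        ("hspA", "heat shock protein Hsp20"),
    ],
    "uncategorized": [
        ("", "hypothetical protein"),
        ("rpoB", "DNA-directed RNA polymerase subunit beta"),
        ("gyrA", "DNA gyrase subunit A"),
        ("recA", "recombinase RecA"),
    ],
}


@dataclass
class SyntheticGenome:
    """A generated genome with its feature table and ground-truth ledger."""

    spec: GenomeSpec
    genome: GenomeRecord
    features: list[GeneFeature]
    #: planted ground truth: one row per expected motif hit
    ledger: pd.DataFrame
    #: true functional category per feature (by locus_tag)
    categories: dict[str, str]

    def ledger_frame(self) -> pd.DataFrame:
        return self.ledger.copy()


# ---------------------------------------------------------------------------
# Genome + features + plants


def _sample_sequence(rng: np.random.Generator, length: int, gc_percent: float) -> np.ndarray:
    gc = gc_percent / 100.0
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def synth_features(spec: GenomeSpec, rng: np.random.Generator) -> tuple[list[GeneFeature], dict[str, str]]:
    """Lay out strand-mixed genes in non-overlapping blocks with known labels.

    Each gene occupies a block of (promoter window + gene length + pad)
    bases on its contig, so promoter windows never overlap one another or a
    gene body. Products are drawn from the category vocabulary with
    probability ``hsp_fraction`` (spread over the four categories) and from
    uncategorised decoys otherwise.
    """
    lo, hi = spec.gene_length
    window = spec.promoter_window
    features: list[GeneFeature] = []
    categories: dict[str, str] = {}
    contig_idx = 0
    cursor = 1
    cat_names = [c for c in _VOCAB if c != "uncategorized"]
    for i in range(spec.n_genes):
        gene_len = int(rng.integers(lo, hi + 1))
        strand = "-" if rng.random() < spec.minus_fraction else "+"
        if i == 0 and spec.leading_gap is not None:
            pad = 0
            strand = "+"  # truncated-at-contig-start case is a +-strand one
            gene_start = spec.leading_gap + 1
        else:
            pad = int(rng.integers(50, 200))
            gene_start = None
        placed = False
        while contig_idx < len(spec.contig_lengths):
            contig_len = spec.contig_lengths[contig_idx]
            if gene_start is None:
                if strand == "+":
                    start = cursor + pad + window
                else:
                    start = cursor + pad
            else:
                start = gene_start
            end = start + gene_len - 1
            block_end = end + (window if strand == "-" else 0)
            if block_end <= contig_len:
                placed = True
                break
            contig_idx += 1
            cursor = 1
        if not placed:
            raise SpecError(
                f"cannot place gene {i}: contigs exhausted (need larger contigs "
                f"or fewer/shorter genes)"
            )
        if rng.random() < spec.hsp_fraction:
            cat = cat_names[int(rng.integers(len(cat_names)))]
        else:
            cat = "uncategorized"
        name, product = _VOCAB[cat][int(rng.integers(len(_VOCAB[cat])))]
        locus = f"SYN_{i:04d}"
        feature = GeneFeature(
            contig_id=f"contig{contig_idx + 1}",
            start=start,
            end=end,
            strand=strand,
            feature_type="CDS",
            gene_name=name,
            product=product,
            locus_tag=locus,
        )
        features.append(feature)
        categories[locus] = cat
        cursor = block_end + 1
    return features, categories


def _plant_forward_interval(
    region: PromoterRegion, plant: Plant
) -> tuple[int, int, str]:
    """Forward-strand (start, end, bases) of a plant in its gene's window."""
    wlen = region.window_length
    d = plant.distance_upstream
    if d < MOTIF_LENGTH or d > wlen:
        raise SpecError(
            f"plant for gene {plant.gene_index} at distance {d} does not fit "
            f"the {wlen}-base promoter window (need {MOTIF_LENGTH} <= d <= {wlen})"
        )
    offset = wlen - d + 1
    if region.gene.strand == "+":
        fs = region.window_start + offset - 1
        return fs, fs + MOTIF_LENGTH - 1, plant.motif.upper()
    fs = region.window_end - offset - (MOTIF_LENGTH - 2)
    return fs, fs + MOTIF_LENGTH - 1, _revcomp(plant.motif.upper())


def synth_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Generate the genome, features, and planted-motif ground truth.

    Plants are substitutions at fixed coordinates (coordinates never shift).
    When plants are present, chance consensus matches inside promoter
    windows are removed so the ledger is the complete truth; with zero
    plants the background is left untouched (chance hits follow the
    analytic 1/2048-per-position law on uniform sequence).
    """
    rng = np.random.default_rng(spec.seed)
    features, categories = synth_features(spec, rng)
    seqs = [
        _sample_sequence(rng, length, spec.gc_percent)
        for length in spec.contig_lengths
    ]
    genome = _assemble(seqs)
    regions = {
        f: r for f, r in zip(features, extract_promoters(genome, features, spec.promoter_window))
    }

    # resolve plants to forward-strand base assignments; consistent overlaps
    # merge, conflicting ones are a spec error
    assignments: dict[tuple[str, int], str] = {}
    plant_rows = []
    for plant in spec.plants:
        if not 0 <= plant.gene_index < len(features):
            raise SpecError(f"plant references gene index {plant.gene_index}, "
                            f"but only {len(features)} genes exist")
        feature = features[plant.gene_index]
        region = regions[feature]
        fs, fe, bases = _plant_forward_interval(region, plant)
        for pos, base in zip(range(fs, fe + 1), bases):
            key = (feature.contig_id, pos)
            if key in assignments and assignments[key] != base:
                raise SpecError(
                    f"colliding plants: conflicting bases at {feature.contig_id}:{pos}"
                )
            assignments[key] = base
        plant_rows.append(
            {
                "gene_index": plant.gene_index,
                "locus_tag": feature.locus_tag,
                "strand": feature.strand,
                "offset": region.window_length - plant.distance_upstream + 1,
                "distance_upstream": plant.distance_upstream,
                "matched": plant.motif.upper(),
                "contig": feature.contig_id,
                "contig_position": fs,
            }
        )

    if spec.plants:
        _scrub_windows(seqs, genome, features, spec, rng, protected=set(assignments))
        for (contig_id, pos), base in assignments.items():
            idx = int(contig_id.removeprefix("contig")) - 1
            seqs[idx][pos - 1] = base.encode()
        genome = _assemble(seqs)
        _fix_junctions(seqs, genome, features, spec, rng, protected=set(assignments))
        genome = _assemble(seqs)
        _augment_ledger_with_internal_overlaps(genome, features, spec, plant_rows)

    ledger = pd.DataFrame(
        plant_rows,
        columns=[
            "gene_index", "locus_tag", "strand", "offset", "distance_upstream",
            "matched", "contig", "contig_position",
        ],
    ).drop_duplicates(subset=["locus_tag", "offset"]).sort_values(
        ["contig", "contig_position", "offset"], kind="stable"
    ).reset_index(drop=True)
    return SyntheticGenome(
        spec=spec, genome=genome, features=features, ledger=ledger, categories=categories
    )


def _assemble(seqs: list[np.ndarray]) -> GenomeRecord:
    return GenomeRecord(
        contigs=[
            Contig(id=f"contig{i + 1}", sequence=arr.tobytes().decode("ascii"))
            for i, arr in enumerate(seqs)
        ]
    )


_PATTERN = re.compile(f"(?=({DEFAULT_MOTIF_PATTERN}))", re.IGNORECASE)


def _window_matches(region: PromoterRegion) -> list[tuple[int, str]]:
    return [(m.start() + 1, m.group(1)) for m in _PATTERN.finditer(region.sequence)]


def _oriented_to_forward(region: PromoterRegion, offset: int) -> int:
    if region.gene.strand == "+":
        return region.window_start + offset - 1
    return region.window_end - offset - (MOTIF_LENGTH - 2)


def _mutate(seqs, region: PromoterRegion, oriented_pos: int, rng, protected) -> bool:
    """Disrupt a match by rewriting one unprotected base inside it."""
    for delta in range(MOTIF_LENGTH):
        p = oriented_pos + delta
        if region.gene.strand == "+":
            fpos = region.window_start + p - 1
        else:
            fpos = region.window_end - p + 1
        key = (region.gene.contig_id, fpos)
        if key in protected:
            continue
        idx = int(region.gene.contig_id.removeprefix("contig")) - 1
        current = seqs[idx][fpos - 1].decode()
        choices = [b for b in "ACGT" if b != current]
        seqs[idx][fpos - 1] = choices[int(rng.integers(3))].encode()
        return True
    return False


def _planted_cover(genome, features, spec) -> dict[str, set[int]]:
    """Oriented-window positions covered by planted bases, per locus tag."""
    regions = {f.locus_tag: r for f, r in zip(
        features, extract_promoters(genome, features, spec.promoter_window))}
    cover: dict[str, set[int]] = {}
    for plant in spec.plants:
        feature = features[plant.gene_index]
        region = regions[feature.locus_tag]
        offset = region.window_length - plant.distance_upstream + 1
        cover.setdefault(feature.locus_tag, set()).update(
            range(offset, offset + MOTIF_LENGTH)
        )
    return cover


def _scrub_windows(seqs, genome, features, spec, rng, protected) -> None:
    """Remove chance consensus matches from all promoter windows.

    Matches lying entirely on soon-to-be-planted bases are left alone: the
    plant substitution will overwrite them.
    """
    cover = _planted_cover(genome, features, spec)
    for _ in range(50):
        genome = _assemble(seqs)
        regions = extract_promoters(genome, features, spec.promoter_window)
        dirty = False
        for region in regions:
            if region.unscannable:
                continue
            allow = cover.get(region.gene.locus_tag, set())
            for offset, _matched in _window_matches(region):
                if set(range(offset, offset + MOTIF_LENGTH)) <= allow:
                    continue
                dirty = True
                if not _mutate(seqs, region, offset, rng, protected):
                    raise SpecError("cannot scrub a chance match overlapping plants")
        if not dirty:
            return
    raise SpecError("window scrubbing did not converge")


def _fix_junctions(seqs, genome, features, spec, rng, protected) -> None:
    """Disrupt matches created at plant junctions, sparing planted bases.

    Matches whose 7 bases all lie on planted bases are legitimate (they
    arise from consistent overlapping plants) and are kept; everything else
    not in the planted ground truth is mutated away at an unplanted base.
    """
    cover = _planted_cover(genome, features, spec)
    for _ in range(50):
        genome = _assemble(seqs)
        regions = extract_promoters(genome, features, spec.promoter_window)
        dirty = False
        for region in regions:
            if region.unscannable:
                continue
            allow = cover.get(region.gene.locus_tag, set())
            for offset, _matched in _window_matches(region):
                if set(range(offset, offset + MOTIF_LENGTH)) <= allow:
                    continue
                dirty = True
                if not _mutate(seqs, region, offset, rng, protected):
                    raise SpecError(
                        "a junction-induced match consists entirely of planted "
                        "bases and cannot be disrupted"
                    )
        if not dirty:
            return
    raise SpecError("junction fixing did not converge")


def _augment_ledger_with_internal_overlaps(genome, features, spec, plant_rows) -> None:
    """Add matches formed where consistent plants overlap into longer runs."""
    planted_cover: dict[str, set[int]] = {}
    regions = {f.locus_tag: r for f, r in zip(
        features, extract_promoters(genome, features, spec.promoter_window))}
    for plant in spec.plants:
        feature = features[plant.gene_index]
        region = regions[feature.locus_tag]
        offset = region.window_length - plant.distance_upstream + 1
        planted_cover.setdefault(feature.locus_tag, set()).update(
            range(offset, offset + MOTIF_LENGTH)
        )
    known = {(row["locus_tag"], row["offset"]) for row in plant_rows}
    for locus, cover in planted_cover.items():
        region = regions[locus]
        for offset, matched in _window_matches(region):
            if (locus, offset) in known:
                continue
            if set(range(offset, offset + MOTIF_LENGTH)) <= cover:
                feature = region.gene
                plant_rows.append(
                    {
                        "gene_index": next(
                            i for i, f in enumerate(features) if f.locus_tag == locus
                        ),
                        "locus_tag": locus,
                        "strand": feature.strand,
                        "offset": offset,
                        "distance_upstream": region.window_length - offset + 1,
                        "matched": matched.upper(),
                        "contig": feature.contig_id,
                        "contig_position": _oriented_to_forward(region, offset),
                    }
                )


# ---------------------------------------------------------------------------
# Light-response curves

#: the study's actinic ladder spans 10-2400 umol photons m^-2 s^-1
DEFAULT_IRRADIANCE_LADDER = (
    10.0, 25.0, 50.0, 100.0, 180.0, 320.0, 560.0, 800.0, 1100.0, 1500.0, 1900.0, 2400.0
)


@dataclass(frozen=True)
class RlcSpec:
    """Eilers-Peeters truth for a synthetic rapid light curve.

    Defaults give an initial slope of ~0.45 (the dark-adapted Fv/Fm scale
    typical of cyanobacteria), a maximum near 70 a.u. and an optimum near
    470 umol photons m^-2 s^-1 — a realistic mid-light-adapted curve on the
    10-2400 ladder.
    """

    a: float = 1e-5
    b: float = 0.005
    c: float = 2.22
    irradiance: tuple[float, ...] = DEFAULT_IRRADIANCE_LADDER
    noise_sd: float = 0.0
    fv_fm: float = 0.45


def synth_rlc(spec: RlcSpec, seed: int = 0) -> tuple[LightResponseCurve, dict]:
    """Sample rETR from P(I) with additive Gaussian noise; truth returned."""
    rng = np.random.default_rng(seed)
    irradiance = np.asarray(spec.irradiance, dtype=float)
    clean = ep_model(irradiance, spec.a, spec.b, spec.c)
    retr = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape) if spec.noise_sd > 0 else clean.copy()
    phi = np.clip(retr / irradiance, 0.0, 1.0)
    curve = LightResponseCurve(
        irradiance=irradiance, phi_psii=phi, retr=retr, fv_fm=spec.fv_fm
    )
    truth = {"a": spec.a, "b": spec.b, "c": spec.c, "clean_retr": clean}
    return curve, truth


# ---------------------------------------------------------------------------
# Rereduction traces


@dataclass(frozen=True)
class KineticsSpec:
    """Exponential rise A (1 - e^(-k t)) with k = ln 2 / half_time.

    The default half-time of 20 ms is a realistic rereduction time scale
    for soluble-carrier kinetics; traces span ten half-times so the plateau
    is well defined.
    """

    amplitude: float = 1.0
    half_time: float = 0.020  # seconds
    duration_halftimes: float = 10.0
    n_points: int = 2001
    noise_sd: float = 0.0
    offset: float = 0.0


def synth_rereduction_trace(
    spec: KineticsSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate (time, signal) for an exponential rereduction rise."""
    rng = np.random.default_rng(seed)
    k = math.log(2.0) / spec.half_time
    t = np.linspace(0.0, spec.duration_halftimes * spec.half_time, spec.n_points)
    y = spec.offset + spec.amplitude * (1.0 - np.exp(-k * t))
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    truth = {"half_time": spec.half_time, "rate": k, "amplitude": spec.amplitude}
    return t, y, truth


# ---------------------------------------------------------------------------
# Ct tables

#: default true fold changes (40C relative to 20C) for the synthetic table;
#: values chosen as realistic heat-stress responses: strong induction of the
#: cytochrome c6 carrier, strong repression of succinate dehydrogenase,
#: mild repression of isocitrate dehydrogenase and the GroES co-chaperonin
DEFAULT_TRUE_FOLDS = {
    "petJ": 3.7142857,
    "sdh": 0.0909091,
    "icdh": 0.8589744,
    "groES": 0.8438124,
}


@dataclass(frozen=True)
class CtSpec:
    """Generator settings for a long-format comparative-Ct table."""

    true_folds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_FOLDS))
    strain: str = "PCC7806"
    conditions: tuple[str, str] = ("20C", "40C")  # (calibrator, treatment)
    reference_gene: str = "ppc"
    base_ct: float = 20.0
    noise_sd: float = 0.2
    replicates: int = 3
    tech_reps: int = 3


def synth_ct_table(spec: CtSpec, seed: int = 0) -> tuple[CtTable, dict[str, float]]:
    """Generate replicate Ct values encoding known fold changes.

    Target Ct = base_ct - log2(expression level) + noise, with the
    calibrator level 1 and the treatment level equal to the true fold; the
    reference gene sits at base_ct in every condition, so dCt recovers
    -log2(level) exactly in the noiseless case.
    """
    rng = np.random.default_rng(seed)
    calibrator, treatment = spec.conditions
    rows = []
    for gene, fold in {**spec.true_folds, spec.reference_gene: None}.items():
        for condition in spec.conditions:
            if gene == spec.reference_gene:
                level = 1.0
            else:
                level = 1.0 if condition == calibrator else fold
            for rep in range(1, spec.replicates + 1):
                for tech in range(1, spec.tech_reps + 1):
                    noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "sample_id": f"{spec.strain}_{condition}_r{rep}",
                            "strain": spec.strain,
                            "condition": condition,
                            "gene": gene,
                            "replicate": rep,
                            "tech_rep": tech,
                            "ct": spec.base_ct - math.log2(level) + noise,
                        }
                    )
    table = CtTable(
        data=pd.DataFrame(rows),
        reference_gene=spec.reference_gene,
        calibrator_condition=calibrator,
    )
    return table, dict(spec.true_folds)
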