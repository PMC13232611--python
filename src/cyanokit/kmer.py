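"""Alignment-free genome similarity from k-mer profiles.

A :class:`KmerProfile` is the multiset of all length-k windows of a genome,
collected by a stride-1 sliding window within each contig (windows never
span contig joins). Windows containing any ambiguous base (anything other
than A/C/G/T after uppercasing) are skipped rather than expanded, and only
the forward strand is profiled — no reverse-complement canonicalisation.

Two similarities are computed between profiles at equal k:

* Jaccard — presence/absence only: shared k-mers over total unique k-mers;
* cosine — on the count vectors over the key union, scale-invariant.

``kmer_similarity_report`` sweeps k over a range (default 3-6, where the
4^k <= 4096 possible words saturate in megabase-scale genomes) and reports
per-k values plus their arithmetic means for headline comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from cyanokit.errors import DomainError
from cyanokit.genome_io import GenomeRecord

# base -> 2-bit code; anything else maps to the sentinel 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = "ACGT"


@dataclass
class KmerProfile:
    """k-mer -> count mapping for one genome at fixed k.

    Keys are uppercase A/C/G/T strings of length k; ``total`` is the number
    of windows kept (sum of counts).
    """

    k: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise DomainError(f"k must be >= 1, got {self.k}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def keys(self) -> set[str]:
        return set(self.counts)

    def __len__(self) -> int:
        return len(self.counts)


def _decode(code: int, k: int) -> str:
    out = []
    for shift in range(k - 1, -1, -1):
        out.append(_BASES[(code >> (2 * shift)) & 3])
    return "".join(out)


def _contig_codes(sequence: str, k: int) -> np.ndarray:
    """Integer codes of all valid (unambiguous) k-windows of one contig."""
    if len(sequence) < k:
        return np.empty(0, dtype=np.uint64)
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    valid = codes != 255
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    keep = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    weights = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    packed = (windows[keep].astype(np.uint64) * weights).sum(axis=1)
    return packed


def kmer_profile(genome: GenomeRecord, k: int) -> KmerProfile:
    """Count every unambiguous k-mer of a genome (forward strand, stride 1).

    A k exceeding every contig length yields an empty profile, which is
    legal but unusable by the similarity functions.
    """
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    if k > 32:
        raise DomainError(f"k must be <= 32 (2-bit packing), got {k}")
    counts: dict[int, int] = {}
    for contig in genome:
        packed = _contig_codes(contig.sequence, k)
        if packed.size == 0:
            continue
        uniq, n = np.unique(packed, return_counts=True)
        for code, count in zip(uniq.tolist(), n.tolist()):
            counts[code] = counts.get(code, 0) + count
    return KmerProfile(k=k, counts={_decode(c, k): n for c, n in counts.items()})


def jaccard(p: KmerProfile, q: KmerProfile) -> float:
    """Jaccard similarity of the two k-mer *sets* (counts are ignored)."""
    if p.k != q.k:
        raise DomainError(f"profiles have different k ({p.k} vs {q.k})")
    a, b = p.keys(), q.keys()
    union = a | b
    if not union:
        raise DomainError("Jaccard undefined: both profiles are empty")
    return len(a & b) / len(union)


def cosine(p: KmerProfile, q: KmerProfile) -> float:
    """Cosine similarity of the k-mer count vectors over the key union.

    Scale-invariant: raw counts and relative frequencies give the same
    value. Result lies in [0, 1] since counts are non-negative.
    """
    if p.k != q.k:
        raise DomainError(f"profiles have different k ({p.k} vs {q.k})")
    norm_p = math.sqrt(sum(v * v for v in p.counts.values()))
    norm_q = math.sqrt(sum(v * v for v in q.counts.values()))
    if norm_p == 0.0 or norm_q == 0.0:
        raise DomainError("cosine undefined for a zero-norm (empty) profile")
    smaller, larger = (p.counts, q.counts) if len(p) <= len(q) else (q.counts, p.counts)
    dot = sum(v * larger.get(key, 0) for key, v in smaller.items())
    return dot / (norm_p * norm_q)


@dataclass
class SimilarityReport:
    """Per-k Jaccard/cosine values between two genomes plus their means."""

    k_min: int
    k_max: int
    jaccard_by_k: dict[int, float]
    cosine_by_k: dict[int, float]

    @property
    def mean_jaccard(self) -> float:
        return sum(self.jaccard_by_k.values()) / len(self.jaccard_by_k)

    @property
    def mean_cosine(self) -> float:
        return sum(self.cosine_by_k.values()) / len(self.cosine_by_k)

    def to_frame(self) -> "pandas.DataFrame":
        import pandas as pd

        rows = [
            {"k": str(k), "jaccard": self.jaccard_by_k[k], "cosine": self.cosine_by_k[k]}
            for k in sorted(self.jaccard_by_k)
        ]
        rows.append({"k": "mean", "jaccard": self.mean_jaccard, "cosine": self.mean_cosine})
        return pd.DataFrame(rows)


def kmer_similarity_report(
    a: GenomeRecord, b: GenomeRecord, k_min: int = 3, k_max: int = 6
) -> SimilarityReport:
    """Jaccard and cosine similarity for every k in [k_min, k_max]."""
    if k_min > k_max:
        raise DomainError(f"k_min ({k_min}) exceeds k_max ({k_max})")
    jac: dict[int, float] = {}
    cos: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        pa, pb = kmer_profile(a, k), kmer_profile(b, k)
        jac[k] = jaccard(pa, pb)
        cos[k] = cosine(pa, pb)
    return SimilarityReport(k_min=k_min, k_max=k_max, jaccard_by_k=jac, cosine_by_k=cos)
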