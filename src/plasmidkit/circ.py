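"""Circularity detection and curation.

A circular molecule assembled as a linear contig carries two independent
signatures: identical sequence at both termini (the assembler walks around
the circle and duplicates the junction region) and read pairs whose mates
map near opposite ends of the contig (fragments spanning the junction).
Both lines of evidence are required jointly for a confident circular call;
either alone is reported as suggestive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from plasmidkit.discover import GeneFeature
from plasmidkit.express import AlignmentRecord

DEFAULT_MIN_OVERLAP = 20
DEFAULT_MAX_OVERLAP = 5000
DEFAULT_MAX_MISMATCH = 0
DEFAULT_MIN_PAIRS = 3
DEFAULT_MAX_INSERT = 1000


@dataclass(frozen=True)
class CircularityCall:
    """Evidence record deciding circular vs linear for one contig."""

    contig_id: str
    overlap_len: int
    mismatches: int
    n_spanning_pairs: int
    is_circular: bool
    circular_length: int
    suggestive: bool = False


def find_terminal_overlap(
    seq: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[int, int]:
    """Longest terminal direct repeat: prefix_k ~ suffix_k within max_mismatch.

    Returns ``(overlap_len, mismatches)``; ``(0, 0)`` when no k in
    [min_overlap, max_overlap] qualifies. Hamming distance is used because
    assembler terminal duplications are exact copies (a small mismatch
    allowance covers base-call errors).
    """
    length = len(seq)
    if length <= 2 * min_overlap:
        raise ValueError(
            f"sequence length {length} too short for min_overlap {min_overlap}"
        )
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    hi = min(max_overlap, length // 2)
    for k in range(hi, min_overlap - 1, -1):
        mism = int(np.count_nonzero(arr[:k] != arr[length - k :]))
        if mism <= max_mismatch:
            return k, mism
    return 0, 0


def count_spanning_pairs(
    alignments: Iterable[AlignmentRecord],
    junction_pos: int,
    linear_length: int,
    max_insert: int = DEFAULT_MAX_INSERT,
) -> int:
    """Count mate pairs spanning a putative circular junction.

    A pair spans when one mate (forward strand) ends within ``max_insert``
    before the junction and its mate (reverse strand) starts within
    ``max_insert`` after the homologous 5' region, i.e. the pair is
    convergent across the wrap-around point. Coordinates are taken on the
    trimmed circle of length ``linear_length``.
    """
    left_start = junction_pos % linear_length  # junction at the end -> 0
    pairs: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        pairs.setdefault(rec.read_id, []).append(rec)
    mated = {rid: recs for rid, recs in pairs.items() if len(recs) == 2}
    if not mated:
        if pairs:
            warnings.warn("no mated pairs in alignment input", stacklevel=2)
        return 0
    n = 0
    for recs in mated.values():
        fwd = next((r for r in recs if r.strand == "+"), None)
        rev = next((r for r in recs if r.strand == "-"), None)
        if fwd is None or rev is None:
            continue
        near_end = junction_pos - max_insert < fwd.end <= junction_pos
        near_start = left_start <= rev.start < left_start + max_insert
        if near_end and near_start:
            n += 1
    return n


def trim_and_circularize(seq: str, overlap_len: int) -> str:
    """Drop the duplicated terminal region, yielding the circular sequence."""
    if overlap_len >= len(seq):
        raise ValueError(
            f"overlap {overlap_len} must be shorter than the sequence ({len(seq)})"
        )
    if overlap_len < 0:
        raise ValueError("overlap_len must be non-negative")
    return seq[: len(seq) - overlap_len] if overlap_len else seq


def assess_circularity(
    contig_id: str,
    seq: str,
    alignments: Iterable[AlignmentRecord],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    max_insert: int = DEFAULT_MAX_INSERT,
) -> CircularityCall:
    """Combine terminal-repeat and spanning-pair evidence into one call."""
    overlap, mismatches = find_terminal_overlap(
        seq, min_overlap=min_overlap, max_overlap=max_overlap, max_mismatch=max_mismatch
    )
    circular_length = len(seq) - overlap
    records = [a for a in alignments if a.contig_id == contig_id]
    n_pairs = count_spanning_pairs(
        records, junction_pos=circular_length, linear_length=circular_length,
        max_insert=max_insert,
    ) if records else 0
    has_repeat = overlap >= min_overlap
    has_pairs = n_pairs >= min_pairs
    return CircularityCall(
        contig_id=contig_id,
        overlap_len=overlap,
        mismatches=mismatches,
        n_spanning_pairs=n_pairs,
        is_circular=has_repeat and has_pairs,
        circular_length=circular_length,
        suggestive=has_repeat != has_pairs,
    )


def rotate_to_start(seq: str, start_pos: int, circular: bool = True) -> str:
    """Rotate a circular sequence so ``start_pos`` becomes index 0."""
    if not circular:
        raise ValueError("cannot rotate a linear sequence")
    length = len(seq)
    if not 0 <= start_pos < length:
        raise ValueError(f"start_pos {start_pos} outside [0, {length})")
    return seq[start_pos:] + seq[:start_pos]


def rotate_features(
    genes: Sequence[GeneFeature], start_pos: int, length: int
) -> list[GeneFeature]:
    """Remap gene coordinates after rotating the replicon to ``start_pos``.

    Genes that would straddle the new sequence start are rejected; pick a
    rotation point in an intergenic region (``snap_to_intergenic``).
    """
    out: list[GeneFeature] = []
    for g in genes:
        new_start = (g.start - start_pos) % length
        new_end = new_start + g.length
        if new_end > length:
            raise ValueError(
                f"gene {g.id} would wrap the new start; rotate at an "
                "intergenic position"
            )
        out.append(
            GeneFeature(
                id=g.id,
                contig_id=g.contig_id,
                start=new_start,
                end=new_end,
                strand=g.strand,
                product=g.product,
                taxonomy=g.taxonomy,
            )
        )
    return out


def snap_to_intergenic(
    genes: Sequence[GeneFeature], pos: int, length: int
) -> int:
    """Nearest position (mod length) that falls between genes.

    Curators place the chosen genome start (e.g. from cumulative GC skew) at
    a gene boundary rather than inside an ORF; this helper does the same.
    """
    if not genes:
        return pos % length
    pos %= length
    inside = [g for g in genes if g.start < g.end and g.start <= pos < g.end]
    if not inside:
        return pos
    candidates = []
    for g in inside:
        for edge in (g.start, g.end % length):
            d = min((edge - pos) % length, (pos - edge) % length)
            candidates.append((d, edge))
    return min(candidates)[1]
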