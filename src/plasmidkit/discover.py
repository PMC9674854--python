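"""Candidate-ECE identification.

Contigs are screened for extrachromosomal elements by combining three lines
of evidence, mirroring how plasmids of *Methanoperedens* are found in
bioreactor metagenomes: a dominant taxonomic profile matching the target
lineage, GC/coverage binning that separates replicons sampled at different
depths or compositions, and the presence of plasmid replication/partitioning
marker genes (Orc1/Cdc6, ParA, RepA) in the annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

#: Canonical rank order used for lineage tuples (domain -> species).
RANKS = ("domain", "phylum", "class", "order", "genus", "species")

#: Default keyword set for plasmid replication/partitioning markers.
DEFAULT_MARKER_TERMS = frozenset({"Orc1", "Cdc6", "ParA", "RepA"})


@dataclass(frozen=True)
class GeneFeature:
    """A predicted gene on a contig, 0-based half-open coordinates."""

    id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    taxonomy: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Contig:
    """An assembled sequence with coverage, GC and gene features."""

    id: str
    sequence: str
    coverage: float | None = None
    genes: list[GeneFeature] = field(default_factory=list)
    gc: float = field(init=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        n_gc = seq.count("G") + seq.count("C")
        n_at = seq.count("A") + seq.count("T")
        denom = n_gc + n_at
        self.gc = n_gc / denom if denom else 0.0
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(
                    f"gene {g.id} extends past contig {self.id} "
                    f"({g.end} > {len(self.sequence)})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonomyProfile:
    """Per-contig summary of gene-level taxonomic classifications."""

    contig_id: str
    n_classified: int
    counts: Mapping[str, int]
    dominant_lineage: str | None
    dominant_fraction: float
    tie: bool = False
    unclassified: bool = False


@dataclass
class Bin:
    """A group of contigs sharing GC, coverage and taxonomy."""

    id: str
    contig_ids: list[str]
    role: str = "other"  # {chromosome, ece_candidate, other}
    mean_gc: float = 0.0
    mean_coverage: float = 0.0
    total_length: int = 0
    lineage: str | None = None


@dataclass(frozen=True)
class MarkerHits:
    contig_id: str
    gene_ids: tuple[str, ...]
    terms_matched: tuple[str, ...]

    def __bool__(self) -> bool:
        return bool(self.gene_ids)


@dataclass(frozen=True)
class EceCandidate:
    bin_id: str
    contig_ids: tuple[str, ...]
    mean_gc: float
    mean_coverage: float
    total_length: int
    lineage: str | None
    marker_gene_ids: tuple[str, ...]
    no_chromosome_flag: bool = False


def lineage_at(taxonomy: Sequence[str] | None, rank: str = "genus") -> str | None:
    """Extract the name at ``rank`` from an ordered lineage, or None."""
    if taxonomy is None:
        return None
    idx = RANKS.index(rank)
    if idx >= len(taxonomy):
        return None
    return taxonomy[idx]


def taxonomy_profile(contig: Contig, rank: str = "genus") -> TaxonomyProfile:
    """Summarize the gene-level taxonomy of a contig at the requested rank.

    The dominant lineage is the most frequent classified lineage; ties are
    broken lexicographically and flagged. Contigs with no classified gene get
    a flagged profile with dominant_fraction 0.
    """
    if not contig.genes:
        raise ValueError(f"contig {contig.id} has no genes")
    counts: dict[str, int] = {}
    for g in contig.genes:
        name = lineage_at(g.taxonomy, rank)
        if name is not None:
            counts[name] = counts.get(name, 0) + 1
    n_classified = sum(counts.values())
    if n_classified == 0:
        return TaxonomyProfile(
            contig.id, 0, {}, None, 0.0, tie=False, unclassified=True
        )
    best = max(counts.values())
    winners = sorted(name for name, c in counts.items() if c == best)
    return TaxonomyProfile(
        contig_id=contig.id,
        n_classified=n_classified,
        counts=counts,
        dominant_lineage=winners[0],
        dominant_fraction=best / n_classified,
        tie=len(winners) > 1,
    )


def has_replication_markers(
    contig: Contig, marker_terms: Iterable[str] = DEFAULT_MARKER_TERMS
) -> MarkerHits:
    """Case-insensitive substring match of gene products against marker terms."""
    terms = [str(t) for t in marker_terms]
    hit_genes: list[str] = []
    hit_terms: set[str] = set()
    for g in contig.genes:
        product = g.product.lower()
        matched = [t for t in terms if t.lower() in product]
        if matched:
            hit_genes.append(g.id)
            hit_terms.update(matched)
    return MarkerHits(contig.id, tuple(hit_genes), tuple(sorted(hit_terms)))


def _coverage_compatible(c1: float, c2: float, cov_window: float) -> bool:
    hi = max(c1, c2)
    if hi == 0:
        return True
    return abs(c1 - c2) / hi <= cov_window


def bin_contigs(
    contigs: Sequence[Contig],
    profiles: Mapping[str, TaxonomyProfile] | None = None,
    gc_window: float = 0.02,
    cov_window: float = 0.15,
    target_lineage: str | None = None,
    min_dominant_fraction: float = 0.5,
    rank: str = "genus",
) -> list[Bin]:
    """Group contigs by single-linkage agreement of GC, coverage and lineage.

    Two contigs join when their GC differs by at most ``gc_window``
    (absolute), their coverages differ by at most ``cov_window`` (relative to
    the larger), and their dominant lineages agree. The largest bin (by
    summed length) whose lineage matches ``target_lineage`` is labeled
    ``chromosome``.
    """
    if not contigs:
        raise ValueError("bin_contigs requires at least one contig")
    if profiles is None:
        profiles = {c.id: taxonomy_profile(c, rank) for c in contigs}

    def lineage_of(c: Contig) -> str | None:
        p = profiles.get(c.id)
        if p is None or p.dominant_fraction < min_dominant_fraction:
            return None
        return p.dominant_lineage

    graph = nx.Graph()
    graph.add_nodes_from(c.id for c in contigs)
    for i, a in enumerate(contigs):
        for b in contigs[i + 1 :]:
            if a.coverage is None or b.coverage is None:
                continue
            if abs(a.gc - b.gc) > gc_window:
                continue
            if not _coverage_compatible(a.coverage, b.coverage, cov_window):
                continue
            if lineage_of(a) != lineage_of(b):
                continue
            graph.add_edge(a.id, b.id)

    by_id = {c.id: c for c in contigs}
    bins: list[Bin] = []
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(graph)),
        key=lambda ids: ids[0],
    )
    for k, ids in enumerate(components):
        members = [by_id[i] for i in ids]
        total = sum(m.length for m in members)
        mean_gc = sum(m.gc * m.length for m in members) / total
        covs = [m.coverage for m in members if m.coverage is not None]
        mean_cov = (
            sum(c * m.length for c, m in zip(covs, members)) / total if covs else 0.0
        )
        lineages = [lineage_of(m) for m in members]
        lineage = max(
            sorted(set(lineages), key=lambda x: (x is None, x)),
            key=lambda x: lineages.count(x),
        )
        bins.append(
            Bin(
                id=f"bin{k:03d}",
                contig_ids=ids,
                mean_gc=mean_gc,
                mean_coverage=mean_cov,
                total_length=total,
                lineage=lineage,
            )
        )

    if target_lineage is not None:
        target_bins = [b for b in bins if b.lineage == target_lineage]
        if target_bins:
            chromosome = max(target_bins, key=lambda b: (b.total_length, b.id))
            chromosome.role = "chromosome"
    return bins


def identify_ece_candidates(
    bins: Sequence[Bin],
    contigs: Sequence[Contig],
    target_lineage: str,
    marker_terms: Iterable[str] = DEFAULT_MARKER_TERMS,
) -> list[EceCandidate]:
    """Report bins that look like ECEs of the target lineage.

    Candidates are bins with the target dominant lineage that are not the
    chromosome bin and carry at least one replication-marker gene. When no
    chromosome bin exists a warning is issued and candidates are still
    emitted, flagged.
    """
    by_id = {c.id: c for c in contigs}
    no_chromosome = not any(b.role == "chromosome" for b in bins)
    if no_chromosome:
        warnings.warn(
            f"no chromosome bin found for lineage {target_lineage!r}; "
            "candidates flagged",
            stacklevel=2,
        )
    candidates: list[EceCandidate] = []
    for b in bins:
        if b.role == "chromosome" or b.lineage != target_lineage:
            continue
        marker_genes: list[str] = []
        for cid in b.contig_ids:
            marker_genes.extend(has_replication_markers(by_id[cid], marker_terms).gene_ids)
        if not marker_genes:
            continue
        b.role = "ece_candidate"
        candidates.append(
            EceCandidate(
                bin_id=b.id,
                contig_ids=tuple(b.contig_ids),
                mean_gc=b.mean_gc,
                mean_coverage=b.mean_coverage,
                total_length=b.total_length,
                lineage=b.lineage,
                marker_gene_ids=tuple(marker_genes),
                no_chromosome_flag=no_chromosome,
            )
        )
    return candidates


def relative_abundance(bins: Sequence[Bin]) -> dict[str, float]:
    """Coverage*length-weighted fraction of the sampled community per bin."""
    weights = {b.id: b.mean_coverage * b.total_length for b in bins}
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("total coverage*length is zero; cannot compute abundance")
    return {bid: w / total for bid, w in weights.items()}
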