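"""Synthetic communities with known ground truth.

The generator emulates the statistical structure of a bioreactor enrichment
dominated by one archaeal host that carries a large circular plasmid:

* a host chromosome and a circular plasmid maintained at a configurable
  copy (depth) ratio, ~1:1 by default;
* a two-replichore GC-skew signal on the plasmid with an AT-rich origin
  region (default 1,743 bp, the scale seen in archaeal replication origins);
* assembler-style linearization of the circular molecule with identical
  termini (a terminal direct repeat);
* uniformly placed paired-end fragments (wrapping across the circular
  junction) and per-gene Poisson transcript counts;
* a protein universe of planted families shared or unshared between plasmid
  and host, plus unrelated background proteins.

The GC skew is generated from per-position base probabilities
P(G) = gc/2*(1+a), P(C) = gc/2*(1-a) on the leading strand (swapped on the
lagging strand) so the expected windowed skew is exactly +a / -a and every
downstream expectation is analytically known. All randomness flows through
one seeded generator; every output is reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from plasmidkit.discover import Contig, GeneFeature
from plasmidkit.express import AlignmentRecord
from plasmidkit.protfam import ProteinRecord

#: Reference lineage used for the synthetic host and its plasmid.
METHANOPEREDENS_LINEAGE = (
    "Archaea",
    "Euryarchaeota",
    "Methanomicrobia",
    "Methanosarcinales",
    "Candidatus Methanoperedens",
    "Candidatus Methanoperedens nitroreducens",
)
OTHER_LINEAGE = (
    "Bacteria",
    "Methylomirabilota",
    "Methylomirabilia",
    "Methylomirabilales",
    "Methylomirabilis",
    "Methylomirabilis oxyfera",
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of the synthetic host+plasmid community."""

    seed: int = 0
    host_length: int = 300_000
    plasmid_length: int = 150_000
    copy_ratio: float = 1.0  # plasmid depth / host depth
    host_depth: float = 50.0
    gc_host: float = 0.45
    gc_plasmid: float = 0.392
    skew_amplitude: float = 0.1
    origin_pos: int = 0
    at_rich_origin_len: int = 1743
    read_length: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    overlap_len: int = 500  # assembler terminal duplication
    n_genes_plasmid: int = 150
    n_genes_host: int = 300

    def validate(self) -> None:
        if not 0 < self.gc_host < 1 or not 0 < self.gc_plasmid < 1:
            raise ValueError("GC fractions must lie in (0, 1)")
        if not 0 <= self.skew_amplitude < 1:
            raise ValueError("skew amplitude must lie in [0, 1)")
        if not 0 <= self.origin_pos < self.plasmid_length:
            raise ValueError("origin_pos must lie on the plasmid")
        if self.overlap_len >= self.plasmid_length // 4:
            raise ValueError("overlap_len must be < plasmid_length/4")
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be >= read_length")
        if self.copy_ratio < 0 or self.host_depth < 0:
            raise ValueError("depths must be non-negative")


@dataclass
class GroundTruth:
    """Planted quantities a correct pipeline must recover."""

    true_origin: int = 0
    true_terminus: int = 0
    true_copy_ratio: float = 1.0
    true_circular: dict[str, bool] = field(default_factory=dict)
    true_family_of_protein: dict[str, str] = field(default_factory=dict)
    true_expressed: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class RepliconSpec:
    """A replicon to simulate reads over (coordinates on the true circle)."""

    id: str
    length: int
    circular: bool = False


@dataclass
class SyntheticCommunity:
    spec: CommunitySpec
    contigs: list[Contig]
    plasmid_contig_id: str
    host_contig_id: str
    plasmid_circular_seq: str
    truth: GroundTruth
    genome_alignments: list[AlignmentRecord]
    transcript_alignments: list[AlignmentRecord]
    expression_rates: dict[str, float]


def _rng(rng_seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def generate_replichore_sequence(
    length: int,
    gc: float,
    a: float,
    leading: bool = True,
    rng_seed: int | np.random.Generator | None = None,
) -> str:
    """DNA with P(G) = gc/2*(1+a), P(C) = gc/2*(1-a) (swapped when lagging).

    A and T are equiprobable at (1-gc)/2 each; the expected windowed GC skew
    is +a on the leading and -a on the lagging replichore.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must lie in (0, 1)")
    if not 0 <= a < 1:
        raise ValueError("amplitude must lie in [0, 1)")
    rng = _rng(rng_seed)
    p_g = gc / 2 * (1 + a)
    p_c = gc / 2 * (1 - a)
    if not leading:
        p_g, p_c = p_c, p_g
    p_at = (1 - gc) / 2
    idx = rng.choice(4, size=length, p=[p_g, p_c, p_at, p_at])
    return bytes(np.frombuffer(b"GCAT", dtype=np.uint8)[idx]).decode("ascii")


def generate_plasmid(
    spec: CommunitySpec, rng_seed: int | np.random.Generator | None = None
) -> tuple[str, GroundTruth]:
    """Circular plasmid sequence with a planted two-replichore skew signal.

    The leading replichore runs from the origin to the terminus (half way
    around) and the lagging replichore back; an AT-rich segment (GC halved)
    of ``at_rich_origin_len`` starts at the origin.
    """
    spec.validate()
    rng = _rng(spec.seed if rng_seed is None else rng_seed)
    length = spec.plasmid_length
    half = length // 2
    leading = generate_replichore_sequence(
        half, spec.gc_plasmid, spec.skew_amplitude, leading=True, rng_seed=rng
    )
    lagging = generate_replichore_sequence(
        length - half, spec.gc_plasmid, spec.skew_amplitude, leading=False,
        rng_seed=rng,
    )
    built = leading + lagging  # index 0 == origin
    if spec.at_rich_origin_len > 0:
        at_seg = generate_replichore_sequence(
            min(spec.at_rich_origin_len, length),
            spec.gc_plasmid / 2,
            spec.skew_amplitude,
            leading=True,
            rng_seed=rng,
        )
        built = at_seg + built[len(at_seg) :]
    shift = spec.origin_pos % length
    seq = built[length - shift :] + built[: length - shift] if shift else built
    truth = GroundTruth(
        true_origin=spec.origin_pos,
        true_terminus=(spec.origin_pos + half) % length,
        true_copy_ratio=spec.copy_ratio,
        true_circular={"plasmid": True},
    )
    return seq, truth


def linearize_with_overlap(circular: str, break_pos: int, overlap_len: int) -> str:
    """Rotation starting at ``break_pos`` with its first ``overlap_len`` bases
    appended at the end — the assembler's terminal direct repeat."""
    length = len(circular)
    if overlap_len >= length:
        raise ValueError("overlap_len must be shorter than the sequence")
    if not 0 <= break_pos < length:
        raise ValueError(f"break_pos {break_pos} outside [0, {length})")
    rot = circular[break_pos:] + circular[:break_pos]
    return rot + rot[:overlap_len]


def simulate_paired_alignments(
    replicons: Sequence[RepliconSpec],
    depths: Mapping[str, float],
    read_length: int = 150,
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
    rng_seed: int | np.random.Generator | None = None,
) -> list[AlignmentRecord]:
    """Uniform paired-end fragments at the requested fold-coverage.

    Fragment starts are uniform on each replicon, wrapping across the
    junction of circular ones (mate coordinates are reported on the true
    circle). Each mate carries identity 1.0; mate linkage is by shared
    read id. The number of pairs is depth * length / (2 * read_length).
    """
    if insert_mean < read_length:
        raise ValueError("insert_mean must be >= read_length")
    if any(d < 0 for d in depths.values()):
        raise ValueError("depths must be non-negative")
    rng = _rng(rng_seed)
    records: list[AlignmentRecord] = []
    for rep in replicons:
        depth = depths.get(rep.id, 0.0)
        n_pairs = int(round(depth * rep.length / (2 * read_length)))
        if n_pairs == 0:
            continue
        inserts = np.clip(
            rng.normal(insert_mean, insert_sd, size=n_pairs),
            2 * read_length,
            max(2 * read_length, rep.length - 1),
        ).astype(int)
        if rep.circular:
            starts = rng.integers(0, rep.length, size=n_pairs)
        else:
            starts = rng.integers(
                0, np.maximum(1, rep.length - inserts), size=n_pairs
            )
        for i, (start, insert) in enumerate(zip(starts, inserts)):
            rid = f"{rep.id}:pair{i:07d}"
            s1 = int(start % rep.length)
            if s1 + read_length > rep.length:  # keep each read contiguous
                s1 = rep.length - read_length
            s2 = int((start + insert - read_length) % rep.length)
            if s2 + read_length > rep.length:
                s2 = 0 if rep.circular else rep.length - read_length
            records.append(
                AlignmentRecord(rid, rep.id, s1, s1 + read_length, "+", 1.0, True)
            )
            records.append(
                AlignmentRecord(rid, rep.id, s2, s2 + read_length, "-", 1.0, False)
            )
    return records


def simulate_expression(
    genes: Sequence[GeneFeature],
    rate_per_kb: Mapping[str, float],
    read_length: int = 100,
    rng_seed: int | np.random.Generator | None = None,
) -> list[AlignmentRecord]:
    """Single-end transcript reads with per-gene Poisson counts.

    Each gene receives Poisson(rate_per_kb * length / 1000) reads placed
    uniformly within the gene body (fully contained, as transcript-derived
    reads are); genes at rate 0 receive none.
    """
    if any(r < 0 for r in rate_per_kb.values()):
        raise ValueError("rates must be non-negative")
    rng = _rng(rng_seed)
    records: list[AlignmentRecord] = []
    for g in sorted(genes, key=lambda g: (g.contig_id, g.start, g.id)):
        rate = rate_per_kb.get(g.id, 0.0)
        if rate == 0:
            continue
        count = int(rng.poisson(rate * g.length / 1000.0))
        if count == 0:
            continue
        rl = min(read_length, g.length)
        starts = rng.integers(g.start, g.end - rl + 1, size=count)
        for j, s in enumerate(starts):
            records.append(
                AlignmentRecord(
                    f"{g.id}:tx{j:05d}", g.contig_id, int(s), int(s) + rl, g.strand,
                    1.0, True,
                )
            )
    return records


def tile_genes(
    contig_id: str,
    contig_length: int,
    n_genes: int,
    id_prefix: str,
    lineage: tuple[str, ...] | None = METHANOPEREDENS_LINEAGE,
    gene_length: int = 800,
    marker_products: Mapping[int, str] | None = None,
) -> list[GeneFeature]:
    """Evenly tile gene features, alternating strand, with optional markers."""
    if n_genes < 1:
        return []
    spacing = contig_length / n_genes
    glen = min(gene_length, max(2, int(spacing * 0.8)))
    genes = []
    for i in range(n_genes):
        start = int(round(i * spacing))
        end = min(start + glen, contig_length)
        if end - start < 2:
            continue
        product = (marker_products or {}).get(i, "hypothetical protein")
        genes.append(
            GeneFeature(
                id=f"{id_prefix}_{i:04d}",
                contig_id=contig_id,
                start=start,
                end=end,
                strand="+" if i % 2 == 0 else "-",
                product=product,
                taxonomy=lineage,
            )
        )
    return genes


PLASMID_MARKERS = {
    0: "origin of replication recognition complex 1 (Orc1/Cdc6)",
    1: "RepA replication protein",
    2: "ParA partition ATPase",
}
HOST_MARKERS = {0: "Orc1/Cdc6 replication initiator"}


def generate_community(
    spec: CommunitySpec, expressed_fraction: float = 0.6,
    expressed_rate_range: tuple[float, float] = (10.0, 100.0),
) -> SyntheticCommunity:
    """Host chromosome + circular plasmid, reads, transcripts and truth.

    The plasmid is emitted as an assembler-style linear contig with a
    terminal direct repeat of ``overlap_len``; genome alignments are on the
    true circle's coordinate system (which matches the linear contig's first
    ``circular_length`` positions). Transcript rates plant
    ``expressed_fraction`` of the genes as expressed at rates drawn
    log-uniformly from ``expressed_rate_range`` (per-kb normalized counts).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    circ_seq, truth = generate_plasmid(spec, rng_seed=rng)
    host_half = spec.host_length // 2
    host_seq = generate_replichore_sequence(
        host_half, spec.gc_host, spec.skew_amplitude, True, rng
    ) + generate_replichore_sequence(
        spec.host_length - host_half, spec.gc_host, spec.skew_amplitude, False, rng
    )
    linear = linearize_with_overlap(circ_seq, 0, spec.overlap_len)
    plasmid_id, host_id = "plasmid_ctg", "host_ctg"
    plasmid_genes = tile_genes(
        plasmid_id, spec.plasmid_length, spec.n_genes_plasmid, "pgene",
        METHANOPEREDENS_LINEAGE, marker_products=PLASMID_MARKERS,
    )
    host_genes = tile_genes(
        host_id, spec.host_length, spec.n_genes_host, "hgene",
        METHANOPEREDENS_LINEAGE, marker_products=HOST_MARKERS,
    )
    contigs = [
        Contig(host_id, host_seq, genes=host_genes),
        Contig(plasmid_id, linear, genes=plasmid_genes),
    ]
    truth.true_circular = {plasmid_id: True, host_id: False}
    replicons = [
        RepliconSpec(host_id, spec.host_length, circular=False),
        RepliconSpec(plasmid_id, spec.plasmid_length, circular=True),
    ]
    depths = {
        host_id: spec.host_depth,
        plasmid_id: spec.host_depth * spec.copy_ratio,
    }
    genome_alignments = simulate_paired_alignments(
        replicons, depths, spec.read_length, spec.insert_mean, spec.insert_sd, rng
    )
    all_genes = plasmid_genes + host_genes
    rates: dict[str, float] = {}
    lo, hi = expressed_rate_range
    for g in all_genes:
        if rng.random() < expressed_fraction:
            rates[g.id] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            rates[g.id] = 0.0
    truth.true_expressed = {gid for gid, r in rates.items() if r > 0}
    transcript_alignments = simulate_expression(all_genes, rates, 100, rng)
    return SyntheticCommunity(
        spec=spec,
        contigs=contigs,
        plasmid_contig_id=plasmid_id,
        host_contig_id=host_id,
        plasmid_circular_seq=circ_seq,
        truth=truth,
        genome_alignments=genome_alignments,
        transcript_alignments=transcript_alignments,
        expression_rates=rates,
    )


def _family_sizes(
    n_families: int,
    family_size_dist: str | Sequence[int],
    rng: np.random.Generator,
) -> list[int]:
    if isinstance(family_size_dist, str):
        if family_size_dist != "geometric":
            raise ValueError(f"unknown family size distribution {family_size_dist!r}")
        sizes = []
        while len(sizes) < n_families:  # geometric truncated to [2, 10]
            s = int(rng.geometric(0.35)) + 1
            if 2 <= s <= 10:
                sizes.append(s)
        return sizes
    sizes = [int(s) for s in family_size_dist]
    if len(sizes) != n_families:
        raise ValueError("explicit size list must have n_families entries")
    return sizes


def default_source_assignment(n_families: int) -> dict[int, str]:
    """~25% plasmid-only, ~35% shared, rest host-only families."""
    n_plasmid = max(1, round(0.25 * n_families))
    n_both = max(1, round(0.35 * n_families))
    out = {}
    for i in range(n_families):
        if i < n_plasmid:
            out[i] = "plasmid"
        elif i < n_plasmid + n_both:
            out[i] = "both"
        else:
            out[i] = "host"
    return out


def generate_protein_universe(
    n_families: int = 20,
    family_size_dist: str | Sequence[int] = "geometric",
    substitution_rate: float = 0.1,
    source_assignment: Mapping[int, str] | None = None,
    n_background: int = 160,
    seed_length: int = 200,
    rng_seed: int | np.random.Generator | None = None,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Planted protein families plus unrelated background proteins.

    Each family grows from a random ~``seed_length``-residue seed; members
    carry i.i.d. substitutions at ``substitution_rate`` per residue (to one
    of the 19 other amino acids). Families are assigned to sources
    ("plasmid", "host" or "both"; "both" alternates member labels).
    Background proteins are independent random sequences labeled
    ``reference``. Protein ids carry their source label; the returned
    GroundTruth maps every protein to its true family.
    """
    if not 0 <= substitution_rate <= 0.5:
        raise ValueError("substitution_rate must lie in [0, 0.5]")
    rng = _rng(rng_seed)
    sizes = _family_sizes(n_families, family_size_dist, rng)
    assignment = dict(source_assignment or default_source_assignment(n_families))
    class_of = {
        "plasmid": "plasmid",
        "host": "methanoperedens_with_plasmid",
        "reference": "reference",
    }
    proteins: list[ProteinRecord] = []
    truth = GroundTruth()
    aa = np.array(list(_AA))
    for fam_idx, size in enumerate(sizes):
        fam_id = f"fam{fam_idx:03d}"
        source = assignment.get(fam_idx, "host")
        seed_idx = rng.integers(0, 20, size=seed_length)
        for j in range(size):
            idx = seed_idx.copy()
            mask = rng.random(seed_length) < substitution_rate
            # substitute to a uniformly chosen *different* residue
            idx[mask] = (idx[mask] + rng.integers(1, 20, size=int(mask.sum()))) % 20
            if source == "both":
                label = "plasmid" if j % 2 == 0 else "host"
            else:
                label = source
            pid = f"{fam_id}.{j:02d}_{label}"
            proteins.append(
                ProteinRecord(
                    id=pid,
                    source_genome=f"{label}_genome",
                    source_class=class_of[label],
                    sequence="".join(aa[idx]),
                )
            )
            truth.true_family_of_protein[pid] = fam_id
    for t in range(n_background):
        pid = f"bg{t:04d}_reference"
        proteins.append(
            ProteinRecord(
                id=pid,
                source_genome="reference_genome",
                source_class="reference",
                sequence="".join(aa[rng.integers(0, 20, size=seed_length)]),
            )
        )
        truth.true_family_of_protein[pid] = f"bgfam{t:04d}"
    return proteins, truth
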