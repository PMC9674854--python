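"""Protein subfamilies and plasmid-enrichment testing.

Proteins are compared all-vs-all by local alignment (BLOSUM62, affine
gaps); pairs pass when the Karlin-Altschul e-value is at most ``e_max``
(default 0.001) and the aligned span covers at least ``cover_min`` (default
0.5) of the shorter sequence. Subfamilies are defined on the resulting
similarity network by greedy set cover: the protein with the largest
uncovered neighborhood becomes a representative and claims it, until every
protein is covered (singletons allowed).

Each subfamily of size >=2 is then tested for enrichment in plasmid-encoded
proteins with a two-sided Fisher exact test on the 2x2 table
(members in/out of the subfamily x plasmid/non-plasmid source), followed by
Benjamini-Hochberg FDR. A subfamily is enriched when its odds ratio is >=1
and the FDR-adjusted p-value is <=0.05. Percent enrichment is
100 * plasmid members / total members, rounded to the nearest integer.

The Fisher test and the BH step-up are implemented here by exact
(big-integer) hypergeometric enumeration and the explicit step-up formula:
they are the statistical core of the enrichment call and must be auditable
against independent oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_E_MAX = 1e-3
DEFAULT_COVER_MIN = 0.5
DEFAULT_FDR = 0.05

#: Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1
#: (the gapped regime matching the alignment model used for scoring).
KA_LAMBDA = 0.267
KA_K = 0.041

_AA = "ACDEFGHIKLMNPQRSTVWY"
_VALID = frozenset(_AA + "X")


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    source_genome: str
    source_class: str  # plasmid / methanoperedens_* / borg / reference
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence.upper()) - _VALID
        if bad:
            raise ValueError(f"protein {self.id}: invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class SimilarityEdge:
    """Symmetric similarity between two proteins (min id stored first)."""

    query_id: str
    target_id: str
    score: float  # raw alignment score
    bits: float
    evalue: float
    coverage: float  # aligned span / shorter sequence length


@dataclass(frozen=True)
class Subfamily:
    id: str
    representative_id: str
    member_ids: tuple[str, ...]
    class_counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class EnrichmentResult:
    subfamily_id: str
    a: int  # plasmid members in subfamily
    b: int  # non-plasmid members in subfamily
    c: int  # plasmid proteins outside
    d: int  # non-plasmid proteins outside
    odds_ratio: float
    percent_enrichment: int
    p: float
    q: float
    enriched: bool


def make_aligner(
    matrix: str = "BLOSUM62", open_gap: float = -11.0, extend_gap: float = -1.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def pairwise_similarity(
    p1: ProteinRecord,
    p2: ProteinRecord,
    db_size: int,
    e_max: float = DEFAULT_E_MAX,
    cover_min: float = DEFAULT_COVER_MIN,
    aligner: Align.PairwiseAligner | None = None,
    ka_lambda: float = KA_LAMBDA,
    ka_k: float = KA_K,
) -> SimilarityEdge | None:
    """Local alignment -> bit score, e-value and coverage; edge if both pass.

    ``db_size`` is the database size in residues, so the search space is
    len(query) * db_size as in a sequence-database search. The raw score S
    converts to bits = (lambda*S - ln K) / ln 2 and E = m*n*2^-bits.
    """
    if aligner is None:
        aligner = make_aligner()
    s1, s2 = p1.sequence.upper(), p2.sequence.upper()
    aln = aligner.align(s1, s2)
    if len(aln) == 0:
        return None
    best = aln[0]
    score = float(best.score)
    if score <= 0:
        return None
    blocks1, blocks2 = best.aligned
    span1 = int(blocks1[-1][1] - blocks1[0][0])
    span2 = int(blocks2[-1][1] - blocks2[0][0])
    span_short = span1 if len(s1) <= len(s2) else span2
    coverage = span_short / min(len(s1), len(s2))
    bits = (ka_lambda * score - math.log(ka_k)) / math.log(2)
    evalue = len(s1) * db_size * 2.0 ** (-bits)
    if evalue > e_max or coverage < cover_min:
        return None
    a, b = sorted((p1.id, p2.id))
    return SimilarityEdge(a, b, score, bits, evalue, coverage)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all(
    proteins: Sequence[ProteinRecord],
    e_max: float = DEFAULT_E_MAX,
    cover_min: float = DEFAULT_COVER_MIN,
    kmer_prefilter: int | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> list[SimilarityEdge]:
    """Evaluate every unordered pair; deterministic (sorted-id) output order.

    ``kmer_prefilter`` skips alignment for pairs sharing no exact k-mer; any
    pair sharing at least one exact k-mer is always aligned, so the filter
    never removes a qualifying pair that shares a k-length exact word. Off by
    default for exactness.
    """
    if len(proteins) < 2:
        return []
    if aligner is None:
        aligner = make_aligner()
    db_size = sum(len(p.sequence) for p in proteins)
    ordered = sorted(proteins, key=lambda p: p.id)
    kmers = (
        {p.id: _kmer_set(p.sequence.upper(), kmer_prefilter) for p in ordered}
        if kmer_prefilter
        else None
    )
    edges: list[SimilarityEdge] = []
    for i, p1 in enumerate(ordered):
        for p2 in ordered[i + 1 :]:
            if kmers is not None and kmers[p1.id].isdisjoint(kmers[p2.id]):
                continue
            edge = pairwise_similarity(
                p1, p2, db_size=db_size, e_max=e_max, cover_min=cover_min,
                aligner=aligner,
            )
            if edge is not None:
                edges.append(edge)
    return edges


def greedy_set_cover_cluster(
    proteins: Sequence[ProteinRecord], edges: Iterable[SimilarityEdge]
) -> list[Subfamily]:
    """Partition proteins into subfamilies by greedy set cover.

    Repeatedly select the uncovered protein whose neighborhood (itself plus
    uncovered neighbors) is largest as representative; ties broken by
    lexicographic id. Its uncovered neighborhood becomes one subfamily.
    """
    ids = sorted(p.id for p in proteins)
    class_of = {p.id: p.source_class for p in proteins}
    adj: dict[str, set[str]] = {pid: set() for pid in ids}
    for e in edges:
        if e.query_id not in adj or e.target_id not in adj:
            raise ValueError(f"edge references unknown protein {e.query_id}/{e.target_id}")
        adj[e.query_id].add(e.target_id)
        adj[e.target_id].add(e.query_id)
    uncovered = set(ids)
    subfamilies: list[Subfamily] = []
    k = 0
    while uncovered:
        rep = max(
            uncovered,
            key=lambda pid: (1 + len(adj[pid] & uncovered), _neg_lex(pid)),
        )
        members = sorted({rep} | (adj[rep] & uncovered))
        uncovered.difference_update(members)
        counts: dict[str, int] = {}
        for m in members:
            counts[class_of[m]] = counts.get(class_of[m], 0) + 1
        subfamilies.append(
            Subfamily(
                id=f"subfam{k:04d}",
                representative_id=rep,
                member_ids=tuple(members),
                class_counts=counts,
            )
        )
        k += 1
    return subfamilies


class _neg_lex(str):
    """Reverse lexicographic ordering helper for max() tie-breaks."""

    def __lt__(self, other: str) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by big-integer hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    hypergeometric probability does not exceed that of the observed table
    (with a 1+1e-7 relative tolerance for ties, matching floating-point
    implementations). All-zero margins give p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = weights[a - lo]
    # integer form of w <= observed * (1 + 1e-7)
    tail = sum(w for w in weights if w * 10**7 <= observed * (10**7 + 1))
    total = math.comb(n, c1)
    return min(1.0, tail / total)


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def percent_enrichment(n_plasmid: int, n_total: int) -> int:
    """100 * plasmid members / total members, rounded half-up to an integer."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_plasmid <= n_total:
        raise ValueError("need 0 <= n_plasmid <= n_total")
    return int(math.floor(100.0 * n_plasmid / n_total + 0.5))


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c), with inf when b*c = 0 and a*d > 0, and 0/0 -> nan."""
    num, den = a * d, b * c
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def enriched_subfamilies(
    subfamilies: Sequence[Subfamily],
    source_class: Mapping[str, str],
    alpha: float = DEFAULT_FDR,
    min_size: int = 2,
    plasmid_class: str = "plasmid",
) -> list[EnrichmentResult]:
    """Fisher/BH enrichment of each subfamily in plasmid-encoded proteins.

    Singletons (size < ``min_size``) are clustered but excluded from
    testing. BH correction is applied across all tested subfamilies.
    """
    missing = [
        m for sf in subfamilies for m in sf.member_ids if m not in source_class
    ]
    if missing:
        raise ValueError(f"unlabeled proteins: {missing[:5]}")
    total = sum(sf.size for sf in subfamilies)
    total_plasmid = sum(
        1
        for sf in subfamilies
        for m in sf.member_ids
        if source_class[m] == plasmid_class
    )
    tested = [sf for sf in subfamilies if sf.size >= min_size]
    rows: list[tuple[Subfamily, int, int, int, int, float]] = []
    for sf in tested:
        a = sum(1 for m in sf.member_ids if source_class[m] == plasmid_class)
        b = sf.size - a
        c = total_plasmid - a
        d = (total - total_plasmid) - b
        rows.append((sf, a, b, c, d, fisher_two_sided(a, b, c, d)))
    qvals = bh_fdr([r[5] for r in rows])
    results = []
    for (sf, a, b, c, d, p), q in zip(rows, qvals):
        orat = odds_ratio(a, b, c, d)
        results.append(
            EnrichmentResult(
                subfamily_id=sf.id,
                a=a, b=b, c=c, d=d,
                odds_ratio=orat,
                percent_enrichment=percent_enrichment(a, sf.size),
                p=p,
                q=q,
                enriched=(orat >= 1.0) and (q <= alpha),
            )
        )
    return results


def pair_f1(
    true_family: Mapping[str, str], subfamilies: Sequence[Subfamily]
) -> float:
    """Pair-level F1 of a clustering against a reference partition.

    Pairs co-clustered in both partitions are true positives; F1 combines
    pairwise precision and recall. Returns 1.0 when the reference has no
    co-clustered pairs and the clustering finds none either.
    """
    def pairs_of(groups: Iterable[Iterable[str]]) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for g in groups:
            members = sorted(g)
            for i, x in enumerate(members):
                for y in members[i + 1 :]:
                    out.add((x, y))
        return out

    by_family: dict[str, list[str]] = {}
    for pid, fam in true_family.items():
        by_family.setdefault(fam, []).append(pid)
    truth = pairs_of(by_family.values())
    predicted = pairs_of(sf.member_ids for sf in subfamilies)
    if not truth and not predicted:
        return 1.0
    tp = len(truth & predicted)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth) if truth else 0.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
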