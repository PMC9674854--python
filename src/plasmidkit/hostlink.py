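"""Host assignment and copy-number estimation for candidate ECEs.

In a community where a single lineage-matching chromosome co-occurs with a
plasmid-like bin, the plasmid/chromosome sequencing-depth ratio estimates
the per-cell copy number. Ratios near 1 ("abundant", default band
[0.67, 1.5]) indicate a plasmid maintained at the same copy number as the
chromosome; much lower ratios indicate a rare plasmid carried by a
subpopulation. When several lineage-matching hosts exist the one with depth
ratio closest to 1 is chosen and the ambiguity is reported, never silently
resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from plasmidkit.express import AlignmentRecord

DEFAULT_RATIO_BAND = (0.67, 1.5)


@dataclass(frozen=True)
class HostAssignment:
    ece_id: str
    host_id: str | None
    ratio: float | None  # ECE coverage / host coverage
    abundance_class: str  # {abundant, rare, unassigned}
    rationale: str
    ambiguous: bool = False


def coverage_from_alignments(
    alignments: Iterable[AlignmentRecord], contig_id: str, contig_length: int
) -> float:
    """Fold coverage: sum of aligned bases on the contig / contig length."""
    if contig_length <= 0:
        raise ValueError("contig length must be positive")
    total = sum(a.aligned_length for a in alignments if a.contig_id == contig_id)
    return total / contig_length


def assign_host(
    ece_id: str,
    ece_lineage: str | None,
    ece_coverage: float,
    candidate_hosts: Sequence[tuple[str, str | None, float]],
    ratio_band: tuple[float, float] = DEFAULT_RATIO_BAND,
) -> HostAssignment:
    """Assign the ECE to a lineage-matching host by coverage ratio.

    ``candidate_hosts`` are ``(id, lineage, coverage)`` triples. With exactly
    one lineage-matching host it is assigned; with several, the one whose
    depth ratio is closest to 1 (smallest |log ratio|, ties by id) is chosen
    and the assignment flagged ambiguous. No match, or a zero-coverage host,
    yields an unassigned record with a rationale.
    """
    matching = [
        (hid, cov) for hid, lin, cov in candidate_hosts if lin == ece_lineage
    ]
    if not matching:
        return HostAssignment(
            ece_id, None, None, "unassigned",
            f"no candidate host with lineage {ece_lineage!r}",
        )
    usable = [(hid, cov) for hid, cov in matching if cov > 0]
    if not usable:
        return HostAssignment(
            ece_id, None, None, "unassigned",
            "all lineage-matching hosts have zero coverage",
        )
    ranked = sorted(
        usable, key=lambda hc: (abs(math.log(ece_coverage / hc[1])), hc[0])
    ) if ece_coverage > 0 else sorted(usable, key=lambda hc: hc[0])
    host_id, host_cov = ranked[0]
    ratio = ece_coverage / host_cov
    lo, hi = ratio_band
    abundance = "abundant" if lo <= ratio <= hi else "rare"
    ambiguous = len(usable) > 1
    rationale = (
        f"coverage ratio {ratio:.3f} vs host {host_id} ({host_cov:.0f}x)"
        + ("; multiple lineage-matching hosts, chose ratio closest to 1"
           if ambiguous else "")
    )
    return HostAssignment(ece_id, host_id, ratio, abundance, rationale, ambiguous)


def copy_number(assignment: HostAssignment) -> float:
    """Plasmid copy number per chromosome, reported to 2 decimals."""
    if assignment.host_id is None or assignment.ratio is None:
        raise ValueError(f"ECE {assignment.ece_id} has no assigned host")
    return round(assignment.ratio, 2)
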