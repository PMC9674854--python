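"""File formats at the package boundary.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
closed) is converted on read and back on write. SAM is consumed through
pysam with the aligned reference span taken from the CIGAR; per-read
identity comes from the NM tag when present (1 - NM / aligned columns),
else 1.0. Tabular outputs are TSV with a comment header naming the package
version and resolved parameters.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from plasmidkit.discover import Contig, GeneFeature
from plasmidkit.express import AlignmentRecord


class FormatError(ValueError):
    """Malformed record, reported with file and line."""

    def __init__(self, path: str, line: int, reason: str) -> None:
        super().__init__(f"{path}:{line}: {reason}")


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str) -> dict[str, str]:
    """Sequences by record id (wrapped lines joined)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(
    seqs: Mapping[str, str], path: str, descriptions: Mapping[str, str] | None = None
) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description=(descriptions or {}).get(name, ""))
        for name, s in seqs.items()
    ]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------- GFF3


def read_gff3(path: str, feature_types: Sequence[str] = ("gene", "CDS")) -> list[GeneFeature]:
    """Gene features, converted to 0-based half-open coordinates."""
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(path, lineno, f"expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in feature_types:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(path, lineno, f"non-integer coordinates: {exc}")
            if start_i < 1 or end_i < start_i:
                raise FormatError(path, lineno, f"bad interval {start}..{end}")
            if strand not in ("+", "-"):
                raise FormatError(path, lineno, f"bad strand {strand!r}")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            gid = attr.get("ID")
            if not gid:
                raise FormatError(path, lineno, "missing ID attribute")
            genes.append(
                GeneFeature(
                    id=gid,
                    contig_id=seqid,
                    start=start_i - 1,  # GFF3 is 1-based closed
                    end=end_i,
                    strand=strand,
                    product=attr.get("product", ""),
                )
            )
    return genes


def write_gff3(genes: Iterable[GeneFeature], path: str, source: str = "plasmidkit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start, g.id)):
            attrs = f"ID={g.id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        source,
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------- taxonomy sidecar


def read_taxonomy_tsv(path: str) -> dict[str, tuple[str, ...]]:
    """gene_id -> lineage tuple from a 2-column TSV (lineage ';'-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"gene_id", "lineage"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    out: dict[str, tuple[str, ...]] = {}
    for _, row in df.iterrows():
        lineage = row["lineage"]
        if pd.isna(lineage) or not str(lineage).strip():
            continue
        out[row["gene_id"]] = tuple(
            part.strip() for part in str(lineage).split(";") if part.strip()
        )
    return out


def attach_taxonomy(
    genes: Sequence[GeneFeature], taxonomy: Mapping[str, tuple[str, ...]]
) -> list[GeneFeature]:
    return [
        GeneFeature(
            g.id, g.contig_id, g.start, g.end, g.strand, g.product,
            taxonomy.get(g.id),
        )
        for g in genes
    ]


# ---------------------------------------------------------------- SAM


def _identity_from_tags(seg: pysam.AlignedSegment) -> float:
    if not seg.has_tag("NM"):
        return 1.0
    nm = int(seg.get_tag("NM"))
    columns = sum(
        length for op, length in (seg.cigartuples or []) if op in (0, 1, 2, 7, 8)
    )  # M, I, D, =, X
    if columns == 0:
        return 1.0
    return max(0.0, 1.0 - nm / columns)


def read_sam(path: str, identity_sidecar: Mapping[str, float] | None = None) -> list[AlignmentRecord]:
    """Mapped reads as AlignmentRecords; reference span from the CIGAR."""
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for seg in sam.fetch(until_eof=True):
            if seg.is_unmapped or seg.reference_name is None:
                continue
            identity = (
                identity_sidecar.get(seg.query_name, 1.0)
                if identity_sidecar is not None and not seg.has_tag("NM")
                else _identity_from_tags(seg)
            )
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    contig_id=seg.reference_name,
                    start=seg.reference_start,
                    end=seg.reference_end,
                    strand="-" if seg.is_reverse else "+",
                    identity=identity,
                    is_read1=not seg.is_read2,
                    ambiguous=bool(seg.is_secondary or seg.is_supplementary),
                )
            )
    return records


def write_sam(
    records: Iterable[AlignmentRecord],
    reference_lengths: Mapping[str, int],
    path: str,
) -> None:
    """Minimal SAM with @SQ headers; one ungapped M CIGAR per record."""
    names = list(reference_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(reference_lengths[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment()
            seg.query_name = rec.read_id
            seg.reference_id = tid[rec.contig_id]
            seg.reference_start = rec.start
            seg.cigarstring = f"{rec.aligned_length}M"
            seg.flag = (
                (16 if rec.strand == "-" else 0)
                | (1 | (64 if rec.is_read1 else 128))
            )
            seg.mapping_quality = 60
            seg.query_sequence = "N" * rec.aligned_length
            seg.set_tag("NM", round((1.0 - rec.identity) * rec.aligned_length))
            out.write(seg)


def aligned_reference_span(cigarstring: str) -> int:
    """Reference span consumed by a CIGAR (M/D/N/=/X operations)."""
    seg = pysam.AlignedSegment()
    seg.cigarstring = cigarstring
    return sum(
        length for op, length in (seg.cigartuples or []) if op in (0, 2, 3, 7, 8)
    )


# ---------------------------------------------------------------- TSV


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(
    df: pd.DataFrame, path: str, params: Mapping[str, object] | None = None
) -> None:
    """TSV with a comment header naming version and resolved parameters."""
    from plasmidkit import __version__

    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# plasmidkit {__version__}\n")
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)
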