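"""Readers and writers for the external formats the pipeline touches.

Coordinate convention: everything in memory is 1-based inclusive, the
convention of VCF and GTF.  BED input (0-based half-open) is converted at
the boundary and converted back on write, so off-by-one bugs are confined
to this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "GenomeRef",
    "AlignedRead",
    "SiteTable",
    "TranscriptModel",
    "ExpressionTable",
    "RegionSet",
    "read_fasta",
    "read_sam",
    "read_gtf_cds",
    "read_site_list",
    "write_site_table",
    "read_expression",
    "read_bed",
    "write_bed",
]

_VALID_BASES = set("ACGTN")

SITE_KEY = ["contig", "pos", "ref", "alt"]


class GenomeRef:
    """In-memory reference genome with 1-based base lookup."""

    def __init__(self, contigs: dict[str, str]):
        for name, seq in contigs.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains non-nucleotide characters: {sorted(bad)}"
                )
        self._contigs = contigs

    @property
    def contigs(self) -> dict[str, str]:
        return self._contigs

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._contigs.items()}

    def base(self, contig: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        seq = self._contigs.get(contig)
        if seq is None:
            raise KeyError(f"unknown contig {contig!r}")
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {contig}:{pos} outside contig (len {len(seq)})")
        return seq[pos - 1]

    def slice(self, contig: str, start: int, end: int) -> str:
        """Sequence for the 1-based inclusive interval [start, end]."""
        seq = self._contigs.get(contig)
        if seq is None:
            raise KeyError(f"unknown contig {contig!r}")
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(f"interval {contig}:{start}-{end} outside contig")
        return seq[start - 1 : end]

    def __contains__(self, contig: str) -> bool:
        return contig in self._contigs


_CIGAR_OPS = "MIDNSHP=X"
# ops that consume the query / the reference
_CONSUMES_QUERY = set("MIS=X")
_CONSUMES_REF = set("MDN=X")


@dataclass
class AlignedRead:
    """One mapped read: coordinates are 1-based, CIGAR ops are M/I/D/N/S."""

    name: str
    contig: str
    pos: int  # leftmost 1-based reference position
    mapq: int
    seq: str
    quals: list[int]
    cigar: list[tuple[str, int]]
    is_duplicate: bool = False

    def __post_init__(self):
        if len(self.seq) != len(self.quals):
            raise ValueError(f"read {self.name}: sequence/quality length mismatch")
        qlen = sum(n for op, n in self.cigar if op in _CONSUMES_QUERY)
        if qlen != len(self.seq):
            raise ValueError(
                f"read {self.name}: CIGAR consumes {qlen} query bases, sequence has {len(self.seq)}"
            )

    @property
    def clip_left(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def clip_right(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def aligned_query_length(self) -> int:
        """Read length after discounting soft-clipped bases."""
        return len(self.seq) - self.clip_left - self.clip_right

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query index 0-based, reference position 1-based) for M/=/X bases."""
        qpos = 0
        rpos = self.pos
        for op, n in self.cigar:
            if op in ("M", "=", "X"):
                for i in range(n):
                    yield qpos + i, rpos + i
                qpos += n
                rpos += n
            elif op in ("I", "S"):
                qpos += n
            elif op in ("D", "N"):
                rpos += n
            elif op == "H":
                continue
            else:
                raise ValueError(f"read {self.name}: unsupported CIGAR op {op!r}")

    def edge_offsets(self, qpos: int) -> tuple[int, int]:
        """Distance of a query base from each end of the aligned (clip-free) query."""
        off = qpos - self.clip_left
        return off, self.aligned_query_length - 1 - off


class SiteTable:
    """A set of single-base substitution sites keyed by (contig, pos, ref, alt)."""

    COLUMNS = SITE_KEY + ["edited", "total", "editing_level", "region_class", "filters_passed"]

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=SITE_KEY)
        df = df.copy()
        for col in SITE_KEY:
            if col not in df.columns:
                raise ValueError(f"site table missing column {col!r}")
        df["pos"] = df["pos"].astype(int)
        bad = df[(df["ref"].str.len() != 1) | (df["alt"].str.len() != 1)]
        if len(bad):
            raise ValueError("site table contains multi-base ref or alt alleles")
        if df.duplicated(subset=SITE_KEY).any():
            raise ValueError("duplicate (contig, pos, ref, alt) rows in site table")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[dict]) -> "SiteTable":
        return cls(pd.DataFrame.from_records(records, columns=None)) if records else cls()

    def keys(self) -> set[tuple]:
        return set(zip(self.df["contig"], self.df["pos"], self.df["ref"], self.df["alt"]))

    def positions(self) -> set[tuple[str, int]]:
        return set(zip(self.df["contig"], self.df["pos"]))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return (row for _, row in self.df.iterrows())

    def subset(self, mask) -> "SiteTable":
        return SiteTable(self.df[mask])

    def sort(self) -> "SiteTable":
        return SiteTable(self.df.sort_values(["contig", "pos", "alt"]))


@dataclass
class TranscriptModel:
    """Stranded CDS structure of one transcript.

    ``cds`` holds 1-based inclusive intervals sorted in genomic order
    regardless of strand; ``phase`` is the number of bases to skip at the
    translation start (the GTF frame of the first CDS in translation order).
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    cds: list[tuple[int, int]]
    phase: int = 0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.transcript_id}: strand must be + or -")
        self.cds = sorted(self.cds)
        prev_end = 0
        for start, end in self.cds:
            if start > end or start <= prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS intervals overlap or are unordered"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds)

    def covers(self, contig: str, pos: int) -> bool:
        return contig == self.contig and any(s <= pos <= e for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        """1-based inclusive intervals between consecutive CDS blocks."""
        return [
            (self.cds[i][1] + 1, self.cds[i + 1][0] - 1)
            for i in range(len(self.cds) - 1)
            if self.cds[i + 1][0] - self.cds[i][1] > 1
        ]


class ExpressionTable:
    """Gene-level expression in TPM."""

    def __init__(self, tpm: dict[str, float]):
        for gene, value in tpm.items():
            if value < 0:
                raise ValueError(f"gene {gene!r} has negative TPM {value}")
        self._tpm = dict(tpm)

    def tpm(self, gene: str, default: float = 0.0) -> float:
        return self._tpm.get(gene, default)

    def __contains__(self, gene: str) -> bool:
        return gene in self._tpm

    def items(self):
        return self._tpm.items()

    def __len__(self) -> int:
        return len(self._tpm)


class RegionSet:
    """Genomic intervals (e.g. Alu repeats), 1-based inclusive internally."""

    def __init__(self, intervals: dict[str, IntervalTree] | None = None):
        self._trees = intervals or {}

    @classmethod
    def from_intervals(cls, intervals: list[tuple[str, int, int]]) -> "RegionSet":
        trees: dict[str, IntervalTree] = {}
        for contig, start, end in intervals:
            if start < 1 or end < start:
                raise ValueError(f"bad interval {contig}:{start}-{end}")
            trees.setdefault(contig, IntervalTree())[start : end + 1] = True
        return cls(trees)

    def contains(self, contig: str, pos: int) -> bool:
        tree = self._trees.get(contig)
        return bool(tree and tree[pos])

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for contig in sorted(self._trees):
            for iv in sorted(self._trees[contig]):
                out.append((contig, iv.begin, iv.end - 1))
        return out

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_fasta(path) -> GenomeRef:
    """Load a FASTA file into memory, uppercasing sequence."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: no records")
    return GenomeRef(records)


def read_sam(path) -> Iterator[AlignedRead]:
    """Stream mapped primary non-duplicate reads from a coordinate-sorted SAM."""
    with pysam.AlignmentFile(str(path), "r") as sam:
        header = sam.header.to_dict()
        if "HD" not in header:
            raise ValueError(f"{path}: SAM header missing @HD line")
        if header["HD"].get("SO") != "coordinate":
            raise ValueError(f"{path}: SAM must be coordinate-sorted (SO:coordinate)")
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_duplicate:
                continue
            yield AlignedRead(
                name=rec.query_name,
                contig=rec.reference_name,
                pos=rec.reference_start + 1,
                mapq=rec.mapping_quality,
                seq=rec.query_sequence,
                quals=list(rec.query_qualities),
                cigar=[(_CIGAR_OPS[op], n) for op, n in rec.cigartuples],
                is_duplicate=False,
            )


def read_gtf_cds(path) -> list[TranscriptModel]:
    """Build one TranscriptModel per transcript from GTF/GFF CDS features.

    Transcripts whose total CDS length (after phase adjustment) is not a
    multiple of 3 are dropped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        if feat.strand not in ("+", "-"):
            raise ValueError(f"{path}: CDS at {feat.seqid}:{feat.start} — strand required")
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        frame = 0 if feat.frame in (None, ".") else int(feat.frame)
        entry = grouped.setdefault(
            tid, {"gene": gid, "contig": feat.seqid, "strand": feat.strand, "rows": []}
        )
        entry["rows"].append((feat.start, feat.end, frame))

    models = []
    for tid, entry in grouped.items():
        rows = sorted(entry["rows"])
        # phase comes from the first CDS in translation order
        first = rows[0] if entry["strand"] == "+" else rows[-1]
        phase = first[2]
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=entry["gene"],
            contig=entry["contig"],
            strand=entry["strand"],
            cds=[(s, e) for s, e, _ in rows],
            phase=phase,
        )
        if (model.cds_length - phase) % 3 != 0:
            warnings.warn(
                f"transcript {tid}: CDS length {model.cds_length} (phase {phase}) "
                "not a multiple of 3; dropped"
            )
            continue
        models.append(model)
    return models


def read_site_list(path) -> SiteTable:
    """Read substitution sites from a VCF or a 3/4-column TSV.

    TSV columns: contig, pos, alt (ref defaults to N) or contig, pos, ref, alt.
    A header row starting with 'contig' is accepted.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pysam.VariantFile(str(path)) as vcf:
                for rec in vcf:
                    for alt in rec.alts or ():
                        if len(rec.ref) == 1 and len(alt) == 1:
                            rows.append(
                                {"contig": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alt}
                            )
        return SiteTable(pd.DataFrame(rows, columns=SITE_KEY))

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "contig" not in df.columns:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
        ncol = df.shape[1]
        if ncol == 3:
            df.columns = ["contig", "pos", "alt"]
            df["ref"] = "N"
        elif ncol >= 4:
            df = df.iloc[:, :4]
            df.columns = SITE_KEY
        else:
            raise ValueError(f"{path}: expected >=3 tab-separated columns")
    for col in ("edited", "total"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    if "editing_level" in df.columns:
        df["editing_level"] = df["editing_level"].astype(float)
    table = SiteTable(df[[c for c in SiteTable.COLUMNS if c in df.columns]])
    if (table.df["pos"] < 1).any():
        raise ValueError(f"{path}: positions must be >= 1")
    return table


def write_site_table(table: SiteTable, path) -> None:
    cols = [c for c in SiteTable.COLUMNS if c in table.df.columns]
    table.sort().df[cols].to_csv(path, sep="\t", index=False)


def read_expression(path) -> ExpressionTable:
    """Read a two-column gene→TPM TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.iloc[0, 0].lower() in ("gene", "gene_id"):
        df = df.iloc[1:]
    return ExpressionTable({g: float(v) for g, v in zip(df.iloc[:, 0], df.iloc[:, 1])})


def read_bed(path) -> RegionSet:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            contig, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            start, end = start0 + 1, end0
            if start < 1:
                raise ValueError(f"{path}:{lineno}: coordinate < 1 after conversion")
            intervals.append((contig, start, end))
    return RegionSet.from_intervals(intervals)


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for contig, start, end in regions.intervals():
            fh.write(f"{contig}\t{start - 1}\t{end}\n")
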