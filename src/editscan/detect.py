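"""Candidate A-to-I editing-site detection and the false-positive filter cascade.

A-to-I editing reads out as A→G mismatches on the genomic plus strand (T→C
on the minus strand), so detection reduces to quality-filtered pileup over
the reference followed by a cascade of artifact filters: known germline
variants, read-edge support, splice-proximal intronic positions outside Alu
repeats, homopolymer-adjacent positions, and a panel of normals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

from .io import AlignedRead, GenomeRef, RegionSet, SiteTable, TranscriptModel, SITE_KEY

DEFAULT_MIN_BASE_Q = 25  # strict >, variant-calling threshold
DEFAULT_MIN_MAP_Q = 20  # strict >
DEFAULT_EDGE_BP = 3
DEFAULT_HOMOPOLYMER = 5
DEFAULT_SPLICE_WINDOW = 4
DEFAULT_PANEL_MIN_SAMPLES = 2
LEVEL_MIN_BASE_Q = 20  # inclusive >=, editing-level threshold


@dataclass
class Observation:
    """One read base overlapping a pileup position."""

    read_name: str
    base: str
    base_q: int
    map_q: int
    offset_start: int  # distance from the start of the aligned (clip-free) query
    offset_end: int  # distance from its end

    @property
    def min_edge_offset(self) -> int:
        return min(self.offset_start, self.offset_end)


@dataclass
class PileupColumn:
    contig: str
    pos: int
    ref: str
    observations: list[Observation]

    def qualifying(self, min_base_q: int, min_map_q: int) -> list[Observation]:
        """Observations passing strict quality thresholds."""
        return [
            o
            for o in self.observations
            if o.base_q > min_base_q and o.map_q > min_map_q
        ]


class Pileup:
    """Per-position read observations accumulated from a read stream."""

    def __init__(self, columns: dict[tuple[str, int], PileupColumn]):
        self._columns = columns

    @classmethod
    def from_reads(cls, reads: Iterable[AlignedRead], genome: GenomeRef) -> "Pileup":
        columns: dict[tuple[str, int], PileupColumn] = {}
        for read in reads:
            if read.contig not in genome:
                raise KeyError(f"read {read.name} maps to unknown contig {read.contig!r}")
            for qpos, rpos in read.aligned_pairs():
                off_start, off_end = read.edge_offsets(qpos)
                key = (read.contig, rpos)
                col = columns.get(key)
                if col is None:
                    col = PileupColumn(read.contig, rpos, genome.base(read.contig, rpos), [])
                    columns[key] = col
                col.observations.append(
                    Observation(
                        read_name=read.name,
                        base=read.seq[qpos],
                        base_q=read.quals[qpos],
                        map_q=read.mapq,
                        offset_start=off_start,
                        offset_end=off_end,
                    )
                )
        return cls(columns)

    def column(self, contig: str, pos: int) -> PileupColumn | None:
        return self._columns.get((contig, pos))

    def __iter__(self) -> Iterator[PileupColumn]:
        return iter(
            sorted(self._columns.values(), key=lambda c: (c.contig, c.pos))
        )

    def __len__(self) -> int:
        return len(self._columns)


# editing substitutions: ref base -> edited base as seen on the plus strand
_EDIT_PAIRS = {"A": "G", "T": "C"}


def _site_row(col: PileupColumn, alt: str, edited: int, total: int) -> dict:
    return {
        "contig": col.contig,
        "pos": col.pos,
        "ref": col.ref,
        "alt": alt,
        "edited": edited,
        "total": total,
        "editing_level": edited / total,
    }


def detect_candidates(
    reads: Iterable[AlignedRead] | Pileup,
    genome: GenomeRef,
    min_base_q: int = DEFAULT_MIN_BASE_Q,
    min_map_q: int = DEFAULT_MIN_MAP_Q,
) -> SiteTable:
    """Call candidate sites where quality-passing reads show A→G or T→C.

    Base quality and mapping quality thresholds are strict (a base with
    quality exactly ``min_base_q`` does not qualify).  Only these two
    substitution classes are materialized; anything else cannot be A-to-I
    editing on either strand.
    """
    pileup = reads if isinstance(reads, Pileup) else Pileup.from_reads(reads, genome)
    rows = []
    for col in pileup:
        alt = _EDIT_PAIRS.get(col.ref)
        if alt is None:
            continue
        obs = col.qualifying(min_base_q, min_map_q)
        edited = sum(1 for o in obs if o.base == alt)
        if edited == 0:
            continue
        rows.append(_site_row(col, alt, edited, len(obs)))
    return SiteTable(pd.DataFrame(rows, columns=SITE_KEY + ["edited", "total", "editing_level"]))


def filter_known_variants(sites: SiteTable, *known: SiteTable) -> SiteTable:
    """Drop sites at positions present in any known-variant list.

    Matching is positional (contig, pos), not allele-aware: a known germline
    variant at the position disqualifies it regardless of the allele.
    """
    known_pos = set()
    for table in known:
        known_pos |= table.positions()
    mask = [
        (c, p) not in known_pos for c, p in zip(sites.df["contig"], sites.df["pos"])
    ]
    return sites.subset(pd.Series(mask, index=sites.df.index))


def filter_read_edges(
    sites: SiteTable, pileup: Pileup, edge_bp: int = DEFAULT_EDGE_BP,
    min_base_q: int = DEFAULT_MIN_BASE_Q, min_map_q: int = DEFAULT_MIN_MAP_Q,
) -> SiteTable:
    """Discard edit support from the first/last ``edge_bp`` bases of each read.

    Read ends are error prone, so observations with offset < edge_bp from
    either end of the aligned query are removed from both the edited and the
    total count; sites left without edited support are dropped and the
    editing level is recomputed from the surviving observations.
    """
    rows = []
    for _, site in sites.df.iterrows():
        col = pileup.column(site["contig"], site["pos"])
        if col is None:
            continue
        kept = [
            o
            for o in col.qualifying(min_base_q, min_map_q)
            if o.min_edge_offset >= edge_bp
        ]
        edited = sum(1 for o in kept if o.base == site["alt"])
        if edited == 0:
            continue
        row = site.to_dict()
        row.update(edited=edited, total=len(kept), editing_level=edited / len(kept))
        rows.append(row)
    return SiteTable(pd.DataFrame(rows, columns=sites.df.columns))


def filter_splice_proximal(
    sites: SiteTable,
    models: list[TranscriptModel],
    alu: RegionSet | None = None,
    window_bp: int = DEFAULT_SPLICE_WINDOW,
) -> SiteTable:
    """Remove non-Alu intronic sites within ``window_bp`` of a splice junction.

    Reads spilling past exon boundaries create artifact mismatches just
    inside introns; sites inside Alu repeats are exempt because Alu introns
    are genuinely edited.  With no Alu annotation every site is treated as
    non-Alu (the stricter choice).
    """
    alu = alu or RegionSet()

    def near_junction(contig: str, pos: int) -> bool:
        for model in models:
            if model.contig != contig:
                continue
            lo, hi = model.span
            if not lo <= pos <= hi or model.covers(contig, pos):
                continue
            for a, b in model.introns():
                if a <= pos <= b and min(pos - a + 1, b - pos + 1) <= window_bp:
                    return True
        return False

    mask = []
    for _, site in sites.df.iterrows():
        if alu.contains(site["contig"], site["pos"]):
            mask.append(True)
        else:
            mask.append(not near_junction(site["contig"], site["pos"]))
    return sites.subset(pd.Series(mask, index=sites.df.index))


def _homopolymer_adjacent(genome: GenomeRef, contig: str, pos: int, min_run: int) -> bool:
    seq = genome.contigs[contig]
    i = pos - 1  # 0-based site index
    # run ending immediately 5' of the site
    if i >= min_run:
        left = seq[i - 1]
        run = 0
        j = i - 1
        while j >= 0 and seq[j] == left:
            run += 1
            j -= 1
        if run >= min_run:
            return True
    # run starting immediately 3' of the site
    if i + min_run < len(seq):
        right = seq[i + 1]
        run = 0
        j = i + 1
        while j < len(seq) and seq[j] == right:
            run += 1
            j += 1
        if run >= min_run:
            return True
    return False


def filter_homopolymer(
    sites: SiteTable, genome: GenomeRef, min_run: int = DEFAULT_HOMOPOLYMER
) -> SiteTable:
    """Remove sites sitting at the end of a homopolymer run of >= ``min_run``.

    Both flanks are scanned: a run of >= min_run identical reference bases
    immediately adjacent to the site on either side disqualifies it.  The
    run base need not match ref or alt — polymerase slippage mangles any
    neighbouring call.
    """
    mask = [
        not _homopolymer_adjacent(genome, c, p, min_run)
        for c, p in zip(sites.df["contig"], sites.df["pos"])
    ]
    return sites.subset(pd.Series(mask, index=sites.df.index))


def build_normal_panel(
    per_sample_sites: list[SiteTable], min_samples: int = DEFAULT_PANEL_MIN_SAMPLES
) -> SiteTable:
    """Sites recurrent in >= ``min_samples`` normal samples (the panel of normals)."""
    if not per_sample_sites:
        raise ValueError("panel requires at least one normal sample")
    counts: dict[tuple, int] = {}
    examples: dict[tuple, dict] = {}
    for table in per_sample_sites:
        for key in table.keys():
            counts[key] = counts.get(key, 0) + 1
            examples.setdefault(
                key, dict(zip(SITE_KEY, key))
            )
    rows = [examples[k] for k, n in counts.items() if n >= min_samples]
    return SiteTable(pd.DataFrame(rows, columns=SITE_KEY)).sort()


def subtract_panel(sites: SiteTable, panel: SiteTable) -> SiteTable:
    """Set difference by (contig, pos, ref, alt)."""
    panel_keys = panel.keys()
    mask = [
        (c, p, r, a) not in panel_keys
        for c, p, r, a in zip(
            sites.df["contig"], sites.df["pos"], sites.df["ref"], sites.df["alt"]
        )
    ]
    return sites.subset(pd.Series(mask, index=sites.df.index))


def somatic_re_filter(tumor: SiteTable, matched_normal: SiteTable) -> SiteTable:
    """Keep tumor sites edited in the tumor and unedited in the matched normal.

    A site absent from the normal table counts as editing level zero.
    """
    normal_level = {
        (row["contig"], row["pos"], row["alt"]): row.get("editing_level", 0.0)
        for _, row in matched_normal.df.iterrows()
    }
    mask = []
    for _, row in tumor.df.iterrows():
        e = row.get("editing_level", 0.0)
        n = normal_level.get((row["contig"], row["pos"], row["alt"]), 0.0)
        mask.append(e > 0 and n == 0)
    return tumor.subset(pd.Series(mask, index=tumor.df.index))


def cohort_recurrence_filter(
    per_sample: list[SiteTable], min_edited_reads: int = 3, min_samples: int = 3
) -> set[tuple]:
    """Sites with >= ``min_edited_reads`` edited reads in >= ``min_samples`` samples."""
    counts: dict[tuple, int] = {}
    for table in per_sample:
        for _, row in table.df.iterrows():
            if row.get("edited", 0) >= min_edited_reads:
                key = (row["contig"], row["pos"], row["ref"], row["alt"])
                counts[key] = counts.get(key, 0) + 1
    return {key for key, n in counts.items() if n >= min_samples}


def editing_level(
    column: PileupColumn, alt: str, min_base_q: int = LEVEL_MIN_BASE_Q
) -> float:
    """Fraction of quality-passing reads carrying the edited base.

    Unlike detection, the quality threshold here is inclusive (>=).
    """
    obs = [o for o in column.observations if o.base_q >= min_base_q]
    if not obs:
        raise ValueError(
            f"no qualifying coverage at {column.contig}:{column.pos} (base quality >= {min_base_q})"
        )
    return sum(1 for o in obs if o.base == alt) / len(obs)
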