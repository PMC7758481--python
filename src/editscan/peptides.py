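"""Strand-aware coding-effect annotation of editing sites and peptide generation.

An A-to-I edit is only biologically meaningful in transcript space: an A→G
genomic substitution edits a plus-strand transcript, a T→C substitution
edits a minus-strand one.  Qualifying missense edits are expanded into a
variant-centered long peptide (up to 21 residues) and all 9–11-mer windows
containing the edited residue — the length range presented by MHC class I.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import GenomeRef, SiteTable, TranscriptModel

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 10
DEFAULT_KMIN = 9
DEFAULT_KMAX = 11

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# standard genetic code, stop = '*'
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate an in-frame coding sequence; stops at the first stop codon."""
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TABLE.get(cds[i : i + 3])
        if aa is None:
            raise ValueError(f"untranslatable codon {cds[i:i + 3]!r} at offset {i}")
        if aa == "*":
            break
        protein.append(aa)
    return "".join(protein)


@dataclass(frozen=True)
class CodingEffect:
    """Consequence of one editing site on one transcript."""

    contig: str
    pos: int
    transcript_id: str
    gene_id: str
    cds_offset: int  # 0-based offset in the (phase-adjusted) coding sequence
    codon_index: int  # 0-based
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    consequence: str  # synonymous | missense | stop_gained | stop_lost


@dataclass(frozen=True)
class PeptidePair:
    """Mutant/normal peptide pair differing at exactly the edited residue."""

    mutant: str
    normal: str
    edit_index: int  # 1-based position of the edited residue in both
    gene_id: str
    transcript_id: str
    length_class: str  # long | short
    contig: str | None = None  # source editing site, if known
    pos: int | None = None

    def __post_init__(self):
        if len(self.mutant) != len(self.normal):
            raise ValueError("mutant and normal peptides must be equal length")
        diffs = [i for i, (a, b) in enumerate(zip(self.mutant, self.normal), 1) if a != b]
        if diffs != [self.edit_index]:
            raise ValueError(
                f"peptides must differ exactly at the edited residue "
                f"(index {self.edit_index}, diffs {diffs})"
            )
        n = len(self.mutant)
        if self.length_class == "long" and n > 21:
            raise ValueError("long peptide exceeds 21 residues")
        if self.length_class == "short" and n not in (9, 10, 11):
            raise ValueError("short peptide length must be 9, 10 or 11")

    def __len__(self) -> int:
        return len(self.mutant)


def strand_rule(ref: str, alt: str, strand: str) -> bool:
    """Keep only substitutions that are A→G in transcript space.

    True iff (plus strand, A→G) or (minus strand, T→C).
    """
    return (strand == "+" and ref == "A" and alt == "G") or (
        strand == "-" and ref == "T" and alt == "C"
    )


def cds_sequence(model: TranscriptModel, genome: GenomeRef) -> str:
    """Phase-adjusted coding sequence in translation orientation."""
    blocks = [genome.slice(model.contig, s, e) for s, e in model.cds]
    seq = "".join(blocks)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return seq[model.phase :]


def genomic_to_cds_offset(model: TranscriptModel, pos: int) -> int | None:
    """Map a genomic position to a 0-based offset in the phase-adjusted CDS.

    Returns None when the position is outside the CDS or falls inside the
    phase-trimmed incomplete leading codon.
    """
    blocks = model.cds if model.strand == "+" else list(reversed(model.cds))
    offset = 0
    for start, end in blocks:
        if start <= pos <= end:
            within = (pos - start) if model.strand == "+" else (end - pos)
            off = offset + within - model.phase
            return off if off >= 0 else None
        offset += end - start + 1
    return None


def annotate_site(
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    models: list[TranscriptModel],
    genome: GenomeRef,
) -> list[CodingEffect]:
    """Coding effects of one substitution on every transcript whose CDS covers it.

    Only strand-consistent edits (A→G on +, T→C on −) are annotated; the
    codon is recomputed on the reverse complement for minus-strand models.
    """
    effects = []
    for model in models:
        if not model.covers(contig, pos):
            continue
        if not strand_rule(ref, alt, model.strand):
            continue
        off = genomic_to_cds_offset(model, pos)
        if off is None:
            continue
        cds = cds_sequence(model, genome)
        codon_index = off // 3
        codon_start = codon_index * 3
        ref_codon = cds[codon_start : codon_start + 3]
        if len(ref_codon) < 3:
            continue
        if "N" in ref_codon:
            logger.warning(
                "site %s:%d transcript %s: ambiguous codon %s dropped",
                contig, pos, model.transcript_id, ref_codon,
            )
            continue
        within = off % 3
        tx_alt = alt if model.strand == "+" else alt.translate(_COMPLEMENT)
        alt_codon = ref_codon[:within] + tx_alt + ref_codon[within + 1 :]
        ref_aa = CODON_TABLE[ref_codon]
        alt_aa = CODON_TABLE[alt_codon]
        if ref_aa == alt_aa:
            consequence = "synonymous"
        elif alt_aa == "*":
            consequence = "stop_gained"
        elif ref_aa == "*":
            consequence = "stop_lost"
        else:
            consequence = "missense"
        effects.append(
            CodingEffect(
                contig=contig,
                pos=pos,
                transcript_id=model.transcript_id,
                gene_id=model.gene_id,
                cds_offset=off,
                codon_index=codon_index,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                consequence=consequence,
            )
        )
    return effects


def long_peptide(
    effect: CodingEffect, protein: str, flank: int = DEFAULT_FLANK
) -> PeptidePair:
    """Variant-centered long peptide: up to ``flank`` residues on each side.

    Interior edits yield the full 2·flank+1 window (21-mer at the default);
    near a protein terminus the window truncates at the boundary.
    """
    if effect.consequence != "missense":
        raise ValueError(f"long peptide requires a missense effect, got {effect.consequence}")
    i = effect.codon_index
    if not 0 <= i < len(protein):
        raise IndexError(f"edited residue {i} outside protein of length {len(protein)}")
    if protein[i] != effect.ref_aa:
        raise ValueError(
            f"protein residue {protein[i]!r} at codon {i} does not match "
            f"reference amino acid {effect.ref_aa!r}"
        )
    lo = max(0, i - flank)
    hi = min(len(protein), i + flank + 1)
    normal = protein[lo:hi]
    edit_index = i - lo + 1
    mutant = normal[: edit_index - 1] + effect.alt_aa + normal[edit_index:]
    return PeptidePair(
        mutant=mutant,
        normal=normal,
        edit_index=edit_index,
        gene_id=effect.gene_id,
        transcript_id=effect.transcript_id,
        length_class="long",
        contig=effect.contig,
        pos=effect.pos,
    )


def chop(
    pair: PeptidePair, kmin: int = DEFAULT_KMIN, kmax: int = DEFAULT_KMAX
) -> list[PeptidePair]:
    """All k-mer windows (kmin <= k <= kmax) containing the edited residue.

    Mutant and normal windows are taken at identical offsets; duplicates by
    (mutant sequence, length) are removed.  Windows without the edited
    residue would be wild-type self peptides and are never emitted.
    """
    n = len(pair)
    out: list[PeptidePair] = []
    seen: set[tuple[str, int]] = set()
    e = pair.edit_index  # 1-based
    for k in range(kmin, kmax + 1):
        if k > n:
            continue
        for start in range(max(1, e - k + 1), min(e, n - k + 1) + 1):
            mut = pair.mutant[start - 1 : start - 1 + k]
            if (mut, k) in seen:
                continue
            seen.add((mut, k))
            out.append(
                PeptidePair(
                    mutant=mut,
                    normal=pair.normal[start - 1 : start - 1 + k],
                    edit_index=e - start + 1,
                    gene_id=pair.gene_id,
                    transcript_id=pair.transcript_id,
                    length_class="short",
                    contig=pair.contig,
                    pos=pair.pos,
                )
            )
    return out


def peptides_for_sites(
    sites: SiteTable,
    models: list[TranscriptModel],
    genome: GenomeRef,
    flank: int = DEFAULT_FLANK,
    kmin: int = DEFAULT_KMIN,
    kmax: int = DEFAULT_KMAX,
) -> tuple[list[tuple[CodingEffect, PeptidePair]], list[PeptidePair]]:
    """Full site→peptide expansion across all supplied transcripts.

    Returns (long pairs with their effects, deduplicated short pairs).
    Synonymous effects are excluded; stop gains/losses are dropped and
    counted in the log, as no peptide contract exists for them.
    """
    longs: list[tuple[CodingEffect, PeptidePair]] = []
    shorts: list[PeptidePair] = []
    seen_short: set[tuple[str, str, int]] = set()
    dropped_stop = 0
    proteins: dict[str, str] = {}
    by_id = {m.transcript_id: m for m in models}
    for _, row in sites.df.iterrows():
        effects = annotate_site(
            row["contig"], int(row["pos"]), row["ref"], row["alt"], models, genome
        )
        for effect in effects:
            if effect.consequence == "synonymous":
                continue
            if effect.consequence in ("stop_gained", "stop_lost"):
                dropped_stop += 1
                continue
            tid = effect.transcript_id
            if tid not in proteins:
                proteins[tid] = translate(cds_sequence(by_id[tid], genome))
            if effect.codon_index >= len(proteins[tid]):
                # edit downstream of an upstream stop codon; not translated
                continue
            pair = long_peptide(effect, proteins[tid], flank=flank)
            longs.append((effect, pair))
            for short in chop(pair, kmin=kmin, kmax=kmax):
                key = (short.mutant, short.normal, len(short))
                if key not in seen_short:
                    seen_short.add(key)
                    shorts.append(short)
    if dropped_stop:
        logger.info("dropped %d stop-gain/stop-loss effects", dropped_stop)
    return longs, shorts
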