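"""Deterministic synthetic fixtures: toy genome, transcripts, reads with planted edits.

The generator builds a small genome hosting three transcripts (two plus
strand, one minus strand, one of them intron-containing), plants A→G edits
of chosen classes at known positions, and emits every file the pipeline
consumes — FASTA, coordinate-sorted SAM, GTF, Alu BED, known-variant VCF,
normal-sample site lists, expression TSV and a precomputed affinity TSV —
together with a per-plant truth table.

Plant classes cover the genuine signal (CDS missense edits at configurable
editing level and codon position, on either strand, plus a synonymous
control) and one bait per artifact filter: a known-SNP position, a site
supported only by read edges, a splice-proximal intronic site (with an
Alu-exempt twin), a homopolymer-adjacent site, and a panel-of-normals site.

Determinism: all randomness flows from the spec's seed through one
numpy Generator, and files are written in a fixed order, so identical
(spec, seed) give byte-identical outputs.

Background sequence never repeats a base twice in a row and CDS regions are
drawn from non-stop codons without internal repeats, so no accidental
homopolymer run or premature stop codon can collide with a plant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .binding import mock_predictor
from .io import GenomeRef, TranscriptModel
from .peptides import PeptidePair, chop, reverse_complement

CONTIG = "chr1"
GENOME_LENGTH = 6000

# fixed transcript layout (1-based inclusive CDS intervals)
GENE_PLUS = TranscriptModel("TP1", "GP1", CONTIG, "+", [(1001, 1300), (1501, 1800)])
GENE_MINUS = TranscriptModel("TM1", "GM1", CONTIG, "-", [(2501, 3100)])
GENE_PLUS2 = TranscriptModel("TP2", "GP2", CONTIG, "+", [(3301, 3600), (3801, 4100)])
MODELS = [GENE_PLUS, GENE_MINUS, GENE_PLUS2]

ALU_INTERVAL = (3590, 3650)  # 1-based inclusive, inside GP2's intron
HOMOPOLYMER_SITE = 2000  # intergenic; CCCCC is written at 1995-1999
INTRON_JUNCTION_SITE = 1302  # 2 bp into GP1's intron (1301-1500)
ALU_SITE = 3603  # 3 bp into GP2's intron, inside the Alu interval

# CDS codon slots on the plus gene, spaced >= 60 bp so reads from one plant
# never overlap another plant's site
PLUS_SLOTS = [10, 30, 50, 70, 110, 130, 150, 170, 190]
MINUS_SLOTS = [10, 30, 50]

# designed codons: (ref codon, edited codon position 1-3) chosen so that the
# A→G edit is missense (or synonymous for the control)
MISSENSE_CODONS = {1: "ATT", 2: "GAT", 3: "ATA"}  # I→V, D→G, I→M
SYNONYMOUS_CODON = "GCA"  # GCA→GCG, both Ala (codon position 3)

DEFAULT_EXPRESSION = {
    "GP1": 50.0, "GM1": 20.0, "GP2": 5.0,
    "GZMA": 8.0, "PRF1": 6.0, "CD8A": 4.0, "CD8B": 3.0, "GZMB": 5.0, "KLRD1": 2.0,
}
DEFAULT_ALLELES = ["HLA-A*02:01", "HLA-B*07:02"]

# codons with no internal adjacent repeat and no stop, used as CDS background
_SAFE_CODONS = [
    c for c in (
        a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT"
    )
    if c[0] != c[1] and c[1] != c[2] and c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class Plant:
    """One planted edit."""

    name: str
    kind: str  # cds | synonymous | known_snp | read_edge | panel |
    #            intron_junction | alu | homopolymer
    level: float = 1.0
    coverage: int = 50
    gene: str = "plus"  # plus | minus (CDS-slot plants only)
    codon_pos: int = 2  # 1-3, position of the edited base within the codon

    def __post_init__(self):
        if not 0.0 < self.level <= 1.0:
            raise ValueError(f"plant {self.name}: level must be in (0, 1]")
        if self.coverage < 1:
            raise ValueError(f"plant {self.name}: coverage must be >= 1")


@dataclass
class FixtureSpec:
    seed: int
    read_length: int = 50
    base_quality: int = 35
    map_quality: int = 60
    plants: list[Plant] = field(default_factory=list)
    expression: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EXPRESSION))
    alleles: list[str] = field(default_factory=lambda: list(DEFAULT_ALLELES))

    @classmethod
    def default(cls, seed: int) -> "FixtureSpec":
        """The standard study fixture: level plants plus one bait per filter."""
        plants = [
            Plant("level_0.1", "cds", level=0.1),
            Plant("level_0.3", "cds", level=0.3),
            Plant("level_0.5", "cds", level=0.5),
            Plant("level_1.0", "cds", level=1.0),
            Plant("minus_1.0", "cds", level=1.0, gene="minus"),
            Plant("synonymous", "synonymous", level=1.0, codon_pos=3),
            Plant("bait_known_snp", "known_snp", level=1.0),
            Plant("bait_read_edge", "read_edge", level=1.0),
            Plant("bait_panel", "panel", level=1.0),
            Plant("bait_intron_junction", "intron_junction", level=1.0),
            Plant("alu_intron_exempt", "alu", level=1.0),
            Plant("bait_homopolymer", "homopolymer", level=1.0),
        ]
        return cls(seed=seed, plants=plants)


@dataclass
class PlantTruth:
    """Expected fate of one plant through the pipeline."""

    name: str
    kind: str
    contig: str
    pos: int
    ref: str
    alt: str
    level: float
    coverage: int
    n_edited: int  # realized edited-read count
    gene_id: str
    transcript_id: str
    in_cds: bool
    consequence: str  # missense | synonymous | non_coding
    survives_known: bool
    survives_edge: bool
    survives_splice: bool
    survives_homopolymer: bool
    survives_panel: bool
    long_mutant: str
    long_normal: str

    @property
    def survives_all(self) -> bool:
        return (
            self.survives_known
            and self.survives_edge
            and self.survives_splice
            and self.survives_homopolymer
            and self.survives_panel
        )


@dataclass
class FixtureTruth:
    plants: list[PlantTruth]
    paths: dict[str, Path]

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.plants])

    def by_name(self, name: str) -> PlantTruth:
        return next(p for p in self.plants if p.name == name)


def _cds_offset_to_genomic(model: TranscriptModel, offset: int) -> int:
    """Inverse of the genomic→CDS mapping, for a phase-0 model."""
    blocks = model.cds if model.strand == "+" else list(reversed(model.cds))
    for start, end in blocks:
        n = end - start + 1
        if offset < n:
            return start + offset if model.strand == "+" else end - offset
        offset -= n
    raise IndexError("CDS offset outside transcript")


def _build_genome(rng: np.random.Generator) -> list[str]:
    """Background with no two adjacent identical bases; CDS from safe codons."""
    bases = "ACGT"
    seq = []
    prev = ""
    for _ in range(GENOME_LENGTH):
        choices = [b for b in bases if b != prev]
        b = choices[rng.integers(len(choices))]
        seq.append(b)
        prev = b
    for model in MODELS:
        n_codons = model.cds_length // 3
        cds = []
        prev = ""
        for _ in range(n_codons):
            options = [c for c in _SAFE_CODONS if c[0] != prev]
            codon = options[rng.integers(len(options))]
            cds.append(codon)
            prev = codon[2]
        tx = "".join(cds)
        genomic = tx if model.strand == "+" else reverse_complement(tx)
        i = 0
        for start, end in model.cds:
            n = end - start + 1
            seq[start - 1 : start - 1 + n] = list(genomic[i : i + n])
            i += n
    return seq


def _place_plants(spec: FixtureSpec) -> dict[str, dict]:
    """Assign genomic coordinates to every plant; raises on infeasible specs."""
    placements: dict[str, dict] = {}
    plus_slots = list(PLUS_SLOTS)
    minus_slots = list(MINUS_SLOTS)
    singleton_sites = {
        "intron_junction": INTRON_JUNCTION_SITE,
        "alu": ALU_SITE,
        "homopolymer": HOMOPOLYMER_SITE,
    }
    used_singletons = set()
    for plant in spec.plants:
        if plant.kind in singleton_sites:
            if plant.kind in used_singletons:
                raise ValueError(f"only one {plant.kind} plant is supported")
            used_singletons.add(plant.kind)
            placements[plant.name] = {
                "pos": singleton_sites[plant.kind], "ref": "A", "alt": "G",
                "model": None, "codon_index": None,
            }
            continue
        # CDS-slot plant (cds, synonymous, known_snp, read_edge, panel)
        model = GENE_MINUS if plant.gene == "minus" else GENE_PLUS
        slots = minus_slots if plant.gene == "minus" else plus_slots
        if not slots:
            raise ValueError(f"no free CDS slot left for plant {plant.name}")
        codon_index = slots.pop(0)
        codon = SYNONYMOUS_CODON if plant.kind == "synonymous" else MISSENSE_CODONS[plant.codon_pos]
        offset = 3 * codon_index + (plant.codon_pos - 1)
        pos = _cds_offset_to_genomic(model, offset)
        if model.strand == "+":
            ref, alt = "A", "G"
        else:
            ref, alt = "T", "C"
        placements[plant.name] = {
            "pos": pos, "ref": ref, "alt": alt,
            "model": model, "codon_index": codon_index, "codon": codon,
        }
    return placements


def _write_plant_codons(seq: list[str], spec: FixtureSpec, placements: dict) -> None:
    for plant in spec.plants:
        pl = placements[plant.name]
        model = pl["model"]
        if model is None:
            if plant.kind == "homopolymer":
                for p in range(HOMOPOLYMER_SITE - 5, HOMOPOLYMER_SITE):
                    seq[p - 1] = "C"
            seq[pl["pos"] - 1] = "A"
            continue
        codon = pl["codon"]
        for i in range(3):
            g = _cds_offset_to_genomic(model, 3 * pl["codon_index"] + i)
            seq[g - 1] = codon[i] if model.strand == "+" else reverse_complement(codon[i])


def _expected_truth(
    plant: Plant, placement: dict, genome: GenomeRef, n_edited: int, flank: int = 10
) -> PlantTruth:
    model = placement["model"]
    in_cds = model is not None
    if plant.kind == "cds":
        consequence = "missense"
    elif plant.kind == "synonymous":
        consequence = "synonymous"
    elif in_cds:
        consequence = "missense"  # baits sit in designed missense codons too
    else:
        consequence = "non_coding"
    long_mut = long_norm = ""
    if in_cds and consequence == "missense":
        # independent translation route (Biopython), used as test truth
        blocks = "".join(genome.slice(model.contig, s, e) for s, e in model.cds)
        tx = blocks if model.strand == "+" else reverse_complement(blocks)
        protein = str(Seq(tx).translate(to_stop=True))
        i = placement["codon_index"]
        codon = placement["codon"]
        edited = codon[: plant.codon_pos - 1] + "G" + codon[plant.codon_pos :]
        alt_aa = str(Seq(edited).translate())
        lo, hi = max(0, i - flank), min(len(protein), i + flank + 1)
        long_norm = protein[lo:hi]
        long_mut = long_norm[: i - lo] + alt_aa + long_norm[i - lo + 1 :]
    return PlantTruth(
        name=plant.name,
        kind=plant.kind,
        contig=CONTIG,
        pos=placement["pos"],
        ref=placement["ref"],
        alt=placement["alt"],
        level=plant.level,
        coverage=plant.coverage,
        n_edited=n_edited,
        gene_id=model.gene_id if in_cds else "",
        transcript_id=model.transcript_id if in_cds else "",
        in_cds=in_cds,
        consequence=consequence,
        survives_known=plant.kind != "known_snp",
        survives_edge=plant.kind != "read_edge",
        survives_splice=plant.kind != "intron_junction",
        survives_homopolymer=plant.kind != "homopolymer",
        survives_panel=plant.kind != "panel",
        long_mutant=long_mut,
        long_normal=long_norm,
    )


def generate(spec: FixtureSpec, outdir) -> FixtureTruth:
    """Write all fixture files under ``outdir`` and return the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    L = spec.read_length

    placements = _place_plants(spec)
    # feasibility: plants must be pairwise >= read_length apart so coverage
    # from one plant never dilutes another plant's editing level
    positions = sorted(pl["pos"] for pl in placements.values())
    for a, b in zip(positions, positions[1:]):
        if b - a < L:
            raise ValueError(f"plants at {a} and {b} are closer than one read length")

    seq = _build_genome(rng)
    _write_plant_codons(seq, spec, placements)
    genome = GenomeRef({CONTIG: "".join(seq)})

    # reads
    reads = []  # (pos, name, seq, qual)
    n_edited_by_plant: dict[str, int] = {}
    for plant in spec.plants:
        pl = placements[plant.name]
        p, alt = pl["pos"], pl["alt"]
        c = plant.coverage
        k = c if plant.level == 1.0 else int(rng.binomial(c, plant.level))
        n_edited_by_plant[plant.name] = k
        for j in range(c):
            edited = j < k
            if plant.kind == "read_edge" and edited:
                off = j % 3  # within the error-prone first 3 bases
            else:
                off = int(rng.integers(3, L - 3))
            start = p - off
            bases = list(genome.slice(CONTIG, start, start + L - 1))
            if edited:
                bases[off] = alt
            reads.append((start, f"{plant.name}.{j:03d}", "".join(bases)))
    reads.sort(key=lambda r: (r[0], r[1]))

    paths: dict[str, Path] = {}

    # FASTA
    paths["fasta"] = outdir / "ref.fa"
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{CONTIG}\n")
        s = genome.contigs[CONTIG]
        for i in range(0, len(s), 80):
            fh.write(s[i : i + 80] + "\n")

    # SAM
    paths["sam"] = outdir / "reads.sam"
    qual_str = chr(spec.base_quality + 33) * L
    with open(paths["sam"], "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{CONTIG}\tLN:{GENOME_LENGTH}\n")
        for start, name, bases in reads:
            fh.write(
                f"{name}\t0\t{CONTIG}\t{start}\t{spec.map_quality}\t{L}M\t*\t0\t0\t"
                f"{bases}\t{qual_str}\n"
            )

    # GTF
    paths["gtf"] = outdir / "genes.gtf"
    with open(paths["gtf"], "w") as fh:
        for model in MODELS:
            blocks = model.cds if model.strand == "+" else list(reversed(model.cds))
            offset = 0
            frames = {}
            for start, end in blocks:
                frames[(start, end)] = (3 - offset % 3) % 3
                offset += end - start + 1
            for start, end in model.cds:
                fh.write(
                    f"{CONTIG}\ttoy\tCDS\t{start}\t{end}\t.\t{model.strand}\t"
                    f"{frames[(start, end)]}\t"
                    f'gene_id "{model.gene_id}"; transcript_id "{model.transcript_id}";\n'
                )

    # Alu BED (0-based half-open on disk)
    paths["alu"] = outdir / "alu.bed"
    with open(paths["alu"], "w") as fh:
        fh.write(f"{CONTIG}\t{ALU_INTERVAL[0] - 1}\t{ALU_INTERVAL[1]}\n")

    # known-variant VCF: the known-SNP bait plus a decoy with no read support
    paths["known"] = outdir / "known.vcf"
    known_rows = [
        (pl["pos"], pl["ref"], pl["alt"])
        for plant in spec.plants
        if plant.kind == "known_snp"
        for pl in [placements[plant.name]]
    ]
    known_rows.append((4500, genome.base(CONTIG, 4500), "G"))
    with open(paths["known"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={CONTIG},length={GENOME_LENGTH}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, ref, alt in sorted(known_rows):
            fh.write(f"{CONTIG}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")

    # panel-of-normals site lists: panel bait in normals 1 and 2; a private
    # site only in normal 3 (below the recurrence threshold)
    normals_dir = outdir / "normals"
    normals_dir.mkdir(exist_ok=True)
    panel_rows = [
        (pl["pos"], pl["ref"], pl["alt"])
        for plant in spec.plants
        if plant.kind == "panel"
        for pl in [placements[plant.name]]
    ]
    private = (4600, genome.base(CONTIG, 4600), "G")
    for i, rows in enumerate([panel_rows, panel_rows, [private]], 1):
        path = normals_dir / f"normal{i}.tsv"
        with open(path, "w") as fh:
            fh.write("contig\tpos\tref\talt\n")
            for pos, ref, alt in sorted(rows):
                fh.write(f"{CONTIG}\t{pos}\t{ref}\t{alt}\n")
        paths[f"normal{i}"] = path
    paths["normals_dir"] = normals_dir

    # expression
    paths["expression"] = outdir / "expression.tsv"
    with open(paths["expression"], "w") as fh:
        for gene, tpm in spec.expression.items():
            fh.write(f"{gene}\t{tpm}\n")

    # truth (needs the final genome for protein windows)
    truths = [
        _expected_truth(plant, placements[plant.name], genome, n_edited_by_plant[plant.name])
        for plant in spec.plants
    ]

    # affinity TSV: mock ranks for every short peptide derivable from truth
    predictor = mock_predictor(spec.seed)
    peptides: set[str] = set()
    for t in truths:
        if not t.long_mutant:
            continue
        edit_index = next(
            i for i, (a, b) in enumerate(zip(t.long_mutant, t.long_normal), 1) if a != b
        )
        pair = PeptidePair(
            mutant=t.long_mutant, normal=t.long_normal, edit_index=edit_index,
            gene_id=t.gene_id, transcript_id=t.transcript_id, length_class="long",
        )
        for short in chop(pair):
            peptides.add(short.mutant)
            peptides.add(short.normal)
    paths["affinity"] = outdir / "affinity.tsv"
    with open(paths["affinity"], "w") as fh:
        fh.write("peptide\tallele\trank\n")
        for pep in sorted(peptides):
            for allele in spec.alleles:
                fh.write(f"{pep}\t{allele}\t{predictor(pep, allele):.6f}\n")

    # truth table
    paths["truth"] = outdir / "truth.tsv"
    truth = FixtureTruth(plants=truths, paths=paths)
    truth.as_dataframe().to_csv(paths["truth"], sep="\t", index=False)
    return truth


def end_to_end_check(truth: FixtureTruth, final_sites, candidate_records) -> dict:
    """Compare pipeline outputs with the planted truth.

    ``final_sites`` is the post-filter SiteTable; ``candidate_records`` the
    kept BindingRecords.  Returns confusion counts for sites and peptides.
    """
    expected_sites = {
        (t.contig, t.pos) for t in truth.plants if t.survives_all
    }
    observed_sites = final_sites.positions()
    planted_positions = {(t.contig, t.pos) for t in truth.plants}
    candidate_mutants = {rec.pair.mutant for rec in candidate_records}
    expected_peptides = {
        t.name: t.long_mutant
        for t in truth.plants
        if t.survives_all and t.consequence == "missense" and t.long_mutant
    }
    recovered_peptides = {
        name: any(pep in long for pep in candidate_mutants)
        for name, long in expected_peptides.items()
    }
    return {
        "sites": {
            "expected": len(expected_sites),
            "recovered": len(expected_sites & observed_sites),
            "missed": sorted(expected_sites - observed_sites),
            "unexpected": sorted(observed_sites - expected_sites),
            "unplanted": sorted(observed_sites - planted_positions),
        },
        "peptides": {
            "expected": len(expected_peptides),
            "recovered": sum(recovered_peptides.values()),
            "missed": sorted(n for n, ok in recovered_peptides.items() if not ok),
        },
    }
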