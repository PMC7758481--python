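"""End-to-end orchestration: detect → filter → peptides → bind → score.

Each stage writes a plain-text intermediate and the run produces a JSON
manifest recording per-stage row counts, so filter attrition is auditable
without re-running anything.  Stage outputs are pure functions of the
inputs, the configuration and the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .binding import (
    BindingRecord,
    HlaAllele,
    candidate_filter,
    mock_predictor,
    neoantigen_burden,
    score_pairs,
    tsv_predictor,
)
from .detect import (
    Pileup,
    build_normal_panel,
    detect_candidates,
    filter_homopolymer,
    filter_known_variants,
    filter_read_edges,
    filter_splice_proximal,
    subtract_panel,
)
from .io import (
    RegionSet,
    SiteTable,
    read_bed,
    read_expression,
    read_fasta,
    read_gtf_cds,
    read_sam,
    read_site_list,
    write_site_table,
)
from .peptides import peptides_for_sites
from .scoring import DEFAULT_MARKERS, NeoantigenCandidate, score_sample

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run.

    Defaults are the reference operating point: strict base quality >25 and
    mapping quality >20 at detection, 3 bp read-edge trimming, homopolymer
    runs >=5, a 4 bp splice-junction window, panel recurrence >=2 normals,
    10-residue peptide flanks chopped to 9-11-mers, and the %rank<2 / TPM>1
    candidate filter.
    """

    sam: str
    ref: str
    gtf: str
    expression: str
    out: str
    sample_id: str = "sample"
    known: list[str] = field(default_factory=list)
    alu: str | None = None
    normals: list[str] = field(default_factory=list)
    alleles: list[str] = field(default_factory=lambda: ["HLA-A*02:01"])
    predictor: str = "mock"  # mock | tsv
    affinity_tsv: str | None = None
    seed: int = 0
    min_base_q: int = 25
    min_map_q: int = 20
    edge_bp: int = 3
    homopolymer: int = 5
    splice_window: int = 4
    panel_min_samples: int = 2
    flank: int = 10
    kmin: int = 9
    kmax: int = 11
    rank_cut: float = 2.0
    tpm_cut: float = 1.0
    markers: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARKERS.items()})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_counts: dict
    outputs: dict

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _predictor_for(config: RunConfig):
    if config.predictor == "mock":
        return mock_predictor(config.seed)
    if config.predictor == "tsv":
        if not config.affinity_tsv:
            raise ValueError("predictor 'tsv' requires affinity_tsv")
        return tsv_predictor(config.affinity_tsv)
    raise ValueError(f"unknown predictor {config.predictor!r}")


def run_all(config: RunConfig) -> RunManifest:
    """Execute the full pipeline; every intermediate is written under config.out."""
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    genome = read_fasta(config.ref)
    models = read_gtf_cds(config.gtf)
    expr = read_expression(config.expression)
    alu = read_bed(config.alu) if config.alu else RegionSet()
    pileup = Pileup.from_reads(read_sam(config.sam), genome)

    sites = detect_candidates(pileup, genome, config.min_base_q, config.min_map_q)
    counts["detected"] = len(sites)
    write_site_table(sites, outdir / "sites_raw.tsv")

    known_tables = [read_site_list(p) for p in config.known]
    sites = filter_known_variants(sites, *known_tables)
    counts["after_known_variants"] = len(sites)

    sites = filter_read_edges(
        sites, pileup, config.edge_bp, config.min_base_q, config.min_map_q
    )
    counts["after_read_edges"] = len(sites)

    sites = filter_splice_proximal(sites, models, alu, config.splice_window)
    counts["after_splice_proximal"] = len(sites)

    sites = filter_homopolymer(sites, genome, config.homopolymer)
    counts["after_homopolymer"] = len(sites)

    if config.normals:
        panel = build_normal_panel(
            [read_site_list(p) for p in config.normals], config.panel_min_samples
        )
        sites = subtract_panel(sites, panel)
    counts["after_panel"] = len(sites)
    write_site_table(sites, outdir / "sites_filtered.tsv")

    longs, shorts = peptides_for_sites(
        sites, models, genome, flank=config.flank, kmin=config.kmin, kmax=config.kmax
    )
    counts["long_peptides"] = len(longs)
    counts["short_peptides"] = len(shorts)
    _write_pairs(longs, shorts, outdir)

    alleles = [HlaAllele(a) for a in config.alleles]
    records = score_pairs(shorts, alleles, _predictor_for(config))
    counts["binding_records"] = len(records)

    kept = candidate_filter(records, expr, config.rank_cut, config.tpm_cut)
    counts["candidates"] = len(kept)
    counts["neoantigen_burden"] = neoantigen_burden(kept)

    level_by_site = {
        (row["contig"], row["pos"]): row["editing_level"] for _, row in sites.df.iterrows()
    }
    candidates = [
        NeoantigenCandidate(
            record=rec,
            F=expr.tpm(rec.pair.gene_id),
            E=level_by_site[(rec.pair.contig, rec.pair.pos)],
        )
        for rec in kept
    ]
    _write_candidates(candidates, outdir / "candidates.tsv")

    score = score_sample(config.sample_id, candidates, expr, config.markers)
    pd.DataFrame(
        [
            {
                "sample": score.sample_id,
                "renis": score.renis,
                "cd8": score.cd8,
                "ctl": score.ctl,
                "rescore": score.rescore,
                "cyt": score.cyt,
                "neoantigen_burden": counts["neoantigen_burden"],
            }
        ]
    ).to_csv(outdir / "sample_scores.tsv", sep="\t", index=False)

    manifest = RunManifest(
        config={k: v for k, v in asdict(config).items()},
        version=__version__,
        stage_counts=counts,
        outputs={
            name: str(outdir / name)
            for name in (
                "sites_raw.tsv",
                "sites_filtered.tsv",
                "pairs_long.tsv",
                "pairs_short.tsv",
                "candidates.tsv",
                "sample_scores.tsv",
            )
        },
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def _write_pairs(longs, shorts, outdir: Path) -> None:
    long_rows = [
        {
            "gene": pair.gene_id,
            "transcript": pair.transcript_id,
            "contig": pair.contig,
            "pos": pair.pos,
            "mutant_peptide": pair.mutant,
            "normal_peptide": pair.normal,
            "edit_residue_index": pair.edit_index,
            "length": len(pair),
            "consequence": effect.consequence,
        }
        for effect, pair in longs
    ]
    cols = [
        "gene", "transcript", "contig", "pos", "mutant_peptide",
        "normal_peptide", "edit_residue_index", "length",
    ]
    pd.DataFrame(long_rows, columns=cols + ["consequence"]).to_csv(
        outdir / "pairs_long.tsv", sep="\t", index=False
    )
    short_rows = [
        {
            "gene": p.gene_id,
            "transcript": p.transcript_id,
            "contig": p.contig,
            "pos": p.pos,
            "mutant_peptide": p.mutant,
            "normal_peptide": p.normal,
            "edit_residue_index": p.edit_index,
            "length": len(p),
        }
        for p in shorts
    ]
    pd.DataFrame(short_rows, columns=cols).to_csv(
        outdir / "pairs_short.tsv", sep="\t", index=False
    )


def _write_candidates(candidates: list[NeoantigenCandidate], path) -> None:
    rows = [
        {
            "gene": c.record.pair.gene_id,
            "transcript": c.record.pair.transcript_id,
            "contig": c.record.pair.contig,
            "pos": c.record.pair.pos,
            "mutant_peptide": c.record.pair.mutant,
            "normal_peptide": c.record.pair.normal,
            "allele": str(c.record.allele),
            "rank_mutant": c.record.rank_mutant,
            "rank_normal": c.record.rank_normal,
            "F": c.F,
            "E": c.E,
            "S": c.S,
            "H": c.H,
            "p": c.p,
        }
        for c in candidates
    ]
    cols = [
        "gene", "transcript", "contig", "pos", "mutant_peptide", "normal_peptide",
        "allele", "rank_mutant", "rank_normal", "F", "E", "S", "H", "p",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
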