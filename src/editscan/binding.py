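"""Peptide–HLA binding %rank acquisition and the expression/affinity filter.

Binding strength is expressed as NetMHCpan-style %rank: a peptide's
percentile among random natural peptides for an allele, lower = stronger
(2.0 means top 2%).  Predictors are pluggable callables so the external
NetMHCpan binary, a precomputed table, or a deterministic mock can all sit
behind the same contract.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .io import ExpressionTable
from .peptides import PeptidePair

logger = logging.getLogger(__name__)

DEFAULT_RANK_CUT = 2.0  # keep %rank strictly below
DEFAULT_TPM_CUT = 1.0  # keep TPM strictly above

# 4-digit class I nomenclature, e.g. HLA-A*02:01
_HLA_RE = re.compile(r"^HLA-[A-C]\*\d{2}:\d{2,3}$")

Predictor = Callable[[str, str], float]


@dataclass(frozen=True)
class HlaAllele:
    name: str

    def __post_init__(self):
        if not _HLA_RE.match(self.name):
            raise ValueError(f"allele {self.name!r} does not match HLA class I nomenclature")

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class BindingRecord:
    """%rank of a mutant/normal peptide pair on one allele."""

    pair: PeptidePair
    allele: HlaAllele
    rank_mutant: float  # Rm, percent scale
    rank_normal: float  # Rn

    def __post_init__(self):
        if self.rank_mutant <= 0 or self.rank_normal <= 0:
            raise ValueError("%rank values must be positive")


def mock_predictor(seed: int = 0) -> Predictor:
    """Deterministic stand-in predictor mapping (peptide, allele) to (0, 100].

    Uses SHA-256 of the inputs so the value is stable across platforms and
    sessions for a fixed seed, with no relation to real binding.
    """

    def predict(peptide: str, allele: str) -> float:
        digest = hashlib.sha256(f"{seed}:{peptide}:{allele}".encode()).digest()
        v = int.from_bytes(digest[:8], "big") / 2**64  # [0, 1)
        return 100.0 * (1.0 - v)  # (0, 100]

    return predict


def tsv_predictor(path) -> Predictor:
    """Predictor backed by a precomputed peptide/allele/rank table."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "allele": str, "rank": float})
    table = {(p, a): r for p, a, r in zip(df["peptide"], df["allele"], df["rank"])}

    def predict(peptide: str, allele: str) -> float:
        try:
            return table[(peptide, allele)]
        except KeyError:
            raise KeyError(f"no precomputed rank for ({peptide}, {allele})") from None

    return predict


def netmhcpan_predictor(binary: str = "netMHCpan") -> Predictor:
    """Adapter around an external NetMHCpan binary (optional, never required)."""
    import subprocess
    import tempfile

    def predict(peptide: str, allele: str) -> float:
        with tempfile.NamedTemporaryFile("w", suffix=".pep", delete=False) as fh:
            fh.write(peptide + "\n")
            name = fh.name
        out = subprocess.run(
            [binary, "-p", name, "-a", allele.replace("*", "")],
            capture_output=True, text=True, check=True,
        ).stdout
        for line in out.splitlines():
            fields = line.split()
            if len(fields) > 12 and fields[2] == peptide:
                return float(fields[12])
        raise RuntimeError(f"could not parse NetMHCpan output for {peptide}/{allele}")

    return predict


def score_pairs(
    pairs: list[PeptidePair],
    alleles: list[HlaAllele],
    predictor: Predictor,
) -> list[BindingRecord]:
    """One BindingRecord per (pair, allele); predictor failures are logged and skipped."""
    records = []
    for pair in pairs:
        for allele in alleles:
            try:
                rm = predictor(pair.mutant, allele.name)
                rn = predictor(pair.normal, allele.name)
            except Exception as exc:  # noqa: BLE001 - run must continue
                logger.warning("predictor failed for %s/%s: %s", pair.mutant, allele, exc)
                continue
            records.append(BindingRecord(pair=pair, allele=allele, rank_mutant=rm, rank_normal=rn))
    return records


def candidate_filter(
    records: list[BindingRecord],
    expr: ExpressionTable,
    rank_cut: float = DEFAULT_RANK_CUT,
    tpm_cut: float = DEFAULT_TPM_CUT,
) -> list[BindingRecord]:
    """Keep binders from expressed genes: mutant %rank < rank_cut AND TPM > tpm_cut.

    A gene absent from the expression table counts as TPM 0 and is dropped.
    Only the mutant rank is filtered on; the normal rank feeds the scoring
    equations unfiltered.
    """
    kept = []
    for rec in records:
        gene = rec.pair.gene_id
        if gene not in expr:
            logger.warning("gene %s missing from expression table; treated as TPM 0", gene)
        tpm = expr.tpm(gene)
        if rec.rank_mutant < rank_cut and tpm > tpm_cut:
            kept.append(rec)
    return kept


def neoantigen_burden(records: list[BindingRecord]) -> int:
    """Distinct mutant short-peptide sequences among kept records."""
    return len({rec.pair.mutant for rec in records})
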