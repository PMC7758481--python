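"""Immunogenicity scoring of RNA-editing neoantigens.

Per-candidate immunogenicity

    p = [tanh(F) * E] * [L(Rm) * (1 - L(Rn)/2) * S] * [H]

with the logistic L(x) = 1 / (1 + exp(5*(x - 2))).  The first bracket is
neoantigen abundance: tanh saturates gene expression F (TPM) toward 1 while
the editing level E enters untransformed.  The second bracket captures
binding of the mutant peptide (L(Rm), high when Rm is a strong rank) net of
tolerance against the normal peptide (the 1 - L(Rn)/2 discount), times the
mutant/normal sequence dissimilarity S.  The third, H, is the probability
that the peptide–MHC complex is recognised by a T cell, modelled from the
hydrophobicity of TCR-contact residues.

Per sample, RENIS = sum of p over candidates, and

    REscore = (abundance(CD8) + abundance(CTL)) * RENIS

weights immunogenicity by infiltrating effector-cell abundance.  CYT, the
cytolytic activity, is the geometric mean of GZMA and PRF1 expression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .binding import BindingRecord
from .io import ExpressionTable

logger = logging.getLogger(__name__)

DEFAULT_SLOPE = 5.0
DEFAULT_MIDPOINT = 2.0

# default marker panels; MCP-counter-style signatures reduced to core markers
DEFAULT_MARKERS = {
    "CD8": ["CD8A", "CD8B"],
    "CTL": ["GZMA", "GZMB", "PRF1", "KLRD1"],
}

# Kyte–Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def logistic_L(x: float, slope: float = DEFAULT_SLOPE, midpoint: float = DEFAULT_MIDPOINT) -> float:
    """L(x) = 1 / (1 + exp(slope * (x - midpoint))); strictly decreasing, L(midpoint) = 0.5."""
    z = slope * (x - midpoint)
    # split to avoid overflow for large |z|
    if z <= 0:
        return 1.0 / (1.0 + math.exp(z))
    ez = math.exp(-z)
    return ez / (1.0 + ez)


def immunogenicity_p(
    F: float, E: float, Rm: float, Rn: float, S: float, H: float,
    slope: float = DEFAULT_SLOPE, midpoint: float = DEFAULT_MIDPOINT,
) -> float:
    """Per-candidate immunogenicity p = [tanh(F)·E]·[L(Rm)·(1−L(Rn)/2)·S]·[H].

    Inputs out of their domains raise; nothing is clamped silently.
    """
    if F < 0:
        raise ValueError(f"expression F must be >= 0, got {F}")
    for name, v in (("E", E), ("S", S), ("H", H)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    abundance = math.tanh(F) * E
    binding = logistic_L(Rm, slope, midpoint) * (1.0 - logistic_L(Rn, slope, midpoint) / 2.0) * S
    return abundance * binding * H


def dissimilarity_S(mutant: str, normal: str) -> float:
    """1 − fraction of identical aligned positions; peptides must be equal length."""
    if len(mutant) != len(normal):
        raise ValueError("peptides must be equal length")
    if not mutant:
        raise ValueError("empty peptides")
    same = sum(1 for a, b in zip(mutant, normal) if a == b)
    return 1.0 - same / len(mutant)


def contact_residues(peptide: str) -> str:
    """TCR-contact span: residues 4..L−1 (1-based) of the peptide.

    For a 9-mer this is positions 4–8, the classical TCR-facing bulge; the
    same interior span (skip 3 N-terminal and 1 C-terminal anchor-proximal
    residues) is used for other lengths.  Peptides too short for the span
    fall back to the whole sequence.
    """
    if len(peptide) <= 4:
        return peptide
    return peptide[3:-1]


def recognition_H(peptide: str, model=None) -> float:
    """T-cell recognition probability in [0, 1].

    The default model is a logistic function of the mean Kyte–Doolittle
    hydropathy of the TCR-contact residues: H = 1/(1+exp(−mean_kd)).  It is
    monotone non-decreasing in contact-residue hydrophobicity.  Any callable
    peptide → [0,1] may be substituted.
    """
    if model is not None:
        return model(peptide)
    contacts = contact_residues(peptide)
    try:
        mean_kd = sum(KYTE_DOOLITTLE[a] for a in contacts) / len(contacts)
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc} in peptide {peptide!r}") from None
    return 1.0 / (1.0 + math.exp(-mean_kd))


@dataclass
class NeoantigenCandidate:
    """A binding record joined with its expression/editing context and score."""

    record: BindingRecord
    F: float  # gene TPM
    E: float  # editing level
    S: float = field(init=False)
    H: float = field(init=False)
    p: float = field(init=False)

    def __post_init__(self):
        self.S = dissimilarity_S(self.record.pair.mutant, self.record.pair.normal)
        self.H = recognition_H(self.record.pair.mutant)
        self.p = immunogenicity_p(
            self.F, self.E, self.record.rank_mutant, self.record.rank_normal, self.S, self.H
        )


def renis(candidates: list) -> float:
    """RENIS: the sum of per-candidate immunogenicities."""
    return float(sum(c.p if isinstance(c, NeoantigenCandidate) else c for c in candidates))


def marker_abundance(expr: ExpressionTable, markers: list[str]) -> float:
    """Immune-cell abundance as the mean of log2(TPM+1) over marker genes.

    Missing markers contribute 0 with a warning.
    """
    if not markers:
        raise ValueError("empty marker set")
    total = 0.0
    for gene in markers:
        if gene not in expr:
            logger.warning("marker gene %s missing from expression table", gene)
        total += math.log2(expr.tpm(gene) + 1.0)
    return total / len(markers)


def rescore(renis_value: float, cd8: float, ctl: float) -> float:
    """REscore = (abundance(CD8) + abundance(CTL)) × RENIS."""
    return (cd8 + ctl) * renis_value


def cyt(expr: ExpressionTable) -> float:
    """Cytolytic activity: geometric mean of GZMA and PRF1 TPM (zero propagates)."""
    return math.sqrt(expr.tpm("GZMA") * expr.tpm("PRF1"))


@dataclass
class SampleScore:
    """Per-sample summary of the scoring stack."""

    sample_id: str
    renis: float
    cd8: float
    ctl: float
    rescore: float
    cyt: float


def score_sample(
    sample_id: str,
    candidates: list[NeoantigenCandidate],
    expr: ExpressionTable,
    markers: dict[str, list[str]] | None = None,
) -> SampleScore:
    markers = markers or DEFAULT_MARKERS
    r = renis(candidates)
    cd8 = marker_abundance(expr, markers["CD8"])
    ctl = marker_abundance(expr, markers["CTL"])
    return SampleScore(
        sample_id=sample_id,
        renis=r,
        cd8=cd8,
        ctl=ctl,
        rescore=rescore(r, cd8, ctl),
        cyt=cyt(expr),
    )
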