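import pandas as pd
import pytest

from editscan import (
    GenomeRef,
    Pileup,
    SiteTable,
    TranscriptModel,
    build_normal_panel,
    cohort_recurrence_filter,
    detect_candidates,
    editing_level,
    filter_homopolymer,
    filter_known_variants,
    filter_read_edges,
    filter_splice_proximal,
    somatic_re_filter,
    subtract_panel,
)
from editscan.detect import Observation, PileupColumn
from editscan.io import RegionSet

from conftest import make_read

GENOME = GenomeRef({"chr1": "GCGCGCGCGAGCGCGCGCGC" + "GCTA" * 20})  # A at pos 10


def _reads_over_pos10(n_alt, n_ref, baseq=30, mapq=60):
    """Reads of length 21 starting at pos 1; pos 10 is query offset 9 (interior)."""
    ref_seq = GENOME.contigs["chr1"][:21]
    alt_seq = ref_seq[:9] + "G" + ref_seq[10:]
    reads = [
        make_read(f"alt{i}", 1, alt_seq, baseq=baseq, mapq=mapq) for i in range(n_alt)
    ] + [make_read(f"ref{i}", 1, ref_seq, baseq=baseq, mapq=mapq) for i in range(n_ref)]
    return reads


def sites(*rows):
    return SiteTable(pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"]))


class TestDetectCandidates:
    def test_unanimous_pileup(self):
        table = detect_candidates(_reads_over_pos10(5, 0), GENOME)
        assert len(table) == 1
        row = table.df.iloc[0]
        assert (row["pos"], row["ref"], row["alt"]) == (10, "A", "G")
        assert (row["edited"], row["total"], row["editing_level"]) == (5, 5, 1.0)

    def test_base_quality_threshold_is_strict(self):
        # quality exactly 25 does not qualify
        assert len(detect_candidates(_reads_over_pos10(5, 0, baseq=25), GENOME)) == 0
        assert len(detect_candidates(_reads_over_pos10(5, 0, baseq=26), GENOME)) == 1

    def test_map_quality_threshold_is_strict(self):
        assert len(detect_candidates(_reads_over_pos10(5, 0, mapq=20), GENOME)) == 0
        assert len(detect_candidates(_reads_over_pos10(5, 0, mapq=21), GENOME)) == 1

    def test_mixed_pileup_counts(self):
        table = detect_candidates(_reads_over_pos10(3, 7), GENOME)
        row = table.df.iloc[0]
        assert (row["edited"], row["total"]) == (3, 10)
        assert row["editing_level"] == pytest.approx(0.3)

    def test_only_editing_substitutions_materialized(self):
        # a C>T mismatch over a C reference never yields a row
        ref_seq = GENOME.contigs["chr1"][:21]
        seq = ref_seq[:1] + "T" + ref_seq[2:]  # pos 2 is C -> T
        table = detect_candidates([make_read("r", 1, seq)], GENOME)
        assert len(table) == 0

    def test_unknown_contig_errors(self):
        read = make_read("r", 1, "ACGT", contig="chrX")
        with pytest.raises(KeyError, match="unknown contig"):
            Pileup.from_reads([read], GENOME)


def test_pileup_matches_brute_force_scanner(fixture_dir):
    """Pileup counts agree exactly with a per-read scan of the SAM text."""
    path, _ = fixture_dir
    genome_seq = "".join(
        line.strip() for line in open(path / "ref.fa") if not line.startswith(">")
    )
    brute: dict[int, dict[str, int]] = {}
    for line in open(path / "reads.sam"):
        if line.startswith("@"):
            continue
        fields = line.split("\t")
        pos, seq = int(fields[3]), fields[9]
        assert fields[5] == f"{len(seq)}M"
        for i, base in enumerate(seq):
            brute.setdefault(pos + i, {}).setdefault(base, 0)
            brute[pos + i][base] += 1

    from editscan import read_fasta, read_sam

    genome = read_fasta(path / "ref.fa")
    pileup = Pileup.from_reads(read_sam(path / "reads.sam"), genome)
    assert len(pileup) == len(brute)
    for col in pileup:
        counts: dict[str, int] = {}
        for obs in col.observations:
            counts[obs.base] = counts.get(obs.base, 0) + 1
        assert counts == brute[col.pos], f"mismatch at {col.pos}"
        assert genome_seq[col.pos - 1] == col.ref


class TestKnownVariantFilter:
    def test_positional_match_removes_site(self):
        table = sites(("chr1", 100, "A", "G"), ("chr1", 200, "A", "G"))
        known = sites(("chr1", 100, "A", "C"))  # different alt: still positional match
        out = filter_known_variants(table, known)
        assert out.keys() == {("chr1", 200, "A", "G")}

    def test_empty_known_set_is_identity(self):
        table = sites(("chr1", 100, "A", "G"))
        assert filter_known_variants(table).keys() == table.keys()

    def test_matches_brute_force_set_subtraction(self):
        table = sites(*[("chr1", p, "A", "G") for p in range(1, 30, 3)])
        known = sites(*[("chr1", p, "A", "G") for p in range(1, 30, 6)])
        expected = table.positions() - known.positions()
        assert filter_known_variants(table, known).positions() == expected


class TestReadEdgeFilter:
    def _pileup(self, offsets_alt, offsets_ref=(), read_len=50):
        """Reads placed so the site at pos 100 is at the given query offsets."""
        ref = "T" * 200
        genome = GenomeRef({"chr1": ref[:99] + "A" + ref[100:]})
        reads = []
        for i, off in enumerate(offsets_alt):
            seq = ["T"] * read_len
            seq[off] = "G"
            reads.append(make_read(f"a{i}", 100 - off, "".join(seq)))
        for i, off in enumerate(offsets_ref):
            seq = ["T"] * read_len
            seq[off] = "A"
            reads.append(make_read(f"r{i}", 100 - off, "".join(seq)))
        return genome, Pileup.from_reads(reads, genome)

    def test_edge_only_support_removes_site(self):
        genome, pileup = self._pileup([2])
        table = detect_candidates(pileup, genome)
        assert len(table) == 1
        assert len(filter_read_edges(table, pileup)) == 0

    def test_offset_three_is_retained(self):
        genome, pileup = self._pileup([3])
        table = detect_candidates(pileup, genome)
        assert len(filter_read_edges(table, pileup)) == 1

    def test_trailing_edge_also_counts(self):
        genome, pileup = self._pileup([47])  # 2 from the 3' end of a 50-mer
        table = detect_candidates(pileup, genome)
        assert len(filter_read_edges(table, pileup)) == 0

    def test_counts_recomputed_after_edge_removal(self):
        genome, pileup = self._pileup([1, 25], offsets_ref=[30])
        table = detect_candidates(pileup, genome)
        assert table.df.iloc[0]["edited"] == 2
        out = filter_read_edges(table, pileup)
        row = out.df.iloc[0]
        assert (row["edited"], row["total"]) == (1, 2)
        assert row["editing_level"] == pytest.approx(0.5)


class TestSpliceProximalFilter:
    MODEL = TranscriptModel("t", "g", "chr1", "+", [(101, 200), (301, 400)])

    def test_intronic_near_junction_removed(self):
        table = sites(("chr1", 202, "A", "G"))  # 2 bp into the intron
        assert len(filter_splice_proximal(table, [self.MODEL])) == 0

    def test_alu_site_exempt(self):
        table = sites(("chr1", 202, "A", "G"))
        alu = RegionSet.from_intervals([("chr1", 195, 210)])
        assert len(filter_splice_proximal(table, [self.MODEL], alu)) == 1

    def test_deep_intronic_and_exonic_retained(self):
        table = sites(("chr1", 250, "A", "G"), ("chr1", 150, "A", "G"))
        assert len(filter_splice_proximal(table, [self.MODEL])) == 2

    def test_acceptor_side_window(self):
        table = sites(("chr1", 298, "A", "G"))  # 3 bp from the acceptor boundary
        assert len(filter_splice_proximal(table, [self.MODEL])) == 0
        assert len(filter_splice_proximal(table, [self.MODEL], window_bp=2)) == 1


class TestHomopolymerFilter:
    def test_site_after_five_run_removed(self):
        genome = GenomeRef({"chr1": "GCGC" + "AAAAA" + "G" + "CGCG"})  # site at pos 10
        out = filter_homopolymer(sites(("chr1", 10, "A", "G")), genome)
        assert len(out) == 0

    def test_run_of_four_retained(self):
        genome = GenomeRef({"chr1": "GCGCG" + "AAAA" + "G" + "CGCG"})
        assert len(filter_homopolymer(sites(("chr1", 10, "A", "G")), genome)) == 1

    def test_downstream_run_also_removes(self):
        genome = GenomeRef({"chr1": "GCGC" + "A" + "TTTTTTT" + "GCGC"})  # site pos 5, 7 T's after
        assert len(filter_homopolymer(sites(("chr1", 5, "A", "G")), genome)) == 0


class TestPanel:
    def test_recurrence_threshold(self):
        a = sites(("chr1", 10, "A", "G"), ("chr1", 20, "A", "G"))
        b = sites(("chr1", 10, "A", "G"))
        c = sites(("chr1", 30, "A", "G"))
        panel = build_normal_panel([a, b, c])
        assert panel.keys() == {("chr1", 10, "A", "G")}

    def test_identical_tables_idempotent(self):
        a = sites(("chr1", 10, "A", "G"))
        panel = build_normal_panel([a, a, a])
        assert panel.keys() == a.keys()

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            build_normal_panel([])

    def test_subtract_matches_set_difference(self):
        tumor = sites(*[("chr1", p, "A", "G") for p in range(1, 20)])
        panel = sites(*[("chr1", p, "A", "G") for p in range(1, 20, 4)])
        out = subtract_panel(tumor, panel)
        assert out.keys() == tumor.keys() - panel.keys()
        assert len(subtract_panel(tumor, tumor)) == 0
        empty = SiteTable()
        assert subtract_panel(tumor, empty).keys() == tumor.keys()


def _esites(*rows):
    return SiteTable(
        pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "edited", "total", "editing_level"])
    )


class TestSomaticAndCohort:
    def test_somatic_requires_zero_in_normal(self):
        tumor = _esites(
            ("chr1", 10, "A", "G", 3, 10, 0.3),
            ("chr1", 20, "A", "G", 3, 10, 0.3),
            ("chr1", 30, "A", "G", 0, 10, 0.0),
        )
        normal = _esites(("chr1", 20, "A", "G", 1, 20, 0.05))
        out = somatic_re_filter(tumor, normal)
        # site 10 absent from normal (level 0), site 20 edited in normal, site 30 unedited in tumor
        assert out.positions() == {("chr1", 10)}

    def test_cohort_recurrence_boundaries(self):
        strong = _esites(("chr1", 10, "A", "G", 3, 10, 0.3))
        weak = _esites(("chr1", 10, "A", "G", 2, 10, 0.2))
        assert cohort_recurrence_filter([strong, strong, strong]) == {("chr1", 10, "A", "G")}
        assert cohort_recurrence_filter([weak, weak, weak]) == set()
        assert cohort_recurrence_filter([strong, strong]) == set()


class TestEditingLevel:
    def _column(self, quals_alt, quals_ref):
        obs = [
            Observation(f"a{i}", "G", q, 60, 10, 10) for i, q in enumerate(quals_alt)
        ] + [Observation(f"r{i}", "A", q, 60, 10, 10) for i, q in enumerate(quals_ref)]
        return PileupColumn("chr1", 5, "A", obs)

    def test_simple_fraction(self):
        col = self._column([30] * 3, [30] * 7)
        assert editing_level(col, "G") == pytest.approx(0.3)

    def test_threshold_is_inclusive_at_20(self):
        col = self._column([20], [19])
        assert editing_level(col, "G") == 1.0  # q20 counts, q19 does not

    def test_no_qualifying_coverage_errors(self):
        col = self._column([10], [15])
        with pytest.raises(ValueError, match="no qualifying coverage"):
            editing_level(col, "G")

    def test_matches_brute_force_recount(self):
        import random

        rng = random.Random(0)
        quals_alt = [rng.randint(10, 40) for _ in range(30)]
        quals_ref = [rng.randint(10, 40) for _ in range(70)]
        col = self._column(quals_alt, quals_ref)
        n_alt = sum(1 for q in quals_alt if q >= 20)
        n_all = n_alt + sum(1 for q in quals_ref if q >= 20)
        assert editing_level(col, "G") == pytest.approx(n_alt / n_all)


def test_output_sites_satisfy_invariants(fixture_dir):
    """Every detected site has edited <= total and editing level in (0, 1]."""
    from editscan import read_fasta, read_sam

    path, _ = fixture_dir
    genome = read_fasta(path / "ref.fa")
    table = detect_candidates(read_sam(path / "reads.sam"), genome)
    df = table.df
    assert (df["edited"] <= df["total"]).all()
    assert ((df["editing_level"] > 0) & (df["editing_level"] <= 1)).all()
    assert (df["editing_level"] == df["edited"] / df["total"]).all()
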