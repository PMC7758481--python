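import pytest

from editscan import FixtureSpec, RunConfig, generate, run_all

FIXTURE_SEED = 11


def make_read(name, pos, seq, baseq=30, mapq=60, cigar=None, contig="chr1"):
    from editscan import AlignedRead

    return AlignedRead(
        name=name,
        contig=contig,
        pos=pos,
        mapq=mapq,
        seq=seq,
        quals=[baseq] * len(seq),
        cigar=cigar or [("M", len(seq))],
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    truth = generate(FixtureSpec.default(FIXTURE_SEED), out)
    return out, truth


def _config(fixture_path, outdir, **overrides):
    base = dict(
        sam=str(fixture_path / "reads.sam"),
        ref=str(fixture_path / "ref.fa"),
        gtf=str(fixture_path / "genes.gtf"),
        expression=str(fixture_path / "expression.tsv"),
        out=str(outdir),
        known=[str(fixture_path / "known.vcf")],
        alu=str(fixture_path / "alu.bed"),
        normals=[str(fixture_path / "normals" / f"normal{i}.tsv") for i in (1, 2, 3)],
        alleles=["HLA-A*02:01", "HLA-B*07:02"],
        predictor="mock",
        seed=FIXTURE_SEED,
    )
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def permissive_run(fixture_dir, tmp_path_factory):
    """Full pipeline on the default fixture with a binding filter wide open."""
    path, truth = fixture_dir
    outdir = tmp_path_factory.mktemp("run_permissive")
    manifest = run_all(_config(path, outdir, rank_cut=100.0))
    return path, truth, outdir, manifest


@pytest.fixture(scope="session")
def default_run(fixture_dir, tmp_path_factory):
    """Full pipeline on the default fixture at the reference operating point."""
    path, truth = fixture_dir
    outdir = tmp_path_factory.mktemp("run_default")
    manifest = run_all(_config(path, outdir))
    return path, truth, outdir, manifest


@pytest.fixture()
def run_config_factory(fixture_dir, tmp_path):
    path, _ = fixture_dir

    def factory(outname="out", **overrides):
        return _config(path, tmp_path / outname, **overrides)

    return factory
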