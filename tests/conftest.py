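import pytest

from cptrx.classify import ClassifyParams, PrimerSet, classify_read
from cptrx.simulate import (
    default_spec,
    make_genome,
    simulate_library,
    simulate_transcripts,
)

pytest_plugins = ()


@pytest.fixture(scope="session")
def primers():
    return PrimerSet()


@pytest.fixture(scope="session")
def params():
    return ClassifyParams()


@pytest.fixture(scope="session")
def planted():
    """The reference synthetic genome used across the suite."""
    return make_genome(default_spec(seed=7))


@pytest.fixture(scope="session")
def transcripts(planted):
    return simulate_transcripts(planted, n_reads=1500, seed=8)


@pytest.fixture(scope="session")
def library(planted, transcripts):
    return simulate_library(transcripts, reference=planted.genome, seed=9)


@pytest.fixture(scope="session")
def classified(library, primers):
    return {
        r.read_id: classify_read(r.seq, primers, read_id=r.read_id)
        for r in library.reads
    }


@pytest.fixture(scope="session")
def truth_classes(library):
    return dict(zip(library.truth.read_id, library.truth.true_class))


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory, planted, library):
    """On-disk FASTA/GFF3/FASTQ/SAM bundle for pipeline-level tests."""
    from cptrx.simulate import write_annotations_gff3, write_genome_fasta

    out = tmp_path_factory.mktemp("bundle")
    write_genome_fasta(planted, out / "genome.fasta")
    write_annotations_gff3(planted, out / "annotations.gff3")
    library.write_fastq(out / "reads.fastq")
    library.write_sam(out / "alignments.sam")
    library.write_truth(out / "truth.tsv")
    return out


@pytest.fixture(scope="session")
def pipeline_result(sim_bundle, tmp_path_factory):
    from cptrx.pipeline import PipelineConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("pipe_out")
    cfg = PipelineConfig(
        genome=str(sim_bundle / "genome.fasta"),
        annotations=str(sim_bundle / "annotations.gff3"),
        reads=str(sim_bundle / "reads.fastq"),
        alignments=str(sim_bundle / "alignments.sam"),
        outdir=str(outdir),
    )
    return run_pipeline(cfg)
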