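import pytest

from qualstrat import ErrorModel, simulate_reads, simulate_reference


@pytest.fixture(scope="session")
def small_simulation():
    """A modest mixed-error simulation shared across tests: 200 reads of ~800 bp
    with clips, indels and both strands."""
    reference = simulate_reference(30_000, gc=0.5, seed=11)
    model = ErrorModel.uniform_phred(q_min=5, q_max=30, clip_flank_mean=30.0)
    reads, truths = simulate_reads(reference, 200, (800, 150), model, seed=11)
    return reference, model, reads, truths


@pytest.fixture()
def fastq_file(tmp_path):
    """Write a tiny FASTQ and return its path."""
    from qualstrat import ReadRecord, write_fastq

    records = [
        ReadRecord("r1", "ACGT", "!!5I"),
        ReadRecord("r2", "GGGTTTA", "???????"),
        ReadRecord("r3", "A", "I"),
    ]
    path = tmp_path / "reads.fastq"
    write_fastq(records, path)
    return path, records
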