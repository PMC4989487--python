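import pytest

from editscan.multisample import SampleRun, run_single_sample
from editscan.synthdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def standard_dataset(tmp_path_factory):
    """The standard simulated study: 50-kb genome, 10 genes, 50 edits,
    ~50 het SNPs, 30x DNA / 50x RNA at ~Q35."""
    return simulate_dataset(SimConfig(), tmp_path_factory.mktemp("std"))


@pytest.fixture(scope="session")
def standard_result(standard_dataset):
    out = standard_dataset
    run = SampleRun("s1", str(out["paths"]["dna_sam"]),
                    str(out["paths"]["rna_sam"]))
    return run_single_sample(run, out["genome"], out["transcripts"])


@pytest.fixture(scope="session")
def paralog_dataset(tmp_path_factory):
    """Same study but with a 97 %-identical 500-bp copy of an edited exon."""
    cfg = SimConfig(paralog_identity=0.97)
    return simulate_dataset(cfg, tmp_path_factory.mktemp("par"))


@pytest.fixture(scope="session")
def paralog_result(paralog_dataset):
    out = paralog_dataset
    run = SampleRun("s1", str(out["paths"]["dna_sam"]),
                    str(out["paths"]["rna_sam"]))
    return run_single_sample(run, out["genome"], out["transcripts"])
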