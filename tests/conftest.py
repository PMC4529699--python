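import numpy as np
import pytest

from exosmallrna import annotation_io as aio
from exosmallrna import synthetic_data as sd


@pytest.fixture(scope="session")
def toy():
    """Small deterministic toy genome shared across tests."""
    return sd.build_toy_genome(sd.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_simulation():
    """A light 6-sample simulation (2000 reads each) with its genome."""
    config = sd.SimulationConfig(seed=11, n_reads=2000)
    toy, samples = sd.simulate_reads(config)
    return config, toy, samples


@pytest.fixture(scope="session")
def feature_index(toy):
    return aio.build_index(toy.all_records())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_record(key: str, record_id: str, chrom="chr1", start=100, end=200, strand="+"):
    """AnnotationRecord whose cascade key equals ``key`` (test helper)."""
    iv = aio.GenomicInterval(chrom, start, end, strand)
    if key.startswith("gencode_small:"):
        return aio.AnnotationRecord(
            record_id, record_id, "gencode_small", [iv],
            {"gene_type": key.split(":", 1)[1]},
        )
    meta = {}
    if key == "tRNA":
        meta = {"anticodon": "CTC", "aa": "Glu"}
    elif key == "repeat":
        meta = {"family": "SINE/Alu"}
    elif key.startswith("miRNA"):
        meta = {"mirna_name": record_id}
    return aio.AnnotationRecord(record_id, record_id, key, [iv], meta)
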