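import random

import pytest
from hypothesis import HealthCheck, settings

from alugrep import SimulationConfig, rp1_aluy_demo, simulate_reads

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

BASES = "ACGT"


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(n))


@pytest.fixture(scope="session")
def demo_event():
    return rp1_aluy_demo()


@pytest.fixture(scope="session")
def het_sample(demo_event, tmp_path_factory):
    """A simulated error-free heterozygote at depth 100 (seed 7)."""
    d = tmp_path_factory.mktemp("het")
    config = SimulationConfig(
        event=demo_event, genotype="het", depth=100, read_len=100,
        error_rate=0.0, seed=7,
    )
    fastq = d / "het.fastq"
    truth = d / "het.truth.tsv"
    simulate_reads(config, fastq, truth)
    return {"config": config, "fastq": fastq, "truth": truth}


@pytest.fixture(scope="session")
def wildtype_sample(demo_event, tmp_path_factory):
    """A simulated error-free wildtype sample at depth 100."""
    d = tmp_path_factory.mktemp("wt")
    config = SimulationConfig(
        event=demo_event, genotype="hom_ref", depth=100, read_len=100,
        error_rate=0.0, seed=5,
    )
    fastq = d / "wt.fastq"
    simulate_reads(config, fastq)
    return {"config": config, "fastq": fastq}


def write_fastq(path, reads):
    """Write (name, sequence) pairs as a 4-line-record FASTQ."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path
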