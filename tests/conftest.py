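from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from mulekit.synthetic import SimulationConfig, simulate_reference
from mulekit.vcf_io import GenomeIndex, open_fasta

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference(tmp_path_factory) -> Path:
    """Session-wide 2 x 100 kb random reference with .fai."""
    out = tmp_path_factory.mktemp("ref")
    return simulate_reference(SimulationConfig(seed=11), out)


@pytest.fixture(scope="session")
def fasta(reference):
    return open_fasta(reference)


@pytest.fixture(scope="session")
def genome_index(reference) -> GenomeIndex:
    return GenomeIndex.from_fasta(reference)


@pytest.fixture
def write_text(tmp_path):
    """Write literal file content (e.g. a hand-built VCF) into tmp_path."""

    def _write(name: str, content: str) -> Path:
        path = tmp_path / name
        path.write_text(content)
        return path

    return _write


def make_vcf_text(lines: list[str], samples: list[str] | None = None) -> str:
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        cols += "\tFORMAT\t" + "\t".join(samples)
    return "\n".join(["##fileformat=VCFv4.2", cols, *lines]) + "\n"
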