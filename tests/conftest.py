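import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=list(HealthCheck),
)
settings.load_profile("suite")

from nichehybrid import SyntheticCommunitySpec, simulate_community


def write_fasta(path, otu_ids, sequences, wrap=None):
    """Write a FASTA file, optionally line-wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for otu_id, seq in zip(otu_ids, sequences):
            fh.write(f">{otu_id}\n")
            if wrap:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")
            else:
                fh.write(seq + "\n")


def write_abundance(path, otu_ids, counts):
    with open(path, "w") as fh:
        fh.write("otu_id\tcount\n")
        for otu_id, count in zip(otu_ids, counts):
            fh.write(f"{otu_id}\t{count}\n")


def write_community_files(tmp_path, table, prefix="sample"):
    fasta = tmp_path / f"{prefix}.fasta"
    abundance = tmp_path / f"{prefix}_abundance.tsv"
    write_fasta(fasta, table.otu_ids, table.sequences)
    write_abundance(abundance, table.otu_ids, table.abundances)
    return fasta, abundance


@pytest.fixture(scope="session")
def hybrid_community():
    """Seeded half-niche community (alpha=0.5) with ground-truth labels."""
    spec = SyntheticCommunitySpec(alpha=0.5, seed=42)
    table, labels = simulate_community(spec)
    return spec, table, labels


@pytest.fixture(scope="session")
def niche_community():
    """Seeded pure-niche community (alpha=1)."""
    spec = SyntheticCommunitySpec(alpha=1.0, seed=43)
    table, labels = simulate_community(spec)
    return spec, table, labels


@pytest.fixture(scope="session")
def neutral_community():
    """Seeded pure-neutral community (alpha=0)."""
    spec = SyntheticCommunitySpec(alpha=0.0, seed=44)
    table, labels = simulate_community(spec)
    return spec, table, labels
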