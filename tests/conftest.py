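import numpy as np
import pytest

import hoxcomp as h


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_truth():
    """A 5 kb three-species simulation with planted CNEs and exons,
    reused across read-only tests."""
    config = h.SimulationConfig(
        tree="((caecilian:0.85,frog:0.85):0.1,coelacanth:0.9);",
        seq_length=5000,
        cne_spec=[
            h.CNESpec(500, 150, 0.05),
            h.CNESpec(2000, 120, 0.05, frozenset({"caecilian", "frog"})),
            h.CNESpec(3500, 200, 0.05),
        ],
        exon_spec=[h.ExonSpec(1000, 300), h.ExonSpec(2800, 300)],
        seed=42,
    )
    return config, h.simulate_clusters(config)


def write_fasta_file(tmp_path, name, records):
    path = tmp_path / name
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n{seq}\n")
    return path
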