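import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sumstats_file(tmp_path):
    """Three-SNP tab-delimited sumstats file with default column names."""
    path = tmp_path / "sumstats.tsv"
    pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3"],
            "CHR": ["1", "1", "2"],
            "BP": [100, 200, 300],
            "A1": ["A", "G", "C"],
            "A2": ["G", "T", "A"],
            "Z": [1.5, -0.7, 2.2],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def synthetic_study(tmp_path_factory):
    """One small written synthetic study shared across tests (seed 7)."""
    from twaskit.simulate import SimConfig, generate_study

    out = tmp_path_factory.mktemp("study")
    config = SimConfig(
        n_loci=20, snps_per_locus=10, genes_per_panel=10,
        causal_fraction=0.2, n_go_terms=20, seed=7,
    )
    study = generate_study(config, out_dir=out)
    return study, out
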