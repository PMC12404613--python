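import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def product_records():
    """50k-record synthetic table generated under the Product law with
    additive Gaussian noise (sigma = 0.05)."""
    from neutrality.synth import SynthConfig, generate_fitness_table

    cfg = SynthConfig(n_genes=2000, n_pairs=50_000, law="product",
                      noise_sigma=0.05, seed=1234)
    return generate_fitness_table(cfg)


@pytest.fixture
def sga_writer(tmp_path):
    """Write rows in the SGA tab-separated dialect; returns the path."""

    def write(rows, name="table.tsv", header=None):
        header = header or [
            "Query Strain ID",
            "Array Strain ID",
            "Query single mutant fitness (SMF)",
            "Array SMF",
            "Double mutant fitness",
        ]
        path = tmp_path / name
        lines = ["\t".join(header)]
        lines += ["\t".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return write


@pytest.fixture(scope="session")
def weisse_wt():
    """Wild-type parameters and steady state of the mechanistic model,
    shared across tests (read-only)."""
    from neutrality import weisse

    params = weisse.WeisseParams.default()
    return params, weisse.steady_state_growth(params)
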