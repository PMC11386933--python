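import numpy as np
import pytest

from cernet.io_formats import CountMatrix
from cernet.synthetic import (
    SimulationConfig,
    simulate_counts,
    simulate_gene_sets,
    simulate_sequences,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()  # the reference study design, seed 1


@pytest.fixture(scope="session")
def default_sim(default_config):
    """One full draw of the default simulation, shared across the suite."""
    circ, mir, mrna, truth = simulate_counts(default_config)
    seqs = simulate_sequences(default_config, truth)
    sets = simulate_gene_sets(default_config, truth)
    return {
        "config": default_config,
        "circ": circ,
        "mir": mir,
        "mrna": mrna,
        "truth": truth,
        "seqs": seqs,
        "sets": sets,
    }


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A full end-to-end pipeline run at the default configuration."""
    from cernet.pipeline import PipelineConfig, run_all

    outdir = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(outdir=str(outdir), rng_seed=1)
    results = run_all(config)
    return {"config": config, "outdir": outdir, "results": results}


def toy_matrix(counts, rna_class="mRNA", feature_ids=None) -> CountMatrix:
    """Small 2-group CountMatrix helper (first half control, second treated)."""
    counts = np.asarray(counts)
    n_feat, n_samp = counts.shape
    assert n_samp % 2 == 0 and n_samp >= 4
    half = n_samp // 2
    sample_ids = [f"c{i}" for i in range(half)] + [f"t{i}" for i in range(half)]
    group_of = {s: ("control" if s.startswith("c") else "treated") for s in sample_ids}
    return CountMatrix(
        feature_ids=feature_ids or [f"g{i}" for i in range(n_feat)],
        rna_class=rna_class,
        sample_ids=sample_ids,
        group_of=group_of,
        counts=counts,
    )
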