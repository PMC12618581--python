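import numpy as np
import pandas as pd
import pytest

from auxospore import (
    AnalysisConfig,
    ExpressionMatrix,
    SimConfig,
    compute_cpm,
    filter_expressed,
    run_species_de,
    simulate_multispecies,
    stagewise_adjust,
)


def make_matrix(counts, meta_rows, lengths=None):
    """Build an ExpressionMatrix from plain dicts/arrays."""
    counts = pd.DataFrame(counts)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    gl = pd.Series(lengths, index=counts.index) if lengths is not None else None
    return ExpressionMatrix(counts=counts, sample_meta=meta, gene_lengths=gl)


def meta_row(sample_id, species="sp1", condition_class="vegetative_control",
             stage="none", condition_label="veg", replicate=1):
    return {
        "sample_id": sample_id, "species": species,
        "condition_class": condition_class, "stage": stage,
        "condition_label": condition_label, "replicate": replicate,
    }


@pytest.fixture(scope="session")
def small_experiment():
    """A compact multi-species experiment with planted markers."""
    return simulate_multispecies(SimConfig(n_families=120), seed=11)


@pytest.fixture(scope="session")
def small_pipeline(small_experiment):
    """DE + stage-wise results and expressed-gene sets for every species."""
    cfg = AnalysisConfig()
    stagewise, expressed = {}, {}
    for sp, m in small_experiment.matrices.items():
        rec = run_species_de(m, sp, cfg)
        stagewise[sp] = stagewise_adjust(rec, cfg.fdr_alpha)
        expressed[sp] = set(
            filter_expressed(compute_cpm(m), cfg.min_cpm, cfg.min_samples)
        )
    return {"config": cfg, "stagewise": stagewise, "expressed": expressed}
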