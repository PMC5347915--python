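import numpy as np
import pandas as pd
import pytest

from polyprof import expression, simulate


def toy_matrix(values_by_gene, time_points=(0, 6), n_reps=3):
    """Matrix with the same per-replicate values at every condition."""
    meta, cols = [], {}
    for tp in time_points:
        for fraction in expression.FRACTIONS:
            for rep in range(1, n_reps + 1):
                sid = f"t{tp}_{fraction}_r{rep}"
                meta.append(
                    {"sample_id": sid, "time_point": tp, "fraction": fraction, "replicate": rep}
                )
                cols[sid] = {g: vals[rep - 1] for g, vals in values_by_gene.items()}
    return expression.ExpressionMatrix(
        pd.DataFrame(cols), pd.DataFrame(meta).set_index("sample_id")
    )


def scaled_config(seed: int = 42, n_genes: int = 2000, scale: int = 10):
    """Default study design scaled down for fast unit tests."""
    cfg = simulate.SimulationConfig(seed=seed)
    cfg.expression.n_genes = n_genes
    for p in cfg.expression.planted:
        p.size //= scale
    return cfg


@pytest.fixture(scope="session")
def small_cfg():
    return scaled_config()


@pytest.fixture(scope="session")
def sim_expression(small_cfg):
    return simulate.simulate_expression(small_cfg)


@pytest.fixture(scope="session")
def sim_transcriptome(small_cfg):
    cfg = scaled_config()
    cfg.transcriptome.n_transcripts = 120
    return simulate.simulate_transcriptome(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
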