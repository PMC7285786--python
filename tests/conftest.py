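import numpy as np
import pandas as pd
import pytest

from sigcollapse import ExpressionMatrix, generate_study, mi_like_config


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples (2 case / 2 control)."""
    values = pd.DataFrame(
        [[7.0, 7.5, 6.0, 6.2], [5.0, 5.1, 5.2, 5.3], [8.0, 8.1, 7.9, 8.2]],
        index=["CD14", "KLRB1", "ADAP2"],
        columns=["s1", "s2", "s3", "s4"],
    )
    group = pd.Series(["case", "case", "control", "control"],
                      index=values.columns)
    return ExpressionMatrix(values, group)


@pytest.fixture(scope="session")
def mi_bundle():
    """One medium synthetic study reused across read-only tests."""
    return generate_study(mi_like_config(seed=11, n_genes=400))


def factor_matrix(groups: dict[str, tuple[float, float]], n: int = 12,
                  seed: int = 5) -> ExpressionMatrix:
    """Expression matrix whose genes load on one shared latent factor.

    ``groups`` maps gene -> (loading on the factor, private noise sd); half
    the samples are cases, half controls (the factor is group-independent).
    """
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)
    rows = {g: 7.0 + load * f + sd * rng.standard_normal(n)
            for g, (load, sd) in groups.items()}
    values = pd.DataFrame(rows).T
    values.columns = [f"s{i}" for i in range(n)]
    group = pd.Series(["case"] * (n // 2) + ["control"] * (n - n // 2),
                      index=values.columns)
    return ExpressionMatrix(values, group)
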