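import numpy as np
import pandas as pd
import pytest

import circlex as cx


@pytest.fixture(scope="session")
def default_config():
    return cx.SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def annotation(default_config):
    return cx.generate_annotation(default_config)


@pytest.fixture(scope="session")
def expression(default_config, annotation):
    return cx.generate_expression(default_config, annotation)


@pytest.fixture(scope="session")
def methylation(default_config, annotation):
    return cx.generate_methylation(default_config, annotation)


@pytest.fixture(scope="session")
def nsc(expression):
    expr, _ = expression
    return expr.subset_samples(expr.metadata.index[expr.metadata["lineage"] == "NSC"])


@pytest.fixture(scope="session")
def de_result(nsc):
    """Default-dataset DE with surrogate variables, shared across tests."""
    labels = nsc.metadata["origin"]
    design = np.column_stack([np.ones(len(labels)), (labels == "iPSC-NSC").to_numpy(float)])
    svs = cx.estimate_surrogate_variables(nsc, design, seed=42)
    de = cx.test_differential_expression(nsc, labels, svs, reference="ESC-NSC", treatment="iPSC-NSC")
    return svs, de


def make_expr(values: np.ndarray, origins=None) -> cx.ExpressionMatrix:
    """Small helper: wrap an array as an ExpressionMatrix with stub metadata."""
    n_g, n_s = values.shape
    sample_ids = [f"s{i}" for i in range(n_s)]
    if origins is None:
        origins = ["A"] * (n_s // 2) + ["B"] * (n_s - n_s // 2)
    meta = pd.DataFrame(
        {"origin": origins, "background": 0, "batch": 0},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    vals = pd.DataFrame(values, index=[f"g{i}" for i in range(n_g)], columns=sample_ids)
    return cx.ExpressionMatrix(vals, meta)
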