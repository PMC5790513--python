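"""Shared test-data builders."""

import numpy as np
import pandas as pd


def two_group_frame(rng, n_genes=10, n1=10, n2=10, shift=0.0):
    """Random log2 expression with an optional group-mean shift."""
    X = rng.normal(size=(n_genes, n1 + n2))
    X[:, :n1] += shift
    cols = [f"s{i}" for i in range(n1 + n2)]
    expr = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    labels = pd.Series(["high"] * n1 + ["low"] * n2, index=cols)
    return expr, labels
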