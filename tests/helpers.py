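"""Shared helpers for the test suite."""

import numpy as np
import pandas as pd

import lncemt as L


def random_expr(rng: np.random.Generator, n_feat: int, n_samp: int) -> L.ExpressionMatrix:
    values = pd.DataFrame(
        rng.normal(size=(n_feat, n_samp)),
        index=[f"g{i}" for i in range(n_feat)],
        columns=[f"s{j}" for j in range(n_samp)],
    )
    return L.ExpressionMatrix(values, pd.Series("protein_coding", index=values.index))
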