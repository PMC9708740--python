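import pandas as pd
import pytest

import lncemt as L


@pytest.fixture
def tiny_expr() -> L.ExpressionMatrix:
    """4 features x 3 samples with known ordering structure."""
    values = pd.DataFrame(
        [[4.0, 1.0, 2.0], [3.0, 2.0, 4.0], [2.0, 3.0, 1.0], [1.0, 4.0, 3.0]],
        index=["g1", "g2", "g3", "g4"],
        columns=["s1", "s2", "s3"],
    )
    biotype = pd.Series("protein_coding", index=values.index)
    return L.ExpressionMatrix(values, biotype)
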