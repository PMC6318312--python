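import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_instruments(
    rng,
    n: int = 50,
    theta: float = -0.3,
    se_out: float = 0.05,
    se_exp: float = 0.01,
    outlier: int | None = None,
    outlier_offset: float | None = None,
) -> pd.DataFrame:
    """Instrument table with a planted causal effect and optional outlier."""
    bx = rng.normal(0, 0.15, n)
    bx = np.sign(bx) * np.maximum(np.abs(bx), 0.075)
    by = theta * bx + rng.normal(0, se_out, n)
    if outlier is not None:
        by[outlier] += (outlier_offset if outlier_offset is not None else 10 * se_out)
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 1_000_000,
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exp": bx,
            "se_exp": se_exp,
            "beta_out": by,
            "se_out": se_out,
        }
    )
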