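import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_calls(records) -> pd.DataFrame:
    """Build a call table from (chrom, pos, strand, context, n_meth, n_total)."""
    df = pd.DataFrame(
        records, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    )
    df["n_unmeth"] = df["n_total"] - df["n_meth"]
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def random_calls(
    rng: np.random.Generator,
    n: int = 200,
    chrom: str = "chr1",
    span: int = 10_000,
    level=None,
) -> pd.DataFrame:
    """Random call table over one chromosome for property tests."""
    pos = np.sort(rng.choice(np.arange(1, span + 1), size=n, replace=False))
    total = rng.poisson(20, n) + 1
    p = rng.random(n) if level is None else np.full(n, level)
    meth = rng.binomial(total, p)
    return make_calls(
        list(
            zip(
                [chrom] * n,
                pos.tolist(),
                rng.choice(["+", "-"], n).tolist(),
                rng.choice(["CG", "CHG", "CHH"], n, p=[0.6, 0.2, 0.2]).tolist(),
                meth.tolist(),
                total.tolist(),
            )
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
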