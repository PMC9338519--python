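import numpy as np
import pytest

from bincfdr.core import EmpiricalCdf, StratumModel, SummaryTable


@pytest.fixture
def toy_model() -> StratumModel:
    """Hand-checkable model: stratum-0 training p = (0.1, 0.5, 0.9)."""
    return StratumModel(
        ecdf_0=EmpiricalCdf(np.array([0.1, 0.5, 0.9])),
        ecdf_1=EmpiricalCdf(np.array([0.2, 0.4, 0.8])),
        m_0=3,
        m_1=3,
        marginal_q=0.5,
        null_q=0.5,
    )


def make_table(rng: np.random.Generator, m: int, q_rate: float = 0.3,
               n_groups: int = 4) -> SummaryTable:
    return SummaryTable(
        p=rng.uniform(size=m),
        q=(rng.random(m) < q_rate).astype(int),
        group=np.arange(m) % n_groups,
    )
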