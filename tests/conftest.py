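import pandas as pd
import pytest

from epicirc.quantify import QuantificationResult, quantify
from epicirc.simulate import simulate_array


def quant_from_m6a(m6a: pd.DataFrame) -> QuantificationResult:
    """Wrap a bare m6A-quantity matrix as a QuantificationResult (all probes
    retained, %Modified from an all-zero Sup channel placeholder)."""
    sup = pd.DataFrame(0.0, index=m6a.index, columns=m6a.columns)
    flags = pd.DataFrame(False, index=m6a.index, columns=m6a.columns)
    return QuantificationResult(
        ip_norm=m6a.astype(float),
        sup_norm=sup,
        percent_modified=pd.DataFrame(1.0, index=m6a.index, columns=m6a.columns),
        out_of_range=flags,
        retained=pd.Series(True, index=m6a.index),
    )


def sheet_for(m6a: pd.DataFrame, groups: dict[str, list[str]]) -> pd.DataFrame:
    rows = [(s, g) for g, cols in groups.items() for s in cols]
    return pd.DataFrame(rows, columns=["sample_id", "group"])


@pytest.fixture(scope="session")
def small_study():
    return simulate_array(
        n_probes=300,
        n_spike=10,
        group_sizes={"TNBC": 5, "LuminalA": 5, "LuminalB": 5},
        frac_dm=0.1,
        flag_absent_rate=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_quant(small_study):
    return quantify(small_study.ip, small_study.sup, small_study.spike_ids)
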