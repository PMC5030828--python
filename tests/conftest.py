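import warnings

import numpy as np
import pandas as pd
import pytest

from toxclust.chemdata import EndpointGlossary, EndpointLoelMatrix
from toxclust.features import FeatureMatrix
from toxclust.potency import PotencyMatrix
from toxclust.synthdata import SynthParams, generate_dataset


def make_loel_matrix(values: dict, compound_ids: list[str],
                     endpoints: list[str]) -> EndpointLoelMatrix:
    """Build an endpoint LOEL matrix from {(cid, endpoint, dclass): mmol}."""
    cols = pd.MultiIndex.from_product([endpoints, ["subacute", "subchronic"]],
                                      names=["endpoint", "duration_class"])
    loel = pd.DataFrame(np.nan, index=pd.Index(compound_ids, name="compound_id"),
                        columns=cols, dtype=float)
    for (cid, ep, dc), v in values.items():
        loel.at[cid, (ep, dc)] = v
    reasons = pd.DataFrame("", index=loel.index, columns=cols, dtype=object)
    reasons = reasons.mask(loel.isna(), "no_information")
    return EndpointLoelMatrix(loel=loel, reasons=reasons)


def make_feature_matrix(bits: np.ndarray, ids: list[str],
                        bit_names: list[str] | None = None,
                        numeric: dict[str, np.ndarray] | None = None) -> FeatureMatrix:
    """Synthetic feature matrix: binary columns + optional numeric columns."""
    bit_names = bit_names or [f"f{j}" for j in range(bits.shape[1])]
    values = pd.DataFrame(np.asarray(bits, dtype=float),
                          index=pd.Index(ids, name="compound_id"),
                          columns=bit_names)
    meta = {c: {"kind": "binary", "description": "", "uninformative": False}
            for c in bit_names}
    for name, col in (numeric or {}).items():
        values[name] = np.asarray(col, dtype=float)
        meta[name] = {"kind": "numeric", "description": "", "uninformative": False}
    return FeatureMatrix(values=values, metadata=meta)


def make_potency(calls: np.ndarray, ids: list[str], endpoints: list[str],
                 thresholds: dict | None = None) -> PotencyMatrix:
    """Potency matrix from an array of 1/0/NaN."""
    df = pd.DataFrame(np.asarray(calls, dtype=float),
                      index=pd.Index(ids, name="compound_id"),
                      columns=endpoints)
    thr = pd.Series(thresholds or {ep: 1.75 for ep in endpoints})
    return PotencyMatrix(calls=df, observed=df.notna(), thresholds=thr)


@pytest.fixture(scope="session")
def synth_small():
    """Small seeded dataset exercising the full ingest path."""
    return generate_dataset(SynthParams(n_compounds=60, n_latent_clusters=3,
                                        seed=11))


@pytest.fixture(scope="session")
def synth_recovery():
    """Well-separated 4-cluster dataset at the documented study scale."""
    return generate_dataset(SynthParams(n_compounds=300, n_latent_clusters=4,
                                        effect_separation=2.0, seed=7))


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*single observed class.*")
        warnings.filterwarnings("ignore", message=".*no observed subacute values.*")
        yield
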