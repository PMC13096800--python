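import numpy as np
import pandas as pd
import pytest

from photoxl.containers import QuantMatrix, SampleMeta


def make_samples(conditions, n_replicates=3, time=1.0, source="led"):
    """One SampleMeta per (condition, replicate)."""
    out = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            out.append(
                SampleMeta(
                    sample_id=f"{cond}_r{rep}",
                    condition=cond,
                    irradiation_time=time,
                    irradiation_source=source,
                    replicate=rep,
                )
            )
    return out


def make_qm(values, conditions=("A", "B"), n_replicates=None, ids=None,
            evidence=None, flags=None):
    """QuantMatrix from a 2-D array; columns split evenly across conditions."""
    values = np.asarray(values, dtype=float)
    if n_replicates is None:
        n_replicates = values.shape[1] // len(conditions)
    samples = make_samples(conditions, n_replicates)
    if ids is None:
        ids = [f"P{i:04d}" for i in range(values.shape[0])]
    ev = None
    if evidence is not None:
        ev = pd.DataFrame(evidence, index=ids)
    fl = None
    if flags is not None:
        fl = pd.DataFrame(flags, index=ids)
    return QuantMatrix(protein_ids=list(ids), intensities=values,
                       samples=samples, evidence=ev, flags=fl)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
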