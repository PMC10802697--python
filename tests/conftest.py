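import numpy as np
import pandas as pd
import pytest

import cnvburden as cb


def make_samples(n=40, seed=0, n_datasets=2):
    """Minimal hand-built sample sheet (not via the generator)."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "sample_id": [f"S{i:03d}" for i in range(n)],
        "is_case": rng.random(n) < 0.5,
        "dataset": [f"ds{i % n_datasets}" for i in range(n)],
        "country": np.where(rng.random(n) < 0.5, "SWE", "NOR"),
        "sex": np.where(rng.random(n) < 0.5, "F", "M"),
        "lrrsd": rng.uniform(0.05, 0.15, n),
        "abs_wf": rng.uniform(0.001, 0.01, n),
        "baf_drift": rng.uniform(1e-5, 5e-4, n),
    })
    for i in range(1, 21):
        df[f"PC{i}"] = rng.standard_normal(n)
    return df


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study with marker signal, shared across tests."""
    cfg = cb.SimConfig.toy(150, 150)
    return cb.simulate_study(cfg, seed=42)


@pytest.fixture(scope="session")
def small_cascade(small_study):
    """Consensus + full filter cascade on the small study's QC-pass samples."""
    st = small_study
    consensus = cb.intersect_callsets(st.calls_a, st.calls_b, st.probe_map)
    kept, _ = cb.run_sample_qc(st.samples, consensus)
    keep = set(kept["sample_id"])
    a = [c for c in st.calls_a if c.sample_id in keep]
    b = [c for c in st.calls_b if c.sample_id in keep]
    res = cb.run_filter_cascade(a, b, kept, st.probe_map, st.annotation.masks,
                                st.annotation.freq_ref, inflation_screen=False)
    res["kept_samples"] = kept
    return res
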