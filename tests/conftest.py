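"""Shared fixtures: synthetic patients and pipeline artifacts.

Everything is generated programmatically at session scope so expensive
artifacts (FASTQ files, histograms, stores) are built once.
"""

import numpy as np
import pytest

from breakseek.count import build_histogram
from breakseek.kvstore import build_store
from breakseek.simulate import SimConfig, make_patient


@pytest.fixture(scope="session")
def clean_patient(tmp_path_factory):
    """Noiseless, uncontaminated patient on a 20 kb genome: 5 SNVs,
    1 insertion, 1 deletion.  Every tumor-exclusive k-mer traces to an
    injected mutation."""
    cfg = SimConfig(
        L=20_000, alpha=30.0, r=100, error_rate=0.0,
        n_snv=5, n_ins=1, n_del=1, min_separation=90,
        contamination=0.0, seed=3,
    )
    out = tmp_path_factory.mktemp("clean_patient")
    info = make_patient(cfg, out)
    info["cfg"] = cfg
    return info


@pytest.fixture(scope="session")
def clean_histogram(clean_patient, tmp_path_factory):
    out = tmp_path_factory.mktemp("clean_hist")
    return build_histogram(
        clean_patient["paths"]["normal"], clean_patient["paths"]["tumor"],
        28, out / "hist.kmh",
    )


@pytest.fixture(scope="session")
def clean_store(clean_histogram, tmp_path_factory):
    out = tmp_path_factory.mktemp("clean_store")
    store = build_store(clean_histogram, out / "store.kvr")
    yield store
    store.close()


@pytest.fixture(scope="session")
def random_histogram_entries():
    """Synthetic sorted histogram entries over a small root space:
    ~3000 roots with 1-6 observed variants each, Zipf-ish totals."""
    from breakseek.sort_reduce import UPDATE_DTYPE

    rng = np.random.default_rng(42)
    k = 10
    roots = np.sort(rng.choice(4 ** (k - 2), size=3000, replace=False).astype(np.uint64))
    rows = []
    for rank, root in enumerate(roots):
        nv = int(rng.integers(1, 7))
        variants = np.sort(rng.choice(32, size=nv, replace=False))
        weight = max(2, int(5000 / (rank + 1)))
        for v in variants:
            n = int(rng.integers(0, weight + 1))
            t = max(0, weight - n) if n == 0 else int(rng.integers(0, weight + 1))
            if n == 0 and t == 0:
                n = 1
                t = 1
            rows.append(((int(root) << 5) | int(v), min(n, 65535), min(t, 65535)))
    out = np.array(rows, dtype=UPDATE_DTYPE)
    return out, k
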