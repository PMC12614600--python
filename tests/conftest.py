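import os

# single-threaded BLAS: many small matmuls thrash thread pools otherwise
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS",
             "NUMEXPR_NUM_THREADS", "VECLIB_MAXIMUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np  # noqa: E402
import pytest  # noqa: E402

from multiprot.synthetic import GeneratorConfig, generate_corpus  # noqa: E402


@pytest.fixture(scope="session")
def tiny_corpus():
    """12 proteins, all modalities present."""
    cfg = GeneratorConfig(missing_pocket_fraction=0.0,
                          missing_text_fraction=0.0,
                          length_range=(12, 20))
    return generate_corpus(12, d_z=4, seed=7, config=cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


def random_unit_rows(n, d, seed=0):
    r = np.random.default_rng(seed)
    x = r.normal(size=(n, d))
    return x / np.linalg.norm(x, axis=1, keepdims=True)
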