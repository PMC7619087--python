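import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracle helper module

from tinvar.model import CopyNumberSegment, ModelParams, SiteObservation


@pytest.fixture
def diploid():
    return CopyNumberSegment("1", 1, 10**9, cn_normal=2, cn_tumour=2)


@pytest.fixture
def default_params():
    """Production-style defaults: 80% tumour purity, 10% TiN, 1% base error."""
    return ModelParams(alpha_t=0.8, alpha_n=0.10, base_error=0.01)


def random_site(rng: np.random.Generator, max_depth: int = 30, max_cn: int = 4):
    """A random small site and segment for oracle-equivalence checks."""
    cn_n = int(rng.integers(1, max_cn + 1))
    cn_t = int(rng.integers(1, max_cn + 1))
    t_depth = int(rng.integers(1, max_depth + 1))
    n_depth = int(rng.integers(1, max_depth + 1))
    site = SiteObservation(
        chrom="1", pos=int(rng.integers(1, 10**6)),
        ref_allele="A", alt_allele="G",
        tumour_depth=t_depth, tumour_alt=int(rng.integers(0, t_depth + 1)),
        normal_depth=n_depth, normal_alt=int(rng.integers(0, n_depth + 1)),
    )
    cn = CopyNumberSegment("1", 1, 10**9, cn_normal=cn_n, cn_tumour=cn_t)
    params = ModelParams(
        alpha_t=float(rng.uniform(0.1, 1.0)),
        alpha_n=float(rng.uniform(0.0, 0.3)),
        base_error=float(rng.uniform(0.001, 0.05)),
    )
    return site, cn, params
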