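import warnings

import numpy as np
import pytest

import embaudit as ea

# umap-learn warns about forced single-threading under a fixed random_state;
# irrelevant noise for the checks here
warnings.filterwarnings("ignore", message=".*n_jobs value 1.*")
warnings.filterwarnings("ignore", message=".*random_state.*")

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=30,
                              deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_mixture():
    """A 600-cell, 300-gene, 6-type mixture used across unit tests."""
    spec = ea.default_mixture_spec(600, 300, 6, seed=11)
    counts, ann = ea.generate_mixture_counts(spec)
    return counts, ann


@pytest.fixture(scope="session")
def small_lognorm(small_mixture):
    counts, ann = small_mixture
    return ea.lognormalize(counts), ann


@pytest.fixture(scope="session")
def small_umap(small_lognorm):
    """PCA-20 → UMAP embedding of the small mixture (seed 0)."""
    lognorm, ann = small_lognorm
    pca = ea.run_pca(lognorm, 20, seed=0)
    emb = ea.run_nonlinear_2d(pca, "umap", seed=0)
    return pca, emb, ann
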