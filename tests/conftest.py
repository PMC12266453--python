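import numpy as np
import pytest
from hypothesis import settings, HealthCheck

# derandomised hypothesis: same examples every run
settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.Generator(np.random.PCG64(20240917))


@pytest.fixture(scope="session")
def toy_proteins():
    from ubisite.synthetic import gen_toy_fasta
    records, sites = gen_toy_fasta(n_proteins=6, length_range=(20, 60),
                                   k_density=0.15, seed=3)
    return records, sites


@pytest.fixture(scope="session")
def separable_data():
    """Cleanly separable synthetic embeddings (no label noise)."""
    from ubisite.synthetic import SynthSpec, gen_embeddings
    spec = SynthSpec(n_pos=100, n_neg=500, dim=32, effect_size=4.0,
                     n_informative=4, noise_flip_rate=0.0, seed=1)
    return gen_embeddings(spec)


@pytest.fixture(scope="session")
def blob_data():
    """Two well-separated 2-d Gaussian blobs."""
    gen = np.random.Generator(np.random.PCG64(2))
    n = 400
    x0 = gen.standard_normal((n // 2, 2)) + [-3, 0]
    x1 = gen.standard_normal((n // 2, 2)) + [3, 0]
    x = np.vstack([x0, x1])
    y = np.r_[np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)]
    return x, y


@pytest.fixture(scope="session")
def audit_head(blob_data):
    """A compact, strongly weight-decayed residual head for quadrature
    audits: heavy decay keeps the trained network close to linear between
    its few activation kinks, which is the regime where a fixed-step path
    integral is accurate."""
    from ubisite.heads import HeadConfig, fit_head
    x, y = blob_data
    cfg = HeadConfig(architecture="res_dnn", input_dim=2, layer_dims=[4],
                     epochs=40, learning_rate=1e-3, weight_decay=10.0,
                     seed=7)
    return fit_head(x, y, cfg)


@pytest.fixture(scope="session")
def trained_toy_head(separable_data):
    """A small residual classifier trained on the separable fixture."""
    from ubisite.heads import HeadConfig, fit_head
    cfg = HeadConfig(architecture="res_dnn", input_dim=32, layer_dims=[16],
                     epochs=30, learning_rate=1e-3, seed=7)
    return fit_head(separable_data.table.features, separable_data.labels, cfg)
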