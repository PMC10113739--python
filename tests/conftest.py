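"""Shared fixtures: small synthetic families and trained models.

Session-scoped so the (seconds-long) VAE trainings run once.  Every fixture
is fully seeded; nothing touches the network or external data.
"""

import numpy as np
import pytest

from lgl.msa_io import Alignment, one_hot_encode
from lgl.potts import compute_frequencies, infer_potts
from lgl.synthetic import SyntheticFamilySpec, make_clustered_family
from lgl.vae import VAEConfig, train


@pytest.fixture(scope="session")
def family():
    """Two-cluster, full-alphabet family of 400 sequences (L=20)."""
    spec = SyntheticFamilySpec(
        L=20, q=23, n=400, n_clusters=2, profile_concentration=0.5, seed=101
    )
    aln, labels = make_clustered_family(spec)
    # rewrap over the canonical alphabet so all models share q=23
    return Alignment(aln.ids, aln.seqs, aln.labels), labels


@pytest.fixture(scope="session")
def family_onehot(family):
    aln, _ = family
    return one_hot_encode(aln)


@pytest.fixture(scope="session")
def vae_model(family_onehot):
    """VAE trained briefly on the two-cluster family (enough to structure
    the latent space; not converged to paper-scale quality)."""
    cfg = VAEConfig(seed=7, learning_rate=1e-3, max_epochs=80, patience_epochs=10)
    return train(family_onehot, cfg)


@pytest.fixture(scope="session")
def potts_model(family_onehot):
    return infer_potts(compute_frequencies(family_onehot))


@pytest.fixture(scope="session")
def memorized():
    """Tiny 3-sequence family with a VAE overfit to exact recall."""
    spec = SyntheticFamilySpec(
        L=8, q=23, n=3, n_clusters=3, profile_concentration=0.3, seed=55
    )
    aln, _ = make_clustered_family(spec)
    aln = Alignment(aln.ids, aln.seqs, aln.labels)
    X = one_hot_encode(aln)
    cfg = VAEConfig(
        learning_rate=1e-2, batch_size=3, max_epochs=2500, patience_epochs=2500, seed=9
    )
    model = train(X, cfg)
    return aln, X, model


@pytest.fixture(scope="session")
def protocol_inputs():
    """Larger family (n=3000) for the clustered sampling protocol, plus a
    landscape-derived Hamiltonian cutoff at the 95th percentile (barrier
    pixels are the top ~5%)."""
    from lgl.landscape import build_landscape, make_grid

    spec = SyntheticFamilySpec(
        L=20, q=23, n=3000, n_clusters=4, profile_concentration=0.8, seed=31
    )
    aln, _ = make_clustered_family(spec)
    aln = Alignment(aln.ids, aln.seqs, aln.labels)
    X = one_hot_encode(aln)
    model = train(X, VAEConfig(seed=5, learning_rate=1e-3, max_epochs=80))
    pm = infer_potts(compute_frequencies(X))
    mu, _ = model.encode(X)
    ls = build_landscape(model, pm, make_grid(model, mu, n=80))
    cutoff = float(np.quantile(ls.H, 0.95))
    return model, pm, aln, cutoff


@pytest.fixture(scope="session")
def potts_model_small(memorized):
    """Potts model on the tiny memorized family (L=8)."""
    _, X, _ = memorized
    return infer_potts(compute_frequencies(X, pseudocount=0.5, reweight_identity=None))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
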