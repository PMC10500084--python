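import os

# grading runs on one CPU; keep BLAS from oversubscribing elsewhere too
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")

import numpy as np
import pytest

from scace import (
    CountMatrix,
    ScaceConfig,
    SimDesign,
    default_paper_design,
    preprocess,
    run_scace,
    simulate,
)
from scace.zinb_vae import VAEModel, encode, pretrain

PINNED_SEED = 0


def small_design(seed: int = 7, **kw) -> SimDesign:
    """Desk-scale 4-population design used by unit tests."""
    base = dict(
        n_genes=300,
        cluster_sizes=(80, 60, 60, 40),
        de_fraction=0.2,
        log_fold_change=2.0,
        dispersion=2.0,
        n_marker_genes=20,
        marker_log_fold_change=3.0,
        seed=seed,
    )
    base.update(kw)
    return SimDesign(**base)


def small_config(seed: int = 0, **kw) -> ScaceConfig:
    base = dict(
        encoder_hidden_width=128,
        latent_dim=12,
        decoder_hidden_width=128,
        pretrain_epochs=60,
        pretrain_lr=3e-3,
        batch_size=64,
        n_neighbors=10,
        seed=seed,
    )
    base.update(kw)
    return ScaceConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """(CountMatrix, labels) for a small well-separated 4-population draw."""
    return simulate(small_design())


@pytest.fixture(scope="session")
def small_pretrained(small_sim):
    """Preprocessed data plus a briefly pretrained small VAE and its embedding."""
    cm, labels = small_sim
    filtered, x_norm = preprocess(cm)
    model = VAEModel(
        n_genes=filtered.n_genes,
        encoder_hidden_width=128,
        latent_dim=12,
        decoder_hidden_width=128,
        seed=0,
    )
    pretrain(model, filtered, x_norm, epochs=60, seed=0, lr=3e-3, batch_size=64)
    emb = encode(model, x_norm)
    return dict(counts=filtered, x_norm=x_norm, model=model, emb=emb, labels=labels)


@pytest.fixture(scope="session")
def paper_sim():
    """The pinned default five-population simulation (600/200/200/100/50)."""
    return simulate(default_paper_design(seed=PINNED_SEED))


@pytest.fixture(scope="session")
def paper_run(paper_sim):
    """De novo pipeline run on the pinned fixture with default config."""
    cm, truth = paper_sim
    result = run_scace(cm, mode="de_novo", config=ScaceConfig(seed=PINNED_SEED))
    return dict(counts=cm, truth=truth, result=result)


def blob_embedding(centers, sizes, spread=0.1, seed=0, dim=None):
    """Latent-space Gaussian blobs as a latent_dim x n array plus labels."""
    rng = np.random.default_rng(seed)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if dim is not None and centers.shape[1] < dim:
        pad = np.zeros((centers.shape[0], dim - centers.shape[1]))
        centers = np.hstack([centers, pad])
    pts, labels = [], []
    for k, (c, s) in enumerate(zip(centers, sizes)):
        pts.append(c + spread * rng.standard_normal((s, centers.shape[1])))
        labels += [k] * s
    return np.vstack(pts).T, np.array(labels)
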