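"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from neuromap.embedding import Embedding
from neuromap.preprocess import multitaper_spectrogram
from neuromap.synthetic import CLASSES, generate_training_set


@pytest.fixture(scope="session")
def small_spectrogram_set():
    """3 well-separated classes x 24 segments, as spectrograms."""
    segs = generate_training_set(
        n_per_class=24, patients_per_class=6, seed=7, classes=["W", "N3", "GPD"]
    )
    return [multitaper_spectrogram(s) for s in segs]


@pytest.fixture(scope="session")
def clustered_embeddings():
    """Synthetic unit-norm embeddings in 11 tight, well-separated clusters.

    20 patients per class, 5 segments per patient; cluster centers are
    random orthogonal-ish directions in 128-D, spread sigma 0.02.
    """
    rng = np.random.default_rng(11)
    centers = rng.standard_normal((len(CLASSES), 128))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    embs = []
    for ci, cls in enumerate(CLASSES):
        for p in range(20):
            for s in range(5):
                v = centers[ci] + 0.02 * rng.standard_normal(128)
                v /= np.linalg.norm(v)
                embs.append(
                    Embedding(
                        vector=v,
                        patient_id=f"{cls}_pat{p}",
                        start_time=10.0 * s,
                        source_label=cls,
                    )
                )
    return embs
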