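import warnings

import numpy as np
import pytest

import ricemorph as rm
from ricemorph import classifier as clf
from ricemorph.synthetic import separable_class_specs


@pytest.fixture(scope="session")
def rice_specs():
    """The packaged 15 rice-type class specifications."""
    return rm.default_class_specs()


@pytest.fixture(scope="session")
def small_scene(rice_specs):
    """A bright-grain scene of three bold classes, fixed seed."""
    return rm.render_grain_scene(
        rice_specs[:3], n_per_class=5, image_size=(512, 512), seed=7
    )


@pytest.fixture(scope="session")
def mixed_scene(rice_specs):
    """All 15 classes (bright and dark grains) in one scene."""
    return rm.render_grain_scene(
        rice_specs, n_per_class=2, image_size=(760, 760), seed=11
    )


@pytest.fixture(scope="session")
def rice_table(rice_specs):
    """Feature table sampled from the per-class moments, 30 rows per class."""
    return rm.sample_feature_table(rice_specs, 30, seed=2)


@pytest.fixture(scope="session")
def separable_table():
    """Well-separated 15-class feature table (means >= 6 pooled SDs apart)."""
    return rm.sample_feature_table(separable_class_specs(), 40, seed=3)


@pytest.fixture(scope="session")
def separable_model(separable_table):
    """Network trained once on the separable condition, reused across tests."""
    train, _ = clf.split_dataset(separable_table, 0.7, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return clf.train_br(
            train, n_hidden=10, config=clf.BRConfig(max_epochs=150, seed=3)
        )


class OneHotStub:
    """Duck-typed stand-in model whose scores are exact one-hot targets.

    Synthetic oracle for the evaluation formulas: with scores equal to the
    targets, accuracy must be exactly 100, MSE exactly 0 and every
    one-vs-rest ROC perfect.
    """

    def __init__(self, class_ids, labels):
        self.class_ids = list(class_ids)
        self._labels = np.asarray(labels)

    def forward(self, X):
        col = {c: j for j, c in enumerate(self.class_ids)}
        out = np.zeros((len(self._labels), len(self.class_ids)))
        out[np.arange(len(self._labels)), [col[c] for c in self._labels]] = 1.0
        return out
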