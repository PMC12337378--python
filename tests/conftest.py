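import numpy as np
import pytest

from icenv.classification import FeedForwardClassifier, evaluate, stratified_split
from icenv.encoding import SurrogateEncoder
from icenv.synthetic_data import (
    DEFAULT_COLUMNS,
    GeneratorConfig,
    generate_dataset,
    planted_signal_dataset,
)

ENVIRONMENTS = (
    "frozen_sediment",
    "rock",
    "subsurface",
    "polar_marine",
    "glacier_ice",
)

#: alignment positions carrying the planted environment signal in the shared
#: study fixture: the two b-face columns of the default face map
SIGNAL_POSITIONS = tuple(
    sorted(DEFAULT_COLUMNS["b_col2"] + DEFAULT_COLUMNS["b_col4"])
)


class Study:
    """A trained synthetic study: data, encoder, split and fitted model."""

    def __init__(self, seqs, face_map, encoder, model, train_idx, test_idx):
        self.seqs = seqs
        self.face_map = face_map
        self.encoder = encoder
        self.model = model
        self.train_idx = train_idx
        self.test_idx = test_idx
        self.y = np.asarray(seqs.environments)
        self.X = encoder.transform(seqs.ungapped())

    @property
    def test_seqs(self):
        return self.seqs.subset(np.array(self.seqs.ids)[self.test_idx])

    def test_report(self):
        return evaluate(
            self.y[self.test_idx],
            self.model.predict(self.X[self.test_idx]),
            classes=self.model.classes_,
        )


def _train_study(seqs, face_map, seed=0):
    encoder = SurrogateEncoder(d=64, seed=5).fit()
    X = encoder.transform(seqs.ungapped())
    y = np.asarray(seqs.environments)
    train_idx, test_idx = stratified_split(y, test_fraction=0.2, seed=3)
    model = FeedForwardClassifier(
        hidden_layers=(64, 32),
        dropout=0.5,
        learning_rate=1e-3,
        batch_size=64,
        epochs=60,
        class_weight="balanced",
        random_state=seed,
    ).fit(X[train_idx], y[train_idx])
    return Study(seqs, face_map, encoder, model, train_idx, test_idx)


@pytest.fixture(scope="session")
def signal_study():
    """Balanced five-environment study with a strong planted column signal."""
    seqs, face_map, _ = planted_signal_dataset(
        {env: 120 for env in ENVIRONMENTS},
        SIGNAL_POSITIONS,
        n_columns=185,
        seed=21,
    )
    return _train_study(seqs, face_map)


@pytest.fixture(scope="session")
def nosignal_study():
    """Same design with no planted signal: a leakage control."""
    config = GeneratorConfig(
        n_per_environment={env: 120 for env in ENVIRONMENTS},
        n_columns=185,
        seed=23,
    )
    seqs, face_map = generate_dataset(config)
    return _train_study(seqs, face_map)
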