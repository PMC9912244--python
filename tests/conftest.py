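"""Shared fixtures: planted-signal guide sets and a small trained model."""

from __future__ import annotations

import numpy as np
import pytest

from cas13guide.deep_model import ModelConfig, build_crnn, fit
from cas13guide.encoding import encode_guide, lfc_to_target, stack_encoded
from cas13guide.simulate import SimConfig, planted_efficiency, simulate
from cas13guide.structure import fold_mfe


def random_spacers(rng: np.random.Generator, n: int, length: int = 22) -> list[str]:
    alphabet = np.array(list("ACGU"))
    return ["".join(rng.choice(alphabet, size=length)) for _ in range(n)]


@pytest.fixture(scope="session")
def planted_dataset():
    """500 guides with the planted sequence/structure efficiency signal."""
    rng = np.random.default_rng(42)
    spacers = random_spacers(rng, 500)
    folds = [fold_mfe(s, engine="maxpair") for s in spacers]
    eff = np.array([planted_efficiency(s, f) for s, f in zip(spacers, folds)])
    lfc = -2.0 * eff + rng.normal(0.0, 0.3, len(eff))
    encoded = [encode_guide(s, f, L=30) for s, f in zip(spacers, folds)]
    return {
        "spacers": spacers,
        "folds": folds,
        "efficiency": eff,
        "lfc": lfc,
        "encoded": encoded,
        "arrays": stack_encoded(encoded),
    }


@pytest.fixture(scope="session")
def small_trained_model(planted_dataset):
    """A compact network trained on the planted dataset (shared across tests)."""
    cfg = ModelConfig(conv_filters=16, dense_units=32, recurrent_units=32,
                      epochs=25, seed=7)
    model = build_crnn(cfg, L=30)
    seq, struct, mask = planted_dataset["arrays"]
    targets = lfc_to_target(planted_dataset["lfc"])
    fit(model, seq, struct, mask, targets, cfg)
    return model


@pytest.fixture(scope="session")
def default_sim():
    """One synthetic screen under the default study conditions."""
    return simulate(SimConfig(seed=3))
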