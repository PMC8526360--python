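"""Shared fixtures.

The expensive artifacts — the desk-scale bimodal dataset, the trained
PixelVAE and the trained supervised classifier — are session-scoped so they
are rendered/trained exactly once and shared by every analysis-level test.
"""

from __future__ import annotations

import numpy as np
import pytest

from glossim.world import WorldConfig, render_dataset
from glossim.pixelvae import PixelVAEConfig, train_unsupervised, encode
from glossim.baselines import SupervisedConfig, train_supervised_classifier

DESK_N = 1500
DESK_SIZE = 32
DESK_SEED = 11


@pytest.fixture(scope="session")
def bimodal_world():
    return WorldConfig(image_size=DESK_SIZE, gloss_regime="bimodal",
                       master_seed=DESK_SEED)


@pytest.fixture(scope="session")
def bimodal_data(bimodal_world):
    images, manifest = render_dataset(bimodal_world, DESK_N, seed=DESK_SEED)
    return images, manifest


N_INSTANCES = 2


@pytest.fixture(scope="session")
def trained_vaes(bimodal_data):
    """Two training instances of the desk PixelVAE (the instance-averaging
    the readout analyses call for), cached in scratch for repeated runs."""
    import hashlib
    import json as _json
    from dataclasses import asdict
    from pathlib import Path

    from glossim.pixelvae import load_model, save_model

    images, manifest = bimodal_data
    train = images[(manifest["split"] == "train").to_numpy()]
    cfg = PixelVAEConfig.desk(image_size=DESK_SIZE)
    cfg_hash = hashlib.sha256(
        _json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:10]
    cache = Path(__file__).resolve().parents[1] / "scratch" / "test_cache"
    models = []
    for inst in range(N_INSTANCES):
        key = cache / f"vae_seed{DESK_SEED}i{inst}_n{DESK_N}_{cfg_hash}.npz"
        if key.exists():
            models.append(load_model(key))
            continue
        model, _ = train_unsupervised(train, cfg, seed=DESK_SEED + 101 * inst)
        try:
            cache.mkdir(parents=True, exist_ok=True)
            save_model(model, key)
        except OSError:
            pass
        models.append(model)
    return models


@pytest.fixture(scope="session")
def trained_vae(trained_vaes):
    return trained_vaes[0], None


@pytest.fixture(scope="session")
def vae_latents_all(trained_vaes, bimodal_data):
    images, _ = bimodal_data
    return [encode(m, images)[0] for m in trained_vaes]


@pytest.fixture(scope="session")
def vae_latents(vae_latents_all):
    return vae_latents_all[0]


@pytest.fixture(scope="session")
def trained_supervised(bimodal_data):
    import json
    from pathlib import Path

    from glossim.baselines import SupervisedNet

    images, manifest = bimodal_data
    labels = (manifest["gloss_label"] == "high").astype(int).to_numpy()
    tr = (manifest["split"] == "train").to_numpy()
    te = (manifest["split"] == "test").to_numpy()
    cfg = SupervisedConfig.desk(image_size=DESK_SIZE, epochs=8)
    cache = Path(__file__).resolve().parents[1] / "scratch" / "test_cache"
    key = cache / f"sup_seed{DESK_SEED}_n{DESK_N}_e{cfg.epochs}.npz"
    if key.exists():
        with np.load(key) as data:
            net = SupervisedNet(cfg, n_out=2, seed=DESK_SEED)
            net.load_state_dict([data[f"arr_{i}"]
                                 for i in range(len(net.parameters()))])
            net.trained = True
            report = {"test_accuracy": float(data["test_accuracy"])}
        return net, report
    net, report, fs = train_supervised_classifier(
        images[tr], labels[tr], cfg, seed=DESK_SEED,
        test_images=images[te], test_labels=labels[te])
    try:
        cache.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(key, *net.state_dict(),
                            test_accuracy=report["test_accuracy"])
    except OSError:
        pass
    return net, report


@pytest.fixture(scope="session")
def supervised_features(trained_supervised, bimodal_data):
    net, _ = trained_supervised
    images, _ = bimodal_data
    return net.features(images)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
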