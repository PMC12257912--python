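"""Shared fixtures: small phantoms/geometries and one desk-scale training run.

Everything is generated programmatically; the heavier objects are session
scoped so the reconstruction-quality and learning tests share them.
"""

import numpy as np
import pytest

from cret.experiment import ExperimentConfig, default_geometry, run_experiment
from cret.fbp import cosine_weight, ramp_filter
from cret.learning import TrainConfig
from cret.phantoms import make_phantom, project_ellipses_analytic


@pytest.fixture(scope="session")
def geom120():
    """Training-scale scanner: 120 views, 128 detectors, 3.6 mm pitch."""
    return default_geometry(n_views=120)


@pytest.fixture(scope="session")
def sl96():
    """Shepp-Logan head phantom on a 96x96, 0.7 mm grid."""
    return make_phantom("shepp_logan", 96, 0.7, 0)


@pytest.fixture(scope="session")
def filtered_sl96(geom120, sl96):
    """Noiseless filtered sinogram of the small Shepp-Logan phantom."""
    p = project_ellipses_analytic(sl96.ellipses, geom120)
    return ramp_filter(cosine_weight(p))


@pytest.fixture(scope="session")
def study():
    """One desk-scale training study shared across tests.

    12 training phantoms at binning scales {1, 2, 4}, 10 held-out phantoms
    evaluated at {2, 4, 8} (8 never seen in training), with the plug-and-play
    restorator trained on top of the frozen step-1 model.
    """
    cfg = ExperimentConfig(
        n_train_phantoms=12,
        n_test_phantoms=10,
        grid_size=96,
        pixel_spacing=0.7,
        n_views=120,
        scales=(1, 2, 4),
        eval_scales=(2, 4, 8),
        patch_extent=22.4,
        out_resolution=32,
        train=TrainConfig(epochs=5, iters_per_epoch=30, batch_size=2,
                          lr=2e-3, seed=0),
        with_restorator=True,
        seed=0,
    )
    model, report = run_experiment(cfg)
    return {"cfg": cfg, "model": model, "report": report}
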