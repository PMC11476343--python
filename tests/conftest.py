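import numpy as np
import pytest

from memquant import flim, synthetic


@pytest.fixture
def ideal_single_exp_image():
    """A FlimImage where every pixel holds the same ideal tau = 1 ns decay.

    Deterministic (no photon noise): the per-pixel FastFLIM estimates are
    identical, so the lifetime distribution occupies a single bin.
    """
    bin_w = 25.0
    edges = np.arange(0, 20000 + bin_w, bin_w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    tau_ps = 1000.0
    profile = np.exp(-centers / tau_ps)
    counts = np.rint(1e4 * profile / profile.sum()).astype(np.int64)
    image = flim.FlimImage(
        counts=np.broadcast_to(counts, (8, 8, len(counts))).copy(),
        bin_edges_ps=edges, irf_fwhm_ps=0.0, irf_center_ps=0.0)
    return image


@pytest.fixture
def two_population_image():
    """A small patterned FLIM image with hybrid + thylakoid populations."""
    layout = synthetic.CorralLayout(corral_size_um=20, template_width_um=5,
                                    grid_shape=(1, 1), pixel_size_um=0.5)
    truth = synthetic.SceneTruth(
        rng_seed=101,
        region_models={"hybrid": synthetic.hybrid_model(),
                       "thylakoid": synthetic.thylakoid_model()})
    image, labels = synthetic.simulate_flim_image(
        layout, truth, photons_per_pixel_mean=300,
        particle_pixel_fraction=0.05)
    return image, labels, layout, truth
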