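import numpy as np
import pytest

from phenoplate import synthetic
from phenoplate.plate_io import FieldImage
from phenoplate.pipeline import process_field


@pytest.fixture(scope="session")
def sim_params():
    return synthetic.default_params()


@pytest.fixture(scope="session")
def well_truth(sim_params):
    """Ground truth for one high-adhesion well (moderate density)."""
    return synthetic.sample_well_population(sim_params, "Fn25", seed=11,
                                            well="C03")


@pytest.fixture(scope="session")
def well_results(sim_params, well_truth):
    """All nine fields of the fixture well, rendered and processed."""
    out = []
    for fld in range(1, sim_params.n_fields + 1):
        sub = well_truth[well_truth["field"] == fld].reset_index(drop=True)
        image = synthetic.render_field(sub, sim_params, seed=500 + fld)
        image = FieldImage(well="C03", field=fld, channels=image.channels,
                           pixel_size_um=sim_params.pixel_size_um)
        out.append((image, sub, process_field(image)))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_label_mask(rng, shape=(120, 120), n_seeds=10):
    """Random touching-region tessellation restricted to disks around seeds.

    Watershed-like random masks: labels may touch (share boundaries) or be
    isolated, exercising clump adjacency in both regimes.
    """
    from scipy import ndimage as ndi
    from skimage.segmentation import watershed

    seeds = np.zeros(shape, dtype=int)
    coords = rng.integers(5, np.array(shape) - 5, size=(n_seeds, 2))
    for i, (r, c) in enumerate(coords, start=1):
        seeds[r, c] = i
    distance = ndi.distance_transform_edt(seeds == 0)
    radius = rng.uniform(8, 22)
    labels = watershed(distance, markers=seeds, mask=distance < radius)
    return labels.astype(np.int32)
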