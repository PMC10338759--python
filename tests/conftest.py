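import numpy as np
import pytest

from canopycce import ForestSpec, TreeSegmenter, generate_forest


@pytest.fixture(scope="session")
def small_plot():
    """A 20 x 20 m cone plot, 20 trees, with ground truth."""
    spec = ForestSpec(
        plot_size=(20.0, 20.0), stem_density=0.05, point_density=150.0,
        min_spacing=3.0, seed=7, slope_deg=5.0,
    )
    cloud, truth = generate_forest(spec)
    return spec, cloud, truth


@pytest.fixture(scope="session")
def small_plot_fit(small_plot):
    """The full pipeline fitted on the small plot (default parameters)."""
    _, cloud, _ = small_plot
    return TreeSegmenter().fit(cloud)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def single_crown_points(seed=3, point_density=300.0):
    """Points of one isolated cone crown (above 2 m), for voxel tests."""
    spec = ForestSpec(
        plot_size=(10.0, 10.0), stem_density=0.01, point_density=point_density,
        min_spacing=0.0, seed=seed, slope_deg=0.0,
    )
    cloud, truth = generate_forest(spec)
    sel = (~cloud.ground) & (cloud.z - cloud.z[cloud.ground].mean() >= 2.0)
    return cloud.xyz[sel], truth
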