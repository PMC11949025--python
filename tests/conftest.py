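import numpy as np
import pytest

from alveo4d import simulate as sim


def voxel_field(shape_um: float, voxel: float, offset: float = 0.25):
    """Voxel-centre coordinate grids (z, y, x) in μm, centred on the field.

    The half-voxel offset keeps analytic phantom surfaces off the sampling
    lattice, avoiding alignment bias in voxel-count oracles.
    """
    n = int(shape_um / voxel)
    axis = np.arange(n) * voxel - n * voxel / 2 + offset
    return np.meshgrid(axis, axis, axis, indexing="ij")


@pytest.fixture(scope="session")
def ball_phantom():
    """Factory: voxelised ball of radius r μm at the given voxel size."""

    def make(r=10.0, voxel=0.5, pad=4):
        n = int(2 * r / voxel) + 2 * pad
        axis = np.arange(n) * voxel - n * voxel / 2 + voxel / 2
        zz, yy, xx = np.meshgrid(axis, axis, axis, indexing="ij")
        return (zz**2 + yy**2 + xx**2 <= r**2).astype(np.int32)

    return make


@pytest.fixture(scope="session")
def small_scene():
    """A small deterministic control scene shared by read-only tests."""
    cfg = sim.SceneConfig(seed=11, n_epithelial=12, n_rings=2, n_frames=8)
    return cfg, sim.build_scene(cfg)


@pytest.fixture(scope="session")
def ring_scene():
    """Ten planted rings in a full-ROI field, mesenchyme only."""
    cfg = sim.SceneConfig(
        field_size=(350.0, 220.0, 80.0), n_rings=10, n_epithelial=0,
        n_frames=2, seed=5,
    )
    truth = sim.build_scene(cfg)
    mask = sim.render_channel(truth, 0, "mesenchymal") > 0.25
    labels = sim.render_labels(truth, 0, "mesenchymal")
    return cfg, truth, mask, labels
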