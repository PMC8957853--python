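import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cytomap.cohort import CohortSpec, TransformJitter
from cytomap.grid import LabelVolume, make_grid
from cytomap.pipeline import PipelineConfig, run_pipeline

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def digitize_ball(radius: float, voxel: float, center=(0.0, 0.0, 0.0),
                  margin: float = 2.0, space_id: str = "phantom") -> LabelVolume:
    """Voxelised ball phantom: label 1 where the voxel centre is inside."""
    center = np.asarray(center, float)
    lo = center - radius - margin
    n = int(np.ceil((2 * (radius + margin)) / voxel))
    grid = make_grid(tuple(lo + voxel / 2), (n, n, n), voxel, space_id)
    idx = np.indices(grid.labels.shape).reshape(3, -1).T
    world = grid.index_to_world(idx)
    inside = ((world - center) ** 2).sum(axis=1) <= radius ** 2
    grid.labels[tuple(idx[inside].T)] = 1
    return grid


def zero_variance_spec(**overrides) -> CohortSpec:
    """Cohort spec with every random spread switched off."""
    kw = dict(
        n_subjects=2,
        volume_cv=0.0,
        position_jitter_sd=0.0,
        transform_jitter=TransformJitter(0.0, 0.0, 0.0),
        brain_volume_mean_sd=(1.25e6, 0.0),
        shrinkage_factor_mean_sd=(1.93, 0.0),
        seed=0,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory):
    """One full default-condition pipeline run shared across tests."""
    out = str(tmp_path_factory.mktemp("pipeline"))
    manifest = run_pipeline(PipelineConfig({}), output_dir=out)
    return manifest, out
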