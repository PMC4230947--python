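"""Shared fixtures.

The expensive end-to-end cohort analysis is run once per session on a
reduced grid (48 x 48 x 36 voxels at 2 mm) with the study-sized 19 + 19
cohort; directional acceptance tests read its outputs.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from qmrivox.phantom import PhantomSpec, build_template
from qmrivox.pipeline import RunConfig, run_pipeline


SMALL_GRID = (32, 32, 24)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(grid_shape=SMALL_GRID)


@pytest.fixture(scope="session")
def noise_free_spec(small_spec) -> PhantomSpec:
    """Spec with all stochastic tissue variation switched off."""
    quiet = {name: replace(cp, between_sd=(0.0, 0.0, 0.0),
                           within_sd=(0.0, 0.0, 0.0))
             for name, cp in small_spec.tissue_params.items()}
    return replace(small_spec, tissue_params=quiet, noise_sigma=0.0)


@pytest.fixture(scope="session")
def template(small_spec):
    return build_template(small_spec, atrophy_factor=1.0)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline execution on the 19 + 19 synthetic cohort."""
    workdir = tmp_path_factory.mktemp("pipeline")
    config = RunConfig(workdir=str(workdir), seed=7, n_ref=19, n_pat=19,
                       grid_shape=(48, 48, 36), n_perm=200)
    report = run_pipeline(config)
    return {"config": config, "workdir": workdir, "report": report}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
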