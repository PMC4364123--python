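import dataclasses

import numpy as np
import pytest

import corticompare as cc


@pytest.fixture(scope="session")
def registry():
    return cc.load_roi_registry()


@pytest.fixture(scope="session")
def small_template():
    """Two-hemisphere ICO2 template (324 vertices) for cheap statistics."""
    return cc.build_cortex_template(2, radius=30.0)


@pytest.fixture(scope="session")
def small_atlas(small_template, registry):
    return cc.build_synthetic_atlas(small_template, registry, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    return cc.make_cohort(cc.CohortDesign(seed=7))


@pytest.fixture(scope="session")
def rendered_small(default_cohort, small_template, small_atlas):
    """Both pipelines rendered on the small template (shared geometry)."""
    cv = cc.render_pipeline_observation(
        default_cohort,
        dataclasses.replace(cc.CIVET_PROFILE, resolution_subdiv=2),
        small_atlas, small_template)
    fs = cc.render_pipeline_observation(
        default_cohort,
        dataclasses.replace(cc.FREESURFER_PROFILE, resolution_subdiv=2),
        small_atlas, small_template)
    return cv, fs


def brute_force_nn(src, tgt):
    """Exhaustive nearest-neighbour oracle (lowest index wins ties)."""
    d2 = ((src[:, None, :] - tgt[None, :, :]) ** 2).sum(-1)
    idx = d2.argmin(axis=1)          # argmin returns the first minimum
    return idx, np.sqrt(d2[np.arange(len(src)), idx])
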