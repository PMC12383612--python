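import numpy as np
import pytest

from maxsdm import (FeatureSpec, GridDef, build_features, default_fixture,
                    sample_background, thin)


@pytest.fixture(scope="session")
def fixture_system():
    """Default synthetic study system: stack, truth, raw occurrences."""
    return default_fixture(seed=0)


@pytest.fixture(scope="session")
def thinned(fixture_system):
    stack, truth, occ = fixture_system
    return thin(occ, stack.grid, stack)


@pytest.fixture(scope="session")
def presence_background(fixture_system, thinned):
    """Raw presence/background variable values on the default fixture."""
    stack, _, _ = fixture_system
    names = stack.layer_names
    rows, cols = stack.grid.locate(thinned.lons, thinned.lats)
    presence = stack.values_at_cells(rows, cols, names)
    background = sample_background(stack, 2000, seed=1, variable_names=names)
    return presence, background, names


@pytest.fixture(scope="session")
def fitted_lqh(presence_background):
    """An LQH model fitted on the default fixture."""
    from maxsdm import fit

    presence, background, names = presence_background
    spec = FeatureSpec("LQH", hinge_knots=10)
    bg = build_features(background, spec, names)
    pr = build_features(presence, spec, names, scaling=bg.scaling)
    return fit(pr, bg, rm=1.0), pr, bg


@pytest.fixture
def rng():
    return np.random.default_rng(42)
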