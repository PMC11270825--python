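import numpy as np
import pytest
from scipy.stats import chisquare

from glycanmc import BasinSpec, LinkageGeometry, make_gaussian_fem


@pytest.fixture
def geometry():
    return LinkageGeometry(ring_dihedral=60.0)


@pytest.fixture
def zigzag_geometry():
    """Geometry whose all-trans conformation is a planar extended zigzag."""
    return LinkageGeometry(ring_dihedral=180.0)


@pytest.fixture
def three_basin_map():
    """Coarse map with three well-separated Gaussian wells of known depths."""
    return make_gaussian_fem(
        [BasinSpec((-74, 117), 20.0, 25.0),
         BasinSpec((50, 123), 14.0, 25.0),
         BasinSpec((-59, -36), 16.0, 25.0)],
        grid_step=20.0, plateau=20.0)


def pooled_chisquare_pvalue(counts, probs, min_expected=5.0):
    """Chi-square goodness-of-fit with low-expectation bins pooled."""
    counts = np.asarray(counts, dtype=float).ravel()
    probs = np.asarray(probs, dtype=float).ravel()
    expected = probs * counts.sum()
    big = expected >= min_expected
    obs = list(counts[big])
    exp = list(expected[big])
    if (~big).any() and expected[~big].sum() > 0:
        obs.append(counts[~big].sum())
        exp.append(expected[~big].sum())
    exp = np.asarray(exp) * (np.sum(obs) / np.sum(exp))
    return chisquare(obs, f_exp=exp).pvalue
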