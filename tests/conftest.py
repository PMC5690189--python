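import numpy as np
import pytest

from dvhrisk import DifferentialDVH, default_params


@pytest.fixture
def params():
    return default_params()


@pytest.fixture
def uniform_dvh():
    """Factory: whole organ in a single bin with exact midpoint dose."""

    def make(dose_gy, organ="heart", width=0.1):
        return DifferentialDVH.uniform(organ, dose_gy, width=width)

    return make


@pytest.fixture
def random_dvh():
    """Factory: random contiguous differential DVH with unit total volume."""

    def make(rng, n_bins=50, width=0.1, organ="lung", start=0.0):
        fv = rng.dirichlet(np.ones(n_bins))
        lo = start + np.arange(n_bins) * width
        return DifferentialDVH(organ=organ, lo=lo, hi=lo + width, frac_volume=fv)

    return make


def bin_voxels(doses, width=0.1, organ="lung"):
    """Independent route: histogram an equal-volume voxel dose list into a
    differential DVH on a uniform grid (used to cross-check binned model
    evaluation against voxelwise brute force)."""
    doses = np.asarray(doses, dtype=float)
    n = int(np.floor(doses.max() / width)) + 1
    edges = np.arange(n + 1) * width
    counts, _ = np.histogram(doses, bins=edges)
    fv = counts / doses.size
    fv[np.argmax(fv)] += 1.0 - fv.sum()
    return DifferentialDVH(organ=organ, lo=edges[:-1], hi=edges[1:], frac_volume=fv)
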