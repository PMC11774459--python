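import numpy as np
import pytest
from scipy import ndimage

import vesselmarks as vm


def make_ball_patch(radius_vox, center_vox, n=41, inside_hu=240.0, outside_hu=-160.0):
    """Solid binary ball rendered as a windowed HU patch (1 voxel spacing)."""
    idx = np.indices((n, n, n)).reshape(3, -1).T
    dist = np.linalg.norm(idx - np.asarray(center_vox, float), axis=1).reshape(n, n, n)
    vox = np.where(dist <= radius_vox, inside_hu, outside_hu)
    return vm.hu_window(vm.Volume(vox)), dist <= radius_vox


def edt_oracle(mask):
    """Maximal-inscribed-sphere oracle: EDT maximum with a distance-weighted
    sub-voxel centroid of the near-maximal plateau."""
    edt = ndimage.distance_transform_edt(mask)
    mx = float(edt.max())
    pts = np.argwhere(edt >= mx - 1.0)
    w = edt[tuple(pts.T)] - (mx - 1.0)
    center = (pts * w[:, None]).sum(axis=0) / w.sum()
    return center, mx


def random_orthonormal(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def junction_case():
    """Y-junction phantom with a ground-truth bifurcation landmark."""
    spec = vm.y_junction_spec(extent_mm=60.0)
    vol, landmarks = vm.make_vessel_phantom(spec, spacing_mm=1.0)
    return vol, landmarks[0], spec
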