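import numpy as np
import pytest

import lapdepth as ld


@pytest.fixture(scope="session")
def smooth_scene() -> ld.GroundTruthScene:
    """A noiseless 96x96 scene with a smooth disparity surface in [2, 12]."""
    return ld.make_scene(96, 96, 2.0, 12.0, seed=11)


@pytest.fixture(scope="session")
def matched_scene(smooth_scene):
    """The smooth scene plus its full AD-CENSUS matching outputs."""
    params = ld.StereoParams(d_min=1, d_max=14)
    d_l, d_r, vol_l, vol_r = ld.match_stereo(smooth_scene.pair, params)
    return smooth_scene, d_l, d_r, vol_l, vol_r


@pytest.fixture(scope="session")
def constant_scene() -> ld.GroundTruthScene:
    """A noiseless scene whose disparity is exactly 5 px everywhere; the
    rendered right view is then an integer column shift of the left, so
    warps reproduce it without interpolation error."""
    tex = ld.make_texture(64, 64, octaves=4, seed=7)
    disp = np.full((64, 64), 5.0)
    pair, validity = ld.render_stereo_pair(tex, disp, noise_sigma=0.0, seed=0)
    camera = ld.CameraModel(fx=150.0, fy=150.0, cx=32.0, cy=32.0, baseline=4.0)
    return ld.GroundTruthScene(texture=tex, gt_disparity=disp,
                               validity=validity, camera=camera, seed=7,
                               pair=pair)
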