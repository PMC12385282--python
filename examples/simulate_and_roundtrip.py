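"""Generate a scene, write it as ENVI BIL cubes, and read it back.

Shows the file-based workflow: the generator writes raw/white/dark
detector-count cubes plus pure reference spectra; reading them back and
calibrating recovers the ground-truth reflectance.
"""

import tempfile
from pathlib import Path

import numpy as np

from pestmap import calibrate_reflectance, read_cube, write_cube
from pestmap.io import read_reference_spectrum
from pestmap.synthetic import (
    CHLORFENAPYR_ENDMEMBER,
    LEAF_ENDMEMBER,
    SceneSpec,
    default_wavelength_grid,
    make_reference_spectra,
    make_scene,
)

scene = make_scene(SceneSpec(shape=(16, 16), noise_sd=0.0, seed=1))

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    for role in ("raw", "white", "dark"):
        write_cube(getattr(scene, role), tmp / f"{role}.bil", "envi")
    cubes = {role: read_cube(tmp / f"{role}.bil", "envi")
             for role in ("raw", "white", "dark")}
    refl = calibrate_reflectance(cubes["raw"], cubes["white"], cubes["dark"])
    err = np.abs(refl.values - scene.truth.values).max()
    print(f"cube shape {refl.shape}, "
          f"{refl.wavelengths[0]:.0f}-{refl.wavelengths[-1]:.0f} nm")
    print(f"max |calibrated - truth| after ENVI round trip: {err:.2e}")

    paths = make_reference_spectra([LEAF_ENDMEMBER, CHLORFENAPYR_ENDMEMBER],
                                   default_wavelength_grid(), tmp / "refs")
    wl, refl_leaf = read_reference_spectrum(paths[0])
    print(f"reference library: {[p.name for p in paths]}, "
          f"{len(wl)} points per spectrum")
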