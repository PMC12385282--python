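"""Test whether residue abundance differs between concentration levels.

Unmixes one scene per concentration level (residue abundance scaled with
the level), collects the per-pixel residue abundances, and runs
Mann-Whitney U tests between consecutive levels.  A significant p-value
(< 0.05) means the abundance distributions of adjacent levels are
distinguishable.
"""

from pestmap.stats import consecutive_level_tests
from pestmap.synthetic import SceneSpec, make_scene
from pestmap.unmixing import MCRConfig, fit_mcr_als, match_components

levels = (0.02, 0.04, 0.06)
groups = {}
for i, level in enumerate(levels):
    scene = make_scene(SceneSpec(shape=(32, 32), noise_sd=0.01,
                                 residue_scale=level / 0.06, seed=20 + i))
    dm = scene.truth.values.reshape(-1, len(scene.wavelengths))
    res = fit_mcr_als(dm, MCRConfig(n_components=2))
    residue_idx = match_components(res.S, scene.S[1:2])[0]
    groups[level] = res.C[:, residue_idx]

table = consecutive_level_tests(groups, ordered_levels=levels)
print(table.to_string(index=False))
print("\nAll consecutive pairs significant:", bool(table["significant"].all()))
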