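"""Generate a dual-stain phantom slide pair with known ground truth.

The generator emulates serial sectioning: one tissue geometry rendered
under two stain appearances, the source displaced by a known similarity
transform.  The printed transform is what every registration step is later
judged against.
"""

import slidealign as sa

spec = sa.PhantomSpec(seed=11, canvas=(2048, 2048), n_glands=8,
                      gland_radius=(40, 90), angle_deg=-9.0, scale=1.05,
                      shift_xy=(40.0, -25.0))
target, source, gt = sa.make_pair(spec)

print("pyramid levels (small -> base):",
      [(li.width, li.height) for li in target.levels])
print(f"global registration level l_low = {gt.l_low} "
      f"({target.level_info(gt.l_low).width} px wide)")
print(f"true transform at l_low: S = {gt.transform.S}, "
      f"angle = {gt.transform.angle_deg:.1f} deg, "
      f"T (y, x) = ({gt.transform.T[0]:.1f}, {gt.transform.T[1]:.1f})")
print(f"{len(gt.landmarks_target_xy)} ground-truth landmark pairs "
      "(gland centers) at the base level")
# The landmark pairs satisfy the transform exactly up to the (zero here)
# jitter amplitude — they stand in for expert annotations.
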