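"""Simulate a multi-view light-sheet acquisition.

Builds a bead+vessel phantom and images it from 12 angles (30° steps)
with an axially elongated Gaussian PSF, each view carrying a random
rigid misalignment — the synthetic stand-in for a rotated-sample LSFM
session.
"""

from corrtomo import study_phantom, study_views

phantom = study_phantom(seed=1)
views = study_views(seed=1)

print(f"phantom: {phantom.shape} voxels, total signal {phantom.sum():.1f}")
print(f"views:   {len(views)} stacks at angles {views.angles.tolist()}")
print("per-view misalignment shifts (voxels):")
for phi, m in zip(views.angles, views.true_shifts):
    print(f"  {phi:5.0f} deg  shift {m}")
# The reference view (0 deg) is pinned at zero shift; all others carry
# the random rigid offsets that classical fusion would have to estimate.
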