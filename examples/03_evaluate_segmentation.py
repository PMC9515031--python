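"""Fuse a noisy segmentation ensemble and evaluate it against ground truth.

Three jittered copies of a cartilage shell stand in for per-plane network
predictions. They are combined by voxelwise majority vote, cleaned by
largest-connected-component extraction, and scored against the clean mask
with Dice, Hausdorff distance and average surface distance.
"""

from hipcart import (
    avg_surface_distance,
    dice,
    hausdorff,
    largest_component,
    majority_vote,
    make_shell_phantom,
)
from hipcart.phantom import PhantomTruth


def shell(noise_sd=0.0, seed=0):
    truth = PhantomTruth(polar_range=(20.0, 110.0), azimuth_range=(-80.0, 80.0))
    _, mask, _ = make_shell_phantom(truth, spacing=(1.0, 1.0, 1.0),
                                    noise_sd=noise_sd, seed=seed)
    return mask


clean = shell()
planes = [shell(noise_sd=0.5, seed=s) for s in (1, 2, 3)]
fused = largest_component(majority_vote(planes))

print(f"Dice similarity coefficient: {100 * dice(fused, clean):.1f} %")
print(f"Hausdorff distance:          {hausdorff(fused, clean):.2f} mm")
print(f"average surface distance:    {avg_surface_distance(fused, clean):.2f} mm")
print("\nMajority voting suppresses the independent per-plane surface jitter:"
      "\nthe fused mask overlaps the truth far better than any single copy"
      f"\n(single-copy Dice: {100 * dice(planes[0], clean):.1f} %).")
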