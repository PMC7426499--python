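"""Measure the pedunculus dimming ratio R = x/y on brain phantoms.

Stacks are uniform except for a darkened pedunculus disk of known contrast
in three slices.  x is the mean intensity of a square ROI on the Ped, y the
mean of the equal-size ROI above it, both averaged over the three
most-dimmed slices; R < 1 quantifies the local signal decrease.
"""
from flysla import BrainPhantomParams, ROISpec, batch_ratios, ped_ratio, synth_brain_stack

spec = ROISpec(top_left=(54, 42), side=12, offset=24)

one = ped_ratio(synth_brain_stack(
    BrainPhantomParams(ped_contrast=0.6, noise_sd=3.0, seed=0)), spec)
print(f"single brain: x = {one.x:.1f}, y = {one.y:.1f}, R = {one.R:.3f} "
      f"(rendered contrast 0.6), slices used {one.slices_used}")

dim = [synth_brain_stack(BrainPhantomParams(ped_contrast=0.5, noise_sd=3.0, seed=s))
       for s in range(8)]
flat = [synth_brain_stack(BrainPhantomParams(ped_contrast=1.0, noise_sd=3.0, seed=100 + s))
        for s in range(8)]
table, test = batch_ratios(dim + flat, spec, ["dimmed"] * 8 + ["uniform"] * 8)

print("\nper-group mean R:")
print(table.groupby("group")["R"].mean().round(3).to_string())
print(f"\nWelch t-test between groups: p = {test['p']:.2e}, tier {test['tier']}")
print("(a contrast-0.5 pedunculus separates from uniform brains decisively "
      "at n = 8 per group)")
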