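"""Full single-field pipeline on a synthetic two-population scene.

Simulates a 64x64 FLIM field with oxidative and glycolytic cells on a
dark background, segments the cells from the NAD(P)H intensity, fits
one aggregated decay per cell, and prints the per-cell table next to
the generator's ground truth.
"""

from flimmet import (
    ChannelImages,
    SceneSpec,
    TcspcCube,
    analyze_scene,
    simulate_flim_scene,
)

scene = simulate_flim_scene(SceneSpec(shape=(64, 64), n_cells=4, seed=3))
cube = TcspcCube(counts=scene.counts, axis=scene.axis)
channels = ChannelImages(nadph=scene.nadph, fad=scene.fad)

result = analyze_scene(cube, channels, mode="roi")
cols = ["label", "n_pixels", "tau_avg", "bound_fraction", "reduced_chi2", "orr"]
print(result["table"][cols].round(3).to_string(index=False))

print("\nground truth per planted cell:")
for i, (pop, tau, orr) in enumerate(
    zip(scene.cell_population, scene.cell_tau_avg, scene.cell_orr), start=1
):
    print(f"  cell {i}: {pop:11s} tau_avg={tau:.3f} ns  orr={orr:.3f}")
# Each segmented ROI's fitted tau_avg and ORR should match one planted
# cell within a few percent; oxidative cells show the larger values.
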