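"""Three-component lifetime unmixing of a synthetic organelle scene.

Builds the default scene — a Golgi-like ring labeled at 5.9 ns, an
elliptical nucleus at 5.5 ns and scattered mitochondria/vesicle-like dots
at 1.4 ns — simulates the time-resolved photon-count stack, and unmixes
every above-threshold pixel into the three lifetime species by the phasor
method.
"""

import numpy as np

from pocketflim import default_scene, simulate_flim_image, unmix_image

spec = default_scene(seed=1)
stack, truth = simulate_flim_image(spec)
taus = [tau for _, tau in spec.components]

result = unmix_image(stack, ref_lifetimes=taus, period=spec.period,
                     intensity_threshold=100)

majority = np.nan_to_num(result.fractions, nan=-1).argmax(axis=0)
labeled = (truth["component_index"] >= 0) & result.mask
accuracy = (majority[labeled] == truth["component_index"][labeled]).mean()

print(f"stack shape                 : {stack.shape} (time bins, Y, X)")
print(f"pixels above threshold      : {int(result.mask.sum())}")
for i, (name, tau) in enumerate(spec.components):
    n = int(((majority == i) & result.mask).sum())
    print(f"  component {name:10s} ({tau} ns): {n} majority pixels")
print(f"majority assignment accuracy: {accuracy:.3f}")
print(f"mean out-of-triangle residual: {result.residual[result.mask].mean():.4f}")
print()
print("Accuracy is the fraction of analyzed pixels whose dominant recovered")
print("species matches the simulated ground truth; 1.0 would be perfect")
print("unmixing of the three lifetime channels.")
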