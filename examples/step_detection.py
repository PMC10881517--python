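"""Unfolding-step detection and step-height mixture fitting.

Synthesises clamp traces in which domain unfolding injects discrete
height gains accompanied by brief force spikes (~0.16 s), detects the
steps with the 3-sigma force-drop detector, pools the recovered heights
and fits a Gaussian mixture to find the characteristic step sizes.
"""

import numpy as np

from tipbond import detect_steps, fit_step_height_mixture
from tipbond.params import INTERFACE_WT, UNFOLDING_CLASSES_EC1_27
from tipbond.synth import TraceRecipe, generate_trace

classes = [
    (5.3, 0.3, UNFOLDING_CLASSES_EC1_27["5nm"]),
    (11.5, 0.2, UNFOLDING_CLASSES_EC1_27["12nm"]),
]

heights = []
n_traces = 400
for seed in range(n_traces):
    recipe = TraceRecipe(
        clamp_force=58.0, kinetic_params=INTERFACE_WT, step_classes=classes
    )
    trace = generate_trace(recipe, seed=seed)
    try:
        events = detect_steps(trace)
    except ValueError:
        continue  # trace dissociated before a clean plateau formed
    # overlapping feedback transients merge into one long spike carrying
    # the summed height gain; exclude them from the class statistics
    heights.extend(
        e.height_gain for e in events if e.spike_duration < 0.25
    )

heights = np.array(heights)
print(f"detected {heights.size} unfolding steps in {n_traces} traces")

fit = fit_step_height_mixture(heights, n_components=2)
for mean, err, w in zip(fit.means, fit.mean_errors, fit.weights):
    print(f"  step class at {mean:5.2f} +- {err:.2f} nm (weight {w:.2f})")
print("The two populations recover the ~5 nm (inter-domain linker) and "
      "~12 nm (partial domain) extensions fed into the generator.")
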