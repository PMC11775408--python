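"""One lesion, two scanners.

Generates a single fissured lesion with low-contrast tract extensions,
observes it with a 7T-like isotropic acquisition and a clinical-like
thick-slice acquisition, and prints the markers side by side. The
clinical arm fills in narrow surface fissures and loses the faint
extensions, so it reads smaller and smoother — the effect the paired
cohort analysis quantifies.
"""

from lesionshape import (
    AcquisitionSpec,
    SyntheticLesionSpec,
    compute_markers,
    degrade_acquisition,
)
from lesionshape.synthetic import generate_lesion_image

spec = SyntheticLesionSpec(
    base_radius=16.0, spike_amplitude=0.6, spike_count=20,
    tendril_count=3, tendril_length=10.0, tendril_radius=2.5,
    bridge=True, bridge_radius=1.2, bridge_length=20.0, seed=4,
)
truth, intensity = generate_lesion_image(spec, grid_spacing=0.4)

highquality = degrade_acquisition(
    truth, AcquisitionSpec((0.75, 0.75, 0.75), (1.0, 1.0, 1.0), seed=1),
    intensity)
clinical = degrade_acquisition(
    truth, AcquisitionSpec((0.4, 0.4, 5.0), (2.8, 2.8, 6.0), seed=2),
    intensity)

print(f"{'marker':<18}{'truth':>9}{'7T-like':>10}{'clinical':>10}")
rows = []
for name, mask in (("truth", truth), ("7T-like", highquality),
                   ("clinical", clinical)):
    rows.append(compute_markers(mask, target_spacing=0.5))
for attr, label in [("volume_ml", "volume (mL)"),
                    ("convexity", "convexity"),
                    ("solidity", "solidity"),
                    ("concavity_index", "concavity index"),
                    ("fractal_dimension", "fractal dim."),
                    ("n_components", "components")]:
    vals = [getattr(r, attr) for r in rows]
    print(f"{label:<18}" + "".join(f"{v:>10.3f}" if isinstance(v, float)
                                   else f"{v:>10d}" for v in vals))
print("\nThe thick-slice arm loses the thin cross-midline bridge (the "
      "component count rises as its distal blob detaches) and reads "
      "more convex/solid and less fractal than the 7T-like arm.")
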