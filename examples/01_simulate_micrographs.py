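"""Simulate a small few-shot picking dataset with known ground truth.

Builds one reference micrograph (whose labeled particles act as the
few-shot exemplars) plus two query micrographs sharing the same particle
motif, and writes MRC images + STAR coordinate files.
"""

from maepick import SimParams, empirical_snr, make_dataset

params = SimParams(image_height=512, image_width=512, particle_diameter=48,
                   n_particles=16, snr=1.0, min_center_distance=56.0, seed=1)
bundle = make_dataset(params, n_query=2, n_exemplars=10)

print(f"reference: {bundle.reference.micrograph_id}, "
      f"{len(bundle.reference_truth.centers)} particles, "
      f"{len(bundle.exemplar_centers)} labeled as exemplars")
for mic, gt in bundle.queries:
    print(f"query: {mic.micrograph_id}, {len(gt.centers)} particles")

# the generator scales the noise so the footprint signal-to-noise
# variance ratio matches the request (estimate is contaminant-biased)
print(f"requested snr {params.snr:.2f}, "
      f"empirical estimate {empirical_snr(bundle.reference.image, bundle.reference_truth):.2f}")

out = bundle.save("scratch/example_data")
print(f"wrote MRC + STAR files to {out}/")
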