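"""Build the K x K first-nearest-neighbour peak-distance matrix.

Runs the full per-sample analysis on a 5-channel scene and prints the peak
matrix: entry (i, j) is the mode of the distance histogram from each channel
i binding site to its nearest channel j site. Motif-linked channel pairs
peak at the few-nm class scale; unlinked pairs peak at the ~1/sqrt(2*pi*
density) spacing of unrelated sites.
"""

import numpy as np

import glycoatlas as ga

spec = ga.SceneSpec(
    seed=3,
    motifs=[ga.Motif(("SNA", "WGA"), 1.0)],
    motif_fraction=0.3,
)
channels, _ = ga.generate_scene(spec)
res = ga.analyze_channels(channels, spec.roi)

print("NN peak matrix (nm, row = source channel, column = target):")
print(res.peak_matrix.to_frame().round(1).to_string())

lam = spec.density_of("AAL")  # µm^-2, no motif partner for AAL
print(f"\nCSR expectation for an unlinked intra-channel pair: "
      f"1/sqrt(2*pi*lambda) = {1/np.sqrt(2*np.pi*lam*1e-6):.0f} nm "
      f"at lambda = {lam} /um^2")
print("SNA->WGA and WGA->SNA peak in the first bins: ~30% of those sites "
      "sit in planted SNA+WGA pairs a few nm apart.")
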