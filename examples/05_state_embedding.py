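"""Separate two synthetic cellular states by PCA on glycan features.

Generates 6 samples per state (state B carries a global remodelling
signature: doubled SNA+WGA class density, reduced AAL+PSA+WGA, and
channel-specific site-density shifts), runs the full pipeline on each,
assembles NN-peak and GlyCo-density feature matrices, and reports the PC1-2
silhouette between states plus the features with the largest loadings.

Runtime: about a minute (12 five-channel scenes).
"""

import numpy as np

import glycoatlas as ga

config = ga.RunConfig(samples=[], out_dir="", nn_smooth_bins="auto", nn_range_nm=500.0)
analyses, conditions = [], []
for spec, cond in ga.simulate.two_condition_panel_specs(seed=2026, n_per_condition=6):
    scene, _ = ga.generate_scene(spec)
    analyses.append(ga.analyze_channels(scene, spec.roi, config))
    conditions.append(cond)
print(f"analyzed {len(analyses)} samples: {conditions}")

for mode in ("nn_peaks", "glyco"):
    objs = [a.glyco_table if mode == "glyco" else a.peak_matrix for a in analyses]
    fm = ga.assemble_features(objs, mode, condition_labels=conditions)
    emb = ga.run_pca(fm)
    sil = ga.separation_score(emb)
    print(f"\n[{mode}] {fm.values.shape[1]} features, "
          f"explained variance {np.round(emb.explained_variance_ratio, 2)}, "
          f"silhouette(A vs B on PC1-2) = {sil:.2f}")
    top = ga.loadings_report(emb, top_n=3)
    print("top PC1 loadings (|correlation| with the score):")
    print(top[top["component"] == 1].to_string(index=False))
# A silhouette well above 0 (and far above label-permuted values) means the
# unsupervised embedding recovers the planted state difference; the top
# loadings name the glycan features that drive it.
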