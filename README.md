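# glycoatlas

Quantitative "glycan atlassing" for multiplexed DNA-PAINT microscopy of the
cell-surface glycocalyx: from per-channel single-molecule localization
tables to lectin binding sites, first-nearest-neighbour (NN) peak-distance
matrices, GlyCo glycan-class tables, and PCA embeddings that separate
cellular states. A synthetic scene generator with full ground truth makes
every stage testable without experimental data.

## Who this is for

Groups doing Exchange-PAINT–style multiplexed imaging of glycans (lectin
panels such as WGA, SNA, PHA-L, AAL, PSA, plus a metabolic DBCO channel)
who need the post-reconstruction half of the analysis: registration, site
calling, spatial statistics and state comparison. Input is any
Picasso-compatible HDF5 localization table (`locs` dataset with
`frame/x/y/photons` in camera pixels) or an equivalent CSV, plus a polygon
ROI; everything downstream works in nanometres.

## The method

1. **Registration** — 90-nm gold beads, localized in every frame, give a
   per-frame drift trace (mean bead displacement about its time average,
   subtracted per localization) and a rigid inter-channel transform
   (least squares on matched bead positions; translation by default).
   Bead localizations are then removed and the polygon ROI is applied.
2. **Precision** — for each channel, the distance from every localization
   in frame *t* to its nearest neighbour in frame *t* + 1 follows
   *p*(*d*) = *d*/(2σ²)·exp(−*d*²/(4σ²)) for same-molecule pairs (σ = per-axis
   localization precision); fitting this plus a linear background to the
   1-nm-binned histogram gives the NeNA-style σ per channel.
3. **Site calling** — localizations are clustered as connected components
   of the distance ≤ 2σ graph; clusters need ≥ 2 localizations; a cluster
   is rejected as unspecific sticking if one 200-frame bin (1% of the
   20,000-frame stack) holds > 90% of its events. Surviving cluster
   centres are the lectin binding sites.
4. **NN analysis** — for every ordered channel pair (*i*, *j*), including
   *i* = *j* with self exclusion, the first-NN distance histogram's peak is
   collected into a K × K matrix (5 × 5, or 6 × 6 with DBCO).
5. **GlyCo classes** — all channels' sites are pooled and grouped at a
   5-nm cut-off (single-linkage components); each group of ≥ 2 sites forms
   a class labelled by the multiset of its channels (e.g. `AAL+WGA+WGA`),
   counted and normalized to densities per µm² of ROI.
6. **State embedding** — per-sample features (flattened peak matrix, class
   densities, or full normalized NN distributions) are z-scored across
   samples and embedded by PCA; loadings are reported as feature–score
   correlations and condition separation as the silhouette on PC1–2.

## Worked example

```python
import glycoatlas as ga

spec = ga.SceneSpec(seed=7, channels=("WGA",), site_density_per_um2=10.0,
                    drift_mode="none")
channels, truth = ga.generate_scene(spec)
table = channels["WGA"]
table = ga.apply_drift(table, ga.estimate_drift(ga.detect_fiducials(table),
                                                table.n_frames))
table = ga.remove_fiducial_localizations(table, ga.detect_fiducials(table))
table = ga.clip_to_roi(table, spec.roi)
est = ga.estimate_precision(table)
sites, report = ga.call_sites(table, ga.ClusterParams(est.clustering_radius_nm))
print(ga.truth_match(sites, truth.sites_by_channel["WGA"], 10.0))
```

prints (examples/02, trimmed):

```
NeNA precision: sigma = 5.06 nm from 13372 adjacent-frame pairs (planted noise was 5.0 nm)
clusters: 660 raw, 11 rejected as sticking, 649 sites
vs truth: recall 99.8%, precision 99.8%, centre RMSE 1.48 nm
```

The recovered σ matches the planted 5-nm noise; sites are found with ~100%
recall/precision, and the centre error beats single-localization precision
by ~√n_locs because each centre averages ~30 localizations. The
`examples/` directory walks through every capability (scene simulation,
registration + site calling, the peak matrix, GlyCo classes, and the
two-condition PCA embedding); each script prints its numbers with a line on
what they mean. A thin CLI mirrors the pipeline
(`glycoatlas simulate|register|precision|cluster|nn|glyco|embed|run`).

## Layout

```
src/glycoatlas/      core (I/O + data model), registration, roi, precision,
                     sites, nn, glyco, embedding, simulate, pipeline, cli
examples/            one narrative script per capability
tests/               pytest suite (unit, property and end-to-end checks)
docs/methods.md      models, parameters, assumptions, limitations
```
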