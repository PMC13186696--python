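# Methods

This note documents the models, parameter choices and numerical decisions
behind `glycoatlas`, and what the synthetic-data validation does and does
not establish about real data.

## Data model and units

A localization table holds one channel's fitted single-molecule positions
(`frame`, `x_nm`, `y_nm`, `photons`). Coordinates are 64-bit nanometres in
image convention (origin upper-left, y downward); frames are 0-based. On
disk, coordinates are camera pixels (Picasso-compatible HDF5 `locs` dataset
or CSV) and are multiplied by the effective pixel size — default 130 nm,
matching a 100× objective with 2×2 camera binning — at load time, so no
downstream module ever sees pixel units. A YAML sidecar carries
`n_frames` (default 20,000, i.e. ~33 min at 100 ms frames),
`pixel_size_nm` and the channel label; write/read round trips are exact to
float64. Records with non-finite coordinates are dropped with a logged
count (or rejected outright in strict mode); nothing else creates or
destroys localizations.

## Registration

Gold beads (90 nm) are detected as emitters present in ≥ 50% of frames
(`min_presence_fraction`); candidates come from a coarse occupancy grid at
the 500-nm link radius, refined to one localization per frame (nearest to
the anchor). The drift trace is the across-bead mean of each bead's
displacement from its own time average, linearly interpolated over missed
frames with end values held, then re-centred to zero mean. Re-centring
makes the correction translation-free but leaves the field offset by the
mean applied drift — irrelevant to every downstream statistic (all are
translation-invariant) but worth knowing when comparing against absolute
ground-truth positions.

Channel alignment matches bead time-averages greedily by ascending distance
(pairing radius 500 nm) and fits a least-squares transform. Default is
translation-only: sequential imaging on one objective has negligible
rotation, and with 3–4 beads the extra parameter only adds variance; a
closed-form 2D Procrustes (rotation + translation) mode is available.
Bead-adjacent localizations (within the link radius) are removed before
analysis — beads are not glycan signal.

## Localization precision (NeNA-style)

A molecule localized in consecutive frames yields two draws from the same
position, so the adjacent-frame NN distance of same-molecule pairs follows
p(d) = d/(2σ²)·exp(−d²/(4σ²)) — Rayleigh with scale √2σ. The estimator
histograms, at 1-nm bins on [0, 100 nm], the distance from each
localization in frame t to its nearest neighbour in frame t+1, and fits a
two-component mixture: the same-molecule term with weight w plus a linearly
rising background 2d/max_d² (unrelated molecules uniform in the plane) with
weight 1 − w, by nonlinear least squares (σ bounded in (0, max_d/2]).
The background parameterization is a deliberate choice among published
variants; it is validated by synthetic recovery (planted σ ∈ {2, 5, 10} nm
recovered within a few percent from 50k pairs, within ~15% under 30%
background). Estimates with background fraction > 0.5 are flagged
unreliable. The fit needs ≥ 500 pairs; at realistic event rates
adjacent-frame pairs come from binding events spanning several frames,
which the scene generator reproduces (below). The clustering radius passed
downstream is 2σ̂ per channel.

## Site calling

Clustering is fixed-radius connected components: localizations within 2σ̂
are linked, components with < 2 members are dropped. Components are the
minimal assumption-free reading of a radius-plus-minimum-size rule,
equivalent to DBSCAN with min_samples = 2 where all points are core, and
admit an exact brute-force oracle (the test suite checks partition equality
against O(n²) union-find).

The temporal filter rejects a cluster if any fixed time bin — consecutive,
non-overlapping, anchored at frame 0, length 1% of the stack (200 frames at
20,000) — holds > 90% of the cluster's events. Note the rule's literal
consequences, both implemented as stated: a 2-event cluster with both
events in one bin is rejected, and a long-lived sticking event whose
lifetime straddles a bin boundary (splitting its events, say, 60/40) is
*not* rejected. Surviving cluster centres (unweighted coordinate means) are
the binding sites, with n_locs and first/last frame recorded; sites are
sorted by (x, y) so output is independent of input record order.

## NN analysis

For each ordered channel pair the first-NN distances (self excluded on the
diagonal) are histogrammed at 1-nm bins over [0, 200 nm] and the peak —
the mode — is reported at the centre of the winning bin. Peak finding runs
on an edge-normalized centred moving average (default 5 bins); raw counts
are stored. Tie-breaks: among equal smoothed maxima, the bin with the
larger raw count wins, then the smaller distance (a moving average turns an
isolated spike into a plateau, and raw counts recover the true bin).

Two estimator caveats are documented rather than hidden. First, a
histogram mode converges extremely slowly (error ~ n^(−1/7)), so for broad
distributions the fixed 5-bin window under-smooths badly;
`smooth_window_bins="auto"` scales the window to half the sample standard
deviation, which stabilizes the mode at the cost of a small (~2–4%)
smoothing bias, and is the right choice whenever the distribution's width
is tens of bins. Second, the histogram range must cover the spacings
actually present: at site densities below ~6 µm⁻² the intra-channel mode
(1/√(2πλ) under CSR) approaches 200 nm and the default range truncates it —
raise `nn_range_nm` accordingly (the two-condition demo panel uses 500 nm).
Missing pairs (empty channel) are flagged NaN in the K × K matrix and
imputed by the per-feature cross-sample mean at embedding time. The full
ordered (asymmetric) matrix is kept; no symmetrization.

## GlyCo classes

All channels' sites are pooled and grouped by single-linkage connected
components at the 5-nm cut-off — a site joins a group via *any* member
within 5 nm, the unique deterministic closure of a pairwise threshold, and
same-channel pairs group too. Each component of ≥ 2 sites is one class
instance; the class label is the multiset of member channels, canonicalized
by sorting (`AAL+WGA+WGA`). Geometry within a group does not affect class
identity. Each site belongs to exactly one instance (hard partition);
singletons are counted but form no class. Densities divide instance counts
by the polygon ROI area (shoelace, nm² → µm²; boundary points count as
inside). Chained components larger than any planted motif are possible in
principle and are kept whole rather than split.

## State embedding

Feature modes per sample: `nn_peaks` (K² flattened peaks), `glyco` (union
of class labels across samples, density per µm², absent = 0), `nn_full`
(all K² histograms, each normalized to sum 1, concatenated). Features are
z-scored across samples (they mix nm and µm⁻²; loadings-as-correlations
presumes standardized inputs), zero-variance columns are dropped, and PCA
runs on the standardized matrix (full SVD, default 2 components, capped at
min(n − 1, p)). Components are sign-fixed so the largest-|loading| feature
is positive. Loadings are computed directly as Pearson correlations between
each standardized feature and each score. Separation between conditions is
the mean silhouette on the first two PC scores; single-sample conditions
are excluded with a warning.

A structural fact worth stating: after z-scoring, a condition difference
confined to a *single* feature gives that feature a correlation-matrix
eigenvalue of exactly 1, below the noise eigenvalues that p ≳ n sample
correlation matrices always have (Marchenko–Pastur), so unsupervised PCA
cannot isolate it. Separability requires the condition to shift several
features coherently — which is also what real cellular state changes do.

## Synthetic scenes

The generator emulates the acquisition the pipeline expects, with full
ground truth. Defaults (the study conditions for all validation): 10 × 10
µm field with a 1-µm margin, rectangular cell ROI inside it, a 5-lectin
panel at 10 sites/µm² per channel, 20,000 frames, Poisson(10) binding
events per site (≥ 2 so every site is in principle detectable), uniform
event start times, geometric event duration with mean 3 frames (~300 ms
bright time) and one independently-noised localization per bright frame,
isotropic Gaussian noise σ = 5 nm, linear drift (0.01, −0.007) nm/frame
(~200 nm over the stack; random-walk and none available), 4 gold beads with
2-nm jitter placed ≥ 600 nm outside the ROI (so their 500-nm exclusion
discs cannot eat signal), and 0.2 µm⁻² sticking artifacts per channel
emitting ~30 events inside one 200-frame window. Background sites and
motif anchors are placed by dart throwing with a 50-nm hard-core minimum
separation — resolvable by construction at 2σ clustering radii and far
beyond the 5-nm class cut-off, so planted classes are exactly recoverable
from true positions. Motif members sit within a 4-nm radius of their
anchor (internal spacing uniform in [1, 4] nm); a stress mode up to 8 nm
probes the cut-off boundary. Sticking windows are bin-aligned by default:
the fixed-bin filter cannot reject a window that straddles a bin boundary,
and a real minutes-long sticker fills whole bins anyway; unaligned
placement is available to measure exactly that operating characteristic.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: Markov blinking kinetics (no imager-concentration
dependence, no photophysics), photon-count–dependent precision, non-rigid
or chromatic registration errors, inhomogeneous site densities (membrane
domains), 3D structure, and detection/fitting artifacts upstream of the
localization table.

The two-condition demo panel (`two_condition_panel_specs`) plants a global
remodelling signature: state B doubles the SNA+WGA class density, lowers
AAL+PSA+WGA to ~0.7×, and shifts every channel's site density by its own
factor (PHA-L spacing ×1.5, AAL ×1.25, SNA ×1.1, PSA ×0.83, WGA ×0.91)
over ~100 µm² ROIs, six samples per state. Those scenes should be analyzed
with `nn_range_nm=500` and adaptive smoothing, for the reasons above.

## Problem sizes and numerics

Validation runs at desk scale: oracle equivalence on 100 scenes up to
2,000 points; precision recovery from 50,000 pairs; filter operating
characteristics on 1,000 + 1,000 planted clusters; site calling on ~600-site
scenes; CSR closed-form checks at λ ∈ {10, 50, 100} µm⁻² with 10⁵-plus
points; the embedding panel on 12 five-channel scenes of ~800 sites per
channel. Determinism: one root seed drives all generation
(`numpy.random.default_rng`); identical seeds give bit-identical tables,
and a full pipeline rerun on identical inputs produces byte-identical CSVs
(verified by SHA-256 in the manifest). Degenerate inputs raise typed
errors (degenerate polygons, < 2 occupied frames, empty NN targets,
all-out-of-range histograms, zero ROI area) rather than returning silent
zeros.

## Known limitations

* The histogram-mode "peak" is a high-variance statistic at realistic
  per-cell site counts; the auto bandwidth mitigates but does not remove
  this. Full-distribution features (`nn_full`) avoid the mode entirely.
* Fiducial detection assumes beads are separated by more than the link
  radius and present near-continuously; dense bead clusters would merge.
* The temporal filter's fixed bins miss window-straddling stickers (by the
  rule's own construction, see above).
* Drift correction is per-channel and residual-only; severe intra-frame
  drift or redundant cross-correlation pre-correction is out of scope.
* GlyCo grouping is single-linkage: at cut-off-scale site densities,
  chaining can merge distinct glycans; the hard partition assigns each
  site to one class only.
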