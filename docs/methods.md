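# Methods

This note documents the models, conventions and numerical choices behind
`ca1quant`, and what the synthetic generators do and do not emulate.

## Morphometry

A reconstruction is a rooted tree of 3D points with SWC compartment labels;
the apical tree is the subtree of apical-labelled nodes rooted at the stem
nearest the soma, with cumulative path distances measured from the soma node
(the soma→stem segment is included in lengths and distances).

**First prominent bifurcation.** Walking the primary apical path from the
root (at each branch point following the daughter with the greater total
subtree length, ties to the lower node id), a bifurcation is *prominent*
when the smaller daughter carries at least `prominence_frac` (default 0.2)
of the remaining apical length. This skips trivial twigs; if no node
qualifies, the distal-most bifurcation is returned with a flag. The default
fraction was chosen so that a 5 µm filopodial stub on a 450 µm trunk never
counts while any split with a ≥ 1:4 length ratio does.

**LRI / ORI.** At the selected node with soma path length `L_p`, daughter
subtree lengths `L_d` and daughter bifurcation counts `N_d`:

    LRI = ln(ΣL_d / L_p)
    ORI = ln((ΣN_d + n_daughters) / (N_p + 1))

where `N_p` counts the non-prominent bifurcations skipped proximal to the
node. When `L_p > D0` (default 150 µm) both indices are scaled by
`D0 / L_p`, down-weighting cells whose first substantial branch point sits
unusually far from the soma. Both formulas are configuration hooks
(`IndexConfig.lri_fn` / `ori_fn`) so an alternative index definition can be
swapped in without touching the classification contract: complex cells
score high on both axes. The indices are functions of path lengths and
counts only, hence exactly invariant to rigid motion of the coordinates.

**Sholl.** Crossings of concentric spheres centred on the soma centroid,
counted segment-wise (a segment crosses radius r when one endpoint is
inside and the other at or beyond r). Default step 20 µm; apical tree only.

## Clustering

Morphological classification is k-means with k = 2 on the (LRI, ORI) plane
(Lloyd's algorithm, k-means++ initialization, best of 50 restarts,
deterministic under a seed). Cluster indices are fixed post hoc by ordering
centres by descending coordinate sum — cluster 0 is always the "high"
(complex) group — never by initialization. Physiological clustering
z-scores the eight intrinsic features (they span mV, MΩ and Hz scales;
unscaled, input resistance dominates the distances), projects onto the top
two principal components (sign fixed by making each loading's
largest-magnitude entry positive), and clusters the scores. Cells missing
any feature are dropped with a logged reason. The elbow diagnostic reuses
the k−1 solution as a warm start so the WSS curve is non-increasing by
construction. Concordance between two labelings is the best
cluster-index pairing of the contingency table.

## Intrinsic properties and pharmacology

Conventions (all configurable): resting potential is the mean of a
≥ 100 ms zero-current baseline; the sag index is ΔV_ss/ΔV_peak with the
steady state taken as the last 20% of a hyperpolarizing step (1 = no sag);
input resistance is the through-origin least-squares slope of steady-state
ΔV against ΔI; spike threshold is the voltage at the first upward crossing
of dV/dt ≥ 20 mV/ms (the sample on the subthreshold side of the crossing);
amplitude is peak − threshold; AHP is the positive magnitude
threshold − minimum within 20 ms of the peak; the adaptation ratio is the
last inter-spike interval over the first; the 2×-threshold firing rate is
spike count over step duration. Series-resistance QC fails a cell when
(max − min)/min exceeds 30% over the recording.

Wash-in outcomes are `100 × mean(amplitudes 10–12 min after drug onset,
inclusive) / mean(baseline amplitudes)`; at least three events are required
in each window. The ≥ 30%-reduction inclusion rule (exclude when the
percentage exceeds 70) is implemented as a separate predicate: it is a
drug-efficacy gate for the blockade experiments, and applying it to toxin
group summaries would contradict reported group means near 75% of baseline,
so the pipeline logs the flag without dropping cells from those summaries.
The feedforward ratio is `(IPSC_total − IPSC_mono)/EPSC`, falling back to
`IPSC_total/EPSC` when no monosynaptic measurement exists (pooled
CA3-stimulation case); it is invariant to common rescaling of the three
amplitudes.

## Puncta quantification

Distances are centroid-to-centroid between puncta and centroid-to-polygon
for soma rules (0 inside the outline); a surface-to-surface alternative can
be expressed by inflating the radii. The filter chain is: gephyrin puncta
within 1 µm of any soma outline → presynaptic puncta within 1 µm of a
retained gephyrin punctum → counted on the nearest soma when within 0.2 µm
of one (each punctum counted at most once; exact ties to the lower soma
id). The bias ratio is sum-then-divide: total counts on marker-positive
somas over total counts on marker-negative somas. Analysis is 2D on a thin
maximum-intensity projection. Detection is a scale-matched
Laplacian-of-Gaussian response (σ = d/(2√2) for an expected diameter d,
default 0.25 µm at 0.04 µm pixels) thresholded at median + 5 × 1.4826 MAD
of the response — robust statistics so bright foreground does not inflate
the background estimate — with sub-pixel centroids from intensity-weighted
means; the threshold multiplier is configurable.

## LFP analysis

Signals are mean-subtracted and band-passed 8–100 Hz with a 4th-order
Butterworth applied forward–backward (zero phase, so lags are not biased by
filter delay). Spectra are Welch averages of 1-s Hann segments with 50%
overlap (1 Hz resolution over the 18–50 Hz gamma band), in Vrms² per bin so
the peak reports as Vrms. Normalized peak power locates the peak bin in the
baseline spectrum and reads the same bin after the drug — a
within-experiment contrast, since absolute power depends on electrode
placement. Cross-correlation is computed in the frequency domain with zero
padding (linear, not circular, correlation; a strict circular mode is a
flag), restricted to |lag| ≤ 25 ms, with peak ties resolved to the smallest
|lag|; 1-s windows are averaged over the recording before the peak is
taken. Sign convention: positive lag means the deep channel leads the
superficial channel. Correlation values are in arbitrary units; only lags
and within-experiment contrasts are comparable across implementations.

Peak-bin readout has a small downward selection bias on the normalized
power (the baseline peak bin is, by selection, high): it shrinks with the
number of averaged segments, so drug-contrast analyses use recordings of
60–120 s — the natural scale of carbachol wash-in recordings — where the
bias is well inside the estimator's dispersion.

## Census

Two somatic depth conventions coexist: distance from the superficial front
of the principal cell layer, and distance from the alveus/cortex border
along the radial axis (both as distance to the nearest point of a landmark
polyline, accommodating CA1 curvature). Deep/superficial bands are depth
intervals; in non-banded controls the single PCL is split into equal radial
halves, and a cell exactly on the boundary is superficial (documented tie
rule). Marker fractions divide marker-positive counts by DAPI counts per
band; histograms default to 20 µm bins and normalize to unit sum.

## Synthetic generators

All generators draw from a single seeded stream per call and are
byte-identical under a fixed configuration; a top-level seed fans out to
independent per-stage substreams. Defaults encode the study conditions of
the wild-type/mutant comparison:

* **Trees.** Complex: first bifurcation ~N(165, 30) µm (clipped 120–220),
  ~8 further bifurcations within 5–35 µm past it, tips to ~N(310, 45) µm —
  giving cohort Sholl peaks of 8–11 intersections near 200 µm. Simple:
  first bifurcation ~N(330, 35) µm (clipped 280–420) on a long sparse
  trunk, ~1 extra branch. Trunks grow radially with small angular jitter;
  two basal stubs and a soma node are included. The generator emulates
  archetype separation and branch statistics, not realistic tortuosity,
  taper or 3D tissue context — classification results on it bound what the
  indices can do when the archetypes are real, not microscope performance.
* **Physiology.** Two diagonal multivariate-normal classes over the eight
  features; resting potential (−63.3 vs −60.3 mV) and input resistance
  (120.4 vs 149.3 MΩ) use the reported group means, the remaining features
  field-typical values with modest contrast. The per-feature sd is 1.4× the
  between-class gap, making the classes overlap enough that PCA + k-means
  agrees with truth only ~75–85% of the time, emulating the loose
  morphology–physiology concordance in wild type. Feature correlations are
  not modelled.
* **Wash-in.** Lognormal event noise (cv 0.1, mean-corrected) around a
  baseline that relaxes exponentially (τ = 1 min) to `drug_factor` ×
  baseline after onset; events every 10 s from −5 to 12 min.
* **Scenes.** Twelve elliptical somas on a jittered grid; boutons on soma
  perimeters at Poisson rates in ratio `bias` (positive:negative), each
  paired with a gephyrin punctum within 0.15 µm; distractor presynaptic
  puncta > 1.5 µm from somas and free-floating gephyrin distractors are
  rejected by the filter chain. Optional rasterization to Gaussian-spot
  images for detector testing. Real tissue adds off-somatic synapses,
  antibody background and optical blur that the geometric scene does not.
* **Oscillations.** A shared narrowband oscillator (white noise band-passed
  ±8% around f0) feeds both channels with the superficial copy delayed by
  the injected lag (integer samples at 10 kHz); independent white noise
  sets the SNR; the post condition scales the oscillator by the drug power
  factor with fresh noise. Real gamma has amplitude and frequency drift and
  shared broadband components that this stationary model omits.
* **Census.** Uniform depths within each band, Bernoulli markers at the
  band's probability, every cell DAPI-detected.

## Problem sizes

Default pipeline runs use 40 reconstructions per class, 40 cells per
physiology class, 8 wash-in cells per class, 5 scenes per stain, 6
oscillation experiments per genotype at 60 s, and 100 census cells per
band; the reproduction script scales these to 100 trees per class, 50
scenes per stain, 14 experiments per genotype at 120 s and 12 slices per
genotype — sizes at which each estimator's sampling error is small against
the effects being measured.

## Known limitations

* The LRI/ORI default formulas are one reasonable member of the family the
  configuration hook admits; absolute index values (and hence cluster
  centre coordinates) are formula-dependent even though the complex/simple
  ordering is robust.
* Spike detection assumes clean somatic waveforms; no provision for noisy
  dV/dt near threshold beyond the refractory window.
* Puncta analysis is strictly 2D; the thin-projection assumption breaks for
  thick stacks.
* Cross-correlation values are unnormalized (arbitrary units), matching the
  convention of reporting lags and within-experiment contrasts only.
* Welch/peak-bin spectral conventions trade variance for simplicity; the
  normalized-power estimator needs tens of averaged segments before its
  selection bias is negligible (see above).
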