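# ca1quant

Quantification toolkit for hippocampal CA1 microcircuitry under cellular
heterotopia. It re-implements, as a tested and reusable library, the analysis
stack used to characterize how mispositioned (heterotopic) pyramidal cells
integrate into the CA1 circuit:

* **Morphometry** — SWC reconstructions are reduced to branch-structure
  indices of the apical dendrite: the length-ratio index
  `LRI = ln((L_d1 + L_d2) / L_p)` and node-ratio index
  `ORI = ln((N_d1 + N_d2 + 2) / (N_p + 1))`, evaluated at the first
  *prominent* bifurcation (the first split where the smaller daughter carries
  ≥ 20% of the remaining apical length), with a `D0/L_p` down-weighting when
  the selected node lies more than `D0 = 150 µm` from the soma. Complex
  (calbindin-predictive) cells score high on both axes; simple cells low.
  Sholl profiles and the soma-to-first-bifurcation distance complete the
  feature set.
* **Clustering** — supervised k-means (k = 2) on the (LRI, ORI) plane for
  morphological class, and z-score + PCA + k-means on eight intrinsic
  electrophysiological properties, with elbow (within-cluster sum of squares)
  diagnostics, nearest-centre assignment of newly recorded cells, and
  morphology–physiology concordance tables.
* **Ephys** — intrinsic-property extraction from current-clamp sweeps
  (resting potential, sag index ΔV_ss/ΔV_peak, input resistance, spike
  threshold/amplitude/AHP, adaptation ratio, firing rate at 2× threshold),
  series-resistance QC (> 30% drift excluded), wash-in percent-of-baseline
  for toxin pharmacology, and the feedforward I/E ratio
  `(IPSC_total − IPSC_mono) / EPSC` with monosynaptic subtraction.
* **Puncta** — the four-channel synaptic bouton count: presynaptic puncta are
  true synapses only if a gephyrin punctum lies within 1 µm and that gephyrin
  punctum lies within 1 µm of a soma outline; boutons within 0.2 µm of a soma
  are counted (six calbindin-positive and six calbindin-negative somas per
  scene), and the innervation bias is Σcounts(CB+) / Σcounts(CB−) — values
  above 1 mean a preference for calbindin-expressing targets.
* **LFP** — carbachol gamma oscillations (18–50 Hz): 8–100 Hz zero-phase
  band-pass, Welch power spectra with gamma-band peak frequency and peak
  Vrms, within-experiment normalized peak power across a drug wash-in, and
  FFT cross-correlation between the deep and superficial channels with a
  signed millisecond lag (positive = deep leads).
* **Census** — somatic depth conventions (from the PCL front, and along the
  radial axis of CA1 from the alveus border), deep/superficial band marker
  fractions against the DAPI denominator, normalized position histograms,
  and birth-dating colocalization fractions.
* **Synth** — seeded generators with ground truth for every stage: dendritic
  archetypes, two-class physiology cohorts, wash-in series, puncta scenes
  with a controllable innervation bias, two-channel gamma oscillators with
  an injected inter-channel lag, and positional censuses.

## Worked example

Classify a synthetic cohort of 60 reconstructions and analyze one
gamma-oscillation experiment:

```python
import numpy as np
from ca1quant import morphology as mor, clustering as clu, lfp, synth

trees, labels = synth.gen_cohort_trees(30, seed=0)       # 30 complex + 30 simple
feats, first_bif = [], []
for tree in trees:
    apical = mor.extract_apical(tree)
    f = mor.lri_ori(apical)
    feats.append((f.lri, f.ori))
    first_bif.append(f.first_bifurcation_um)
feats, first_bif = np.asarray(feats), np.asarray(first_bif)

res = clu.kmeans(feats, 2, seed=0)                       # cluster 0 = complex
purity = max((res.labels == labels).mean(), (res.labels != labels).mean())
print(f"label purity: {purity:.3f}")
print(f"complex centre (LRI, ORI): ({res.centers[0,0]:.2f}, {res.centers[0,1]:.2f})")
print(f"mean first prominent bifurcation: complex {first_bif[labels==0].mean():.0f} um, "
      f"simple {first_bif[labels==1].mean():.0f} um")

pre, post = synth.gen_lfp(f0_hz=30.0, lag_ms=1.0, drug_power_factor=0.93,
                          duration_s=60.0, snr=5.0, seed=0, experiment_id="slice01")
fs = pre.sampling_rate_hz
deep = lfp.preprocess(pre.channel_deep, fs)
sup = lfp.preprocess(pre.channel_superficial, fs)
sp_pre = lfp.power_spectrum(deep, fs, experiment_id="slice01")
sp_post = lfp.power_spectrum(lfp.preprocess(post.channel_deep, fs), fs,
                             experiment_id="slice01")
xc = lfp.xcorr_windowed(deep, sup, fs)
print(f"gamma peak: {sp_pre.peak_freq_hz:.0f} Hz")
print(f"normalized peak power after drug: {lfp.normalized_peak_power(sp_pre, sp_post):.2f}")
print(f"deep leads superficial by {xc.lag_at_max_ms:+.1f} ms")
```

prints

```
label purity: 0.917
complex centre (LRI, ORI): (2.06, 2.14)
mean first prominent bifurcation: complex 163 um, simple 329 um
gamma peak: 30 Hz
normalized peak power after drug: 0.91
deep leads superficial by +1.0 ms
```

The k-means recovers the two dendritic archetypes almost perfectly; complex
cells bifurcate far sooner along the primary apical dendrite than simple
cells; the oscillation analysis reads back the generator's 30 Hz centre
frequency, the 0.93 drug power step (to within spectral-estimation error),
and the injected +1 ms inter-channel lag exactly.

## Command line

```bash
ca1quant run --out runs/demo --seed 1          # full synthetic pipeline
ca1quant run --stage lfp --out runs/lfp --seed 1
ca1quant report runs/demo                      # consolidated n/mean/SEM table
```

Runs are configured by a YAML file (`--config`); unknown keys are rejected.
Identical configuration and seed produce byte-identical reports.

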