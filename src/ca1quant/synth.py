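"""Seeded synthetic-data generators with known ground truth.

Every pipeline stage gets an input emulator whose defaults encode the study
conditions reported for wild-type and mutant CA1: two apical-dendrite
archetypes (complex = early balanced bifurcation with dense branching,
simple = long sparsely branched trunk), two-class intrinsic-physiology
cohorts, evoked-amplitude wash-in time courses with a step reduction,
puncta scenes with a controllable innervation bias, two-channel gamma
oscillations with an injected inter-channel lag, and positional censuses.

All randomness in a call flows from one ``numpy.random.Generator`` seeded
by the ``seed`` argument, so identical configurations are bit-identical.
``substreams`` fans a top-level seed out to independent per-stage streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from shapely.geometry import Point, Polygon
from shapely import affinity

from .census import BandRois
from .ephys import Sweep, WashinSeries
from .lfp import LfpRecording
from .morphology import COMPARTMENT_CODES, NeuronMorphology
from .puncta import Punctum, PunctaScene, SomaContour

__all__ = [
    "substreams",
    "gen_tree",
    "gen_cohort_trees",
    "gen_physiology",
    "gen_rc_sag_sweep",
    "gen_spike_sweep",
    "gen_washin",
    "gen_scene",
    "rasterize_scene",
    "gen_lfp",
    "gen_census",
    "PHYSIOLOGY_CLASS_MEANS",
]


def substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Fan one top-level seed out to ``n`` independent generator streams."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Dendritic-tree archetypes

TREE_ARCHETYPES = {
    # complex: early balanced bifurcation, dense branching just distal to it
    # (cohort Sholl peak 8-11 intersections near 200 um); simple: late
    # bifurcation on a long sparse trunk.
    "complex": dict(
        first_bif_mean=165.0, first_bif_sd=30.0, first_bif_clip=(120.0, 220.0),
        n_extra_bifs_mean=8.0, extra_bif_zone=(5.0, 35.0),   # offsets past first bif
        tip_len_mean=310.0, tip_len_sd=45.0, tip_len_clip=(230.0, 420.0),
    ),
    "simple": dict(
        first_bif_mean=330.0, first_bif_sd=35.0, first_bif_clip=(280.0, 420.0),
        n_extra_bifs_mean=1.0, extra_bif_zone=(10.0, 80.0),
        tip_len_mean=460.0, tip_len_sd=40.0, tip_len_clip=(380.0, 540.0),
    ),
}

_SEG_UM = 10.0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def gen_tree(archetype: str, seed: int | np.random.Generator = 0) -> NeuronMorphology:
    """One synthetic pyramidal-cell reconstruction of the named archetype.

    The apical trunk grows radially (+y) in 10-um segments with small
    angular jitter; at the drawn first-bifurcation distance it splits into
    two balanced daughters, after which additional bifurcations are placed
    at drawn path offsets.  A soma node and two short basal stubs are
    included.  Ground truth (archetype, first-bifurcation distance) is
    stored in the metadata.
    """
    params = TREE_ARCHETYPES[archetype]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    first_bif = float(
        np.clip(
            rng.normal(params["first_bif_mean"], params["first_bif_sd"]),
            *params["first_bif_clip"],
        )
    )
    n_extra = int(min(rng.poisson(params["n_extra_bifs_mean"]), 14))
    zone = params["extra_bif_zone"]
    extra_depths = np.sort(first_bif + rng.uniform(zone[0], zone[1], size=n_extra))

    xyz = [np.zeros(3)]
    radius = [6.0]
    comp = [COMPARTMENT_CODES["soma"]]
    parent = [-1]

    def add_node(p: int, pos: np.ndarray, r: float, c: int) -> int:
        xyz.append(pos)
        radius.append(r)
        comp.append(c)
        parent.append(p)
        return len(xyz) - 1

    # two short basal stubs
    for direction in (np.array([0.6, -1.0, 0.1]), np.array([-0.6, -1.0, -0.1])):
        node, pos = 0, np.zeros(3)
        for _ in range(5):
            pos = pos + _unit(direction + rng.normal(0, 0.15, 3)) * _SEG_UM
            node = add_node(node, pos.copy(), 1.0, COMPARTMENT_CODES["basal"])

    # apical growth: tips as (node, pos, direction, path_len, max_len)
    apical = COMPARTMENT_CODES["apical"]

    def grow_daughters(node, pos, direction, path):
        """Split a tip into two balanced daughters diverging +/- ~28 deg."""
        out = []
        for sign in (1.0, -1.0):
            ang = math.radians(rng.uniform(20.0, 38.0)) * sign
            cos_a, sin_a = math.cos(ang), math.sin(ang)
            d = np.array(
                [direction[0] * cos_a - direction[1] * sin_a,
                 direction[0] * sin_a + direction[1] * cos_a,
                 direction[2] + rng.normal(0, 0.05)]
            )
            max_len = float(
                np.clip(
                    rng.normal(params["tip_len_mean"], params["tip_len_sd"]),
                    *params["tip_len_clip"],
                )
            )
            max_len = max(max_len, path + 40.0)   # daughters always grow

            out.append([node, pos.copy(), _unit(d), path, max_len])
        return out

    # trunk up to the first prominent bifurcation
    node, pos, direction, path = 0, np.zeros(3), np.array([0.0, 1.0, 0.0]), 0.0
    while path < first_bif:
        step = min(_SEG_UM, first_bif - path)
        direction = _unit(direction + rng.normal(0, 0.04, 3) + np.array([0, 0.02, 0]))
        pos = pos + direction * step
        path += step
        node = add_node(node, pos.copy(), 1.5, apical)

    tips = grow_daughters(node, pos, direction, path)
    pending = list(extra_depths)

    while tips:
        tip = tips.pop(0)
        node, pos, direction, path, max_len = tip
        if pending and path >= pending[0]:
            pending.pop(0)
            tips.extend(grow_daughters(node, pos, direction, path))
            continue
        if path >= max_len:
            continue
        next_stop = pending[0] if pending else np.inf
        step = min(_SEG_UM, max_len - path, max(next_stop - path, 1.0))
        direction = _unit(direction + rng.normal(0, 0.06, 3) + np.array([0, 0.03, 0]))
        pos = pos + direction * step
        path += step
        node = add_node(node, pos.copy(), 1.0, apical)
        tips.append([node, pos, direction, path, max_len])

    return NeuronMorphology(
        xyz=np.array(xyz),
        radius=np.array(radius),
        compartment=np.array(comp),
        parent=np.array(parent),
        metadata={"archetype": archetype, "true_first_bif_um": first_bif},
    )


def gen_cohort_trees(
    n_per_class: int, seed: int = 0
) -> tuple[list[NeuronMorphology], np.ndarray]:
    """Balanced complex/simple cohort; returns (trees, true labels)
    with label 0 = complex, 1 = simple."""
    rng = np.random.default_rng(seed)
    trees, labels = [], []
    for arch, lab in (("complex", 0), ("simple", 1)):
        for _ in range(n_per_class):
            trees.append(gen_tree(arch, rng))
            labels.append(lab)
    return trees, np.array(labels)


# ---------------------------------------------------------------------------
# Intrinsic physiology

# Group means for the eight clustering features.  RMP and input resistance
# follow the reported complex/simple group means; the remaining features are
# set to field-typical CA1 pyramidal values with a modest class contrast.
PHYSIOLOGY_CLASS_MEANS = pd.DataFrame(
    {
        "rmp_mV": [-63.3, -60.3],
        "sag_index": [0.85, 0.92],
        "rin_MOhm": [120.4, 149.3],
        "spike_amplitude_mV": [78.0, 82.0],
        "adaptation_ratio": [2.0, 1.6],
        "f_2x_Hz": [25.0, 18.0],
        "spike_threshold_mV": [-45.0, -43.0],
        "ahp_mV": [12.0, 10.0],
    },
    index=["complex", "simple"],
)

# Within-class sd as a multiple of the between-class gap; 1.4 makes the two
# classes overlap enough that PCA + k-means recovers labels only partially
# (agreement ~0.75-0.85), emulating the loose morphology-physiology
# concordance seen in wild-type recordings.
PHYSIOLOGY_NOISE_GAP_RATIO = 1.4


def gen_physiology(
    n_per_class: int = 50,
    seed: int = 0,
    class_means: pd.DataFrame | None = None,
    noise_sd: pd.Series | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-class multivariate-normal cohort over the eight features.

    Returns (feature table, true labels) with label 0 = complex.  Default
    per-feature noise sd is ``PHYSIOLOGY_NOISE_GAP_RATIO`` times the
    between-class gap (diagonal covariance).
    """
    rng = np.random.default_rng(seed)
    means = class_means if class_means is not None else PHYSIOLOGY_CLASS_MEANS
    if noise_sd is None:
        noise_sd = (means.iloc[0] - means.iloc[1]).abs() * PHYSIOLOGY_NOISE_GAP_RATIO
    if np.any(np.asarray(noise_sd) < 0):
        raise ValueError("noise sd must be non-negative")
    frames, labels = [], []
    for lab, (_, mu) in enumerate(means.iterrows()):
        X = rng.normal(mu.to_numpy(), np.asarray(noise_sd), size=(n_per_class, len(mu)))
        frames.append(pd.DataFrame(X, columns=means.columns))
        labels.extend([lab] * n_per_class)
    df = pd.concat(frames, ignore_index=True)
    df.index = [f"cell{i:03d}" for i in range(len(df))]
    return df, np.array(labels)


def gen_rc_sag_sweep(
    rin_MOhm: float = 150.0,
    sag_index: float = 0.8,
    step_pA: float = -100.0,
    rmp_mV: float = -65.0,
    fs_hz: float = 20_000.0,
    baseline_s: float = 0.2,
    step_s: float = 0.5,
    tau_m_ms: float = 5.0,
    tau_sag_ms: float = 40.0,
    noise_sd_mV: float = 0.0,
    seed: int = 0,
) -> Sweep:
    """Hyperpolarizing-step sweep with known Rin and sag index.

    The deflection charges quickly (tau_m) to the peak value, then relaxes
    exponentially (tau_sag) to the steady state, so the generator's
    ``rin_MOhm`` and ``sag_index`` are exactly recoverable by the standard
    peak / last-20% conventions.
    """
    if not 0 < sag_index <= 1:
        raise ValueError("sag_index must be in (0, 1]")
    rng = np.random.default_rng(seed)
    dv_ss = rin_MOhm * step_pA * 1e-3              # mV, negative
    dv_peak = dv_ss / sag_index
    n_base = int(baseline_s * fs_hz)
    n_step = int(step_s * fs_hz)
    t = np.arange(n_step) / fs_hz * 1e3            # ms within step
    t_peak = 6.0 * tau_m_ms
    charge = dv_peak * (1.0 - np.exp(-t / tau_m_ms))
    relax = dv_ss + (dv_peak - dv_ss) * np.exp(-(t - t_peak) / tau_sag_ms)
    deflect = np.where(t < t_peak, charge, relax)
    v = np.concatenate(
        [np.full(n_base, rmp_mV), rmp_mV + deflect, np.full(n_base, rmp_mV)]
    )
    if noise_sd_mV > 0:
        v = v + rng.normal(0, noise_sd_mV, len(v))
    return Sweep(
        samples=v,
        sampling_rate_hz=fs_hz,
        stim_onset_s=baseline_s,
        stim_offset_s=baseline_s + step_s,
        stim_amplitude=step_pA,
    )


def gen_spike_sweep(
    n_spikes: int = 10,
    threshold_mV: float = -45.0,
    peak_mV: float = 35.0,
    ahp_min_mV: float = -58.0,
    rmp_mV: float = -65.0,
    isi_ms=None,
    fs_hz: float = 20_000.0,
    baseline_s: float = 0.2,
    step_s: float = 0.5,
    step_pA: float = 200.0,
) -> Sweep:
    """Current-clamp sweep with a constructed spike train.

    Each spike's upstroke accelerates from exactly 20 mV/ms at the
    threshold voltage, so dV/dt-criterion detection recovers the nominal
    threshold; between spikes the voltage ramps slowly.  ``isi_ms`` may be
    a scalar (uniform train) or a sequence of n_spikes-1 intervals.
    """
    n_base = int(baseline_s * fs_hz)
    n_step = int(step_s * fs_hz)
    dt_ms = 1e3 / fs_hz
    if isi_ms is None:
        isi_ms = (step_s * 1e3 - 60.0) / max(1, n_spikes - 1) if n_spikes > 1 else 0.0
    isis = (
        np.full(n_spikes - 1, float(isi_ms))
        if np.isscalar(isi_ms)
        else np.asarray(isi_ms, dtype=float)
    )
    spike_t = np.concatenate([[30.0], 30.0 + np.cumsum(isis)]) if n_spikes else []

    base_v = rmp_mV + 8.0                          # depolarized plateau during step
    v_step = np.full(n_step, base_v)
    # quadratic upstroke: dV/dt = 20 + 2 c t, starting exactly at threshold
    c = 300.0                                      # mV/ms^2
    t_up = (-20.0 + math.sqrt(400.0 + 4 * c * (peak_mV - threshold_mV))) / (2 * c)
    n_up = int(math.ceil(t_up / dt_ms))
    n_down = int(round(1.0 / dt_ms))               # 1 ms fall to AHP minimum
    n_rec = int(round(8.0 / dt_ms))                # recovery toward plateau
    for ts in spike_t:
        i0 = int(round(ts / dt_ms))
        if i0 + n_up + n_down + n_rec >= n_step:
            break
        # slow approach ramp to threshold over 4 ms (dV/dt ~ 2-3 mV/ms)
        n_ramp = int(round(4.0 / dt_ms))
        ramp = np.linspace(base_v, threshold_mV, n_ramp, endpoint=False)
        v_step[i0 - n_ramp: i0] = ramp
        tt = np.arange(n_up + 1) * dt_ms
        up = threshold_mV + 20.0 * tt + c * tt**2
        up[-1] = peak_mV
        v_step[i0: i0 + n_up + 1] = up
        down = np.linspace(peak_mV, ahp_min_mV, n_down + 1)[1:]
        v_step[i0 + n_up + 1: i0 + n_up + 1 + n_down] = down
        rec = np.linspace(ahp_min_mV, base_v, n_rec)
        v_step[i0 + n_up + 1 + n_down: i0 + n_up + 1 + n_down + n_rec] = rec
    v = np.concatenate([np.full(n_base, rmp_mV), v_step, np.full(n_base, rmp_mV)])
    return Sweep(
        samples=v,
        sampling_rate_hz=fs_hz,
        stim_onset_s=baseline_s,
        stim_offset_s=baseline_s + step_s,
        stim_amplitude=step_pA,
    )


def gen_washin(
    baseline_pA: float = 200.0,
    drug_factor: float = 0.525,
    event_cv: float = 0.10,
    interval_s: float = 10.0,
    t_start_min: float = -5.0,
    t_end_min: float = 12.0,
    tau_min: float = 1.0,
    seed: int = 0,
    drug_label: str = "",
) -> WashinSeries:
    """Evoked-amplitude wash-in series with a multiplicative drug step.

    Amplitudes carry lognormal event noise (coefficient of variation
    ``event_cv``, mean-corrected) around a baseline that relaxes
    exponentially (``tau_min``) to ``drug_factor`` x baseline after drug
    onset at t = 0.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(t_start_min, t_end_min + 1e-9, interval_s / 60.0)
    scale = np.where(
        times < 0,
        1.0,
        drug_factor + (1.0 - drug_factor) * np.exp(-np.maximum(times, 0) / tau_min),
    )
    sigma = math.sqrt(math.log(1.0 + event_cv**2))
    noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=len(times))
    return WashinSeries(
        event_times_min=times,
        amplitudes_pA=baseline_pA * scale * noise,
        drug_label=drug_label,
    )


# ---------------------------------------------------------------------------
# Puncta scenes

def _ellipse(cx, cy, rx, ry, angle_deg, n_vertices=32) -> Polygon:
    circ = Point(0, 0).buffer(1.0, quad_segs=n_vertices // 4)
    e = affinity.scale(circ, rx, ry)
    e = affinity.rotate(e, angle_deg)
    return affinity.translate(e, cx, cy)


def gen_scene(
    bias: float = 1.0,
    puncta_rate_per_soma: float = 12.0,
    n_pos: int = 6,
    n_neg: int = 6,
    field_um: float = 60.0,
    n_distractor_presyn: int = 40,
    n_distractor_gephyrin: int = 60,
    gephyrin_jitter_um: float = 0.15,
    seed: int = 0,
) -> PunctaScene:
    """Puncta scene with a controllable innervation bias.

    Elliptical somas (6 marker-positive + 6 marker-negative) are laid on a
    jittered grid; presynaptic boutons are placed on soma perimeters at
    Poisson rates in ratio ``bias`` (positive:negative), each paired with a
    gephyrin punctum within ``gephyrin_jitter_um``.  Distractor presynaptic
    puncta sit well away from somas and distractor gephyrin puncta are
    scattered freely; neither survives the full filter chain.
    """
    rng = np.random.default_rng(seed)
    n_somas = n_pos + n_neg
    cols = int(math.ceil(math.sqrt(n_somas)))
    rows = int(math.ceil(n_somas / cols))
    pitch = field_um / max(cols, rows)
    marker = np.array([True] * n_pos + [False] * n_neg)
    rng.shuffle(marker)

    somas, boutons, gephyrin = [], [], []
    n_boutons_by_class = {True: 0, False: 0}
    for i in range(n_somas):
        r, c = divmod(i, cols)
        cx = (c + 0.5) * pitch + rng.uniform(-1.5, 1.5)
        cy = (r + 0.5) * pitch + rng.uniform(-1.5, 1.5)
        poly = _ellipse(
            cx, cy, rng.uniform(3.5, 5.0), rng.uniform(4.5, 6.0), rng.uniform(0, 180)
        )
        somas.append(SomaContour(soma_id=i, polygon=poly, marker_positive=bool(marker[i])))

        rate = puncta_rate_per_soma * (bias if marker[i] else 1.0)
        n_boutons = rng.poisson(rate)
        n_boutons_by_class[bool(marker[i])] += int(n_boutons)
        boundary = poly.exterior
        for _ in range(n_boutons):
            p = boundary.interpolate(rng.uniform(0, boundary.length))
            outward = np.array([p.x - cx, p.y - cy])
            outward = outward / (np.linalg.norm(outward) + 1e-12)
            offset = rng.uniform(0.0, 0.12)
            bx, by = p.x + outward[0] * offset, p.y + outward[1] * offset
            boutons.append(Punctum(bx, by, channel="presyn"))
            ang = rng.uniform(0, 2 * math.pi)
            jit = rng.uniform(0, gephyrin_jitter_um)
            gephyrin.append(
                Punctum(bx + jit * math.cos(ang), by + jit * math.sin(ang), channel="gephyrin")
            )

    # distractor presynaptic puncta: rejection-sampled > 1.5 um from somas
    placed = 0
    while placed < n_distractor_presyn:
        x, y = rng.uniform(0, field_um, 2)
        if min(s.polygon.distance(Point(x, y)) for s in somas) > 1.5:
            boutons.append(Punctum(x, y, channel="presyn", provenance="supplied"))
            placed += 1
    for _ in range(n_distractor_gephyrin):
        x, y = rng.uniform(0, field_um, 2)
        gephyrin.append(Punctum(x, y, channel="gephyrin"))

    return PunctaScene(
        pixel_size_um=0.04,
        somas=somas,
        puncta={"presyn": boutons, "gephyrin": gephyrin},
        ground_truth={
            "bias": bias,
            "n_boutons_pos": n_boutons_by_class[True],
            "n_boutons_neg": n_boutons_by_class[False],
        },
    )


def rasterize_scene(
    puncta_list,
    extent_um: float,
    pixel_size_um: float = 0.04,
    spot_sigma_um: float = 0.1,
    amplitude: float = 100.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render puncta as Gaussian spots for detector testing."""
    rng = np.random.default_rng(seed)
    n_px = int(round(extent_um / pixel_size_um))
    img = np.full((n_px, n_px), background, dtype=float)
    sig = spot_sigma_um / pixel_size_um
    half = int(math.ceil(4 * sig))
    for p in puncta_list:
        cx, cy = p.x_um / pixel_size_um, p.y_um / pixel_size_um
        r0, c0 = int(round(cy)), int(round(cx))
        rr = np.arange(max(0, r0 - half), min(n_px, r0 + half + 1))
        cc = np.arange(max(0, c0 - half), min(n_px, c0 + half + 1))
        if len(rr) == 0 or len(cc) == 0:
            continue
        gy = np.exp(-((rr - cy) ** 2) / (2 * sig**2))
        gx = np.exp(-((cc - cx) ** 2) / (2 * sig**2))
        img[np.ix_(rr, cc)] += amplitude * np.outer(gy, gx)
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    return img


# ---------------------------------------------------------------------------
# LFP oscillations

def gen_lfp(
    f0_hz: float = 30.0,
    lag_ms: float = 1.0,
    amp: float = 100.0,
    snr: float = 5.0,
    drug_power_factor: float = 0.93,
    duration_s: float = 10.0,
    fs_hz: float = 10_000.0,
    seed: int = 0,
    experiment_id: str | None = None,
) -> tuple[LfpRecording, LfpRecording]:
    """Two-channel gamma oscillation pre/post a drug power step.

    A shared narrowband oscillator (white noise band-passed around
    ``f0_hz``) feeds both channels; the superficial channel is a delayed
    copy (positive ``lag_ms`` = deep leads).  Independent white noise sets
    the SNR (oscillator sd over noise sd).  The post condition scales the
    oscillator amplitude by ``drug_power_factor`` with fresh noise.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    lag_samples = int(round(lag_ms * fs_hz / 1e3))
    pad = abs(lag_samples) + int(fs_hz)           # 1 s of filter warm-up
    bw = max(2.0, 0.08 * f0_hz)
    sos = signal.butter(2, (f0_hz - bw, f0_hz + bw), btype="bandpass", fs=fs_hz, output="sos")

    def make(scale: float, condition: str) -> LfpRecording:
        base = signal.sosfilt(sos, rng.standard_normal(n + 2 * pad))
        base = base / base[pad:-pad].std() * amp * scale
        deep = base[pad: pad + n].copy()
        superficial = base[pad - lag_samples: pad - lag_samples + n].copy()
        noise_sd = amp / snr
        deep += rng.normal(0, noise_sd, n)
        superficial += rng.normal(0, noise_sd, n)
        return LfpRecording(
            channel_deep=deep,
            channel_superficial=superficial,
            sampling_rate_hz=fs_hz,
            condition=condition,
            experiment_id=experiment_id,
        )

    return make(1.0, "CCh"), make(drug_power_factor, "+WIN")


# ---------------------------------------------------------------------------
# Positional census

def gen_census(
    p_marker: tuple = (0.089, 0.251),            # (deep, superficial)
    n_cells_per_band: tuple = (100, 100),
    band_extents_um: tuple = ((75.0, 150.0), (0.0, 75.0)),
    marker: str = "calbindin",
    seed: int = 0,
) -> tuple[pd.DataFrame, BandRois, dict]:
    """DAPI census with per-band marker probabilities.

    Returns (cell table, band ROIs, ground truth).  Cells are uniform in
    depth within their band; every cell is DAPI-detected and the marker is
    Bernoulli with the band's probability.
    """
    rng = np.random.default_rng(seed)
    (deep_ext, sup_ext) = band_extents_um
    rois = BandRois(superficial=tuple(sup_ext), deep=tuple(deep_ext))
    rows = []
    for (p, n, ext, band) in (
        (p_marker[0], n_cells_per_band[0], deep_ext, "deep"),
        (p_marker[1], n_cells_per_band[1], sup_ext, "superficial"),
    ):
        depths = rng.uniform(ext[0], ext[1], n)
        flags = rng.random(n) < p
        for d, f in zip(depths, flags):
            rows.append(
                {"x_um": rng.uniform(0, 400.0), "depth_pcl_um": float(d),
                 "dapi": True, marker: bool(f), "true_band": band}
            )
    cells = pd.DataFrame(rows)
    truth = {"p_deep": p_marker[0], "p_superficial": p_marker[1], "marker": marker}
    return cells, rois, truth
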