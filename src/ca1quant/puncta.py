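"""Synaptic-puncta quantification and the innervation-bias statistic.

Re-creates the four-channel confocal workflow in 2D: maximum-intensity
projection of a thin sub-stack, blob detection of fluorescent puncta,
gephyrin proximity filtering (a presynaptic bouton only counts as a
synapse if a postsynaptic gephyrin punctum lies within 1 um and that
gephyrin punctum lies within 1 um of a soma), somatic counting (0.2 um or
less from a principal-cell soma outline), and finally the innervation
bias: summed counts on marker-positive somas divided by counts on
marker-negative somas.  Values above 1 indicate a preference for the
marker-positive (calbindin-expressing) class.

Distances are centroid-to-centroid between puncta and centroid-to-polygon
for soma rules (0 inside the polygon); both conventions are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon
from skimage.feature import peak_local_max

__all__ = [
    "Punctum",
    "SomaContour",
    "PunctaScene",
    "BiasResult",
    "max_intensity_projection",
    "detect_puncta",
    "filter_gephyrin_by_soma",
    "filter_presyn_by_gephyrin",
    "count_on_somas",
    "innervation_bias",
    "quantify_scene",
    "load_stack",
    "read_puncta_csv",
    "write_puncta_csv",
    "read_somas_csv",
    "write_somas_csv",
]

GEPHYRIN_SOMA_RADIUS_UM = 1.0
PRESYN_GEPHYRIN_RADIUS_UM = 1.0
SOMA_COUNT_RADIUS_UM = 0.2


@dataclass
class Punctum:
    x_um: float
    y_um: float
    diameter_um: float = 0.25
    channel: str = ""
    provenance: str = "supplied"      # "detected" | "supplied"

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")


@dataclass
class SomaContour:
    """Traced soma outline with its calbindin status."""

    soma_id: int
    polygon: Polygon
    marker_positive: bool
    in_analysis: bool = True

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError(f"soma {self.soma_id}: polygon must be simple with area > 0")

    def distance_um(self, p: Punctum) -> float:
        """Distance from punctum centroid to the soma (0 inside the outline)."""
        return float(self.polygon.distance(Point(p.x_um, p.y_um)))


@dataclass
class PunctaScene:
    pixel_size_um: float
    somas: list = field(default_factory=list)
    puncta: dict = field(default_factory=dict)        # channel -> list[Punctum]
    images: dict = field(default_factory=dict)        # channel -> 2D array
    ground_truth: dict = field(default_factory=dict)


@dataclass
class BiasResult:
    per_soma_counts: pd.DataFrame    # soma_id, marker_positive, count
    total_pos: int
    total_neg: int
    bias_ratio: float


def load_stack(path) -> np.ndarray:
    """Read a (multi-page) TIFF Z stack as a (z, y, x) array."""
    import tifffile

    stack = tifffile.imread(path)
    return stack[None] if stack.ndim == 2 else stack


def write_puncta_csv(puncta_list, path) -> None:
    pd.DataFrame(
        [
            {"x_um": p.x_um, "y_um": p.y_um, "diameter_um": p.diameter_um,
             "channel": p.channel, "provenance": p.provenance}
            for p in puncta_list
        ]
    ).to_csv(path, index=False)


def read_puncta_csv(path) -> list:
    df = pd.read_csv(path)
    return [
        Punctum(r.x_um, r.y_um, r.diameter_um, r.channel, r.provenance)
        for r in df.itertuples()
    ]


def write_somas_csv(somas, path) -> None:
    pd.DataFrame(
        [
            {"soma_id": s.soma_id, "wkt_polygon": s.polygon.wkt,
             "marker_positive": s.marker_positive, "in_analysis": s.in_analysis}
            for s in somas
        ]
    ).to_csv(path, index=False)


def read_somas_csv(path) -> list:
    from shapely import wkt

    df = pd.read_csv(path)
    return [
        SomaContour(int(r.soma_id), wkt.loads(r.wkt_polygon),
                    bool(r.marker_positive), bool(r.in_analysis))
        for r in df.itertuples()
    ]


def max_intensity_projection(stack: np.ndarray, n_slices: int) -> np.ndarray:
    """Per-pixel maximum over the first ``n_slices`` planes of a Z stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) stack")
    if n_slices > stack.shape[0]:
        raise ValueError(f"n_slices {n_slices} exceeds stack depth {stack.shape[0]}")
    return stack[:n_slices].max(axis=0)


def detect_puncta(
    image: np.ndarray,
    pixel_size_um: float,
    expected_diameter_um: float = 0.25,
    threshold_sds: float = 5.0,
    channel: str = "",
) -> list:
    """Scale-matched blob detection of fluorescent puncta.

    A Laplacian-of-Gaussian response at the expected punctum scale is
    thresholded at ``background mean + threshold_sds x background sd``
    (background statistics are taken robustly from the median and MAD of
    the response), local maxima are extracted with a minimum separation of
    one expected radius, and centroids are refined to sub-pixel precision
    by an intensity-weighted mean over the blob neighbourhood.
    """
    img = np.asarray(image, dtype=float)
    sigma_px = (expected_diameter_um / 2.0) / np.sqrt(2.0) / pixel_size_um
    if sigma_px < 1.0:
        raise ValueError("expected diameter must be >= 2 pixels after scaling")
    if img.max() == img.min():
        return []
    response = -ndimage.gaussian_laplace(img, sigma=sigma_px) * sigma_px**2
    med = np.median(response)
    mad = np.median(np.abs(response - med))
    thresh = med + threshold_sds * 1.4826 * mad
    radius_px = max(1, int(round(sigma_px * np.sqrt(2.0))))
    coords = peak_local_max(
        response, min_distance=radius_px, threshold_abs=thresh, exclude_border=False
    )
    out = []
    w = radius_px + 1
    for r, c in coords:
        r0, r1 = max(0, r - w), min(img.shape[0], r + w + 1)
        c0, c1 = max(0, c - w), min(img.shape[1], c + w + 1)
        patch = img[r0:r1, c0:c1]
        weights = patch - patch.min()
        if weights.sum() == 0:
            cy, cx = float(r), float(c)
        else:
            yy, xx = np.mgrid[r0:r1, c0:c1]
            cy = float((yy * weights).sum() / weights.sum())
            cx = float((xx * weights).sum() / weights.sum())
        out.append(
            Punctum(
                x_um=cx * pixel_size_um,
                y_um=cy * pixel_size_um,
                diameter_um=expected_diameter_um,
                channel=channel,
                provenance="detected",
            )
        )
    return out


def filter_gephyrin_by_soma(
    geph: list, somas: list, radius_um: float = GEPHYRIN_SOMA_RADIUS_UM
) -> list:
    """Keep gephyrin puncta within ``radius_um`` of any soma outline."""
    if not somas:
        raise ValueError("no somas supplied")
    return [p for p in geph if min(s.distance_um(p) for s in somas) <= radius_um]


def filter_presyn_by_gephyrin(
    pre: list, geph_kept: list, radius_um: float = PRESYN_GEPHYRIN_RADIUS_UM
) -> list:
    """Keep presynaptic puncta with a retained gephyrin punctum within
    ``radius_um`` (centroid to centroid)."""
    if not geph_kept or not pre:
        return []
    tree = cKDTree([(g.x_um, g.y_um) for g in geph_kept])
    pts = np.array([(p.x_um, p.y_um) for p in pre])
    dist, _ = tree.query(pts, k=1)
    return [p for p, d in zip(pre, dist) if d <= radius_um]


def count_on_somas(
    pre_kept: list, somas: list, radius_um: float = SOMA_COUNT_RADIUS_UM
) -> dict:
    """Assign each surviving punctum to the nearest qualifying soma.

    A punctum counts when its distance to a soma flagged ``in_analysis``
    is at most ``radius_um``; it is counted once, on the nearest soma,
    with exact ties going to the lower ``soma_id``.
    """
    active = sorted((s for s in somas if s.in_analysis), key=lambda s: s.soma_id)
    counts = {s.soma_id: 0 for s in active}
    for p in pre_kept:
        best_id, best_d = None, np.inf
        for s in active:
            d = s.distance_um(p)
            if d < best_d - 1e-12:
                best_id, best_d = s.soma_id, d
        if best_id is not None and best_d <= radius_um:
            counts[best_id] += 1
    return counts


def innervation_bias(counts: dict, somas: list) -> BiasResult:
    """Innervation bias ratio: summed counts on marker-positive somas over
    summed counts on marker-negative somas (sum-then-divide)."""
    marker = {s.soma_id: s.marker_positive for s in somas}
    rows = [
        {"soma_id": sid, "marker_positive": marker[sid], "count": n}
        for sid, n in sorted(counts.items())
    ]
    df = pd.DataFrame(rows)
    total_pos = int(df.loc[df.marker_positive, "count"].sum())
    total_neg = int(df.loc[~df.marker_positive, "count"].sum())
    if total_neg == 0:
        raise ZeroDivisionError("no puncta counted on marker-negative somas; bias undefined")
    return BiasResult(
        per_soma_counts=df,
        total_pos=total_pos,
        total_neg=total_neg,
        bias_ratio=total_pos / total_neg,
    )


def quantify_scene(
    scene: PunctaScene,
    presyn_channel: str = "presyn",
    gephyrin_channel: str = "gephyrin",
    geph_soma_radius_um: float = GEPHYRIN_SOMA_RADIUS_UM,
    presyn_geph_radius_um: float = PRESYN_GEPHYRIN_RADIUS_UM,
    soma_count_radius_um: float = SOMA_COUNT_RADIUS_UM,
) -> BiasResult:
    """Full filter chain on a scene: gephyrin-by-soma, presyn-by-gephyrin,
    somatic counting, then the bias ratio."""
    geph = filter_gephyrin_by_soma(
        scene.puncta[gephyrin_channel], scene.somas, geph_soma_radius_um
    )
    pre = filter_presyn_by_gephyrin(
        scene.puncta[presyn_channel], geph, presyn_geph_radius_um
    )
    counts = count_on_somas(pre, scene.somas, soma_count_radius_um)
    return innervation_bias(counts, scene.somas)
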