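"""Somatic-position bookkeeping for heterotopic CA1.

Two depth conventions coexist: ``depth_pcl_um`` is measured from the
superficial front of the principal cell layer, while ``depth_radial_um``
runs from the alveus/cortex border toward the radiatum (the radial axis of
CA1, used for interneuron positions).  Cells are binned into deep and
superficial bands (in non-banded controls the single PCL is split into two
equal radial halves), per-band marker fractions are computed against the
DAPI denominator, and birth-dating experiments reduce to colocalization
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

__all__ = [
    "BandRois",
    "band_marker_fraction",
    "assign_bands",
    "position_histogram",
    "colocalization_fraction",
    "depth_convert",
]


@dataclass
class BandRois:
    """Deep and superficial bands as half-open depth intervals (um).

    Intervals are on the ``depth_pcl_um`` axis.  A cell exactly on the
    boundary between the bands is superficial (documented tie rule).
    """

    superficial: tuple
    deep: tuple

    def __post_init__(self) -> None:
        s0, s1 = self.superficial
        d0, d1 = self.deep
        if s0 >= s1 or d0 >= d1:
            raise ValueError("band intervals must be non-empty")
        if max(s0, d0) < min(s1, d1):
            raise ValueError("deep and superficial bands must be disjoint")

    @classmethod
    def split_single_pcl(cls, extent_um: tuple) -> "BandRois":
        """Control convention: divide the single PCL into two equal radial
        halves, the nearer half being superficial."""
        lo, hi = extent_um
        mid = (lo + hi) / 2.0
        return cls(superficial=(lo, mid), deep=(mid, hi))

    def band_of(self, depth_um: float) -> str:
        s0, s1 = self.superficial
        d0, d1 = self.deep
        if s0 <= depth_um <= s1:
            return "superficial"          # boundary ties resolve superficial
        if d0 <= depth_um <= d1:
            return "deep"
        return "none"


def assign_bands(cells: pd.DataFrame, rois: BandRois, depth_col: str = "depth_pcl_um") -> pd.Series:
    """Band label per cell from its depth; 'none' outside both bands."""
    return cells[depth_col].map(rois.band_of).rename("band")


def band_marker_fraction(
    cells: pd.DataFrame,
    rois: BandRois,
    marker: str,
    detection_marker: str = "dapi",
    depth_col: str = "depth_pcl_um",
) -> pd.Series:
    """Per-band fraction: marker-positive count / detected (DAPI) count.

    ``cells`` holds one row per cell with boolean marker columns.  Bands
    with no detected cell report NaN (undefined-fraction flag).
    """
    bands = assign_bands(cells, rois, depth_col)
    out = {}
    for band in ("deep", "superficial"):
        sel = cells[(bands == band) & cells[detection_marker].astype(bool)]
        out[band] = (
            float(sel[marker].astype(bool).mean()) if len(sel) else float("nan")
        )
    return pd.Series(out, name=f"{marker}_fraction")


def position_histogram(
    depths_um, bin_um: float = 20.0, normalize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of soma depths; normalized to unit sum when requested.

    Returns (bin_edges, values); edges start at 0 in steps of ``bin_um``.
    """
    if bin_um <= 0:
        raise ValueError("bin_um must be positive")
    depths = np.asarray(depths_um, dtype=float)
    hi = bin_um * (int(np.floor(depths.max() / bin_um)) + 1) if len(depths) else bin_um
    edges = np.arange(0.0, hi + bin_um / 2, bin_um)
    counts, _ = np.histogram(depths, bins=edges)
    values = counts / counts.sum() if normalize and counts.sum() else counts.astype(float)
    return edges, values


def colocalization_fraction(marked, costained) -> float:
    """Fraction of marked (e.g. birth-dated) cells co-staining for the
    second marker: |marked AND costained| / |marked|."""
    marked = set(marked)
    if not marked:
        return float("nan")
    return len(marked & set(costained)) / len(marked)


def depth_convert(
    xy_um, pcl_front: np.ndarray, alveus_border: np.ndarray
) -> pd.DataFrame:
    """Both somatic depth conventions from landmark polylines.

    ``pcl_front`` and ``alveus_border`` are (n, 2) polyline vertex arrays in
    um; depth is the distance to the nearest point on the polyline.  Returns
    a DataFrame with ``depth_pcl_um`` and ``depth_radial_um`` per cell.
    """
    pts = np.atleast_2d(np.asarray(xy_um, dtype=float))
    front = LineString(np.asarray(pcl_front, dtype=float))
    alveus = LineString(np.asarray(alveus_border, dtype=float))
    rows = []
    for x, y in pts:
        p = Point(x, y)
        rows.append(
            {"depth_pcl_um": float(front.distance(p)),
             "depth_radial_um": float(alveus.distance(p))}
        )
    return pd.DataFrame(rows)
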