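"""Dendritic morphometry from SWC reconstructions.

Parses single-neuron reconstructions, isolates the apical dendritic tree,
and computes the branch-structure summaries used to classify complex
(calbindin-predictive) versus simple CA1 pyramidal cells:

* the length-ratio index (LRI) and node-ratio index (ORI) evaluated at the
  first *prominent* apical bifurcation,
* the soma-to-first-prominent-bifurcation path distance, and
* Sholl intersection profiles of the apical tree.

All coordinates are micrometres.  SWC compartment codes follow the usual
convention: 1 = soma, 2 = axon, 3 = basal dendrite, 4 = apical dendrite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "NeuronMorphology",
    "DendriticTree",
    "MorphoFeatures",
    "ShollProfile",
    "IndexConfig",
    "SwcError",
    "read_swc",
    "write_swc",
    "extract_apical",
    "first_prominent_bifurcation",
    "lri_ori",
    "sholl",
]

SWC_COMPARTMENTS = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
COMPARTMENT_CODES = {v: k for k, v in SWC_COMPARTMENTS.items()}


class SwcError(ValueError):
    """Raised for malformed or structurally invalid SWC content."""


@dataclass
class NeuronMorphology:
    """A rooted 3D reconstruction.

    Node ids are contiguous 0..n-1 after ingest; ``parent[i]`` is the index
    of node *i*'s parent, or ``-1`` for the root.  Parents always precede
    their children, which rules out cycles.
    """

    xyz: np.ndarray                  # (n, 3) float, um
    radius: np.ndarray               # (n,) float, um
    compartment: np.ndarray          # (n,) int SWC type codes
    parent: np.ndarray               # (n,) int, -1 for root
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.compartment = np.asarray(self.compartment, dtype=int)
        self.parent = np.asarray(self.parent, dtype=int)
        n = len(self.xyz)
        if not np.all(np.isfinite(self.xyz)):
            raise SwcError("non-finite coordinates in reconstruction")
        if n and not np.any(self.compartment == COMPARTMENT_CODES["soma"]):
            raise SwcError("reconstruction has no soma node")
        for i, p in enumerate(self.parent):
            if p >= i:
                raise SwcError(
                    f"node {i}: parent {p} does not precede it (cycle or forward reference)"
                )
            if p < -1:
                raise SwcError(f"node {i}: invalid parent {p}")

    @property
    def n_nodes(self) -> int:
        return len(self.xyz)

    @property
    def soma_centroid(self) -> np.ndarray:
        mask = self.compartment == COMPARTMENT_CODES["soma"]
        return self.xyz[mask].mean(axis=0)

    def compartment_names(self) -> np.ndarray:
        return np.array([SWC_COMPARTMENTS.get(c, "other") for c in self.compartment])


@dataclass
class DendriticTree:
    """One compartment class of a reconstruction, as a rooted subtree.

    ``path_dist[i]`` is the cumulative path length from the soma node to
    node *i*, summing 3D segment lengths (the stem segment soma->root is
    included).  ``parent`` indexes within the subtree (-1 at the root).
    """

    xyz: np.ndarray
    parent: np.ndarray
    path_dist: np.ndarray
    soma_centroid: np.ndarray
    node_ids: np.ndarray        # indices into the source NeuronMorphology

    def __post_init__(self) -> None:
        self._children: list[list[int]] = [[] for _ in range(len(self.parent))]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self._children[p].append(i)
        # edge length from each node to its parent; root edge = stem length
        seg = np.empty(len(self.parent))
        for i, p in enumerate(self.parent):
            if p >= 0:
                seg[i] = np.linalg.norm(self.xyz[i] - self.xyz[p])
            else:
                seg[i] = self.path_dist[i]
        self.segment_length = seg

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def children(self, i: int) -> list[int]:
        return self._children[i]

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def is_bifurcation(self, i: int) -> bool:
        return len(self._children[i]) >= 2

    @property
    def bifurcation_count(self) -> int:
        return sum(len(c) >= 2 for c in self._children)

    @property
    def total_length(self) -> float:
        """Total dendritic length including the soma->stem segment."""
        return float(self.segment_length.sum())

    def subtree_nodes(self, i: int) -> list[int]:
        out, stack = [], [i]
        while stack:
            j = stack.pop()
            out.append(j)
            stack.extend(self._children[j])
        return out

    def subtree_length(self, i: int, include_edge: bool = True) -> float:
        """Summed segment length of the subtree rooted at node *i*.

        With ``include_edge`` the segment from *i* back to its parent is
        counted, so daughter lengths at a bifurcation partition the
        remaining length exactly.
        """
        nodes = self.subtree_nodes(i)
        total = float(self.segment_length[nodes].sum())
        if not include_edge:
            total -= float(self.segment_length[i])
        return total

    def subtree_bifurcation_count(self, i: int) -> int:
        return sum(len(self._children[j]) >= 2 for j in self.subtree_nodes(i))


@dataclass
class MorphoFeatures:
    """Per-cell branch-structure summary used for k-means classification."""

    lri: float
    ori: float
    first_bifurcation_um: float
    selected_node_distance_um: float
    pcl_depth_um: float = float("nan")
    total_apical_length_um: float = float("nan")
    bifurcation_count: int = 0
    defined: bool = True            # False for unbranched trees


@dataclass
class ShollProfile:
    radii: np.ndarray               # um, uniform step
    intersections: np.ndarray       # integer crossing counts

    @property
    def peak_count(self) -> int:
        return int(self.intersections.max(initial=0))

    @property
    def peak_radius_um(self) -> float:
        if len(self.radii) == 0:
            return float("nan")
        return float(self.radii[int(np.argmax(self.intersections))])


@dataclass
class IndexConfig:
    """Configuration for the LRI/ORI branch indices.

    ``lri_fn``/``ori_fn`` allow swapping in an alternative formula (they
    receive the same measurement dict); the defaults implement

        LRI = ln((Ld1 + Ld2) / Lp)
        ORI = ln((Nd1 + Nd2 + n_daughters) / (Np + 1))

    where Lp is the soma-to-selected-node path length, Ld the daughter
    subtree total lengths, Nd the daughter subtree bifurcation counts and
    Np the number of non-prominent bifurcations skipped proximal to the
    selected node.  When the selected node is distant from the soma
    (Lp > d0_um) both indices are scaled by d0_um / Lp.
    """

    prominence_frac: float = 0.2
    d0_um: float = 150.0
    lri_fn: Callable[[dict], float] | None = None
    ori_fn: Callable[[dict], float] | None = None


# ---------------------------------------------------------------------------
# SWC I/O

def read_swc(path) -> NeuronMorphology:
    """Read a 7-column SWC file into a validated :class:`NeuronMorphology`.

    Node ids are remapped to contiguous 0-based indices.  Comment lines
    start with ``#``.  Units are assumed to be micrometres.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SwcError(f"line {lineno}: expected 7 fields, got {len(fields)}")
            try:
                nid = int(fields[0])
                ctype = int(fields[1])
                x, y, z, r = (float(v) for v in fields[2:6])
                pid = int(fields[6])
            except ValueError as exc:
                raise SwcError(f"line {lineno}: non-numeric field ({exc})") from None
            records.append((nid, ctype, x, y, z, r, pid))
    if not records:
        raise SwcError("empty SWC file")

    id_map: dict[int, int] = {}
    for nid, *_ in records:
        if nid in id_map:
            raise SwcError(f"duplicate node id {nid}")
        id_map[nid] = len(id_map)

    n = len(records)
    xyz = np.empty((n, 3))
    radius = np.empty(n)
    comp = np.empty(n, dtype=int)
    parent = np.empty(n, dtype=int)
    for i, (nid, ctype, x, y, z, r, pid) in enumerate(records):
        xyz[i] = (x, y, z)
        radius[i] = r
        comp[i] = ctype
        if pid == -1:
            parent[i] = -1
        else:
            if pid not in id_map:
                raise SwcError(f"node {nid}: parent id {pid} not found (orphan)")
            parent[i] = id_map[pid]
    return NeuronMorphology(xyz=xyz, radius=radius, compartment=comp, parent=parent)


def write_swc(neuron: NeuronMorphology, path) -> None:
    """Write a reconstruction as 7-column SWC (1-based contiguous ids)."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(neuron.n_nodes):
            p = neuron.parent[i]
            fh.write(
                "%d %d %.4f %.4f %.4f %.4f %d\n"
                % (
                    i + 1,
                    neuron.compartment[i],
                    neuron.xyz[i, 0],
                    neuron.xyz[i, 1],
                    neuron.xyz[i, 2],
                    neuron.radius[i],
                    p + 1 if p >= 0 else -1,
                )
            )


# ---------------------------------------------------------------------------
# Tree extraction and measures

def extract_compartment(neuron: NeuronMorphology, name: str) -> DendriticTree:
    code = COMPARTMENT_CODES[name]
    mask = neuron.compartment == code
    if not mask.any():
        raise ValueError(f"reconstruction has no '{name}' nodes")
    idx = np.flatnonzero(mask)
    pos = {int(j): k for k, j in enumerate(idx)}

    soma = neuron.soma_centroid
    parent = np.empty(len(idx), dtype=int)
    path = np.empty(len(idx))
    for k, j in enumerate(idx):
        p = neuron.parent[j]
        seg = (
            float(np.linalg.norm(neuron.xyz[j] - neuron.xyz[p]))
            if p >= 0
            else float(np.linalg.norm(neuron.xyz[j] - soma))
        )
        if p >= 0 and int(p) in pos:
            parent[k] = pos[int(p)]
            path[k] = path[pos[int(p)]] + seg
        else:
            # stem node: parent is the soma (or missing) -> subtree root
            parent[k] = -1
            path[k] = seg
    return DendriticTree(
        xyz=neuron.xyz[idx],
        parent=parent,
        path_dist=path,
        soma_centroid=soma,
        node_ids=idx,
    )


def extract_apical(neuron: NeuronMorphology) -> DendriticTree:
    """Isolate the apical dendritic tree rooted at the stem nearest the soma."""
    return extract_compartment(neuron, "apical")


def _primary_daughter(tree: DendriticTree, kids: Sequence[int]) -> int:
    """Daughter carrying the greater total subtree length; ties -> lower id."""
    best, best_len = None, -1.0
    for c in sorted(kids):
        ln = tree.subtree_length(c)
        if ln > best_len + 1e-12:
            best, best_len = c, ln
    return best


@dataclass
class BifurcationResult:
    node: int
    distance_um: float
    prominent: bool            # False when no bifurcation qualified
    n_skipped: int             # non-prominent bifurcations passed on the way


def first_prominent_bifurcation(
    tree: DendriticTree, prominence_frac: float = 0.2
) -> BifurcationResult:
    """Walk the primary apical path to the first prominent bifurcation.

    At each bifurcation the daughters' shares of the remaining length are
    computed; the node qualifies when the smallest daughter's share is at
    least ``prominence_frac``.  If no node qualifies, the distal-most
    bifurcation on the primary path is returned flagged ``prominent=False``
    (or the tip, for an unbranched tree).
    """
    if not 0 < prominence_frac <= 0.5:
        raise ValueError("prominence_frac must be in (0, 0.5]")
    node = tree.root
    skipped = 0
    last_bif: int | None = None
    while True:
        kids = tree.children(node)
        if len(kids) == 0:
            if last_bif is not None:
                return BifurcationResult(
                    last_bif, float(tree.path_dist[last_bif]), False, skipped
                )
            return BifurcationResult(node, float(tree.path_dist[node]), False, 0)
        if len(kids) >= 2:
            lengths = np.array([tree.subtree_length(c) for c in kids])
            shares = lengths / lengths.sum()
            if shares.min() >= prominence_frac:
                return BifurcationResult(
                    node, float(tree.path_dist[node]), True, skipped
                )
            skipped += 1
            last_bif = node
            node = _primary_daughter(tree, kids)
        else:
            node = kids[0]


def lri_ori(tree: DendriticTree, cfg: IndexConfig | None = None) -> MorphoFeatures:
    """Length-ratio and node-ratio indices at the first prominent bifurcation.

    Returns ``defined=False`` (NaN indices) for unbranched trees, which are
    excluded from clustering downstream.
    """
    cfg = cfg or IndexConfig()
    sel = first_prominent_bifurcation(tree, cfg.prominence_frac)
    kids = tree.children(sel.node)
    if len(kids) < 2:
        return MorphoFeatures(
            lri=float("nan"),
            ori=float("nan"),
            first_bifurcation_um=sel.distance_um,
            selected_node_distance_um=sel.distance_um,
            total_apical_length_um=tree.total_length,
            bifurcation_count=tree.bifurcation_count,
            defined=False,
        )
    lp = float(tree.path_dist[sel.node])
    daughter_lengths = [tree.subtree_length(c) for c in kids]
    daughter_bifs = [tree.subtree_bifurcation_count(c) for c in kids]
    meas = {
        "Lp": lp,
        "Ld": daughter_lengths,
        "Nd": daughter_bifs,
        "Np": sel.n_skipped,
        "n_daughters": len(kids),
    }
    lri = (
        cfg.lri_fn(meas)
        if cfg.lri_fn is not None
        else math.log(sum(daughter_lengths) / lp)
    )
    ori = (
        cfg.ori_fn(meas)
        if cfg.ori_fn is not None
        else math.log((sum(daughter_bifs) + len(kids)) / (sel.n_skipped + 1))
    )
    if lp > cfg.d0_um:
        scale = cfg.d0_um / lp
        lri *= scale
        ori *= scale
    return MorphoFeatures(
        lri=float(lri),
        ori=float(ori),
        first_bifurcation_um=sel.distance_um,
        selected_node_distance_um=sel.distance_um,
        total_apical_length_um=tree.total_length,
        bifurcation_count=tree.bifurcation_count,
        defined=True,
    )


def sholl(tree: DendriticTree, step_um: float = 20.0) -> ShollProfile:
    """Sholl intersection profile: crossings of concentric spheres.

    Spheres are centred on the soma centroid.  A segment crosses radius r
    when one endpoint lies strictly inside and the other at or beyond r
    (linear interpolation along segments; the stem segment from the soma
    is included).
    """
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    if tree.n_nodes == 0:
        return ShollProfile(radii=np.array([]), intersections=np.array([], dtype=int))
    rdist = np.linalg.norm(tree.xyz - tree.soma_centroid, axis=1)
    max_r = float(rdist.max())
    n_radii = int(math.floor(max_r / step_um)) + 1   # last radius has zero crossings
    radii = step_um * np.arange(1, n_radii + 1)
    counts = np.zeros(n_radii, dtype=int)
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        d_child = rdist[i]
        d_parent = rdist[p] if p >= 0 else 0.0   # stem starts at the soma centroid
        lo, hi = min(d_parent, d_child), max(d_parent, d_child)
        # crossed radii r with lo < r <= hi
        k_lo = int(math.floor(lo / step_um)) + 1
        k_hi = int(math.floor(hi / step_um))
        if hi % step_um == 0 and hi > 0:
            k_hi = int(round(hi / step_um))
        for k in range(k_lo, min(k_hi, n_radii) + 1):
            counts[k - 1] += 1
    return ShollProfile(radii=radii, intersections=counts)
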