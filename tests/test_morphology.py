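import math

import numpy as np
import pytest

from ca1quant import morphology as mor
from ca1quant.morphology import (
    IndexConfig,
    SwcError,
    extract_apical,
    first_prominent_bifurcation,
    lri_ori,
    read_swc,
    sholl,
    write_swc,
)
from ca1quant.synth import gen_tree

from conftest import build_neuron


class TestSwcIO:
    def test_three_node_file(self, tmp_path):
        p = tmp_path / "cell.swc"
        p.write_text(
            "# comment\n"
            "1 1 0 0 0 5 -1\n"
            "2 4 0 10 0 1 1\n"
            "3 4 0 20 0 1 2\n"
        )
        neuron = read_swc(p)
        assert neuron.n_nodes == 3
        assert extract_apical(neuron).total_length == pytest.approx(20.0)

    def test_orphan_parent_is_structural_error(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 4 0 10 0 1 99\n")
        with pytest.raises(SwcError, match="99"):
            read_swc(p)

    def test_non_numeric_field_names_line(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 4 zero 10 0 1 1\n")
        with pytest.raises(SwcError, match="line 2"):
            read_swc(p)

    def test_wrong_field_count(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5\n")
        with pytest.raises(SwcError, match="7 fields"):
            read_swc(p)

    def test_round_trip(self, tmp_path):
        neuron = gen_tree("complex", seed=7)
        p = tmp_path / "t.swc"
        write_swc(neuron, p)
        back = read_swc(p)
        assert back.n_nodes == neuron.n_nodes
        np.testing.assert_allclose(back.xyz, neuron.xyz, atol=1e-4)
        np.testing.assert_array_equal(back.parent, neuron.parent)
        np.testing.assert_array_equal(back.compartment, neuron.compartment)


class TestExtractApical:
    def test_label_filter(self):
        nodes = [(0, 0, 0, "soma", -1)]
        for i in range(5):
            nodes.append((0, 10 * (i + 1), 0, "apical", i))
        for i in range(4):
            nodes.append((10 * (i + 1), 0, 0, "basal", 0 if i == 0 else len(nodes) - 1))
        tree = extract_apical(build_neuron(nodes))
        assert tree.n_nodes == 5

    def test_straight_cable_cumulative_distance(self):
        nodes = [(0, 0, 0, "soma", -1)]
        for i in range(30):
            nodes.append((0, 10 * (i + 1), 0, "apical", i))
        tree = extract_apical(build_neuron(nodes))
        assert tree.path_dist.max() == pytest.approx(300.0)
        assert tree.total_length == pytest.approx(300.0)

    def test_no_apical_nodes_errors(self):
        neuron = build_neuron([(0, 0, 0, "soma", -1), (10, 0, 0, "basal", 0)])
        with pytest.raises(ValueError, match="apical"):
            extract_apical(neuron)

    @pytest.mark.parametrize("seed", range(10))
    def test_total_length_matches_bruteforce(self, seed):
        """Tree length equals a naive edge-by-edge re-count (oracle equivalence)."""
        neuron = gen_tree("complex" if seed % 2 else "simple", seed=seed)
        tree = extract_apical(neuron)
        apical_code = mor.COMPARTMENT_CODES["apical"]
        brute = 0.0
        for i in range(neuron.n_nodes):
            if neuron.compartment[i] != apical_code:
                continue
            p = neuron.parent[i]
            src = neuron.xyz[p] if p >= 0 else neuron.soma_centroid
            brute += float(np.linalg.norm(neuron.xyz[i] - src))
        assert tree.total_length == pytest.approx(brute, rel=1e-12)
        # bifurcation count by naive child tally
        kids = {}
        for i in range(tree.n_nodes):
            if tree.parent[i] >= 0:
                kids[tree.parent[i]] = kids.get(tree.parent[i], 0) + 1
        assert tree.bifurcation_count == sum(1 for v in kids.values() if v >= 2)


class TestFirstProminentBifurcation:
    def test_symmetric_y(self, y_tree):
        res = first_prominent_bifurcation(extract_apical(y_tree))
        assert res.prominent
        assert res.distance_um == pytest.approx(150.0)

    def test_twig_is_skipped(self):
        # trunk with a 5-um twig at 50 um, balanced split at 300 um
        nodes = [(0, 0, 0, "soma", -1)]
        parent = 0
        for y in range(10, 51, 10):
            nodes.append((0, y, 0, "apical", parent))
            parent = len(nodes) - 1
        twig_at = parent
        nodes.append((5, 50, 0, "apical", twig_at))          # the twig
        parent = twig_at
        for y in range(60, 301, 10):
            nodes.append((0, y, 0, "apical", parent))
            parent = len(nodes) - 1
        split = parent
        for dx in (1.0, -1.0):
            parent = split
            for k in range(1, 11):
                nodes.append((dx * 6 * k, 300 + 8 * k, 0, "apical", parent))
                parent = len(nodes) - 1
        res = first_prominent_bifurcation(extract_apical(build_neuron(nodes)), 0.2)
        assert res.prominent
        assert res.distance_um == pytest.approx(300.0)
        assert res.n_skipped == 1

    def test_unbranched_tree_flagged(self):
        nodes = [(0, 0, 0, "soma", -1)] + [
            (0, 10 * (i + 1), 0, "apical", i) for i in range(10)
        ]
        res = first_prominent_bifurcation(extract_apical(build_neuron(nodes)))
        assert not res.prominent
        assert res.distance_um == pytest.approx(100.0)

    def test_complex_cohort_bifurcates_sooner(self):
        dist = {"complex": [], "simple": []}
        rng = np.random.default_rng(5)
        for arch in dist:
            for _ in range(25):
                tree = extract_apical(gen_tree(arch, rng))
                dist[arch].append(first_prominent_bifurcation(tree).distance_um)
        assert np.mean(dist["complex"]) < np.mean(dist["simple"])


class TestLriOri:
    def test_reference_values(self, index_tree):
        f = lri_ori(extract_apical(index_tree), IndexConfig(d0_um=150.0))
        assert f.lri == pytest.approx(math.log(2.0), abs=1e-12)
        assert f.ori == pytest.approx(math.log(6.0), abs=1e-12)

    def test_distant_node_scaling(self, index_tree):
        """With Lp = 300 > D0 = 150, both indices are scaled by 150/300."""
        neuron = index_tree
        stretched = neuron.xyz.copy()
        apical_code = mor.COMPARTMENT_CODES["apical"]
        trunk = (neuron.compartment == apical_code) & (np.abs(stretched[:, 0]) < 1e-9)
        stretched[trunk, 1] *= 3.0                 # trunk now 300 um
        shift = (neuron.compartment == apical_code) & ~trunk
        stretched[shift, 1] += 200.0               # keep daughters attached
        moved = build_neuron(
            [
                (x, y, z, "soma" if c == 1 else "apical", p)
                for (x, y, z), c, p in zip(stretched, neuron.compartment, neuron.parent)
            ]
        )
        f = lri_ori(extract_apical(moved), IndexConfig(d0_um=150.0))
        assert f.lri == pytest.approx(0.5 * math.log(200.0 / 300.0), abs=1e-12)
        assert f.ori == pytest.approx(0.5 * math.log(6.0), abs=1e-12)

    def test_unbranched_tree_undefined(self):
        nodes = [(0, 0, 0, "soma", -1)] + [
            (0, 10 * (i + 1), 0, "apical", i) for i in range(5)
        ]
        f = lri_ori(extract_apical(build_neuron(nodes)))
        assert not f.defined
        assert math.isnan(f.lri) and math.isnan(f.ori)

    def test_rigid_motion_invariance(self, index_tree):
        """LRI/ORI depend only on path lengths, not the coordinate frame."""
        ref = lri_ori(extract_apical(index_tree))
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = index_tree.xyz @ q.T + np.array([13.0, -7.0, 4.0])
        rotated = build_neuron(
            [
                (x, y, z, "soma" if c == 1 else "apical", p)
                for (x, y, z), c, p in zip(moved, index_tree.compartment, index_tree.parent)
            ]
        )
        f = lri_ori(extract_apical(rotated))
        assert f.lri == pytest.approx(ref.lri, abs=1e-9)
        assert f.ori == pytest.approx(ref.ori, abs=1e-9)

    def test_lri_monotone_in_daughter_length(self, index_tree):
        """Extending a daughter subtree strictly increases LRI."""
        ref = lri_ori(extract_apical(index_tree))
        extended = index_tree.xyz.copy()
        tip = extended[:, 1].argmax()
        extended[tip, 1] += 50.0
        longer = build_neuron(
            [
                (x, y, z, "soma" if c == 1 else "apical", p)
                for (x, y, z), c, p in zip(extended, index_tree.compartment, index_tree.parent)
            ]
        )
        assert lri_ori(extract_apical(longer)).lri > ref.lri

    def test_cohort_ordering(self):
        """Complex archetypes score higher than simple on both indices."""
        rng = np.random.default_rng(11)
        vals = {"complex": [], "simple": []}
        for arch in vals:
            for _ in range(25):
                f = lri_ori(extract_apical(gen_tree(arch, rng)))
                vals[arch].append((f.lri, f.ori))
        c = np.mean(vals["complex"], axis=0)
        s = np.mean(vals["simple"], axis=0)
        assert c[0] > s[0] and c[1] > s[1]


class TestSholl:
    def test_straight_cable(self):
        nodes = [(0, 0, 0, "soma", -1)] + [
            (0, 10 * (i + 1), 0, "apical", i) for i in range(30)
        ]
        prof = sholl(extract_apical(build_neuron(nodes)), 50.0)
        np.testing.assert_array_equal(prof.intersections, [1, 1, 1, 1, 1, 1, 0])

    def test_y_tree_hand_count(self):
        # split at 75 um, both daughters reaching radius just over 200 um
        nodes = [(0, 0, 0, "soma", -1)]
        parent = 0
        for y in (25, 50, 75):
            nodes.append((0, y, 0, "apical", parent))
            parent = len(nodes) - 1
        split = parent
        for dx in (0.5, -0.5):
            parent = split
            for y in (120, 160, 200.5):
                nodes.append((dx, y, 0, "apical", parent))
                parent = len(nodes) - 1
        prof = sholl(extract_apical(build_neuron(nodes)), 50.0)
        np.testing.assert_array_equal(prof.intersections, [1, 2, 2, 2, 0])
        assert prof.peak_count == 2
        assert prof.peak_radius_um == 100.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_beyond_max_extent(self, seed):
        tree = extract_apical(gen_tree("complex", seed=seed))
        prof = sholl(tree, 20.0)
        max_extent = np.linalg.norm(tree.xyz - tree.soma_centroid, axis=1).max()
        beyond = prof.radii > max_extent
        assert np.all(prof.intersections[beyond] == 0)

    def test_step_must_be_positive(self, y_tree):
        with pytest.raises(ValueError):
            sholl(extract_apical(y_tree), 0.0)
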