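import numpy as np
import pytest

import sigflow as sf
from sigflow.treegraph import _attachment


def brute_force_distance(tree, shoot_id, sam_id):
    """Independent oracle: enumerate the root path between attachments."""
    def root_path(cid):
        path = [cid]
        while tree.components[path[-1]].parent is not None:
            path.append(tree.components[path[-1]].parent)
        return path

    shoot = tree.shoots[shoot_id]
    target = tree.shoots[tree.sams[sam_id].shoot_id]
    a, b = _attachment(tree, shoot), _attachment(tree, target)
    pa, pb = root_path(a), root_path(b)
    common = set(pa) & set(pb)
    ia = next(i for i, c in enumerate(pa) if c in common)
    ib = next(i for i, c in enumerate(pb) if c in common)
    walk = pa[:ia + 1] + list(reversed(pb[:ib]))
    path_len = sum(
        np.linalg.norm(tree.components[u].base - tree.components[v].base)
        for u, v in zip(walk, walk[1:]))
    return (np.linalg.norm(shoot.base - shoot.barycenter) + path_len
            + np.linalg.norm(target.base - target.extremity))


class TestDistances:
    def test_single_shoot_self_distance(self):
        # straight 0.10 m shoot, barycenter at midpoint: 0.05 + 0 + 0.10
        tree = sf.build_linear_branch(n_shoots=1, spacing=0.15,
                                      shoot_length=0.10)
        D = sf.compute_distances(tree)
        assert D.d.shape == (1, 1)
        assert D.d[0, 0] == pytest.approx(0.15, abs=1e-12)

    def test_two_shoots_same_attachment(self):
        # both branches hang at the origin: inter-attachment path is zero
        tree = sf.build_two_branch(shoots_per_branch=2, spacing=0.15,
                                   shoot_length=0.10)
        D = sf.compute_distances(tree)
        i = D.shoot_ids.index("B1S1")
        j = D.sam_ids.index("B2S1/sam")
        assert D.d[i, j] == pytest.approx(0.05 + 0.0 + 0.10, abs=1e-12)

    def test_linear_spacing_distances(self, six_shoot):
        # shoots k apart along the carrier differ by k * 0.15 m of path
        D = sf.compute_distances(six_shoot)
        i = D.shoot_ids.index("S1")
        for k, sid in enumerate(D.sam_ids):
            expected = 0.05 + 0.15 * k + 0.10
            assert D.d[i, k] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_shoot_zero_distance(self):
        tree = sf.TreeGraph()
        tree.components["T"] = sf.Component("T", "tree", None, None,
                                            (0, 0, 0), (0, 0, 0))
        tree.components["S"] = sf.Component("S", "segment", "T", "branching",
                                            (0, 0, 0), (0, 0, 0))
        tree.shoots["s1"] = sf.AnnualShoot("s1", ["S"], (0, 0, 0), (0, 0, 0),
                                           (0, 0, 0))
        tree.sams["s1/sam"] = sf.SAM("s1/sam", "s1", (0, 0, 0))
        D = sf.compute_distances(tree)
        assert D.d[0, 0] == 0.0

    @pytest.mark.parametrize("builder", [
        lambda: sf.build_linear_branch(6, 0.15, 0.1, fruiting={1, 2, 4}),
        lambda: sf.build_two_branch(4, "by_shoot", "fruit"),
        lambda: sf.build_four_branch(2),
        lambda: sf.generate_digitized_like_tree(seed=11, n_shoots=10,
                                                shoots_per_branch=3),
    ])
    def test_matches_brute_force_oracle(self, builder):
        tree = builder()
        D = sf.compute_distances(tree)
        for i, sid in enumerate(D.shoot_ids):
            for j, mid in enumerate(D.sam_ids):
                assert D.d[i, j] == pytest.approx(
                    brute_force_distance(tree, sid, mid), abs=1e-9)

    def test_own_sam_is_strictly_nearest(self, six_shoot):
        # needed for the large-r concentration limit to be tie-free
        D = sf.compute_distances(six_shoot)
        for j, mid in enumerate(D.sam_ids):
            owner = six_shoot.sams[mid].shoot_id
            i = D.shoot_ids.index(owner)
            assert D.d[i, j] > 0
            others = [D.d[k, j] for k in range(len(D.shoot_ids)) if k != i]
            assert D.d[i, j] < min(others)

    def test_disconnected_component_rejected(self, six_shoot):
        six_shoot.components["orphan"] = sf.Component(
            "orphan", "segment", None, None, (9, 9, 9), (9, 9, 10))
        with pytest.raises(sf.StructureError):
            sf.compute_distances(six_shoot)


class TestBuilders:
    def test_six_shoot_counts(self, six_shoot):
        assert len(six_shoot.sams) == 6
        total_fruit = sum(s.fruit_count for s in six_shoot.shoots.values())
        assert total_fruit == 3

    def test_single_shoot_structure(self):
        tree = sf.build_linear_branch(n_shoots=1)
        assert len(tree.shoots) == 1 and len(tree.sams) == 1

    def test_empty_fruiting_selection(self):
        tree = sf.build_linear_branch(n_shoots=6)
        assert sum(s.fruit_count for s in tree.shoots.values()) == 0

    def test_out_of_range_ids_rejected(self):
        with pytest.raises(ValueError):
            sf.build_linear_branch(n_shoots=6, fruiting={7})

    def test_two_branch_by_branch_fruit(self, two_branch_fruit):
        fc = {s.branch_id: [] for s in two_branch_fruit.shoots.values()}
        for s in two_branch_fruit.shoots.values():
            fc[s.branch_id].append(s.fruit_count)
        assert all(v == 1 for v in fc["B1"])
        assert all(v == 0 for v in fc["B2"])

    @pytest.mark.parametrize("k", [2, 5, 6])
    def test_two_branch_by_shoot_halving(self, k):
        tree = sf.build_two_branch(k, "by_shoot", "fruit")
        for b in ("B1", "B2"):
            n = sum(s.fruit_count for s in tree.shoots.values()
                    if s.branch_id == b)
            assert n in (k // 2, -(-k // 2))

    def test_four_branch_labels_and_organs(self, four_branch):
        labels = {s.part_label for s in four_branch.shoots.values()}
        assert len(labels) == 4
        b2 = [s for s in four_branch.shoots.values()
              if s.part_label.startswith("2")]
        assert all(s.leaf_area > 0 and s.fruit_count == 0 for s in b2)
        b4 = [s for s in four_branch.shoots.values()
              if s.part_label.startswith("4")]
        assert all(s.leaf_area == 0 and s.fruit_count == 0 for s in b4)

    def test_four_branch_single_shoot_count(self):
        assert len(sf.build_four_branch(1).sams) == 4


class TestGenerator:
    def test_seeded_determinism(self):
        a = sf.generate_digitized_like_tree(seed=42, n_shoots=50)
        b = sf.generate_digitized_like_tree(seed=42, n_shoots=50)
        assert a.shoot_ids() == b.shoot_ids()
        for sid in a.shoot_ids():
            assert a.shoots[sid].leaf_area == b.shoots[sid].leaf_area
            assert np.array_equal(a.shoots[sid].base, b.shoots[sid].base)

    def test_leaf_area_spread(self):
        tree = sf.generate_digitized_like_tree(seed=7, n_shoots=500,
                                               la_mean=100, la_spread=20)
        la = np.array([s.leaf_area for s in tree.shoots.values()])
        frac = ((la >= 80) & (la <= 120)).mean()
        assert 0.70 <= frac <= 0.85

    def test_y_shape_has_two_sides(self):
        tree = sf.generate_digitized_like_tree(seed=1, n_shoots=40,
                                               form="y_shape")
        sides = {s.side for s in tree.shoots.values()}
        assert sides == {"side1", "side2"}
        trunk_roots = [c for c in tree.components.values()
                       if c.parent == "T" and c.scale == "segment"]
        assert len(trunk_roots) == 2
        assert all(c.edge_kind == "branching" for c in trunk_roots)

    def test_on_configuration_one_fruit_per_shoot(self):
        tree = sf.generate_digitized_like_tree(seed=5, n_shoots=30)
        assert all(s.fruit_count == 1 for s in tree.shoots.values())


class TestLeafAreaAllometry:
    def test_zero_length(self):
        assert sf.reconstruct_leaf_area(0.0, (500.0, 1.2)) == 0.0

    def test_linear_case(self):
        assert sf.reconstruct_leaf_area(0.10, (1000.0, 1.0)) == pytest.approx(100.0)

    def test_monotone_in_length(self):
        lengths = np.linspace(0, 0.5, 20)
        areas = [sf.reconstruct_leaf_area(x, (800.0, 1.4)) for x in lengths]
        assert all(a <= b for a, b in zip(areas, areas[1:]))

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError):
            sf.reconstruct_leaf_area(0.1, (-1.0, 1.0))


class TestStructureFile:
    @pytest.mark.parametrize("builder", [
        lambda: sf.build_linear_branch(6, 0.15, 0.1, fruiting={1, 2, 4},
                                       leafy={1, 3}),
        lambda: sf.build_two_branch(4, "by_shoot", "leaf"),
        lambda: sf.generate_digitized_like_tree(seed=2, n_shoots=20,
                                                form="y_shape"),
    ])
    def test_round_trip(self, builder, tmp_path):
        tree = builder()
        path = tmp_path / "t.txt"
        sf.write_structure(tree, path)
        back = sf.read_structure(path)
        assert back.shoot_ids() == tree.shoot_ids()
        assert back.sam_ids() == tree.sam_ids()
        assert set(back.components) == set(tree.components)
        assert back.tcsa == tree.tcsa
        for sid in tree.shoot_ids():
            a, b = tree.shoots[sid], back.shoots[sid]
            assert np.allclose(a.base, b.base) and np.allclose(a.extremity,
                                                               b.extremity)
            assert np.allclose(a.barycenter, b.barycenter)
            assert (a.leaf_area, a.fruit_count, a.part_label, a.branch_id,
                    a.side) == (b.leaf_area, b.fruit_count, b.part_label,
                                b.branch_id, b.side)
        # and the distances, the quantity the file exists to carry
        assert np.allclose(sf.compute_distances(tree).d,
                           sf.compute_distances(back).d, atol=1e-12)

    def test_scale_nesting_violation(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(
            "unit m\n"
            "component T tree - - 0 0 0 0 0 0\n"
            "component M metamer T succession 0 0 0 0 0 1\n")
        with pytest.raises(sf.ParseError, match="line 3"):
            sf.read_structure(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "dup.txt"
        path.write_text(
            "component T tree - - 0 0 0 0 0 0\n"
            "component S segment T branching 0 0 0 0 0 1\n"
            "component S segment T branching 0 0 0 0 0 2\n")
        with pytest.raises(sf.ParseError, match="duplicate"):
            sf.read_structure(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("# nothing here\n")
        with pytest.raises(sf.ParseError):
            sf.read_structure(path)
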