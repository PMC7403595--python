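"""Multiscale tree architectures: data model, distances, builders and file I/O.

A tree is described at three nested topological scales — the whole tree, the
stem segments that compose its axes, and the metamers of current-year shoots.
Annual shoots are the functional units: each bears leaves (a source of
flowering-activating signal), optionally fruit (a source of inhibiting
signal), and a terminal shoot apical meristem (SAM) whose floral fate the
model predicts.

Distances between a source shoot ``i`` and a target SAM ``j`` follow the
topological pathway through the structure: the Euclidean distance from the
base of shoot ``i`` to its barycenter, plus the Euclidean lengths between the
successive component bases along the unique path linking the two shoot
attachments, plus the distance from the base of the SAM-bearing shoot to its
extremity.  All coordinates are Cartesian (z up) and the canonical length
unit is the metre; attenuation parameters are only interpretable with metre
distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Component",
    "AnnualShoot",
    "SAM",
    "TreeGraph",
    "DistanceMatrix",
    "StructureError",
    "ParseError",
    "compute_distances",
    "build_linear_branch",
    "build_two_branch",
    "build_four_branch",
    "generate_digitized_like_tree",
    "reconstruct_leaf_area",
    "read_structure",
    "write_structure",
]

SCALES = ("tree", "segment", "metamer")
EDGE_KINDS = ("succession", "branching")

#: TCSA values (cm^2) typical of the two training systems emulated by the
#: synthetic generator: one vertical trunk ("solaxe") vs two inclined trunks
#: ("y_shape").
DEFAULT_TCSA = {"solaxe": 20.4, "y_shape": 24.7}


class StructureError(ValueError):
    """Raised when a tree graph violates a structural invariant."""


class ParseError(ValueError):
    """Raised on malformed structure files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _pt(x) -> np.ndarray:
    p = np.asarray(x, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"expected a 3D point, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError(f"non-finite coordinates: {p}")
    return p


@dataclass
class Component:
    """One topological component (tree, segment or metamer scale).

    ``base`` and ``tip`` are the 3D endpoints in metres.  ``parent`` is the
    id of the supporting component (None only for the tree-scale root);
    ``edge_kind`` qualifies the connection to the parent.
    """

    id: str
    scale: str
    parent: str | None
    edge_kind: str | None
    base: np.ndarray
    tip: np.ndarray

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.edge_kind is not None and self.edge_kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {self.edge_kind!r}")
        self.base = _pt(self.base)
        self.tip = _pt(self.tip)


@dataclass
class AnnualShoot:
    """Current-year shoot: the source unit for both signals.

    ``leaf_area`` is in cm^2 (0 for a defoliated shoot); ``fruit_count`` is
    the number of fruit borne at the shoot base.  ``part_label`` is a free
    tag used to aggregate floral-induction probabilities over tree parts;
    ``branch_id`` and ``side`` support organ removal at branch and half-tree
    scales.
    """

    id: str
    segment_ids: list[str]
    base: np.ndarray
    extremity: np.ndarray
    barycenter: np.ndarray
    leaf_area: float = 0.0
    fruit_count: int = 0
    has_terminal_sam: bool = True
    part_label: str = ""
    branch_id: str = ""
    side: str = ""

    def __post_init__(self):
        self.base = _pt(self.base)
        self.extremity = _pt(self.extremity)
        self.barycenter = _pt(self.barycenter)
        if self.leaf_area < 0:
            raise ValueError("leaf_area must be >= 0")
        if self.fruit_count < 0:
            raise ValueError("fruit_count must be >= 0")


@dataclass
class SAM:
    """Terminal shoot apical meristem; its position is the shoot extremity."""

    id: str
    shoot_id: str
    position: np.ndarray

    def __post_init__(self):
        self.position = _pt(self.position)


@dataclass
class TreeGraph:
    """A multiscale architecture: components, annual shoots and their SAMs.

    ``tcsa`` (trunk cross-sectional area, cm^2) is optional metadata used
    only for crop-load computations.  Iteration order over shoots and SAMs
    is deterministic (sorted by id).
    """

    components: dict[str, Component] = field(default_factory=dict)
    shoots: dict[str, AnnualShoot] = field(default_factory=dict)
    sams: dict[str, SAM] = field(default_factory=dict)
    tcsa: float | None = None
    unit: str = "m"

    def shoot_ids(self) -> list[str]:
        return sorted(self.shoots)

    def sam_ids(self) -> list[str]:
        return sorted(self.sams)

    def n_sams(self) -> int:
        return len(self.sams)

    def copy(self) -> "TreeGraph":
        return TreeGraph(
            components={k: replace(v) for k, v in self.components.items()},
            shoots={k: replace(v, segment_ids=list(v.segment_ids))
                    for k, v in self.shoots.items()},
            sams={k: replace(v) for k, v in self.sams.items()},
            tcsa=self.tcsa,
            unit=self.unit,
        )

    def validate(self) -> None:
        roots = [c for c in self.components.values()
                 if c.parent is None and c.scale == "tree"]
        if len(roots) != 1:
            raise StructureError(
                f"expected exactly one tree-scale root, found {len(roots)}")
        for c in self.components.values():
            if c.parent is not None and c.parent not in self.components:
                raise StructureError(f"component {c.id!r}: unknown parent {c.parent!r}")
        for s in self.shoots.values():
            for seg in s.segment_ids:
                if seg not in self.components:
                    raise StructureError(f"shoot {s.id!r}: unknown segment {seg!r}")
        for m in self.sams.values():
            if m.shoot_id not in self.shoots:
                raise StructureError(f"SAM {m.id!r}: unknown shoot {m.shoot_id!r}")
        if not self.sams:
            raise StructureError("tree has no SAM")
        # cycle check on the component forest
        g = nx.DiGraph()
        g.add_nodes_from(self.components)
        g.add_edges_from((c.parent, c.id) for c in self.components.values()
                         if c.parent is not None)
        if not nx.is_directed_acyclic_graph(g):
            raise StructureError("component topology contains a cycle")


@dataclass
class DistanceMatrix:
    """Topological-path distances (m), shoots x SAMs, deterministic id order."""

    shoot_ids: list[str]
    sam_ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.shoot_ids), len(self.sam_ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and >= 0")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _component_graph(tree: TreeGraph) -> nx.Graph:
    """Undirected component graph with edge weight = distance between bases."""
    g = nx.Graph()
    g.add_nodes_from(tree.components)
    for c in tree.components.values():
        if c.parent is not None:
            p = tree.components[c.parent]
            g.add_edge(c.parent, c.id, weight=float(np.linalg.norm(c.base - p.base)))
    return g


def _attachment(tree: TreeGraph, shoot: AnnualShoot) -> str:
    """Component at which the shoot hangs on the structure (first segment)."""
    if not shoot.segment_ids:
        raise StructureError(f"shoot {shoot.id!r} has no segments")
    return shoot.segment_ids[0]


def compute_distances(tree: TreeGraph) -> DistanceMatrix:
    """Source-shoot to SAM distances along the topological pathway.

    ``d[i, j]`` = |base_i - barycenter_i| + sum of Euclidean lengths between
    successive component bases on the unique path from shoot *i*'s attachment
    to the attachment of the shoot bearing SAM *j* + |base_j - extremity_j|.
    The path term is symmetric in (i, j); the end terms are not.
    """
    tree.validate()
    shoot_ids = tree.shoot_ids()
    sam_ids = tree.sam_ids()
    g = _component_graph(tree)
    if not nx.is_connected(g) and len(g) > 0:
        comps = list(nx.connected_components(g))
        orphan = sorted(min(comps, key=len))[0]
        raise StructureError(f"component {orphan!r} is disconnected from the root")

    attach = {sid: _attachment(tree, tree.shoots[sid]) for sid in shoot_ids}
    # pairwise path lengths between the (few) distinct attachment components
    nodes = sorted(set(attach.values()))
    plen: dict[str, dict[str, float]] = {}
    for a in nodes:
        plen[a] = nx.single_source_dijkstra_path_length(g, a, weight="weight")

    d = np.zeros((len(shoot_ids), len(sam_ids)))
    src_term = {
        sid: float(np.linalg.norm(tree.shoots[sid].base - tree.shoots[sid].barycenter))
        for sid in shoot_ids
    }
    for j, mid in enumerate(sam_ids):
        sam = tree.sams[mid]
        tgt_shoot = tree.shoots[sam.shoot_id]
        tgt_term = float(np.linalg.norm(tgt_shoot.base - tgt_shoot.extremity))
        a_j = attach[sam.shoot_id]
        for i, sid in enumerate(shoot_ids):
            d[i, j] = src_term[sid] + plen[attach[sid]][a_j] + tgt_term
    return DistanceMatrix(shoot_ids, sam_ids, d)


# ---------------------------------------------------------------------------
# builders for hypothetical structures
# ---------------------------------------------------------------------------

def _add_shoot(tree: TreeGraph, shoot_id: str, parent: str, edge_kind: str,
               base: np.ndarray, tip: np.ndarray, *, leaf_area: float = 0.0,
               fruit_count: int = 0, part_label: str = "", branch_id: str = "",
               side: str = "") -> None:
    """Append one single-segment shoot (with one metamer and its SAM)."""
    seg_id = f"{shoot_id}/seg"
    tree.components[seg_id] = Component(seg_id, "segment", parent, edge_kind,
                                        base, tip)
    met_id = f"{shoot_id}/met"
    tree.components[met_id] = Component(met_id, "metamer", seg_id, "succession",
                                        base, tip)
    bary = (np.asarray(base) + np.asarray(tip)) / 2.0
    tree.shoots[shoot_id] = AnnualShoot(
        shoot_id, [seg_id], base, tip, bary, leaf_area=leaf_area,
        fruit_count=fruit_count, part_label=part_label, branch_id=branch_id,
        side=side)
    tree.sams[f"{shoot_id}/sam"] = SAM(f"{shoot_id}/sam", shoot_id, tip)


def _new_tree(tcsa: float | None = None) -> TreeGraph:
    t = TreeGraph(tcsa=tcsa)
    t.components["T"] = Component("T", "tree", None, None, (0, 0, 0), (0, 0, 0))
    return t


def _carrier_axis(tree: TreeGraph, prefix: str, parent: str, origin: np.ndarray,
                  direction: np.ndarray, n_points: int, spacing: float,
                  edge_kind: str = "branching") -> list[tuple[str, np.ndarray]]:
    """Chain of carrier segments; returns (component id, attachment point)."""
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    out = []
    prev = parent
    kind = edge_kind
    for k in range(n_points):
        base = origin + k * spacing * direction
        tip = origin + (k + 1) * spacing * direction
        cid = f"{prefix}{k + 1}"
        tree.components[cid] = Component(cid, "segment", prev, kind, base, tip)
        out.append((cid, base))
        prev, kind = cid, "succession"
    return out


def build_linear_branch(n_shoots: int = 6, spacing: float = 0.15,
                        shoot_length: float = 0.10,
                        fruiting: Iterable[int] = (),
                        leafy: Iterable[int] = (),
                        leaf_area: float = 100.0,
                        attachment_offset: float = 0.0) -> TreeGraph:
    """Branch of ``n_shoots`` shoots equidistant along a carrier axis.

    Shoots are numbered 1..n from the branch base; ids in ``fruiting`` get
    one fruit at their base, ids in ``leafy`` get ``leaf_area`` cm^2 of
    leaves.  ``attachment_offset`` shifts the first attachment point away
    from the branch insertion.  The classic six-shoot demonstration places
    fruit on shoots 1, 2 and 4.
    """
    if n_shoots < 1:
        raise ValueError("n_shoots must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    fruiting = set(fruiting)
    leafy = set(leafy)
    bad = (fruiting | leafy) - set(range(1, n_shoots + 1))
    if bad:
        raise ValueError(f"shoot ids out of range 1..{n_shoots}: {sorted(bad)}")

    tree = _new_tree()
    pts = _carrier_axis(tree, "C", "T", (attachment_offset, 0, 0), (1, 0, 0),
                        n_shoots, spacing, edge_kind="branching")
    for k in range(1, n_shoots + 1):
        cid, at = pts[k - 1]
        label = "fruiting" if k in fruiting else "non-fruiting"
        _add_shoot(tree, f"S{k}", cid, "branching", at,
                   at + np.array([0, 0, shoot_length]),
                   leaf_area=leaf_area if k in leafy else 0.0,
                   fruit_count=1 if k in fruiting else 0,
                   part_label=label, branch_id="B1", side="side1")
    return tree


def build_two_branch(shoots_per_branch: int = 6, layout: str = "by_branch",
                     organ: str = "fruit", spacing: float = 0.15,
                     shoot_length: float = 0.10,
                     leaf_area: float = 100.0) -> TreeGraph:
    """Two opposite complete branches with contrasted organ distributions.

    ``layout='by_branch'``: one branch fully bears the organ, the other is
    bare (organ removal at the branch scale).  ``layout='by_shoot'``:
    alternating shoots on both branches bear the organ (removal on half of
    the shoots).  When the organ under study is fruit every shoot keeps its
    leaves, and vice versa, so the complementary signal is uniform.
    """
    if shoots_per_branch < 2:
        raise ValueError("shoots_per_branch must be >= 2")
    if layout not in ("by_branch", "by_shoot"):
        raise ValueError(f"unknown layout {layout!r}")
    if organ not in ("fruit", "leaf"):
        raise ValueError(f"unknown organ {organ!r}")

    tree = _new_tree()
    for b, direction in ((1, (1, 0, 0)), (2, (-1, 0, 0))):
        pts = _carrier_axis(tree, f"B{b}C", "T", (0, 0, 0), direction,
                            shoots_per_branch, spacing, edge_kind="branching")
        for k in range(1, shoots_per_branch + 1):
            cid, at = pts[k - 1]
            if layout == "by_branch":
                bearing = b == 1
            else:
                bearing = (k % 2) == 1
            if organ == "fruit":
                la, fc = leaf_area, 1 if bearing else 0
                status = "fruiting" if bearing else "non-fruiting"
            else:
                la, fc = (leaf_area if bearing else 0.0), 0
                status = "leafy" if bearing else "defoliated"
            _add_shoot(tree, f"B{b}S{k}", cid, "branching", at,
                       at + np.array([0, 0, shoot_length]),
                       leaf_area=la, fruit_count=fc,
                       part_label=f"branch{b}:{status}",
                       branch_id=f"B{b}", side=f"side{b}")
    return tree


FOUR_BRANCH_LABELS = {
    1: "1:leafy-fruiting",
    2: "2:leafy-nonfruiting",
    3: "3:nonleafy-fruiting",
    4: "4:nonleafy-nonfruiting",
}


def build_four_branch(shoots_per_branch: int = 6, spacing: float = 0.15,
                      shoot_length: float = 0.10,
                      leaf_area: float = 100.0) -> TreeGraph:
    """Four contrasted branches crossing leaf presence with fruit presence.

    Branch 1 is leafy and fruiting, branch 2 leafy without fruit, branch 3
    fruiting without leaves, branch 4 bare; used to compare the two
    signal-combination formalisms.
    """
    if shoots_per_branch < 1:
        raise ValueError("shoots_per_branch must be >= 1")
    dirs = {1: (1, 0, 0), 2: (-1, 0, 0), 3: (0, 1, 0), 4: (0, -1, 0)}
    has_leaf = {1: True, 2: True, 3: False, 4: False}
    has_fruit = {1: True, 2: False, 3: True, 4: False}
    tree = _new_tree()
    for b in (1, 2, 3, 4):
        pts = _carrier_axis(tree, f"B{b}C", "T", (0, 0, 0), dirs[b],
                            shoots_per_branch, spacing, edge_kind="branching")
        for k in range(1, shoots_per_branch + 1):
            cid, at = pts[k - 1]
            _add_shoot(tree, f"B{b}S{k}", cid, "branching", at,
                       at + np.array([0, 0, shoot_length]),
                       leaf_area=leaf_area if has_leaf[b] else 0.0,
                       fruit_count=1 if has_fruit[b] else 0,
                       part_label=FOUR_BRANCH_LABELS[b],
                       branch_id=f"B{b}", side=f"side{1 if b <= 2 else 2}")
    return tree


def generate_digitized_like_tree(seed: int, n_shoots: int = 100,
                                 la_mean: float = 100.0,
                                 la_spread: float = 20.0,
                                 form: str = "solaxe",
                                 shoots_per_branch: int = 10,
                                 branch_spacing: float = 0.25,
                                 shoot_spacing: float = 0.10,
                                 shoot_length: float = 0.08,
                                 fruit_on: bool = True) -> TreeGraph:
    """Synthetic stand-in for a 3D-digitized orchard tree.

    Builds a reproducible architecture — one vertical trunk (``solaxe``) or
    two inclined trunks (``y_shape``) carrying lateral branches of shoots —
    with per-shoot leaf areas drawn from a truncated normal whose scale is
    ``la_spread / 1.2``, so roughly 77% of shoots fall within
    ``la_mean +/- la_spread`` (matching the narrow leaf-area distribution of
    mature orchard shoots).  With ``fruit_on`` every shoot bears exactly one
    fruit at its base, emulating an ON tree after commercial thinning.
    """
    if n_shoots < 10:
        raise ValueError("n_shoots must be >= 10")
    if form not in ("solaxe", "y_shape"):
        raise ValueError(f"unknown form {form!r}")
    rng = np.random.default_rng(seed)
    tree = _new_tree(tcsa=DEFAULT_TCSA[form])

    if form == "solaxe":
        trunk_dirs = [("TR", np.array([0.0, 0.0, 1.0]), "side1")]
    else:
        trunk_dirs = [("TRa", np.array([0.6, 0.0, 0.8]), "side1"),
                      ("TRb", np.array([-0.6, 0.0, 0.8]), "side2")]

    n_branches = max(2, math.ceil(n_shoots / shoots_per_branch))
    # round-robin branches over trunks; azimuth alternates around each trunk
    branch_specs = []
    for bi in range(n_branches):
        trunk = trunk_dirs[bi % len(trunk_dirs)]
        branch_specs.append((bi, trunk))

    trunk_pts: dict[str, list[tuple[str, np.ndarray]]] = {}
    per_trunk = {name: 0 for name, _, _ in trunk_dirs}
    for bi, (tname, _, _) in branch_specs:
        per_trunk[tname] += 1
    for tname, tdir, _ in trunk_dirs:
        trunk_pts[tname] = _carrier_axis(tree, tname, "T", (0, 0, 0), tdir,
                                         per_trunk[tname], branch_spacing,
                                         edge_kind="branching")

    sd = la_spread / 1.2  # ~77% of a normal lies within +/-1.2 sd
    areas = rng.normal(la_mean, sd, size=n_shoots)
    areas = np.clip(areas, 1.0, None)

    counter = {name: 0 for name, _, _ in trunk_dirs}
    made = 0
    for bi, (tname, tdir, side) in branch_specs:
        slot = counter[tname]
        counter[tname] += 1
        cid, at = trunk_pts[tname][slot]
        az = (bi * 2.399963)  # golden-angle phyllotaxy
        bdir = np.array([math.cos(az), math.sin(az), 0.15])
        bdir /= np.linalg.norm(bdir)
        n_here = min(shoots_per_branch, n_shoots - made)
        if n_here <= 0:
            break
        pts = _carrier_axis(tree, f"BR{bi}_", cid, at, bdir, n_here,
                            shoot_spacing, edge_kind="branching")
        for k in range(n_here):
            scid, sat = pts[k]
            _add_shoot(tree, f"BR{bi}S{k + 1}", scid, "branching", sat,
                       sat + np.array([0, 0, shoot_length]),
                       leaf_area=float(areas[made]),
                       fruit_count=1 if fruit_on else 0,
                       part_label="canopy", branch_id=f"BR{bi}", side=side)
            made += 1
    return tree


def reconstruct_leaf_area(shoot_length: float, allometry: tuple[float, float]
                          ) -> float:
    """Shoot leaf area (cm^2) from shoot length (m) via a power law a*L^b.

    The coefficient pair is configurable: allometric fits differ between
    cultivars and between short and long shoots, so no universal default is
    hard-wired.
    """
    a, b = allometry
    if a < 0:
        raise ValueError("allometric coefficient a must be >= 0")
    if shoot_length < 0:
        raise ValueError("shoot_length must be >= 0")
    if shoot_length == 0:
        return 0.0
    return max(0.0, a * shoot_length ** b)


# ---------------------------------------------------------------------------
# simplified structure-file dialect
# ---------------------------------------------------------------------------
#
# Line-based, UTF-8, '#' comments.  Header records the unit and scales, then
# one record per component and per shoot:
#
#   unit m
#   scales tree,segment,metamer
#   tcsa 20.4                      (optional)
#   component <id> <scale> <parent|-> <edge|-> bx by bz tx ty tz
#   shoot <id> <seg1,seg2,...> <leaf_area_cm2> <fruit_count> <has_sam 0|1> \
#         <part_label|-> <branch_id|-> <side|->
#
# SAM records are implicit: every shoot with has_sam=1 gets one SAM at its
# extremity (id "<shoot>/sam").  Field values never contain whitespace.

_SCALE_RANK = {"tree": 0, "segment": 1, "metamer": 2}


def write_structure(tree: TreeGraph, path) -> None:
    lines = ["# sigflow structure v1",
             f"unit {tree.unit}",
             "scales " + ",".join(SCALES)]
    if tree.tcsa is not None:
        lines.append(f"tcsa {tree.tcsa!r}")
    # parents must precede children for the reader; topological order with
    # sorted siblings keeps the output deterministic
    children: dict[str | None, list[str]] = {}
    for cid, c in tree.components.items():
        children.setdefault(c.parent, []).append(cid)
    order: list[str] = []
    stack = sorted(children.get(None, []), reverse=True)
    while stack:
        cid = stack.pop()
        order.append(cid)
        stack.extend(sorted(children.get(cid, []), reverse=True))
    for cid in order:
        c = tree.components[cid]
        coords = " ".join(repr(float(v)) for v in (*c.base, *c.tip))
        lines.append(f"component {c.id} {c.scale} {c.parent or '-'} "
                     f"{c.edge_kind or '-'} {coords}")
    for sid in sorted(tree.shoots):
        s = tree.shoots[sid]
        lines.append(
            f"shoot {s.id} {','.join(s.segment_ids)} {s.leaf_area!r} "
            f"{s.fruit_count} {1 if s.has_terminal_sam else 0} "
            f"{s.part_label or '-'} {s.branch_id or '-'} {s.side or '-'}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_structure(path) -> TreeGraph:
    tree = TreeGraph()
    seen_record = False
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            kw = fields[0]
            try:
                if kw == "unit":
                    tree.unit = fields[1]
                elif kw == "scales":
                    pass
                elif kw == "tcsa":
                    tree.tcsa = float(fields[1])
                elif kw == "component":
                    seen_record = True
                    _, cid, scale, parent, edge, *coords = fields
                    if len(coords) != 6:
                        raise ParseError("expected 6 coordinates", ln)
                    if cid in tree.components:
                        raise ParseError(f"duplicate component id {cid!r}", ln)
                    parent = None if parent == "-" else parent
                    edge = None if edge == "-" else edge
                    if parent is not None:
                        pc = tree.components.get(parent)
                        if pc is None:
                            raise ParseError(f"unknown parent {parent!r} "
                                             "(parents must precede children)", ln)
                        if _SCALE_RANK[scale] < _SCALE_RANK[pc.scale]:
                            raise ParseError(
                                f"scale nesting violation: {scale} component "
                                f"under {pc.scale} parent {parent!r}", ln)
                        if pc.scale == "tree" and scale == "metamer":
                            raise ParseError(
                                "scale nesting violation: metamer directly "
                                f"under tree-scale component {parent!r}", ln)
                    xyz = [float(v) for v in coords]
                    tree.components[cid] = Component(cid, scale, parent, edge,
                                                     xyz[:3], xyz[3:])
                elif kw == "shoot":
                    seen_record = True
                    (_, sid, segs, la, fc, has_sam,
                     label, branch, side) = fields
                    seg_ids = segs.split(",")
                    for seg in seg_ids:
                        if seg not in tree.components:
                            raise ParseError(f"unknown segment {seg!r}", ln)
                    base = tree.components[seg_ids[0]].base
                    tip = tree.components[seg_ids[-1]].tip
                    pts = np.array([[*tree.components[g].base,
                                     *tree.components[g].tip] for g in seg_ids])
                    bary = pts.reshape(-1, 3).mean(axis=0)
                    shoot = AnnualShoot(
                        sid, seg_ids, base, tip, bary,
                        leaf_area=float(la), fruit_count=int(fc),
                        has_terminal_sam=has_sam == "1",
                        part_label="" if label == "-" else label,
                        branch_id="" if branch == "-" else branch,
                        side="" if side == "-" else side)
                    if sid in tree.shoots:
                        raise ParseError(f"duplicate shoot id {sid!r}", ln)
                    tree.shoots[sid] = shoot
                    if shoot.has_terminal_sam:
                        tree.sams[f"{sid}/sam"] = SAM(f"{sid}/sam", sid, tip)
                else:
                    raise ParseError(f"unknown record type {kw!r}", ln)
            except ParseError:
                raise
            except (ValueError, IndexError) as exc:
                raise ParseError(str(exc), ln) from exc
    if not seen_record:
        raise ParseError("file contains no component or shoot records")
    tree.validate()
    return tree
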