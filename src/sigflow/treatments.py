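"""In-silico organ removal, crop-load series and parameter-sweep experiments.

Treatments mirror orchard manipulations: leaves or fruit are removed on a
fraction of shoots, on whole branches, or on one half of a two-trunk tree.
Removal never touches topology or geometry — only the ``leaf_area`` /
``fruit_count`` attributes and the part labels used for aggregation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .induction import ParameterSet, run_model
from .transport import source_vector
from .treegraph import StructureError, TreeGraph, compute_distances

__all__ = [
    "TreatmentSpec",
    "CropLoadPoint",
    "apply_treatment",
    "crop_load_series",
    "reference_cropload_curve",
    "sweep",
]

ORGANS = ("leaf", "fruit")
SCALES = ("none", "shoot", "branch", "half_tree")
SELECTIONS = ("alternate", "seeded_random")


@dataclass
class TreatmentSpec:
    """One organ-removal experiment.

    ``fraction`` is the proportion of units (shoots or branches) treated;
    the default alternate selection walks units in sorted-id order and is
    fully deterministic, ``seeded_random`` draws them uniformly without
    replacement.
    """

    organ: str
    scale: str = "shoot"
    fraction: float = 0.5
    selection: str = "alternate"
    seed: int | None = None

    def __post_init__(self):
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.selection not in SELECTIONS:
            raise ValueError(f"unknown selection {self.selection!r}")
        if self.selection == "seeded_random" and self.seed is None:
            raise ValueError("seeded_random selection requires a seed")


@dataclass
class CropLoadPoint:
    fruit_fraction_kept: float
    crop_load: float  # fruit per cm^2 of trunk cross-section
    fi_proportion: float
    n_fruit: int = 0


def _pick(units: list[str], fraction: float, selection: str,
          seed: int | None) -> set[str]:
    k = round(fraction * len(units))
    if selection == "alternate":
        # every other unit in deterministic order until k are taken, then
        # fill from the remainder (exact count for any fraction)
        order = list(units[0::2]) + list(units[1::2])
        return set(order[:k])
    rng = np.random.default_rng(seed)
    return set(rng.choice(units, size=k, replace=False).tolist())


def apply_treatment(tree: TreeGraph, spec: TreatmentSpec) -> TreeGraph:
    """Return a treated copy of ``tree``; the input is left untouched.

    Treated shoots get ``leaf_area = 0`` (organ='leaf') or ``fruit_count =
    0`` (organ='fruit') and their ``part_label`` becomes ``treated`` /
    ``untreated``.
    """
    out = tree.copy()
    shoot_ids = out.shoot_ids()
    if spec.scale == "none":
        return out
    if spec.scale == "shoot":
        treated = _pick(shoot_ids, spec.fraction, spec.selection, spec.seed)
    elif spec.scale == "branch":
        branches = sorted({out.shoots[s].branch_id for s in shoot_ids})
        if "" in branches or len(branches) < 2:
            raise StructureError(
                "branch-scale treatment requires branch_id labels on shoots")
        sel = _pick(branches, spec.fraction, spec.selection, spec.seed)
        treated = {s for s in shoot_ids if out.shoots[s].branch_id in sel}
    else:  # half_tree
        sides = sorted({out.shoots[s].side for s in shoot_ids})
        if len(sides) < 2 or "" in sides:
            raise StructureError(
                "half-tree treatment requires a structure with two sides")
        treated = {s for s in shoot_ids if out.shoots[s].side == sides[0]}
    for sid in shoot_ids:
        shoot = out.shoots[sid]
        if sid in treated:
            if spec.organ == "leaf":
                shoot.leaf_area = 0.0
            else:
                shoot.fruit_count = 0
            shoot.part_label = "treated"
        else:
            shoot.part_label = "untreated"
    return out


def crop_load_series(tree: TreeGraph, fractions, params: ParameterSet,
                     mode: str = "multiplicative", seed: int = 0,
                     mean_leaf_area: float | str = "auto"
                     ) -> list[CropLoadPoint]:
    """Mean FI proportion against crop load under graded fruit thinning.

    For each kept fraction, fruit is removed from a seeded uniform sample of
    fruiting shoots, the model is run, and (crop load = kept fruit / TCSA,
    tree-mean FI probability) is recorded.
    """
    if tree.tcsa is None or tree.tcsa <= 0:
        raise ValueError("crop-load series requires a tree with tcsa > 0")
    src = source_vector(tree, "inhibiting")
    if src.Q.sum() == 0:
        raise ValueError("crop-load series requires fruit on the tree")
    if mean_leaf_area == "auto":
        la = [tree.shoots[s].leaf_area for s in tree.shoot_ids()]
        leafy = [a for a in la if a > 0]
        mean_leaf_area = float(np.mean(leafy))
    D = compute_distances(tree)
    fruiting = [s for s in tree.shoot_ids() if tree.shoots[s].fruit_count > 0]
    rng = np.random.default_rng(seed)
    points = []
    for frac in fractions:
        if not 0.0 <= frac <= 1.0:
            raise ValueError("kept fractions must lie in [0, 1]")
        keep = set(rng.choice(fruiting, size=round(frac * len(fruiting)),
                              replace=False).tolist())
        t = tree.copy()
        for sid in fruiting:
            if sid not in keep:
                t.shoots[sid].fruit_count = 0
        n_fruit = sum(t.shoots[s].fruit_count for s in keep)
        fi = run_model(t, params, mode=mode, D=D,
                       mean_leaf_area=mean_leaf_area)
        points.append(CropLoadPoint(
            fruit_fraction_kept=float(frac),
            crop_load=n_fruit / tree.tcsa,
            fi_proportion=float(fi.P.mean()),
            n_fruit=int(n_fruit)))
    return points


def reference_cropload_curve(x) -> np.ndarray:
    """Logistic FI-vs-crop-load relationship fitted on orchard observations.

    y = exp(-0.3721 x + 2.9273) / (1 + exp(-0.3721 x + 2.9273)), with x the
    crop load in fruit per cm^2 TCSA.  Used as the field reference when
    validating simulated thinning series.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("crop load must be >= 0")
    z = -0.3721 * x + 2.9273
    return np.exp(z) / (1.0 + np.exp(z))


def sweep(tree: TreeGraph, base: ParameterSet, grid: dict[str, list[float]],
          mode: str = "multiplicative",
          mean_leaf_area: float | str = "auto") -> pd.DataFrame:
    """Cartesian parameter sweep returning a long-form per-part table.

    ``grid`` maps parameter names (``r_minus``, ``t_minus``, ...) to value
    lists; every combination is evaluated on ``tree`` starting from
    ``base``.  Output columns: the swept parameters, part_label, mean_P,
    mean_QF_plus, mean_QF_minus, n_sams.  Distances are computed once.
    """
    names = list(grid)
    for n in names:
        if n not in base.to_dict():
            raise ValueError(f"unknown parameter {n!r}")
    D = compute_distances(tree)
    sam_ids = list(D.sam_ids)
    labels = np.array([tree.shoots[tree.sams[m].shoot_id].part_label
                       for m in sam_ids])
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        d = base.to_dict()
        d.update(dict(zip(names, combo)))
        params = ParameterSet(**d)
        fi = run_model(tree, params, mode=mode, D=D,
                       mean_leaf_area=mean_leaf_area)
        for lab in sorted(set(labels)):
            m = labels == lab
            row = dict(zip(names, combo))
            row.update(part_label=lab,
                       mean_P=float(fi.P[m].mean()),
                       mean_P_plus=float(fi.P_plus[m].mean()),
                       mean_P_minus=float(fi.P_minus[m].mean()),
                       mean_QF_plus=float(fi.QF_plus[m].mean()),
                       mean_QF_minus=float(fi.QF_minus[m].mean()),
                       n_sams=int(m.sum()))
            rows.append(row)
    cols = names + ["part_label", "mean_P", "mean_P_plus", "mean_P_minus",
                    "mean_QF_plus", "mean_QF_minus", "n_sams"]
    return pd.DataFrame(rows, columns=cols)
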