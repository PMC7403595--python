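"""Grid-search estimation of signal parameters against observed FI proportions.

Each signal sign is fitted separately: activating parameters (r+, t+, v+)
on defoliation experiments over non-fruiting structures, inhibiting
parameters (r-, t-, v-) on fruit-removal experiments over leafy structures.
For every candidate (r, t, v) the model is run on every treated structure,
per-part mean FI probabilities are compared with the observed proportions
pooled over all conditions, and the candidate minimizing RMSE wins (bias
breaks ties, then deterministic grid order).  A second, narrowed grid
refines the incumbent.

Goodness of fit follows the conventions of the calibration dataset:
RMSE = sqrt(mean (sim - obs)^2), bias = |sum(sim - obs)| / n_replicates,
R^2 = squared Pearson correlation between simulated and observed values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .induction import (ParameterSet, prob_activation, prob_inhibition,
                        run_model, SigmoidParams)
from .transport import source_vector
from .treegraph import TreeGraph, compute_distances

__all__ = [
    "Score",
    "ObservationSet",
    "CalibrationGrid",
    "CalibrationResult",
    "score",
    "enumerate_grid",
    "fit_signal",
    "refine",
    "compare_formalisms",
]


class Score(NamedTuple):
    rmse: float
    r2: float  # NaN when either vector has zero variance
    bias: float


def score(simulated, observed, n_replicates: int | None = None) -> Score:
    """RMSE, R^2 and bias between simulated and observed FI proportions.

    ``bias`` divides the absolute sum of signed differences by
    ``n_replicates`` (default: the number of observations), so systematic
    over/under-prediction registers while scatter cancels.  R^2 is the
    squared Pearson correlation; it is NaN (flagged, not raised) when either
    vector is constant.
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape or sim.ndim != 1 or sim.size < 1:
        raise ValueError("simulated and observed must be equal-length 1-D vectors")
    n = n_replicates if n_replicates is not None else sim.size
    diff = sim - obs
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    bias = float(abs(diff.sum()) / n)
    if sim.size < 2 or np.std(sim) == 0 or np.std(obs) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(sim, obs)[0, 1] ** 2)
    return Score(rmse, r2, bias)


@dataclass
class ObservationSet:
    """Observed FI proportions per (structure, part) condition.

    ``data`` columns: structure_id, part_label, fi_observed in [0, 1],
    n_replicates.  Structures are referenced by id and must already carry
    the treatment (organ removal) they were observed under.
    """

    data: pd.DataFrame

    REQUIRED = ("structure_id", "part_label", "fi_observed", "n_replicates")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"observation table lacks columns {missing}")
        if len(self.data) == 0:
            raise ValueError("observation set is empty")
        fi = self.data["fi_observed"].to_numpy(dtype=float)
        if np.any((fi < 0) | (fi > 1)):
            raise ValueError("observed FI proportions must lie in [0, 1]")

    @property
    def observed(self) -> np.ndarray:
        return self.data["fi_observed"].to_numpy(dtype=float)

    @property
    def total_replicates(self) -> int:
        return int(self.data["n_replicates"].sum())


def _axis(lo: float, hi: float, step: float) -> list[float]:
    # integer index arithmetic keeps axes exact (0.1-step axes included)
    n = int(round((hi - lo) / step)) + 1
    return [float(np.round(lo + k * step, 12)) for k in range(n)]


@dataclass
class CalibrationGrid:
    """Candidate axes for one signal sign: attenuation r, transition t, shape v."""

    r_values: list[float]
    t_values: list[float]
    v_values: list[float]

    def __post_init__(self):
        for name in ("r_values", "t_values", "v_values"):
            vals = [float(v) for v in getattr(self, name)]
            if not vals:
                raise ValueError(f"{name} axis is empty")
            setattr(self, name, vals)
        if any(v < 0 for v in self.r_values):
            raise ValueError("r values must be >= 0")
        if any(not 0 <= v <= 1 for v in self.t_values):
            raise ValueError("t values must lie in [0, 1]")
        if any(v <= 0 for v in self.v_values):
            raise ValueError("v values must be > 0")

    @classmethod
    def coarse(cls) -> "CalibrationGrid":
        """The wide first-pass grid: r 0-15 step 0.1, t 0-1 step 0.1,
        v in {0.01, 0.1, 0.3, 0.6} — 6,644 candidates."""
        return cls(_axis(0.0, 15.0, 0.1), _axis(0.0, 1.0, 0.1),
                   [0.01, 0.1, 0.3, 0.6])

    @classmethod
    def from_ranges(cls, r: tuple[float, float, float],
                    t: tuple[float, float, float],
                    v: list[float]) -> "CalibrationGrid":
        return cls(_axis(*r), _axis(*t), list(v))

    def size(self) -> int:
        return len(self.r_values) * len(self.t_values) * len(self.v_values)

    def steps(self) -> dict[str, float]:
        """Axis step sizes (0 for singleton axes); v reports the largest gap."""
        def gap(vals):
            return max((b - a for a, b in zip(vals, vals[1:])), default=0.0)
        return {"r": gap(self.r_values), "t": gap(self.t_values),
                "v": gap(sorted(self.v_values))}


def enumerate_grid(grid: CalibrationGrid) -> list[tuple[float, float, float]]:
    """Cartesian candidate list in deterministic r-outer, t, v-inner order."""
    return list(itertools.product(grid.r_values, grid.t_values, grid.v_values))


@dataclass
class CalibrationResult:
    sign: str
    r: float
    t: float
    v: float
    rmse: float
    r2: float
    bias: float
    table: pd.DataFrame
    ties: list[tuple[float, float, float]] = field(default_factory=list)
    grid: CalibrationGrid | None = None

    def as_parameter_set(self, base: ParameterSet | None = None) -> ParameterSet:
        d = (base or ParameterSet()).to_dict()
        suffix = "minus" if self.sign == "inhibiting" else "plus"
        d[f"r_{suffix}"], d[f"t_{suffix}"], d[f"v_{suffix}"] = self.r, self.t, self.v
        return ParameterSet(**d)


def _prepare_conditions(observations: ObservationSet,
                        structures: dict[str, TreeGraph], sign: str,
                        mean_leaf_area):
    """Precompute, per structure, everything that does not depend on (r,t,v)."""
    conds = []
    for struct_id, rows in observations.data.groupby("structure_id", sort=True):
        if struct_id not in structures:
            raise ValueError(f"observations reference unknown structure "
                             f"{struct_id!r}")
        tree = structures[struct_id]
        D = compute_distances(tree)
        mla = (mean_leaf_area.get(struct_id, "auto")
               if isinstance(mean_leaf_area, dict) else mean_leaf_area)
        src = source_vector(tree, sign,
                            **({"mean_leaf_area": mla}
                               if sign == "activating" else {}))
        logw = np.log1p(D.d)  # weight = exp(-r * log(1 + d))
        labels = np.array([tree.shoots[tree.sams[m].shoot_id].part_label
                           for m in D.sam_ids])
        groups = []
        for _, row in rows.iterrows():
            mask = labels == row["part_label"]
            if not mask.any():
                raise ValueError(
                    f"part {row['part_label']!r} has no SAM in structure "
                    f"{struct_id!r}")
            groups.append((mask, row.name))
        conds.append({"Q": src.Q, "logw": logw, "groups": groups})
    return conds


def _qf_for_r(cond, r: float) -> np.ndarray:
    w = np.exp(-r * cond["logw"])
    q = cond["Q"][:, None] * w / w.sum(axis=1, keepdims=True)
    return q.sum(axis=0)


def fit_signal(observations: ObservationSet, structures: dict[str, TreeGraph],
               sign: str, grid: CalibrationGrid,
               mean_leaf_area="auto") -> CalibrationResult:
    """Exhaustive grid search for one signal sign.

    For each candidate, per-part mean probabilities (P+ for the activating
    fit on defoliation data, P- for the inhibiting fit on fruit-removal
    data) are pooled over all conditions and scored against the observed
    proportions; the RMSE argmin is returned, with bias then grid order
    breaking ties.  Distances and source vectors are computed once per
    structure, and each r shares its transport solution across all (t, v).
    """
    if sign not in ("inhibiting", "activating"):
        raise ValueError(f"unknown sign {sign!r}")
    conds = _prepare_conditions(observations, structures, sign, mean_leaf_area)
    obs = observations.observed
    n_rep = observations.total_replicates
    prob = prob_inhibition if sign == "inhibiting" else prob_activation
    n_rows = len(observations.data)
    # positional index of each condition group in the observation vector
    positions = [observations.data.index.get_loc(name)
                 for cond in conds for _, name in cond["groups"]]

    records = []
    best = None  # (rmse, bias, index, candidate, Score)
    idx = 0
    for r in grid.r_values:
        qf_groups = []  # per observation row: QF over that part's SAMs
        for cond in conds:
            qf = _qf_for_r(cond, r)
            for mask, _ in cond["groups"]:
                qf_groups.append(qf[mask])
        for t in grid.t_values:
            for v in grid.v_values:
                params = SigmoidParams(t, v, sign)
                sim = np.empty(n_rows)
                for pos, qf in zip(positions, qf_groups):
                    sim[pos] = prob(qf, params).mean()
                sc = score(sim, obs, n_replicates=n_rep)
                records.append((r, t, v, sc.rmse, sc.r2, sc.bias))
                key = (sc.rmse, sc.bias, idx)
                if best is None or key < best[0]:
                    best = (key, (r, t, v), sc)
                idx += 1

    table = pd.DataFrame(records,
                         columns=["r", "t", "v", "rmse", "r2", "bias"])
    (best_rmse, best_bias, _), (r, t, v), sc = best
    tol = 1e-12
    tied = table[(np.abs(table["rmse"] - best_rmse) <= tol)
                 & (np.abs(table["bias"] - best_bias) <= tol)]
    ties = [tuple(row) for row in tied[["r", "t", "v"]].itertuples(index=False)]
    return CalibrationResult(sign, r, t, v, sc.rmse, sc.r2, sc.bias,
                             table, ties=ties, grid=grid)


def refine(result: CalibrationResult, grid: CalibrationGrid,
           window: dict[str, float] | None = None,
           step: dict[str, float] | None = None) -> CalibrationGrid:
    """Narrowed grid centered on the incumbent, clipped to the original bounds.

    ``window`` and ``step`` give the half-width and step of the new r and t
    axes (defaults: r +/- 0.5 step 0.05, t +/- 0.05 step 0.01); the shape
    axis keeps the incumbent value plus its immediate neighbours on the
    original axis, since it was searched on a discrete set.
    """
    window = {"r": 0.5, "t": 0.05, **(window or {})}
    step = {"r": 0.05, "t": 0.01, **(step or {})}
    for name in ("r", "t"):
        if window[name] < 0 or step[name] <= 0:
            raise ValueError(f"degenerate refine axis for {name!r}")

    def clipped(center, w, s, lo, hi):
        lo_, hi_ = max(lo, center - w), min(hi, center + w)
        vals = _axis(lo_, hi_, s) if hi_ > lo_ else [center]
        return [v for v in vals if lo - 1e-12 <= v <= hi + 1e-12]

    r_vals = clipped(result.r, window["r"], step["r"],
                     min(grid.r_values), max(grid.r_values))
    t_vals = clipped(result.t, window["t"], step["t"],
                     min(grid.t_values), max(grid.t_values))
    vs = sorted(grid.v_values)
    i = vs.index(result.v)
    v_vals = vs[max(0, i - 1):i + 2]
    return CalibrationGrid(r_vals, t_vals, v_vals)


def compare_formalisms(observations: ObservationSet,
                       structures: dict[str, TreeGraph],
                       params: ParameterSet,
                       mean_leaf_area="auto") -> pd.DataFrame:
    """Score the combined model under both combination formalisms.

    Runs the full two-signal model with the supplied parameter set on every
    condition and reports RMSE / R^2 / bias per mode, mirroring the
    validation comparison between the limiting-factor and multiplicative
    formalisms.
    """
    rows_out = []
    obs = observations.observed
    n_rep = observations.total_replicates
    for mode in ("limiting", "multiplicative"):
        sim = np.empty(len(observations.data))
        for struct_id, rows in observations.data.groupby("structure_id",
                                                         sort=True):
            tree = structures[struct_id]
            mla = (mean_leaf_area.get(struct_id, "auto")
                   if isinstance(mean_leaf_area, dict) else mean_leaf_area)
            fi = run_model(tree, params, mode=mode, mean_leaf_area=mla)
            labels = np.array([tree.shoots[tree.sams[m].shoot_id].part_label
                               for m in fi.sam_ids])
            for pos, row in rows.iterrows():
                mask = labels == row["part_label"]
                if not mask.any():
                    raise ValueError(
                        f"part {row['part_label']!r} has no SAM in structure "
                        f"{struct_id!r}")
                sim[observations.data.index.get_loc(pos)] = fi.P[mask].mean()
        sc = score(sim, obs, n_replicates=n_rep)
        rows_out.append({"mode": mode, "rmse": sc.rmse, "r2": sc.r2,
                         "bias": sc.bias})
    return pd.DataFrame(rows_out)
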