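"""Distance-attenuated allocation of shoot-borne signals to meristems.

Each annual shoot emits a quantity ``Q_i`` of signal — one unit per fruit
for the inhibiting signal, leaf area normalized by the mean shoot leaf area
for the activating signal.  The fraction of ``Q_i`` reaching SAM ``j``
decays with the topological-path distance ``d_ij`` through the kernel
``(1 / (1 + d_ij))^r`` and is normalized over all SAMs, so each source's
output is conserved exactly:

    q_ij = Q_i * (1/(1+d_ij))^r / sum_k (1/(1+d_ik))^r

``r = 0`` spreads every source uniformly over the n SAMs; large ``r``
concentrates it on the nearest SAM.  Accumulation sums contributions over
sources: ``QF_j = sum_i q_ij``.  The model is static and symmetric between
the two signal signs; distances are in metres, so the dimensionally naive
"+1" offset in the kernel ties fitted ``r`` values to metre-scale inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treegraph import DistanceMatrix, StructureError, TreeGraph

__all__ = [
    "SourceVector",
    "AllocationMatrix",
    "SignalField",
    "source_vector",
    "allocate",
    "accumulate",
    "attenuation_profile",
]

SIGNS = ("inhibiting", "activating")


@dataclass
class SourceVector:
    """Per-shoot emitted quantity Q (dimensionless, normalized)."""

    sign: str
    shoot_ids: list[str]
    Q: np.ndarray

    def __post_init__(self):
        if self.sign not in SIGNS:
            raise ValueError(f"unknown sign {self.sign!r}")
        self.Q = np.asarray(self.Q, dtype=float)
        if np.any(self.Q < 0):
            raise ValueError("source quantities must be >= 0")


@dataclass
class AllocationMatrix:
    """q[i, j]: signal exported by shoot i to SAM j; rows sum to Q_i."""

    shoot_ids: list[str]
    sam_ids: list[str]
    q: np.ndarray


@dataclass
class SignalField:
    """Accumulated quantity QF_j per SAM for one signal sign."""

    sign: str
    sam_ids: list[str]
    QF: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.sam_ids, self.QF.tolist()))


def source_vector(tree: TreeGraph, sign: str,
                  mean_leaf_area: float | str = "auto") -> SourceVector:
    """Emitted quantities per shoot.

    Inhibiting: ``Q_i = fruit_count_i`` (one normalized unit per fruit).
    Activating: ``Q_i = leaf_area_i / mean_leaf_area``; with
    ``mean_leaf_area='auto'`` the mean is taken over the leafy shoots
    (leaf_area > 0) of this tree.  Pass the reference tree's mean explicitly
    when scoring treated structures so defoliation does not shift the scale.
    """
    shoot_ids = tree.shoot_ids()
    if sign == "inhibiting":
        Q = np.array([float(tree.shoots[s].fruit_count) for s in shoot_ids])
    elif sign == "activating":
        la = np.array([tree.shoots[s].leaf_area for s in shoot_ids])
        if mean_leaf_area == "auto":
            leafy = la[la > 0]
            if leafy.size == 0:
                raise ValueError(
                    "cannot normalize leaf areas on a fully defoliated tree; "
                    "pass mean_leaf_area explicitly")
            mean_leaf_area = float(leafy.mean())
        if mean_leaf_area <= 0:
            raise ValueError("mean_leaf_area must be > 0")
        Q = la / float(mean_leaf_area)
    else:
        raise ValueError(f"unknown sign {sign!r}")
    return SourceVector(sign, shoot_ids, Q)


def _weights(d: np.ndarray, r: float) -> np.ndarray:
    return (1.0 / (1.0 + d)) ** r


def allocate(sources: SourceVector, D: DistanceMatrix, r: float
             ) -> AllocationMatrix:
    """Distribute each source over all SAMs with distance attenuation ``r``.

    Row ``i`` of the result sums to ``Q_i`` exactly (each row is normalized
    by its own kernel sum), so the total emitted signal is conserved through
    transport.
    """
    if r < 0:
        raise ValueError("attenuation parameter r must be >= 0")
    if sources.shoot_ids != D.shoot_ids:
        raise ValueError("source vector and distance matrix shoot order differ")
    w = _weights(D.d, float(r))
    row_sums = w.sum(axis=1)
    if np.any(row_sums == 0):
        bad = sources.shoot_ids[int(np.argmin(row_sums))]
        raise StructureError(f"shoot {bad!r} has zero kernel weight to every SAM")
    q = sources.Q[:, None] * w / row_sums[:, None]
    return AllocationMatrix(list(D.shoot_ids), list(D.sam_ids), q)


def accumulate(q: AllocationMatrix, sign: str = "inhibiting") -> SignalField:
    """Total signal reaching each SAM: QF_j = sum over sources of q_ij."""
    return SignalField(sign, list(q.sam_ids), q.q.sum(axis=0))


def transport(tree: TreeGraph, D: DistanceMatrix, sign: str, r: float,
              mean_leaf_area: float | str = "auto") -> SignalField:
    """Convenience composition: sources -> allocation -> accumulation."""
    src = source_vector(tree, sign, mean_leaf_area=mean_leaf_area)
    return accumulate(allocate(src, D, r), sign=sign)


def attenuation_profile(r: float, d_grid) -> np.ndarray:
    """Unnormalized kernel (1/(1+d))^r over a distance grid (m).

    Diagnostic of signal reach: the fraction of weight a source would send
    to a target at distance d relative to one at distance 0, before the
    per-source normalization.
    """
    if r < 0:
        raise ValueError("attenuation parameter r must be >= 0")
    return _weights(np.asarray(d_grid, dtype=float), float(r))
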