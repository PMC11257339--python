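"""Angular sectors of the positive objective quadrant.

The quadrant is split into K evenly spaced sectors Ψ_k delimited by rays
at angles φ_k = (k−1)·(π/2)/K. Each boundary ray r_k = (cos φ_k, sin φ_k)
carries the normal z_k = (−sin φ_k, cos φ_k) (the ray rotated +90°), so a
point v lies in Ψ_k iff v·z_k ≥ 0 and v·z_{k+1} ≤ 0. The trainer pins
network k inside Ψ_k through the two constraints

    G1 = −F·z_k ≤ 0      (not below the lower boundary)
    G2 =  F·z_{k+1} ≤ 0  (not above the upper boundary)

— only two constraints per network regardless of K, which is what keeps
the direction-finding QP small.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["RegionSet", "build_regions", "constraint_values", "active_set", "contains"]

DEFAULT_EPSILON = 1e-3


@dataclass(frozen=True)
class RegionSet:
    """K sectors with boundary angles φ_1..φ_{K+1} spanning [0, π/2] and
    unit boundary normals z_1..z_{K+1}."""

    K: int
    angles: np.ndarray  # shape (K+1,)
    normals: np.ndarray  # shape (K+1, 2)

    def to_json(self) -> str:
        return json.dumps({"K": self.K, "angles": self.angles.tolist()})


def build_regions(K: int) -> RegionSet:
    """Evenly spaced sectors; K=1 degenerates to the whole quadrant."""
    if K < 1:
        raise ValueError("K must be >= 1")
    angles = np.arange(K + 1) * (np.pi / 2) / K
    normals = np.stack([-np.sin(angles), np.cos(angles)], axis=1)
    return RegionSet(K=int(K), angles=angles, normals=normals)


def constraint_values(F_norm, regions: RegionSet, k: int) -> tuple[float, float]:
    """(G1, G2) = (−F·z_k, F·z_{k+1}) for region k (1-based); both ≤ 0
    iff F lies in Ψ_k."""
    if not (1 <= k <= regions.K):
        raise IndexError(f"region index {k} out of range 1..{regions.K}")
    F = np.asarray(F_norm, dtype=np.float64)
    g1 = -float(F @ regions.normals[k - 1])
    g2 = float(F @ regions.normals[k])
    return g1, g2


def active_set(cs: tuple[float, float], epsilon: float = DEFAULT_EPSILON) -> list[int]:
    """Constraints within ε of violation: {j : G_j ≥ −ε}.

    The sector geometry admits at most one truly active constraint; if ε
    is large enough relative to the sector width that both qualify, only
    the more violated one is kept (with a warning).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    act = [j for j in (1, 2) if cs[j - 1] >= -epsilon]
    if len(act) == 2:
        warnings.warn(
            "both region constraints near-active; keeping the larger one "
            "(epsilon may be too large for this sector width)",
            stacklevel=2,
        )
        act = [1] if cs[0] >= cs[1] else [2]
    return act


def contains(F_norm, regions: RegionSet, k: int) -> bool:
    g1, g2 = constraint_values(F_norm, regions, k)
    return g1 <= 0.0 and g2 <= 0.0
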