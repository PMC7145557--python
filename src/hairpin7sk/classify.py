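"""Family assignment (M1 / M2 / M2* / E) and ensemble composition.

The band rule on the classification angle follows the published cutoffs,
with boundaries resolved downward for determinism: xi in [0, 60] is M1,
(60, 100] is M2 and (100, 180] is E.  An M2 assignment is refined to
M2* when the U63.U44-A65 triplet is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contacts import HBondCriteria, TripletAnnotation, detect_triplets, triplet_presence
from .geometry import AngleSpec, u63_angle, xi_angle
from .structure import Conformation, Ensemble

FAMILIES = ("M1", "M2", "M2STAR", "E")


@dataclass
class ClassifiedFrame:
    frame: Conformation | None
    xi: float
    u63: float
    family: str
    triplets: list[TripletAnnotation] = field(default_factory=list)

    @property
    def triplet_flags(self) -> dict[str, bool]:
        return triplet_presence(self.triplets)


@dataclass
class EnsembleComposition:
    fractions: dict[str, float]
    n: int
    weighting: str = "uniform"

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")

    def folded(self) -> dict[str, float]:
        """Fractions with the M2* subset folded back into M2."""
        out = {k: v for k, v in self.fractions.items() if k != "M2STAR"}
        out["M2"] = out.get("M2", 0.0) + self.fractions.get("M2STAR", 0.0)
        return out

    def get(self, family: str) -> float:
        return self.fractions.get(family, 0.0)


def assign_family(xi: float,
                  triplets: Sequence[TripletAnnotation] | None = None) -> str:
    """Family label from the xi band rule, refined to M2* by the U63 triplet."""
    if not 0.0 <= xi <= 180.0:
        raise ValueError(f"xi={xi} outside [0, 180]")
    if xi <= 60.0:
        family = "M1"
    elif xi <= 100.0:
        family = "M2"
    else:
        family = "E"
    if family == "M2" and triplets is not None:
        if triplet_presence(triplets).get("M2STAR", False):
            family = "M2STAR"
    return family


def classify_frame(conf: Conformation, spec: AngleSpec = AngleSpec(),
                   criteria: HBondCriteria = HBondCriteria(),
                   keep_frame: bool = True) -> ClassifiedFrame:
    triplets = detect_triplets(conf, criteria=criteria)
    xi = xi_angle(conf, spec)
    u63 = u63_angle(conf, spec)
    return ClassifiedFrame(conf if keep_frame else None, xi, u63,
                           assign_family(xi, triplets), triplets)


def classify_ensemble(ens: Ensemble, spec: AngleSpec = AngleSpec(),
                      criteria: HBondCriteria = HBondCriteria(),
                      keep_frames: bool = False) -> list[ClassifiedFrame]:
    """Per-frame xi, U63 angle, triplets and family label."""
    return [classify_frame(f, spec, criteria, keep_frame=keep_frames) for f in ens]


def composition(frames: Sequence[ClassifiedFrame],
                weights: Sequence[float] | None = None,
                weighting: str = "uniform") -> EnsembleComposition:
    """Weighted family fractions over classified frames.

    M2* is reported as its own family; use :meth:`EnsembleComposition.folded`
    for the view in which it counts as M2.
    """
    if not frames:
        raise ValueError("no frames to compose")
    if weights is None:
        w = np.ones(len(frames))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(frames),) or np.any(w < 0):
            raise ValueError("weights must be non-negative, one per frame")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    fractions = {f: 0.0 for f in FAMILIES}
    for frame, wi in zip(frames, w):
        fractions[frame.family] += float(wi)
    fractions = {k: v / total for k, v in fractions.items()}
    return EnsembleComposition(fractions, len(frames), weighting)


def projection_histogram(frames: Sequence[ClassifiedFrame],
                         xi_bins=None, u63_bins=None,
                         density: bool = False):
    """2-D (xi, U63-angle) histogram of classified frames.

    Returns (counts, xi_edges, u63_edges); counts sum to the frame count
    unless ``density`` is set.
    """
    xi_edges = np.asarray(xi_bins if xi_bins is not None
                          else np.linspace(0.0, 180.0, 37), dtype=float)
    u63_edges = np.asarray(u63_bins if u63_bins is not None
                           else np.linspace(0.0, 180.0, 37), dtype=float)
    for edges in (xi_edges, u63_edges):
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if edges[0] > 0.0 or edges[-1] < 180.0:
            raise ValueError("bin edges must cover [0, 180]")
    xi = [f.xi for f in frames]
    u63 = [f.u63 for f in frames]
    counts, _, _ = np.histogram2d(xi, u63, bins=[xi_edges, u63_edges],
                                  density=density)
    return counts, xi_edges, u63_edges


def u63_state(u63: float, threshold: float = 100.0) -> str:
    """'out' iff the U44-A65-U63 angle is at or above the threshold."""
    if not 0.0 <= u63 <= 180.0:
        raise ValueError(f"u63={u63} outside [0, 180]")
    return "out" if u63 >= threshold else "in"
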