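"""Global and regional gradient descriptors.

Range, explanation ratio and standard deviation summarize one component;
dispersion and eccentricity live in the 2-D space spanned by gradients 1 and
3, where inter-node distance reflects multiscale structural differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gradients import GradientSet
from .synthetic import ParcelSet

__all__ = [
    "GradientSpace2D", "gradient_space", "global_measures", "dispersion",
    "eccentricity", "community_summary",
]


@dataclass
class GradientSpace2D:
    """Node positions in the plane of two gradients (1 and 3 by default)."""

    points: np.ndarray      # (N, 2)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("need a node×2 matrix")

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def gradient_space(g: GradientSet, components: tuple[int, int] = (0, 2)) -> GradientSpace2D:
    """2-D gradient space from two components (defaults: first and third)."""
    return GradientSpace2D(points=g.components[:, list(components)])


def global_measures(g: GradientSet, which: int = 0) -> dict[str, float]:
    """Range (max − min), explanation ratio and population SD of one component."""
    if not 0 <= which < g.k:
        raise ValueError(f"component index {which} out of range")
    scores = g.components[:, which]
    return {
        "range": float(scores.max() - scores.min()),
        "explanation_ratio": float(g.explanation_ratio[which]),
        "sd": float(scores.std()),       # population SD: descriptor of a fixed parcel set
    }


def dispersion(space: GradientSpace2D) -> float:
    """Sum of Euclidean distances of each node to the space's own centroid."""
    if space.points.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    return float(np.linalg.norm(space.points - space.centroid, axis=1).sum())


def eccentricity(space: GradientSpace2D, template_centroid: np.ndarray) -> np.ndarray:
    """Per-node Euclidean distance to the template-space centroid."""
    c = np.asarray(template_centroid, dtype=float)
    return np.linalg.norm(space.points - c, axis=1)


def community_summary(
    g: GradientSet,
    parcels: ParcelSet,
    which: int = 0,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-community mean and SD of one component.

    With ``reference`` (a previous summary, e.g. from the youngest age group),
    a ``diff`` column of mean differences is added for radar-style comparisons.
    """
    scores = g.components[:, which]
    labels = np.asarray(parcels.community)
    if labels.shape[0] != scores.shape[0]:
        raise ValueError("community labels do not match node count")
    df = (
        pd.DataFrame({"community": labels, "score": scores})
        .groupby("community")["score"]
        .agg(mean="mean", sd=lambda x: float(np.std(x)), n="size")
        .reset_index()
    )
    if reference is not None:
        ref = reference.set_index("community")["mean"]
        df["diff"] = df["mean"] - df["community"].map(ref)
    return df
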