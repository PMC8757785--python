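"""Scalar fields on surface meshes and their summary statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriSurfaceMesh


@dataclass
class SurfaceField:
    """A per-face or per-vertex scalar (or 3-vector) field on a wall mesh.

    ``association`` is ``"face"`` or ``"vertex"``; ``units`` a free tag
    (``"Pa"``, ``"mm"``, ``"1"``).
    """

    values: np.ndarray
    association: str
    units: str = "1"
    name: str = "field"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.association not in ("face", "vertex"):
            raise ValueError("association must be 'face' or 'vertex'")
        if np.isnan(self.values).any():
            raise ValueError("field contains NaN")

    def check_mesh(self, mesh: TriSurfaceMesh) -> None:
        n = mesh.n_faces if self.association == "face" else mesh.n_vertices
        if len(self.values) != n:
            raise ValueError(
                f"field has {len(self.values)} values for {n} {self.association}s")


@dataclass
class FieldSummary:
    """Distribution summary of a wall field (the box-plot numbers).

    ``mean`` is area-weighted; order statistics (quartiles, whiskers) are
    per-element, unweighted, with Tukey 1.5 IQR whiskers clamped to the data
    range.
    """

    min: float
    max: float
    mean: float
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    mean_unweighted: float
    n_elements: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("min", "max", "mean", "q1", "median", "q3",
                 "whisker_low", "whisker_high", "mean_unweighted", "n_elements")}
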