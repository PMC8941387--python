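"""Feature extraction: the 52 facial distances plus facial area.

For each subject, the 26 registry distances are measured in Euclidean
form from the landmarks alone and in geodesic form over the subject's
face mesh; facial area is the total mesh surface area.  Geodesic values
and area are flagged absent when no mesh is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import (
    ALL_FEATURES,
    DISTANCE_DEFINITIONS,
    EUCLIDEAN_FEATURES,
    GEODESIC_FEATURES,
    LOG_TRANSFORM_FEATURES,
    feature_name,
)
from .geodesic import GeodesicSolver
from .landmarks import LandmarkSet
from .mesh import FaceMesh, euclidean_distance

log = logging.getLogger(__name__)


@dataclass
class FeatureVector:
    """The 52 distances (mm) and facial area (mm^2) of one face."""

    subject_id: str
    euclidean: dict[str, float] = field(default_factory=dict)
    geodesic: dict[str, float] = field(default_factory=dict)
    facial_area: float | None = None

    @property
    def has_geodesic(self) -> bool:
        return bool(self.geodesic)

    def as_series(self) -> pd.Series:
        data: dict[str, float] = {}
        data.update(self.euclidean)
        data.update(self.geodesic)
        if self.facial_area is not None:
            data["facial_area"] = self.facial_area
        return pd.Series(data, name=self.subject_id)


def extract_features(landmarks: LandmarkSet,
                     mesh: FaceMesh | None = None,
                     solver: GeodesicSolver | None = None) -> FeatureVector:
    """Measure all registry distances (and area) for one subject.

    Parameters
    ----------
    landmarks:
        Complete 21-landmark set.
    mesh:
        Subject face surface; required for geodesic distances and area.
    solver:
        Optional prebuilt :class:`GeodesicSolver` for ``mesh`` (saves the
        graph construction when extracting repeatedly on one mesh).
    """
    fv = FeatureVector(landmarks.subject_id)
    for d in DISTANCE_DEFINITIONS:
        a, b = d.endpoints
        fv.euclidean[feature_name(d, "euclidean")] = euclidean_distance(
            landmarks[a], landmarks[b]
        )
    if mesh is not None or solver is not None:
        if solver is None:
            solver = GeodesicSolver(mesh)
        pts = landmarks.to_array()
        code_idx = {c: i for i, c in enumerate(landmarks.points)}
        pairs = np.array(
            [[code_idx[d.endpoints[0]], code_idx[d.endpoints[1]]]
             for d in DISTANCE_DEFINITIONS], dtype=np.int64
        )
        geo = solver.pair_distances(pts, pairs)
        for d, g in zip(DISTANCE_DEFINITIONS, geo):
            fv.geodesic[feature_name(d, "geodesic")] = float(g)
        fv.facial_area = solver.mesh.area()
    return fv


def features_to_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a table (one row per subject)."""
    df = pd.DataFrame([v.as_series() for v in vectors])
    df.index.name = "subject_id"
    return df


#: |skewness| above which a warning is logged during transformation.
SKEW_WARN = 1.0


def transform_features(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the fixed analysis transformations to a feature table.

    The two geodesic variables that are positively skewed in adult face
    cohorts — geodesic forehead width and geodesic mandible height — are
    replaced by their natural logarithm; every other column is unchanged.
    A skewness audit is logged for any column with \\|skew\\| > 1 but never
    changes the transform set, keeping the analysis pipeline fixed.

    Returns the transformed table and a metadata dict recording which
    columns were log-transformed.
    """
    if table.empty:
        raise ValueError("empty feature table")
    out = table.copy()
    applied = []
    for col in LOG_TRANSFORM_FEATURES:
        if col not in out.columns:
            continue
        vals = out[col].to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError(f"non-positive value in log column {col!r}")
        out[col] = np.log(vals)
        applied.append(col)
    numeric = out.select_dtypes(include=[np.number])
    skew = numeric.skew()
    for col, s in skew.items():
        if abs(s) > SKEW_WARN and col not in applied:
            log.warning("column %r has skewness %.2f (not transformed; "
                        "the transform set is fixed)", col, s)
    meta = {"log_transformed": applied, "log_base": "e"}
    return out, meta


__all__ = [
    "FeatureVector", "extract_features", "features_to_table",
    "transform_features", "ALL_FEATURES", "EUCLIDEAN_FEATURES",
    "GEODESIC_FEATURES",
]
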