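"""Farkas facial landmarks: names, containers and CSV I/O.

The pipeline works from 21 named craniofacial landmarks (Farkas
anthropometry), each a 3D point in millimetres.  Paired landmarks carry a
``_l``/``_r`` side suffix; midline landmarks are unsuffixed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

#: The 21 landmark codes, in canonical order.
#: Ft = frontotemporale, Ex = exocanthion, En = endocanthion, N = nasion,
#: Al = alare, Sbal = subalare, Ch = cheilion, Pg = pogonion, Tr = trichion,
#: G = glabella, Prn = pronasale, Sn = subnasale, Sto = stomion,
#: Ls = labiale superius, Li = labiale inferius.
LANDMARK_CODES: tuple[str, ...] = (
    "Ft_l", "Ft_r", "Ex_l", "Ex_r", "En_l", "En_r", "N",
    "Al_l", "Al_r", "Sbal_l", "Sbal_r", "Ch_l", "Ch_r", "Pg",
    "Tr", "G", "Prn", "Sn", "Sto", "Ls", "Li",
)

#: Left/right pairs; everything else is midline.
PAIRED_CODES: tuple[tuple[str, str], ...] = (
    ("Ft_l", "Ft_r"), ("Ex_l", "Ex_r"), ("En_l", "En_r"),
    ("Al_l", "Al_r"), ("Sbal_l", "Sbal_r"), ("Ch_l", "Ch_r"),
)

MIDLINE_CODES: tuple[str, ...] = tuple(
    c for c in LANDMARK_CODES if c.endswith(("_l", "_r")) is False
)

_CODE_SET = frozenset(LANDMARK_CODES)


class LandmarkError(ValueError):
    """Raised for missing/unknown landmarks or malformed landmark files."""


@dataclass
class LandmarkSet:
    """All 21 landmarks of one face, in mm.

    Parameters
    ----------
    subject_id:
        Identifier of the subject the face belongs to.
    points:
        Mapping from landmark code to a length-3 coordinate array.
    """

    subject_id: str
    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for code, xyz in self.points.items():
            if code not in _CODE_SET:
                raise LandmarkError(
                    f"subject {self.subject_id!r}: unknown landmark code {code!r}"
                )
            arr = np.asarray(xyz, dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise LandmarkError(
                    f"subject {self.subject_id!r}: non-finite coordinates for {code!r}"
                )
            clean[code] = arr
        missing = [c for c in LANDMARK_CODES if c not in clean]
        if missing:
            raise LandmarkError(
                f"subject {self.subject_id!r}: missing landmark(s) {', '.join(missing)}"
            )
        self.points = {c: clean[c] for c in LANDMARK_CODES}

    def __getitem__(self, code: str) -> np.ndarray:
        try:
            return self.points[code]
        except KeyError:
            raise LandmarkError(
                f"subject {self.subject_id!r}: missing landmark {code!r}"
            ) from None

    def to_array(self) -> np.ndarray:
        """Coordinates as a (21, 3) array in canonical code order."""
        return np.stack([self.points[c] for c in LANDMARK_CODES])

    @classmethod
    def from_array(cls, subject_id: str, coords: np.ndarray) -> "LandmarkSet":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(LANDMARK_CODES), 3):
            raise LandmarkError(
                f"subject {subject_id!r}: expected (21, 3) coordinates, "
                f"got {coords.shape}"
            )
        return cls(subject_id, dict(zip(LANDMARK_CODES, coords)))

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    scale: float = 1.0) -> "LandmarkSet":
        """Return a rigidly moved / uniformly scaled copy."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return LandmarkSet.from_array(
            self.subject_id, scale * self.to_array() @ R.T + t
        )


def write_landmarks(sets: Iterable[LandmarkSet], path: str | Path) -> None:
    """Write landmark sets to CSV (subject_id, landmark_code, x, y, z)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "landmark_code", "x", "y", "z"])
        for lset in sets:
            for code in LANDMARK_CODES:
                x, y, z = (float(v) for v in lset.points[code])
                w.writerow([lset.subject_id, code, repr(x), repr(y), repr(z)])


def read_landmarks(path: str | Path) -> list[LandmarkSet]:
    """Read a landmark CSV into one LandmarkSet per subject.

    Raises
    ------
    LandmarkError
        If a row has an unknown code, a subject lacks one of the 21
        landmarks, or the file is malformed.  The error names the subject
        and landmark involved.
    """
    path = Path(path)
    per_subject: dict[str, dict[str, np.ndarray]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "landmark_code", "x", "y", "z"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise LandmarkError(
                f"{path}: expected columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            sid = row["subject_id"]
            code = row["landmark_code"]
            if code not in _CODE_SET:
                raise LandmarkError(
                    f"{path}:{i}: subject {sid!r}: unknown landmark code {code!r}"
                )
            try:
                xyz = np.array(
                    [float(row["x"]), float(row["y"]), float(row["z"])]
                )
            except ValueError as exc:
                raise LandmarkError(
                    f"{path}:{i}: subject {sid!r}, landmark {code!r}: {exc}"
                ) from None
            per_subject.setdefault(sid, {})[code] = xyz
    return [LandmarkSet(sid, pts) for sid, pts in per_subject.items()]


def read_metadata(path: str | Path):
    """Read the subject metadata CSV (subject_id, sex, family_group, age)."""
    import pandas as pd

    meta = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "sex", "family_group", "age"}
    missing = required - set(meta.columns)
    if missing:
        raise LandmarkError(f"{path}: metadata missing columns {sorted(missing)}")
    return meta
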