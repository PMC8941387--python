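"""The shipped average-face template: landmarks, surface and dimorphism.

Coordinate frame: x lateral (subject's left negative), y vertical (up
positive), z anterior (out of the face), all in mm, origin roughly at the
mid-face.  The template is an analytic smooth surface — an elliptical
facial dome with nose, brow, lip and chin features — over an elliptical
(x, y) domain, triangulated as a mirror-symmetric criss-cross grid.  The female template is
tuned so its inter-landmark distances approximate an average adult female
face of the size reported for comparison mothers in this literature; a
male parameter set defines the sexual-dimorphism displacement field
(male minus female landmark positions), which doubles as the
masculinization direction applied to family groups.
"""

from __future__ import annotations

import numpy as np

from .landmarks import LANDMARK_CODES, LandmarkSet
from .mesh import FaceMesh
from ._tps import warp_3d

# -- analytic surface ------------------------------------------------------

#: Surface shape parameters, female template.
FEMALE_SURFACE = dict(
    dome_a=74.0,      # lateral semi-axis of the facial dome (mm)
    dome_b=125.0,     # vertical semi-axis (mm)
    dome_c=88.0,      # depth of the dome (mm)
    dome_y0=-6.0,     # vertical centre of the dome
    nose_h=23.5,      # nose ridge height (mm)
    nose_y=-16.0,     # nose peak (pronasale) vertical position
    nose_sx=8.5,      # lateral nose spread
    nose_sy=8.0,      # vertical nose spread
    brow_h=6.0,       # brow/glabella ridge height
    lip_h=6.0,        # perioral bump height
    lip_y=-46.0,
    chin_h=5.0,       # chin (pogonion) bump height
    chin_y=-79.0,
    domain_rx=72.0,   # lateral semi-axis of the meshed domain
    domain_ry=104.0,  # vertical semi-axis
    domain_y0=-6.0,
)

#: Male surface: a uniformly larger dome with a more protrusive nose,
#: heavier brow and longer face.
MALE_SURFACE = dict(
    FEMALE_SURFACE,
    dome_a=77.5, dome_b=131.0, dome_c=92.5,
    nose_h=26.0, brow_h=9.5, chin_h=7.0,
    domain_rx=75.5, domain_ry=109.0,
)

#: Landmark (x, y) positions on the female template; z comes from the
#: surface.  Mirrored pairs share magnitude.
FEMALE_LANDMARK_XY = {
    "Tr": (0.0, 72.0),
    "G": (0.0, 40.0),
    "Ft_l": (-57.0, 45.0), "Ft_r": (57.0, 45.0),
    "Ex_l": (-44.5, 15.0), "Ex_r": (44.5, 15.0),
    "En_l": (-16.5, 16.5), "En_r": (16.5, 16.5),
    "N": (0.0, 22.0),
    "Al_l": (-8.8, -22.5), "Al_r": (8.8, -22.5),
    "Sbal_l": (-7.5, -25.0), "Sbal_r": (7.5, -25.0),
    "Prn": (0.0, -16.0),
    "Sn": (0.0, -26.0),
    "Ls": (0.0, -39.5),
    "Sto": (0.0, -46.3),
    "Li": (0.0, -53.0),
    "Ch_l": (-26.0, -46.0), "Ch_r": (26.0, -46.0),
    "Pg": (0.0, -79.0),
}

#: Male landmark (x, y): laterally/vertically expanded and feature-shifted.
MALE_LANDMARK_XY = {
    "Tr": (0.0, 78.0),
    "G": (0.0, 43.0),
    "Ft_l": (-60.5, 47.0), "Ft_r": (60.5, 47.0),
    "Ex_l": (-47.0, 16.0), "Ex_r": (47.0, 16.0),
    "En_l": (-17.2, 17.5), "En_r": (17.2, 17.5),
    "N": (0.0, 24.0),
    "Al_l": (-9.65, -24.0), "Al_r": (9.65, -24.0),
    "Sbal_l": (-8.2, -26.5), "Sbal_r": (8.2, -26.5),
    "Prn": (0.0, -17.5),
    "Sn": (0.0, -28.0),
    "Ls": (0.0, -42.5),
    "Sto": (0.0, -49.8),
    "Li": (0.0, -57.0),
    "Ch_l": (-27.5, -49.0), "Ch_r": (27.5, -49.0),
    "Pg": (0.0, -85.0),
}


def surface_height(x, y, params: dict | None = None) -> np.ndarray:
    """Anterior (z) height of the analytic face surface at (x, y)."""
    p = FEMALE_SURFACE if params is None else params
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho2 = (x / p["dome_a"]) ** 2 + ((y - p["dome_y0"]) / p["dome_b"]) ** 2
    dome = p["dome_c"] * np.sqrt(np.clip(1.0 - rho2, 0.0, None))
    nose = p["nose_h"] * np.exp(
        -0.5 * (x / p["nose_sx"]) ** 2
        - 0.5 * ((y - p["nose_y"]) / p["nose_sy"]) ** 2
    )
    brow = p["brow_h"] * np.exp(
        -0.5 * (x / 30.0) ** 2 - 0.5 * ((y - 36.0) / 9.0) ** 2
    )
    lips = p["lip_h"] * np.exp(
        -0.5 * (x / 20.0) ** 2 - 0.5 * ((y - p["lip_y"]) / 8.0) ** 2
    )
    chin = p["chin_h"] * np.exp(
        -0.5 * (x / 16.0) ** 2 - 0.5 * ((y - p["chin_y"]) / 12.0) ** 2
    )
    return dome + nose + brow + lips + chin


def _landmark_coords(xy: dict, params: dict) -> np.ndarray:
    pts = np.array([xy[c] for c in LANDMARK_CODES], dtype=float)
    z = surface_height(pts[:, 0], pts[:, 1], params)
    return np.column_stack([pts, z])


#: (21, 3) landmark coordinate arrays, canonical code order.
FEMALE_TEMPLATE: np.ndarray = _landmark_coords(FEMALE_LANDMARK_XY, FEMALE_SURFACE)
MALE_TEMPLATE: np.ndarray = _landmark_coords(MALE_LANDMARK_XY, MALE_SURFACE)

#: Sexual-dimorphism displacement field (mm): full application takes the
#: female template to the male template.
DIMORPHISM_FIELD: np.ndarray = MALE_TEMPLATE - FEMALE_TEMPLATE


def template_landmarks(sex: str = "female",
                       subject_id: str = "template") -> LandmarkSet:
    base = FEMALE_TEMPLATE if sex == "female" else MALE_TEMPLATE
    if sex not in ("female", "male"):
        raise ValueError(f"unknown sex {sex!r}")
    return LandmarkSet.from_array(subject_id, base.copy())


def _disk_grid(n: int):
    """Mirror-symmetric triangulation of the unit disk.

    A square (2n+1)-per-side grid is mapped onto the disk with the
    square-to-disk map ``x = u sqrt(1 - v^2/2)``; every grid cell is
    split into four triangles about its centre (criss-cross pattern), so
    the triangulation — and hence every surface path length — is exactly
    symmetric under left-right mirroring.
    """
    m = 2 * n + 1
    t = np.linspace(-1.0, 1.0, m)
    t = 0.5 * (t - t[::-1])  # bitwise antisymmetric
    # odd cubic stretches: denser cells near the midline and mid-height,
    # where the nose carries the strongest surface curvature (strong
    # laterally, moderate vertically)
    u = 0.4 * t + 0.6 * t ** 3
    v = 0.7 * t + 0.3 * t ** 3
    U, V = np.meshgrid(u, v, indexing="ij")
    cu = 0.5 * (u[:-1] + u[1:])
    cv = 0.5 * (v[:-1] + v[1:])
    CU, CV = np.meshgrid(cu, cv, indexing="ij")

    def to_disk(a, b):
        return (a * np.sqrt(1.0 - 0.5 * b ** 2),
                b * np.sqrt(1.0 - 0.5 * a ** 2))

    gx, gy = to_disk(U, V)
    cx, cy = to_disk(CU, CV)
    verts = np.column_stack([
        np.concatenate([gx.ravel(), cx.ravel()]),
        np.concatenate([gy.ravel(), cy.ravel()]),
    ])

    def gid(i, j):
        return i * m + j

    n_grid = m * m

    def cid(i, j):
        return n_grid + i * (m - 1) + j

    tris = []
    for i in range(m - 1):
        for j in range(m - 1):
            c = cid(i, j)
            a = gid(i, j)
            b = gid(i + 1, j)
            d = gid(i + 1, j + 1)
            e = gid(i, j + 1)
            tris.extend([[a, b, c], [b, d, c], [d, e, c], [e, a, c]])
    return verts, np.array(tris, dtype=np.int64)


def template_mesh(params: dict | None = None, resolution: int = 18) -> FaceMesh:
    """Triangulated analytic template surface.

    ``resolution`` controls mesh density (~``8 resolution^2`` vertices).
    """
    p = FEMALE_SURFACE if params is None else params
    uv, tris = _disk_grid(resolution)
    x = p["domain_rx"] * uv[:, 0]
    y = p["domain_ry"] * uv[:, 1] + p["domain_y0"]
    z = surface_height(x, y, p)
    return FaceMesh(np.column_stack([x, y, z]), tris)


def subject_mesh(landmarks: LandmarkSet, resolution: int = 18) -> FaceMesh:
    """Face mesh for one subject: TPS warp of the female template mesh
    taking the template landmarks onto the subject's landmarks."""
    base = template_mesh(resolution=resolution)
    warped = warp_3d(FEMALE_TEMPLATE, landmarks.to_array(), base.vertices)
    return FaceMesh(warped, base.triangles)
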