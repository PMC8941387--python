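"""Thin-plate-spline interpolation (2D heightfields and 3D warps).

Used to build the smooth template face surface and to deform the template
mesh so that it interpolates a subject's landmarks exactly.
"""

from __future__ import annotations

import numpy as np


def _kernel_2d(r: np.ndarray) -> np.ndarray:
    # biharmonic kernel in 2D: r^2 log r  (0 at r=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = r * r * np.log(r)
    return np.where(r > 0, k, 0.0)


def _kernel_3d(r: np.ndarray) -> np.ndarray:
    # biharmonic kernel in 3D: r
    return r


class ThinPlateSpline:
    """Interpolating TPS from d-dimensional sites to scalar/vector values.

    Parameters
    ----------
    sites:
        (n, d) control point coordinates, d in {2, 3}.
    values:
        (n,) or (n, m) values at the control points.
    regularization:
        Diagonal ridge on the kernel block; 0 gives exact interpolation.
    """

    def __init__(self, sites: np.ndarray, values: np.ndarray,
                 regularization: float = 0.0):
        sites = np.asarray(sites, dtype=float)
        values = np.asarray(values, dtype=float)
        n, d = sites.shape
        if d not in (2, 3):
            raise ValueError("TPS supports 2D or 3D sites")
        self.sites = sites
        self._kernel = _kernel_2d if d == 2 else _kernel_3d

        r = np.linalg.norm(sites[:, None, :] - sites[None, :, :], axis=2)
        K = self._kernel(r) + regularization * np.eye(n)
        P = np.column_stack([np.ones(n), sites])
        L = np.zeros((n + d + 1, n + d + 1))
        L[:n, :n] = K
        L[:n, n:] = P
        L[n:, :n] = P.T
        vals2d = values if values.ndim == 2 else values[:, None]
        rhs = np.zeros((n + d + 1, vals2d.shape[1]))
        rhs[:n] = vals2d
        sol = np.linalg.solve(L, rhs)
        self.w = sol[:n]
        self.a = sol[n:]
        self._scalar = values.ndim == 1

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        r = np.linalg.norm(x[:, None, :] - self.sites[None, :, :], axis=2)
        out = self._kernel(r) @ self.w
        out += np.column_stack([np.ones(len(x)), x]) @ self.a
        return out[:, 0] if self._scalar else out


def warp_3d(source_landmarks: np.ndarray, target_landmarks: np.ndarray,
            points: np.ndarray) -> np.ndarray:
    """Deform ``points`` by the TPS taking source to target landmarks.

    The warp interpolates the landmarks exactly and extends smoothly
    (affine plus biharmonic terms) elsewhere.
    """
    disp = np.asarray(target_landmarks, float) - np.asarray(source_landmarks, float)
    tps = ThinPlateSpline(source_landmarks, disp)
    return np.asarray(points, float) + tps(points)
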