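"""Topographic map (BEAM) construction and perturbation resampling.

Rhythm powers measured at the C electrodes are spread over the scalp by an
exactly-interpolating, C1-smooth piecewise-cubic scheme (Clough-Tocher on the
Delaunay triangulation of the projected electrode sites), evaluated at the
regular grid of cell centres.  Grid points outside the electrode convex hull
are filled with the value of the nearest inside grid point, so maps contain no
extrapolation artefacts; the affected region is available as a mask.

Going back, a perturbation image defined on the grid is resampled at the
electrode positions by bicubic spline interpolation on the regular lattice.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator, RegularGridInterpolator
from scipy.spatial import QhullError, cKDTree

from .montage import GridSpec, InvalidGeometryError, Montage

__all__ = ["interpolate_beam", "build_beams", "sample_perturbation", "hull_mask", "BeamTransformer"]


def _scattered_to_grid(values: np.ndarray, montage: Montage, grid: GridSpec) -> np.ndarray:
    """Clough-Tocher interpolation of per-electrode values onto the grid.

    values: (C,) or (C, K); returns (H, W) or (H, W, K).
    """
    pts = montage.coords2d
    if pts.shape[0] < 4:
        raise InvalidGeometryError("need at least 4 electrodes for a 2-D map")
    try:
        interp = CloughTocher2DInterpolator(pts, values)
    except QhullError as exc:
        raise InvalidGeometryError(f"degenerate electrode geometry: {exc}") from exc
    flat = grid.centers.reshape(-1, 2)
    out = interp(flat)  # NaN outside the convex hull
    nan = np.isnan(out if out.ndim == 1 else out[:, 0])
    if nan.any():
        tree = cKDTree(flat[~nan])
        _, nearest = tree.query(flat[nan])
        out[nan] = out[~nan][nearest]
    return out.reshape(grid.centers.shape[:2] + values.shape[1:])


def hull_mask(montage: Montage, grid: GridSpec) -> np.ndarray:
    """Boolean (H, W) mask of grid centres inside the electrode convex hull."""
    probe = _interp_nan(montage, grid)
    return ~np.isnan(probe)


def _interp_nan(montage: Montage, grid: GridSpec) -> np.ndarray:
    interp = CloughTocher2DInterpolator(montage.coords2d, np.zeros(montage.n_channels))
    return interp(grid.centers.reshape(-1, 2)).reshape(grid.H, grid.W)


def interpolate_beam(powers: np.ndarray, montage: Montage, grid: GridSpec) -> np.ndarray:
    """One H x W topographic map from C per-electrode power values."""
    powers = np.asarray(powers, dtype=np.float64)
    if powers.shape != (montage.n_channels,):
        raise ValueError(f"expected {montage.n_channels} powers, got shape {powers.shape}")
    return _scattered_to_grid(powers, montage, grid)


def build_beams(P: np.ndarray, montage: Montage, grid: GridSpec) -> np.ndarray:
    """BEAM tensor (..., T, B, H, W) from a rhythm power array (..., T, B, C).

    All T*B (and any leading batch) maps share one triangulation and are
    interpolated in a single vectorized call.
    """
    P = np.asarray(P, dtype=np.float64)
    if P.shape[-1] != montage.n_channels:
        raise ValueError(f"last axis of P must be C={montage.n_channels}")
    lead = P.shape[:-1]
    vals = P.reshape(-1, montage.n_channels).T  # (C, prod(lead))
    maps = _scattered_to_grid(vals, montage, grid)  # (H, W, prod(lead))
    return np.moveaxis(maps.reshape(grid.H, grid.W, *lead), (0, 1), (-2, -1))


def sample_perturbation(eta_beam: np.ndarray, montage: Montage, grid: GridSpec) -> np.ndarray:
    """Resample a grid image stack (..., H, W) at the electrodes -> (..., C).

    Bicubic spline interpolation on the regular grid of cell centres; electrodes
    between the rectangle edge and the outermost cell centres fall in the
    half-cell margin and are handled by the spline's polynomial extension.
    """
    eta_beam = np.asarray(eta_beam, dtype=np.float64)
    if eta_beam.shape[-2:] != (grid.H, grid.W):
        raise ValueError(f"image shape {eta_beam.shape[-2:]} does not match grid {(grid.H, grid.W)}")
    if not grid.contains(montage.coords2d).all():
        raise InvalidGeometryError("electrode outside the grid bounds")
    lead = eta_beam.shape[:-2]
    flat = np.moveaxis(eta_beam.reshape(-1, grid.H, grid.W), 0, -1)  # (H, W, K)
    interp = RegularGridInterpolator(
        (grid.ys, grid.xs), flat, method="cubic", bounds_error=False, fill_value=None
    )
    out = interp(montage.coords2d[:, ::-1])  # query as (y, x); -> (C, K)
    return np.moveaxis(out, -1, 0).reshape(lead + (montage.n_channels,))


class BeamTransformer:
    """sklearn-style transformer: raw EEG samples -> BEAM tensors.

    Parameters
    ----------
    montage, grid : geometry shared by every map.
    sample_rate : Hz.

    ``transform`` accepts (N, T, C, S) or a single (T, C, S) sample and returns
    (N, T, B, H, W) / (T, B, H, W).
    """

    def __init__(self, montage: Montage, grid: GridSpec, sample_rate: float = 256.0):
        self.montage = montage
        self.grid = grid
        self.sample_rate = sample_rate

    def get_params(self, deep: bool = True) -> dict:
        return {"montage": self.montage, "grid": self.grid, "sample_rate": self.sample_rate}

    def set_params(self, **params) -> "BeamTransformer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "BeamTransformer":  # stateless
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        from .rhythms import rhythm_powers

        P = rhythm_powers(np.asarray(X), self.sample_rate)
        return build_beams(P, self.montage, self.grid)

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.transform(X)
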