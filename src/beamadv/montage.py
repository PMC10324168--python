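"""Electrode geometry: spherical head model, azimuthal projection, interpolation grid.

The scalp is modeled as a sphere of radius ``r`` (default 0.095 m).  Electrodes
sit at idealized 10-20 / 10-10 angular positions on that sphere and are flattened
onto a plane with an equidistant azimuthal projection centred at the vertex
(Cz), which preserves both the great-circle distance from the vertex and the
azimuth of every electrode.  Topographic maps are rasterized on a regular grid
of cell centres tiling the minimum bounding rectangle of the projected
positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

HEAD_RADIUS_M = 0.095

__all__ = [
    "Montage",
    "GridSpec",
    "InvalidGeometryError",
    "MissingElectrodeError",
    "project_equidistant_azimuthal",
    "build_montage",
    "build_grid",
    "load_channel_mapping",
    "CHBMIT_22",
    "HEAD_RADIUS_M",
]


class InvalidGeometryError(ValueError):
    """Raised for off-sphere points, antipodal ambiguity, or degenerate layouts."""


class MissingElectrodeError(KeyError):
    """Raised when an electrode label cannot be resolved to a 3-D position."""


# Idealized spherical angles (inclination from the vertex, azimuth), degrees.
# Azimuth is measured counter-clockwise from the +x axis (right preauricular
# point); +y points to the nasion.  These are the canonical equidistant 10-20
# angles (midline and temporal ring at 90 deg from Cz, parasagittal rows at
# 45/60 deg) with the inferior 10-10 ring (FT9/FT10, TP9/TP10) at 108 deg.
_ANGLES_DEG: dict[str, tuple[float, float]] = {
    "Cz": (0.0, 0.0),
    "C3": (45.0, 180.0),
    "C4": (45.0, 0.0),
    "Fz": (45.0, 90.0),
    "Pz": (45.0, 270.0),
    "F3": (60.0, 129.0),
    "F4": (60.0, 51.0),
    "P3": (60.0, 231.0),
    "P4": (60.0, 309.0),
    "Fpz": (90.0, 90.0),
    "Fp1": (90.0, 108.0),
    "Fp2": (90.0, 72.0),
    "F7": (90.0, 144.0),
    "F8": (90.0, 36.0),
    "T7": (90.0, 180.0),
    "T8": (90.0, 0.0),
    "P7": (90.0, 216.0),
    "P8": (90.0, 324.0),
    "O1": (90.0, 252.0),
    "O2": (90.0, 288.0),
    "Oz": (90.0, 270.0),
    "FT9": (108.0, 162.0),
    "FT10": (108.0, 18.0),
    "TP9": (108.0, 198.0),
    "TP10": (108.0, 342.0),
    "FT7": (90.0, 162.0),
    "FT8": (90.0, 18.0),
    "TP7": (90.0, 198.0),
    "TP8": (90.0, 342.0),
}

# Older 10-20 nomenclature for the temporal chain.
_ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

#: Default 22-channel layout standing in for the 22 CHB-MIT channels mapped
#: onto 10-20 labels (19 classic positions + FT9/FT10/Oz).
CHBMIT_22 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT9", "T7", "C3", "Cz", "C4", "T8", "FT10",
    "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
]

_STANDARDS = {
    "standard-1020": sorted(_ANGLES_DEG),
    "chbmit-22": CHBMIT_22,
}


def _resolve_label(label: str) -> str:
    key = label.strip()
    for cand in (key, key.capitalize(), key.upper(), _ALIASES.get(key.upper())):
        if cand is None:
            continue
        if cand in _ANGLES_DEG:
            return cand
        # labels like FP1 -> Fp1, FCZ -> Fcz
        norm = cand[:-1].capitalize() + cand[-1].lower() if cand[-1].lower() == "z" else cand.capitalize()
        if norm in _ANGLES_DEG:
            return norm
    raise MissingElectrodeError(f"unknown electrode label: {label!r}")


def _sphere_point(label: str, radius: float) -> np.ndarray:
    inc, azi = _ANGLES_DEG[label]
    inc, azi = math.radians(inc), math.radians(azi)
    return radius * np.array(
        [math.sin(inc) * math.cos(azi), math.sin(inc) * math.sin(azi), math.cos(inc)]
    )


def project_equidistant_azimuthal(
    points3d: np.ndarray, radius: float = HEAD_RADIUS_M, *, rtol: float = 1e-6
) -> np.ndarray:
    """Project points on a sphere to the plane, preserving vertex distance and azimuth.

    The projection centre (apex) is the vertex ``(0, 0, radius)``.  A point at
    great-circle distance ``d`` from the apex and azimuth ``phi`` maps to the
    planar point at radius ``d``, azimuth ``phi``; the apex maps to the origin.

    Parameters
    ----------
    points3d : (..., 3) array
        Points on the sphere of the given radius.
    radius : float
        Sphere radius in metres.

    Returns
    -------
    (..., 2) array of planar coordinates in metres.
    """
    pts = np.asarray(points3d, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    norms = np.linalg.norm(pts, axis=-1)
    if np.any(np.abs(norms - radius) > rtol * radius):
        bad = np.abs(norms - radius).max()
        raise InvalidGeometryError(
            f"point off the sphere of radius {radius}: max |deviation| = {bad:.3e} m"
        )
    z = np.clip(pts[..., 2] / radius, -1.0, 1.0)
    arc = radius * np.arccos(z)  # great-circle distance from the apex
    rho = np.hypot(pts[..., 0], pts[..., 1])
    if np.any((rho <= rtol * radius) & (pts[..., 2] < 0)):
        raise InvalidGeometryError("antipodal point (0, 0, -r) has no defined azimuth")
    out = np.zeros(pts.shape[:-1] + (2,))
    mask = rho > 0
    out[mask, 0] = arc[mask] * pts[mask, 0] / rho[mask]
    out[mask, 1] = arc[mask] * pts[mask, 1] / rho[mask]
    return out[0] if single else out


@dataclass(frozen=True)
class Montage:
    """An ordered set of named electrodes with 3-D and projected 2-D positions."""

    names: tuple[str, ...]
    coords3d: np.ndarray  # (C, 3), metres, on the sphere
    coords2d: np.ndarray  # (C, 2), metres, in the projected plane
    radius: float = HEAD_RADIUS_M

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise InvalidGeometryError("duplicate electrode labels in montage")
        if not (len(self.names) == len(self.coords3d) == len(self.coords2d)):
            raise InvalidGeometryError("montage field lengths disagree")
        norms = np.linalg.norm(self.coords3d, axis=1)
        if np.any(np.abs(norms - self.radius) > 1e-9):
            raise InvalidGeometryError("coords3d not on the head sphere")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        return self.names.index(_resolve_label(label))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tx3d\ty3d\tz3d\tx2d\ty2d\n")
            for name, p3, p2 in zip(self.names, self.coords3d, self.coords2d):
                fh.write(
                    f"{name}\t{p3[0]:.9f}\t{p3[1]:.9f}\t{p3[2]:.9f}"
                    f"\t{p2[0]:.9f}\t{p2[1]:.9f}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Montage":
        rows = [ln.split("\t") for ln in Path(path).read_text().strip().splitlines()[1:]]
        names = tuple(r[0] for r in rows)
        vals = np.array([[float(v) for v in r[1:6]] for r in rows])
        radius = float(np.linalg.norm(vals[:, :3], axis=1).mean())
        return cls(names, vals[:, :3], vals[:, 3:5], radius)


def build_montage(
    standard: str = "chbmit-22",
    channels: list[str] | None = None,
    radius: float = HEAD_RADIUS_M,
) -> Montage:
    """Build a montage from a named standard or an explicit label list.

    Parameters
    ----------
    standard : str
        ``"chbmit-22"`` (default 22-channel layout) or ``"standard-1020"``
        (every label in the built-in table).
    channels : list of str, optional
        Explicit labels; overrides the standard's list.  Old temporal names
        (T3/T4/T5/T6) are accepted as aliases.
    """
    if channels is None:
        try:
            channels = _STANDARDS[standard]
        except KeyError:
            raise MissingElectrodeError(
                f"unknown montage standard {standard!r}; known: {sorted(_STANDARDS)}"
            ) from None
    names = tuple(_resolve_label(ch) for ch in channels)
    coords3d = np.array([_sphere_point(n, radius) for n in names])
    coords2d = project_equidistant_azimuthal(coords3d, radius)
    return Montage(names, coords3d, coords2d, radius)


@dataclass(frozen=True)
class GridSpec:
    """Regular H x W lattice of cell centres tiling the montage bounding rectangle."""

    H: int
    W: int
    centers: np.ndarray = field(repr=False)  # (H, W, 2), metres
    bounds: tuple[float, float, float, float]  # (xmin, xmax, ymin, ymax)

    @property
    def xs(self) -> np.ndarray:
        return self.centers[0, :, 0]

    @property
    def ys(self) -> np.ndarray:
        return self.centers[:, 0, 1]

    def contains(self, points2d: np.ndarray) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.bounds
        p = np.atleast_2d(points2d)
        return (
            (p[:, 0] >= xmin - 1e-12) & (p[:, 0] <= xmax + 1e-12)
            & (p[:, 1] >= ymin - 1e-12) & (p[:, 1] <= ymax + 1e-12)
        )


def build_grid(montage: Montage, H: int = 22, W: int = 22) -> GridSpec:
    """Mesh the minimum bounding rectangle of the 2-D head into H x W cells.

    Cell centres are equally spaced along each axis (spacing = extent / count);
    the outermost centres are inset by half a cell so that the cells tile the
    rectangle exactly.
    """
    if H < 2 or W < 2:
        raise ValueError("grid needs H >= 2 and W >= 2")
    pts = montage.coords2d
    # collinear electrodes span no area and cannot support a 2-D map
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-12) < 2:
        raise InvalidGeometryError("electrode positions are collinear")
    xmin, xmax = pts[:, 0].min(), pts[:, 0].max()
    ymin, ymax = pts[:, 1].min(), pts[:, 1].max()
    dx, dy = (xmax - xmin) / W, (ymax - ymin) / H
    xs = xmin + dx * (np.arange(W) + 0.5)
    ys = ymin + dy * (np.arange(H) + 0.5)
    centers = np.stack(np.meshgrid(xs, ys), axis=-1)  # (H, W, 2)
    return GridSpec(H=H, W=W, centers=centers, bounds=(xmin, xmax, ymin, ymax))


def load_channel_mapping(path: str | Path | None = None) -> dict[str, str]:
    """Load the dataset-channel -> 10-20-label mapping TSV.

    Defaults to the packaged CHB-MIT mapping; pass a path to use an edited copy.
    """
    if path is None:
        src = resources.files("beamadv.data").joinpath("chbmit_channel_map.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chan, label = line.split("\t")[:2]
        mapping[chan] = label
    return mapping
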