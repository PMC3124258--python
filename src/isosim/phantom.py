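"""Digital fuzzy tissue phantoms.

A phantom is a voxel grid plus one *fraction volume* per tissue: a scalar
field in [0, 1] giving the amount of that tissue in each voxel (partial
volume by construction), in the style of voxel-based anatomical brain
phantoms distributed as one fuzzy volume per tissue class.  Synthetic
generators (uniform block, sphere, layered brain-like) remove any need
for external data.

Coordinates
-----------
Voxel indices are 0-based.  Physical coordinates are grid-centered: voxel
``(i, j, k)`` sits at ``(index - (shape - 1) / 2) * voxel_size`` per axis,
so the isocenter is at the volume center and gradient fields are
symmetric about zero.

I/O
---
A phantom is stored as a directory: one NIfTI fraction volume per tissue
(``fraction_<nn>_<name>.nii.gz``), an optional ``db0_map.nii.gz``, a
tab-separated tissue table ``tissues.tsv`` (name, rho, t1_s, t2_s,
delta_b_T) and a small ``phantom.json`` with grid metadata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "TissueParams",
    "Phantom",
    "make_uniform_phantom",
    "make_sphere_phantom",
    "make_layered_brain_phantom",
    "voxel_center_position",
    "position_to_index",
    "read_phantom",
    "write_phantom",
    "BRAIN_LAYER_TEMPLATES",
]

_FRACTION_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue MR properties.

    Parameters
    ----------
    name : str
        Tissue label.
    rho : float
        Spin density (equilibrium magnetization M0 per unit tissue
        fraction), arbitrary units >= 0.
    t1 : float
        Spin-lattice relaxation time, seconds (> 0).
    t2 : float
        Spin-spin relaxation time, seconds (> 0).
    delta_b : float
        Chemical-shift / susceptibility field offset, tesla, added to the
        local field wherever this tissue sits.
    """

    name: str
    rho: float
    t1: float
    t2: float
    delta_b: float = 0.0

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(f"t1 and t2 must be positive, got {self.t1}, {self.t2}")
        if self.t2 > self.t1:
            warnings.warn(
                f"tissue {self.name!r}: t2 ({self.t2}) > t1 ({self.t1}); "
                "physical tissues satisfy t2 <= t1",
                stacklevel=2,
            )


@dataclass
class Phantom:
    """Fuzzy tissue phantom: grid geometry + per-tissue fraction volumes.

    Attributes
    ----------
    shape : tuple of int
        Voxel counts ``(nx, ny, nz)``.
    voxel_size : tuple of float
        Voxel edge lengths, meters per axis.
    tissues : list of TissueParams
        Ordered tissue table.
    fractions : ndarray, shape (n_tissues, nx, ny, nz)
        Fuzzy occupancy of each tissue per voxel, values in [0, 1];
        per-voxel sums must not exceed 1 (+ tolerance).
    db0_map : ndarray or None
        Optional per-voxel static field deviation, tesla.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    tissues: list[TissueParams]
    fractions: np.ndarray
    db0_map: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        self.fractions = np.asarray(self.fractions, dtype=float)
        expected = (len(self.tissues),) + self.shape
        if self.fractions.shape != expected:
            raise ValueError(
                f"fractions shape {self.fractions.shape} != (n_tissues,)+shape {expected}"
            )
        if self.fractions.min(initial=0.0) < 0 or self.fractions.max(initial=0.0) > 1:
            raise ValueError("tissue fractions must lie in [0, 1]")
        total = self.fractions.sum(axis=0)
        if total.max(initial=0.0) > 1 + _FRACTION_SUM_TOL:
            raise ValueError(
                f"per-voxel tissue fractions sum to {total.max():.6f} > 1"
            )
        if self.db0_map is not None:
            self.db0_map = np.asarray(self.db0_map, dtype=float)
            if self.db0_map.shape != self.shape:
                raise ValueError(
                    f"db0_map shape {self.db0_map.shape} != phantom shape {self.shape}"
                )

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def fov(self) -> tuple[float, float, float]:
        """Physical extent of the grid per axis, meters."""
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))


def voxel_center_position(phantom: Phantom, index) -> np.ndarray:
    """Grid-centered physical position (meters) of voxel ``index``.

    ``position = (index - (shape - 1) / 2) * voxel_size`` per axis; the
    center voxel of an odd-sized axis maps to 0.
    """
    index = np.asarray(index)
    shape = np.asarray(phantom.shape)
    if index.shape[-1] != 3:
        raise ValueError("index must have 3 components")
    if np.any(index < 0) or np.any(index >= shape):
        raise IndexError(f"index {index} outside grid of shape {phantom.shape}")
    return (index - (shape - 1) / 2.0) * np.asarray(phantom.voxel_size)


def position_to_index(phantom: Phantom, position) -> np.ndarray:
    """Inverse of `voxel_center_position` (float voxel coordinates)."""
    position = np.asarray(position, dtype=float)
    shape = np.asarray(phantom.shape)
    return position / np.asarray(phantom.voxel_size) + (shape - 1) / 2.0


def make_uniform_phantom(
    shape, voxel_size, tissues, fractions_per_tissue
) -> Phantom:
    """Phantom with spatially constant fractions (one value per tissue)."""
    shape = tuple(int(n) for n in shape)
    fr = np.empty((len(tissues),) + shape)
    for t, f in enumerate(fractions_per_tissue):
        fr[t] = f
    return Phantom(shape, _as_voxel_size(voxel_size), list(tissues), fr)


def _as_voxel_size(voxel_size) -> tuple[float, float, float]:
    v = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    return tuple(float(x) for x in v)


def sphere_fraction_volume(
    shape, center, radius: float, supersample: int = 1
) -> np.ndarray:
    """Occupancy volume of a sphere on a voxel grid (voxel units).

    With ``supersample == 1`` a voxel is inside iff its center is strictly
    within ``radius`` of ``center`` (so a radius of 0 is empty).  With ``supersample == s`` each voxel is
    sampled on a regular s^3 sub-grid and the fraction of sub-points
    inside gives a fuzzy (partial-volume) boundary.
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    shape = tuple(int(n) for n in shape)
    center = np.asarray(center, dtype=float)
    axes = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    if supersample == 1:
        d2 = sum((ax - c) ** 2 for ax, c in zip(axes, center))
        return (d2 < radius**2).astype(float)
    # sub-voxel offsets centered in the voxel: (u + 0.5)/s - 0.5, u = 0..s-1
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    frac = np.zeros(shape)
    for ox in offs:
        for oy in offs:
            for oz in offs:
                d2 = (
                    (axes[0] + ox - center[0]) ** 2
                    + (axes[1] + oy - center[1]) ** 2
                    + (axes[2] + oz - center[2]) ** 2
                )
                frac += d2 < radius**2
    return frac / supersample**3


def make_sphere_phantom(
    shape,
    voxel_size,
    center,
    radius: float,
    tissue: TissueParams,
    supersample: int = 1,
) -> Phantom:
    """Single spherical object of one tissue.

    Parameters
    ----------
    center : tuple of float
        Sphere center in voxel coordinates (may be fractional).
    radius : float
        Sphere radius in voxels (>= 0; 0 gives an empty phantom).
    supersample : int
        Sub-voxel sampling factor per axis for fuzzy boundary voxels.
    """
    shape = tuple(int(n) for n in shape)
    center = np.asarray(center, dtype=float)
    if radius < 0:
        raise ValueError(f"invalid geometry: radius must be >= 0, got {radius}")
    if np.any(center < -0.5) or np.any(center > np.asarray(shape) - 0.5):
        raise ValueError(
            f"invalid geometry: center {tuple(center)} outside grid {shape}"
        )
    frac = sphere_fraction_volume(shape, center, radius, supersample)
    return Phantom(shape, _as_voxel_size(voxel_size), [tissue], frac[None])


#: Layer templates for the brain-like generator, outermost first.
#: Values are representative 1.5 T properties (rho arbitrary units,
#: times in seconds, delta_b in tesla).
BRAIN_LAYER_TEMPLATES: tuple[TissueParams, ...] = (
    TissueParams("skin", rho=0.85, t1=0.60, t2=0.060),
    TissueParams("skull", rho=0.12, t1=0.25, t2=0.005),
    TissueParams("fat", rho=0.90, t1=0.26, t2=0.080, delta_b=-5.25e-6 * 1.5),
    TissueParams("csf", rho=1.00, t1=4.00, t2=2.000),
    TissueParams("grey_matter", rho=0.85, t1=0.90, t2=0.100),
    TissueParams("white_matter", rho=0.70, t1=0.60, t2=0.080),
    TissueParams("deep_grey", rho=0.80, t1=1.00, t2=0.090),
    TissueParams("ventricle_csf", rho=1.00, t1=4.00, t2=2.000),
)


def make_layered_brain_phantom(
    shape, voxel_size, n_tissues: int, seed: int = 0
) -> Phantom:
    """Brain-like phantom: concentric fuzzy layers with partial-volume edges.

    The outer boundary is a slightly wobbled ellipse/ellipsoid (seeded
    low-order harmonic perturbation, so runs with the same seed are
    bit-identical); successive tissues occupy concentric radial bands
    whose boundaries are smoothed over about one voxel, so every
    inter-layer voxel carries fractions of both neighbours and per-voxel
    fractions sum to exactly 1 inside the head and 0 outside.

    Parameters
    ----------
    n_tissues : int
        Number of layers, 2 .. ``len(BRAIN_LAYER_TEMPLATES)``.
    """
    if n_tissues < 2:
        raise ValueError("n_tissues must be >= 2")
    if n_tissues > len(BRAIN_LAYER_TEMPLATES):
        raise ValueError(
            f"n_tissues={n_tissues} exceeds the {len(BRAIN_LAYER_TEMPLATES)} "
            "available layer templates"
        )
    shape = tuple(int(n) for n in shape)
    voxel_size = _as_voxel_size(voxel_size)
    tissues = list(BRAIN_LAYER_TEMPLATES[:n_tissues])
    rng = np.random.default_rng(seed)

    # normalized radial coordinate: 1 at the head surface, 0 at center
    half = np.asarray([(n - 1) / 2.0 for n in shape])
    extent = np.asarray([max(n / 2.0, 0.5) for n in shape])
    axes = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    u = [(ax - h) / e for ax, h, e in zip(axes, half, extent)]
    r = np.sqrt(sum(x**2 for x in u))
    # seeded harmonic wobble of the outer boundary (in-plane angle)
    phi = np.arctan2(u[1], u[0])
    amp = rng.uniform(0.01, 0.04, size=3)
    pha = rng.uniform(0, 2 * np.pi, size=3)
    wobble = sum(a * np.cos((k + 2) * phi + p) for k, (a, p) in enumerate(zip(amp, pha)))
    r = r * (1.0 + wobble)

    # band edges from the surface inward; innermost band absorbs the rest
    edges = np.linspace(0.92, 0.0, n_tissues + 1)[:-1]  # outer radius per layer
    soft = 1.0 / min(shape[0], shape[1])  # ~1-voxel fuzzy transition width

    def smooth_inside(rr, edge):
        """1 inside radius `edge`, 0 outside, smooth over `soft`."""
        return np.clip((edge - rr) / (2 * soft) + 0.5, 0.0, 1.0)

    inside_prev = smooth_inside(r, edges[0])  # head mask, fuzzy surface
    fractions = np.zeros((n_tissues,) + shape)
    for t in range(n_tissues):
        if t + 1 < n_tissues:
            inside_next = smooth_inside(r, edges[t + 1])
        else:
            inside_next = np.zeros(shape)
        fractions[t] = inside_prev - inside_next
        inside_prev = inside_next
    np.clip(fractions, 0.0, 1.0, out=fractions)
    return Phantom(shape, voxel_size, tissues, fractions)


# ---------------------------------------------------------------------------
# I/O: one NIfTI fraction volume per tissue + tissue table + metadata
# ---------------------------------------------------------------------------

_TISSUE_COLUMNS = ("name", "rho", "t1_s", "t2_s", "delta_b_T")


def write_phantom(phantom: Phantom, path) -> Path:
    """Write a phantom to directory ``path`` (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    affine = np.diag([v * 1e3 for v in phantom.voxel_size] + [1.0])  # mm for NIfTI
    names = []
    for t, tissue in enumerate(phantom.tissues):
        fname = f"fraction_{t:02d}_{tissue.name}.nii.gz"
        nib.save(nib.Nifti1Image(phantom.fractions[t], affine), path / fname)
        names.append(fname)
    if phantom.db0_map is not None:
        nib.save(nib.Nifti1Image(phantom.db0_map, affine), path / "db0_map.nii.gz")
    with open(path / "tissues.tsv", "w") as fh:
        fh.write("\t".join(_TISSUE_COLUMNS) + "\n")
        for tissue in phantom.tissues:
            fh.write(
                f"{tissue.name}\t{tissue.rho!r}\t{tissue.t1!r}\t"
                f"{tissue.t2!r}\t{tissue.delta_b!r}\n"
            )
    meta = {
        "shape": list(phantom.shape),
        "voxel_size_m": list(phantom.voxel_size),
        "fraction_volumes": names,
        "db0_map": "db0_map.nii.gz" if phantom.db0_map is not None else None,
    }
    (path / "phantom.json").write_text(json.dumps(meta, indent=2))
    return path


def read_phantom(path) -> Phantom:
    """Read a phantom directory written by `write_phantom`."""
    path = Path(path)
    meta_file = path / "phantom.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"no phantom.json under {path}")
    meta = json.loads(meta_file.read_text())
    shape = tuple(meta["shape"])
    voxel_size = tuple(meta["voxel_size_m"])

    tissues = []
    with open(path / "tissues.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TISSUE_COLUMNS:
            raise ValueError(f"unexpected tissue table columns: {header}")
        for line in fh:
            if not line.strip():
                continue
            name, rho, t1, t2, db = line.rstrip("\n").split("\t")
            tissues.append(
                TissueParams(name, float(rho), float(t1), float(t2), float(db))
            )
    volumes = meta["fraction_volumes"]
    if len(volumes) != len(tissues):
        raise ValueError(
            f"format error: {len(volumes)} fraction volumes but "
            f"{len(tissues)} tissue table rows"
        )
    fractions = np.empty((len(tissues),) + shape)
    for t, fname in enumerate(volumes):
        data = np.asarray(nib.load(path / fname).dataobj, dtype=float)
        if data.shape != shape:
            raise ValueError(
                f"format error: {fname} has shape {data.shape}, expected {shape}"
            )
        fractions[t] = data
    db0_map = None
    if meta.get("db0_map"):
        db0_map = np.asarray(nib.load(path / meta["db0_map"]).dataobj, dtype=float)
    return Phantom(shape, voxel_size, tissues, fractions, db0_map)
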