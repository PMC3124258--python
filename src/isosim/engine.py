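"""Simulation engine: drive isochromats through the timeline, sum signals.

The engine spawns one isochromat per (voxel, tissue with nonzero
fraction, sub-voxel position), advances each through the pulse-sequence
events with the `isosim.physics` operators, records the quadrature
signal ``sum(Mx) + i sum(My)`` at every readout sample, assembles
k-space, and reconstructs the image by a centered inverse DFT.

Work distribution
-----------------
Work is split with a manager/worker tree: isochromats are divided evenly
among managers, each manager's share evenly among its workers (contiguous
index ranges, sizes differing by at most one).  The tree is *logical*:
worker chunks are executed one after another in a fixed order, so the
scheme fixes which isochromats travel together and in which order their
signals are combined, not how many OS processes run.

Determinism contract: each worker returns per-isochromat signal rows;
`reduce_signals` concatenates them in manager-major, worker-major,
ascending-index order — recovering the original isochromat order bit
for bit regardless of the partition — and applies one canonical sum
over the isochromat axis.  k-space is therefore bit-identical for any
manager/worker count.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .phantom import Phantom, voxel_center_position
from .physics import (
    GAMMA_HYDROGEN,
    apply_rf_pulse,
    equilibrium_magnetization,
    precess_relax,
)
from .sequence import SequenceEvent, SpinEchoConfig, build_spin_echo

__all__ = [
    "Isochromat",
    "IsochromatSet",
    "KSpace",
    "WorkPartition",
    "ParallelConfig",
    "SimulationResult",
    "spawn_isochromats",
    "acquire_sample",
    "run_events",
    "partition_isochromats",
    "reduce_signals",
    "reconstruct",
    "simulate",
]

logger = logging.getLogger("isosim")


@dataclass(frozen=True)
class Isochromat:
    """Read-only view of one isochromat (see `IsochromatSet`)."""

    position: np.ndarray
    tissue_index: int
    m: np.ndarray
    m0: float
    db_static: float


class IsochromatSet:
    """Struct-of-arrays container for a population of isochromats.

    Attributes
    ----------
    positions : (n, 3) float array, meters.
    tissue_index : (n,) int array — row into the phantom tissue table.
    m : (n, 3) float array — current magnetization, initialized to
        ``(0, 0, m0)``.
    m0 : (n,) equilibrium magnitudes (fraction * rho / n_per_voxel).
    t1, t2 : (n,) relaxation times, seconds.
    db_static : (n,) static field offsets (tissue delta_b + voxel db0
        map), tesla.
    """

    def __init__(self, positions, tissue_index, m0, t1, t2, db_static):
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.tissue_index = np.asarray(tissue_index, dtype=int).reshape(n)
        self.m0 = np.asarray(m0, dtype=float).reshape(n)
        if np.any(self.m0 < 0):
            raise ValueError("m0 must be >= 0")
        self.t1 = np.asarray(t1, dtype=float).reshape(n)
        self.t2 = np.asarray(t2, dtype=float).reshape(n)
        self.db_static = np.asarray(db_static, dtype=float).reshape(n)
        self.m = equilibrium_magnetization(self.m0)

    def __len__(self) -> int:
        return len(self.positions)

    def __getitem__(self, i: int) -> Isochromat:
        return Isochromat(
            position=self.positions[i],
            tissue_index=int(self.tissue_index[i]),
            m=self.m[i],
            m0=float(self.m0[i]),
            db_static=float(self.db_static[i]),
        )

    def view(self, start: int, stop: int) -> "IsochromatChunk":
        return IsochromatChunk(self, start, stop)


class IsochromatChunk:
    """A contiguous worker slice of an `IsochromatSet` (shares state)."""

    def __init__(self, parent: IsochromatSet, start: int, stop: int):
        self.parent = parent
        self.start, self.stop = start, stop
        self.positions = parent.positions[start:stop]
        self.m0 = parent.m0[start:stop]
        self.t1 = parent.t1[start:stop]
        self.t2 = parent.t2[start:stop]
        self.db_static = parent.db_static[start:stop]

    def __len__(self) -> int:
        return self.stop - self.start

    @property
    def m(self) -> np.ndarray:
        return self.parent.m[self.start : self.stop]

    @m.setter
    def m(self, value) -> None:
        self.parent.m[self.start : self.stop] = value


def spawn_isochromats(phantom: Phantom, n_per_voxel: int = 1) -> IsochromatSet:
    """Create the isochromat population of a phantom.

    One isochromat per (voxel, tissue with fraction > 0, sub-position);
    ``n_per_voxel`` sub-positions are laid on a fixed regular sub-grid
    inside each voxel (must be a cube number for 3D sub-grids; 1 places
    a single isochromat at the voxel center).  Each isochromat carries
    ``m0 = fraction * rho / n_per_voxel`` so the total equilibrium
    magnetization per voxel is conserved.

    Intravoxel static dephasing (and hence realistic echo formation
    under field inhomogeneity) only appears for ``n_per_voxel > 1``.
    """
    if n_per_voxel < 1:
        raise ValueError("n_per_voxel must be >= 1")
    if n_per_voxel == 1:
        sub_offsets = np.zeros((1, 3))
    else:
        s = round(n_per_voxel ** (1 / 3))
        if s**3 != n_per_voxel:
            raise ValueError(
                f"n_per_voxel must be a cube number for the regular sub-grid, "
                f"got {n_per_voxel}"
            )
        u = (np.arange(s) + 0.5) / s - 0.5
        sub_offsets = (
            np.stack(np.meshgrid(u, u, u, indexing="ij"), axis=-1).reshape(-1, 3)
        )
    voxel_size = np.asarray(phantom.voxel_size)

    all_pos, all_tissue, all_m0, all_t1, all_t2, all_db = [], [], [], [], [], []
    for t, tissue in enumerate(phantom.tissues):
        idx = np.argwhere(phantom.fractions[t] > 0)
        if len(idx) == 0:
            continue
        frac = phantom.fractions[t][tuple(idx.T)]
        centers = voxel_center_position(phantom, idx)
        db = np.full(len(idx), tissue.delta_b)
        if phantom.db0_map is not None:
            db = db + phantom.db0_map[tuple(idx.T)]
        for off in sub_offsets:
            all_pos.append(centers + off * voxel_size)
            all_tissue.append(np.full(len(idx), t))
            all_m0.append(frac * tissue.rho / n_per_voxel)
            all_t1.append(np.full(len(idx), tissue.t1))
            all_t2.append(np.full(len(idx), tissue.t2))
            all_db.append(db)
    if not all_pos:
        return IsochromatSet(
            np.zeros((0, 3)), np.zeros(0, int), np.zeros(0), np.ones(0), np.ones(0),
            np.zeros(0),
        )
    return IsochromatSet(
        np.concatenate(all_pos),
        np.concatenate(all_tissue),
        np.concatenate(all_m0),
        np.concatenate(all_t1),
        np.concatenate(all_t2),
        np.concatenate(all_db),
    )


def acquire_sample(isochromats) -> complex:
    """Quadrature signal of a subset: ``sum(Mx) + i * sum(My)``."""
    m = isochromats.m if hasattr(isochromats, "m") else np.asarray(isochromats)
    return complex(np.sum(m[..., 0]) + 1j * np.sum(m[..., 1]))


def _local_deviation(chunk, gradients) -> np.ndarray:
    """Field deviation from b0 (tesla) per isochromat for active gradients.

    Written as elementwise ufunc arithmetic (not a BLAS mat-vec): ufunc
    results are identical per element regardless of array length, which
    the bit-identity contract across work partitions relies on.
    """
    gx, gy, gz = (float(g) for g in gradients)
    p = chunk.positions
    return chunk.db_static + (p[:, 0] * gx + p[:, 1] * gy + p[:, 2] * gz)


def run_events(chunk, events: list[SequenceEvent], b0: float,
               gamma: float = GAMMA_HYDROGEN) -> np.ndarray:
    """Advance a chunk of isochromats through a repetition's events.

    Mutates the chunk's magnetization in place and returns the
    per-isochromat signal rows for the repetition's acquire events:
    a complex array of shape ``(len(chunk), n_samples_total)`` whose
    column ``s`` holds ``Mx + i My`` of each isochromat at sample ``s``.
    (Summing a column gives the k-space sample; keeping rows separate is
    what makes the reduction partition-invariant.)

    Events execute in order: ``rf`` applies the pulse rotation using
    each isochromat's local field; ``evolve`` applies the closed-form
    precession/relaxation update over the event duration with the
    event's gradients active; ``acquire`` alternates sample recording
    and one-dwell evolution, sample 0 recorded at the event start.
    """
    n = len(chunk)
    cols = []
    m = chunk.m
    for ev in events:
        if ev.kind == "rf":
            b_i = b0 + _local_deviation(chunk, ev.gradients)
            m = apply_rf_pulse(m, ev.rf, b_i, gamma)
        elif ev.kind == "evolve":
            if ev.duration > 0:
                nu = gamma * _local_deviation(chunk, ev.gradients)
                m = precess_relax(m, nu, ev.duration, chunk.t1, chunk.t2, chunk.m0)
        elif ev.kind == "acquire":
            nu = gamma * _local_deviation(chunk, ev.gradients)
            for _ in range(ev.n_samples):
                cols.append(m[..., 0] + 1j * m[..., 1])
                m = precess_relax(m, nu, ev.dwell, chunk.t1, chunk.t2, chunk.m0)
    chunk.m = m
    if not cols:
        return np.zeros((n, 0), dtype=complex)
    return np.stack(cols, axis=1)


@dataclass(frozen=True)
class WorkPartition:
    """Manager/worker assignment over contiguous isochromat index ranges.

    ``ranges[w] = (start, stop)`` for worker ``w``; workers are numbered
    manager-major (manager 0's workers first).  Ranges are disjoint,
    cover ``0..n``, and within a manager differ in size by at most one.
    """

    n_managers: int
    n_workers: int
    ranges: tuple[tuple[int, int], ...]

    @property
    def workers_per_manager(self) -> int:
        return self.n_workers // self.n_managers

    def manager_of(self, worker: int) -> int:
        return worker // self.workers_per_manager


def _even_split(n: int, k: int) -> list[tuple[int, int]]:
    """Split range(n) into k contiguous spans with sizes differing <= 1."""
    base, extra = divmod(n, k)
    spans, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        spans.append((start, start + size))
        start += size
    return spans


def partition_isochromats(
    n_isochromats: int, n_managers: int, n_workers: int
) -> WorkPartition:
    """Divide isochromats evenly: managers first, then each share by worker.

    ``n_workers`` must be a positive multiple of ``n_managers``. Ranges
    are arbitrary contiguous index spans, independent of phantom
    geometry (no slice-boundary alignment); empty ranges are allowed
    when workers outnumber isochromats.
    """
    if n_managers < 1 or n_workers < 1:
        raise ValueError("need n_managers >= 1 and n_workers >= 1")
    if n_workers % n_managers != 0:
        raise ValueError(
            f"n_workers ({n_workers}) must be divisible by n_managers ({n_managers})"
        )
    per_manager = n_workers // n_managers
    ranges: list[tuple[int, int]] = []
    for mstart, mstop in _even_split(n_isochromats, n_managers):
        for wstart, wstop in _even_split(mstop - mstart, per_manager):
            ranges.append((mstart + wstart, mstart + wstop))
    return WorkPartition(n_managers, n_workers, tuple(ranges))


def reduce_signals(worker_arrays, partition: WorkPartition | None = None) -> np.ndarray:
    """Combine per-worker signal arrays into the total signal.

    ``worker_arrays[w]`` holds worker ``w``'s per-isochromat signal rows
    (shape ``(n_w, ...)``, identical trailing dimensions).  Arrays are
    concatenated in fixed order — ascending worker index within each
    manager, then ascending manager index, i.e. simply ascending worker
    index manager-major — and summed over the leading axis with one
    canonical `numpy.sum`.  Because concatenation restores the original
    ascending isochromat order for every partition, the result is
    bit-identical for any manager/worker count; repeated runs are
    bit-identical by determinism of the whole pipeline.
    """
    arrays = [np.asarray(a) for a in worker_arrays]
    if partition is not None and len(arrays) != partition.n_workers:
        raise ValueError(
            f"got {len(arrays)} worker arrays for {partition.n_workers} workers"
        )
    trailing = {a.shape[1:] for a in arrays if a.size or a.ndim > 1}
    if len(trailing) > 1:
        raise ValueError(f"worker arrays disagree in shape: {sorted(trailing)}")
    return np.concatenate(arrays, axis=0).sum(axis=0)


@dataclass
class KSpace:
    """Acquired k-space.

    ``data`` is complex with the frequency-encode axis last:
    ``(n_phase, n_freq)`` for 2D or ``(n_phase2, n_phase, n_freq)`` for
    3D, in *centered* layout (DC at index ``N // 2`` on every axis,
    k-index grid {-N/2, ..., N/2-1} scaled by ``delta_k = 1/FOV``).
    """

    data: np.ndarray
    delta_k: tuple[float, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("k-space contains non-finite entries")


def reconstruct(kspace: KSpace | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centered inverse DFT of k-space -> (complex image, magnitude image).

    DC sits at matrix center before and after the transform.  A
    half-sample linear phase per axis aligns the reconstruction grid
    with the grid-centered voxel coordinates ``(j - (N-1)/2) * dx`` used
    by the phantom, so an object at voxel ``j`` lands at image index
    ``j`` exactly.  Axes are reordered so the frequency-encode axis
    comes first: the image is indexed ``(x, y[, z])`` like the phantom.
    Normalization: ``sum |kspace|^2 = N_total * sum |image|^2``.
    """
    data = kspace.data if isinstance(kspace, KSpace) else np.asarray(kspace, complex)
    shifted = data.copy()
    for ax, n in enumerate(data.shape):
        m = np.arange(n) - n // 2  # centered k index
        ramp = np.exp(1j * np.pi * m / n)
        shape = [1] * data.ndim
        shape[ax] = n
        shifted *= ramp.reshape(shape)
    img = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(shifted)))
    img = img.transpose(tuple(reversed(range(img.ndim))))  # (freq, phase[, phase2])
    return img, np.abs(img)


@dataclass(frozen=True)
class ParallelConfig:
    """Logical manager/worker layout (affects scheduling order only)."""

    n_managers: int = 1
    n_workers: int = 1


@dataclass
class SimulationResult:
    kspace: KSpace
    image: np.ndarray  # complex, phantom-ordered axes (x, y[, z])
    magnitude: np.ndarray
    info: dict = field(default_factory=dict)


def simulate(
    phantom: Phantom,
    cfg: SpinEchoConfig,
    b0: float = 1.5,
    gamma: float = GAMMA_HYDROGEN,
    parallel: ParallelConfig = ParallelConfig(),
    n_per_voxel: int = 1,
    prep_repetitions: int = 1,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> SimulationResult:
    """Full Bloch simulation: phantom -> k-space -> reconstructed image.

    Composes spawn -> partition -> per-repetition event execution per
    worker -> fixed-order reduction -> centered inverse DFT.
    Magnetization evolves continuously across repetitions;
    ``prep_repetitions`` extra unrecorded repetitions are run first so
    acquisition starts from the TR-periodic steady state (one suffices
    whenever transverse magnetization has decayed by the end of TR).

    Parameters
    ----------
    b0, gamma : float
        Main field (T) and gyromagnetic ratio (rad s^-1 T^-1).
    parallel : ParallelConfig
        Logical manager/worker counts; k-space is bit-identical for any
        choice (see `reduce_signals`).
    n_per_voxel : int
        Isochromats per (voxel, tissue); cube number.
    noise_sigma : float
        Std of seeded complex Gaussian noise added per k-space sample
        (0 = noiseless).
    seed : int or None
        Seed for the noise generator.
    """
    iso = spawn_isochromats(phantom, n_per_voxel)
    part = partition_isochromats(len(iso), parallel.n_managers, parallel.n_workers)
    chunks = [iso.view(a, b) for a, b in part.ranges]
    reps = build_spin_echo(cfg, b0, gamma)

    n_freq = cfg.matrix[0]
    n_phase = cfg.matrix[1]
    n_phase2 = cfg.matrix[2] if len(cfg.matrix) == 3 else None
    lines_shape = (n_phase2, n_phase) if n_phase2 else (n_phase,)
    kdata = np.zeros(lines_shape + (n_freq,), dtype=complex)

    logger.info(
        "simulate: %d isochromats, %d lines x %d samples, %d managers x %d workers",
        len(iso), len(reps), n_freq, part.n_managers, part.n_workers,
    )

    # steady-state preparation: run the DC line's timeline, discard signal
    dc_line = len(reps) // 2
    for _ in range(prep_repetitions):
        for chunk in chunks:
            run_events(chunk, reps[dc_line], b0, gamma)

    for r, events in enumerate(reps):
        t0 = time.perf_counter()
        worker_rows = [run_events(chunk, events, b0, gamma) for chunk in chunks]
        line = reduce_signals(worker_rows, part)
        kdata[np.unravel_index(r, lines_shape)] = line
        logger.debug(
            "repetition %d/%d (%.1f ms)", r + 1, len(reps),
            1e3 * (time.perf_counter() - t0),
        )

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        kdata = kdata + noise_sigma * (
            rng.standard_normal(kdata.shape) + 1j * rng.standard_normal(kdata.shape)
        )

    # data axes are (phase2?, phase, freq); fov is listed (freq, phase[, phase2])
    delta_k = tuple(1.0 / f for f in reversed(cfg.fov))
    kspace = KSpace(kdata, delta_k)
    image, magnitude = reconstruct(kspace)
    info = {
        "n_isochromats": len(iso),
        "n_lines": len(reps),
        "prep_repetitions": prep_repetitions,
        "partition": part.ranges,
    }
    return SimulationResult(kspace, image, magnitude, info)
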