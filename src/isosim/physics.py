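"""Magnetization kinematics for isochromat-summation MR simulation.

An isochromat — a group of spins close enough together to see the same
local field — is represented by a 3-vector ``[Mx, My, Mz]``.  This module
implements the elementary operators that drive it:

* Larmor precession about the main field at ``nu = gamma * B``,
* T2 (spin-spin) transverse decay and T1 (spin-lattice) longitudinal
  recovery toward the equilibrium magnetization ``M0``,
* hard (rectangular) RF excitation, including off-resonance behaviour via
  the effective-field tilt, composed as three rotations
  ``Ry(beta) @ Rx(theta) @ Ry(-beta)``.

All functions are vectorized: ``m`` may be a single vector of shape
``(3,)`` or a stack of shape ``(n, 3)``; per-isochromat parameters
broadcast against the leading axes.

Conventions
-----------
* ``gamma`` is in rad s^-1 T^-1, so ``nu * dt`` and ``gamma * b1 * tau``
  are angles in radians directly.
* The simulation frame rotates at the demodulation frequency
  ``gamma * B0``; precession uses only the deviation field, i.e.
  ``nu = gamma * (B_local - B0)``.
* Positive ``nu`` rotates magnetization clockwise in the xy-plane:
  ``Mx' = cos(a) Mx + sin(a) My``, ``My' = -sin(a) Mx + cos(a) My``.
  The handedness is a bookkeeping choice (unobservable after magnitude
  reconstruction) and every downstream k-space convention is kept
  consistent with it.
* No relaxation is applied during an RF pulse (pulse durations are
  assumed much shorter than T1 and T2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAMMA_HYDROGEN",
    "DEFAULT_B0",
    "FieldContext",
    "RFPulse",
    "equilibrium_magnetization",
    "larmor_frequency",
    "local_field",
    "precess_relax",
    "effective_field_angle",
    "flip_angle",
    "rf_rotation_matrix",
    "apply_rf_pulse",
]

#: Gyromagnetic ratio of hydrogen (1H), rad s^-1 T^-1.
GAMMA_HYDROGEN = 2.67522128e8

#: Default main static field strength, tesla.
DEFAULT_B0 = 1.5


@dataclass(frozen=True)
class FieldContext:
    """Magnetic environment of an isochromat.

    Parameters
    ----------
    b0 : float
        Main static field, tesla. Must be positive.
    gradients : tuple of float
        Linear gradient strengths ``(gx, gy, gz)``, tesla / meter.
    db_local : float or ndarray
        Static field deviation at the isochromat (susceptibility /
        chemical shift / shim error), tesla.
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1. Must be positive.
    """

    b0: float = DEFAULT_B0
    gradients: tuple[float, float, float] = (0.0, 0.0, 0.0)
    db_local: float = 0.0
    gamma: float = GAMMA_HYDROGEN

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError(f"b0 must be positive, got {self.b0}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


@dataclass(frozen=True)
class RFPulse:
    """A hard (rectangular) RF pulse, or a piecewise train of them.

    Parameters
    ----------
    b1 : float
        Pulse field amplitude, tesla (>= 0).
    tau : float
        Duration, seconds (> 0).
    b_target : float
        Local field ``Bt`` the pulse frequency is tuned to, tesla
        (``nu_p = gamma * Bt``). Isochromats whose local field deviates
        from ``Bt`` are excited about a tilted effective field.
    segments : tuple of (b1, tau), optional
        If given, the pulse is a train of rectangular segments applied
        in order (used to represent shaped pulses, e.g. sinc).
    """

    b1: float
    tau: float
    b_target: float
    segments: tuple[tuple[float, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.segments:
            if any(t <= 0 for _, t in self.segments) or any(
                b < 0 for b, _ in self.segments
            ):
                raise ValueError("piecewise segments need b1 >= 0 and tau > 0")
        else:
            if self.tau <= 0:
                raise ValueError(f"pulse duration must be positive, got {self.tau}")
            if self.b1 < 0:
                raise ValueError(f"pulse amplitude must be >= 0, got {self.b1}")

    @classmethod
    def hard(
        cls, flip: float, tau: float, b_target: float, gamma: float = GAMMA_HYDROGEN
    ) -> "RFPulse":
        """Rectangular pulse producing on-resonance flip angle ``flip`` (rad)."""
        return cls(b1=flip / (gamma * tau), tau=tau, b_target=b_target)


def equilibrium_magnetization(m0):
    """Thermal-equilibrium magnetization ``(0, 0, M0)`` for scalar/array ``m0``."""
    m0 = np.asarray(m0, dtype=float)
    out = np.zeros(m0.shape + (3,))
    out[..., 2] = m0
    return out


def larmor_frequency(gamma, b_local):
    """Angular precession frequency ``nu = gamma * B`` (rad/s)."""
    return gamma * np.asarray(b_local, dtype=float)


def local_field(ctx: FieldContext, position) -> np.ndarray:
    """Local field ``b0 + db_local + x*gx + y*gy + z*gz`` at ``position`` (m)."""
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position must be finite")
    gx, gy, gz = (float(g) for g in ctx.gradients)
    grad_term = position[..., 0] * gx + position[..., 1] * gy + position[..., 2] * gz
    return ctx.b0 + np.asarray(ctx.db_local, dtype=float) + grad_term


def precess_relax(m, nu, dt, t1, t2, m0) -> np.ndarray:
    """Advance magnetization by ``dt`` seconds of free evolution.

    Applies the z-rotation by ``nu * dt`` first, then the diagonal
    relaxation operator, then the longitudinal recovery term — exactly
    the operator order of the combined precession/relaxation update

    ``M(t+dt) = E(dt) @ Rz(nu*dt) @ M(t) + [0, 0, M0 (1 - exp(-dt/T1))]``

    with ``E = diag(exp(-dt/T2), exp(-dt/T2), exp(-dt/T1))``.  The update
    is exact for constant ``nu`` over the interval, so a single call can
    span an arbitrarily long event.

    Parameters
    ----------
    m : array_like, shape (..., 3)
        Magnetization at time ``t``.
    nu : float or array_like
        Angular frequency relative to the rotating frame, rad/s.
    dt : float
        Interval, seconds (>= 0; ``inf`` yields the equilibrium limit).
    t1, t2 : float or array_like
        Relaxation time constants, seconds (> 0; ``inf`` disables).
    m0 : float or array_like
        Equilibrium longitudinal magnetization.
    """
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    m = np.asarray(m, dtype=float)
    nu = np.asarray(nu, dtype=float)
    angle = nu * dt
    if np.isinf(dt):
        # equilibrium limit of the recovery/decay exponentials
        angle = np.zeros_like(nu)
    c, s = np.cos(angle), np.sin(angle)
    mx = c * m[..., 0] + s * m[..., 1]
    my = -s * m[..., 0] + c * m[..., 1]
    with np.errstate(over="ignore"):
        e2 = np.exp(-dt / np.asarray(t2, dtype=float))
        e1 = np.exp(-dt / np.asarray(t1, dtype=float))
    out = np.empty(np.broadcast_shapes(m.shape[:-1], np.shape(e1), np.shape(e2)) + (3,))
    out[..., 0] = e2 * mx
    out[..., 1] = e2 * my
    out[..., 2] = e1 * m[..., 2] + np.asarray(m0, dtype=float) * (1.0 - e1)
    return out


def effective_field_angle(b_target, b_i, b1):
    """Tilt ``beta = atan((Bt - Bi) / B1)`` of the effective field from B1 (rad)."""
    b1 = np.asarray(b1, dtype=float)
    if np.any(b1 == 0):
        raise ValueError("b1 = 0: effective-field angle is degenerate")
    return np.arctan((np.asarray(b_target, float) - np.asarray(b_i, float)) / b1)


def flip_angle(gamma, b1, tau, b_target, b_i):
    """Rotation angle about the effective field.

    ``theta = gamma * tau * sqrt((Bt - Bi)^2 + B1^2)``; reduces to the
    on-resonance flip ``gamma * B1 * tau`` when ``Bi == Bt``.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    off = np.asarray(b_target, float) - np.asarray(b_i, float)
    return gamma * tau * np.hypot(off, np.asarray(b1, dtype=float))


def rf_rotation_matrix(beta: float, theta: float) -> np.ndarray:
    """Explicit 3x3 operator ``Ry(beta) @ Rx(theta) @ Ry(-beta)`` for scalars.

    ``Ry(a) = [[cos a, 0, -sin a], [0, 1, 0], [sin a, 0, cos a]]`` and
    ``Rx(t) = [[1, 0, 0], [0, cos t, sin t], [0, -sin t, cos t]]`` (the
    same handedness as the precession rotation).  Mostly useful for
    testing; `apply_rf_pulse` evaluates the composition componentwise.
    """

    def ry(a):
        ca, sa = np.cos(a), np.sin(a)
        return np.array([[ca, 0.0, -sa], [0.0, 1.0, 0.0], [sa, 0.0, ca]])

    ct, st = np.cos(theta), np.sin(theta)
    rx = np.array([[1.0, 0.0, 0.0], [0.0, ct, st], [0.0, -st, ct]])
    return ry(beta) @ rx @ ry(-beta)


def _apply_rect(m, b1, tau, b_target, b_i, gamma):
    """One rectangular segment: tilt into the effective frame, flip, tilt back."""
    off = np.asarray(b_target, float) - np.asarray(b_i, float)
    beta = np.arctan2(off, b1)  # atan((Bt-Bi)/B1), well-defined for b1 > 0
    theta = gamma * tau * np.hypot(off, b1)
    cb, sb = np.cos(beta), np.sin(beta)
    ct, st = np.cos(theta), np.sin(theta)
    x, y, z = m[..., 0], m[..., 1], m[..., 2]
    # Ry(-beta)
    x1 = cb * x + sb * z
    z1 = -sb * x + cb * z
    # Rx(theta)
    y2 = ct * y + st * z1
    z2 = -st * y + ct * z1
    # Ry(beta)
    out = np.empty(np.broadcast_shapes(m.shape[:-1], np.shape(beta)) + (3,))
    out[..., 0] = cb * x1 - sb * z2
    out[..., 1] = y2
    out[..., 2] = sb * x1 + cb * z2
    return out


def apply_rf_pulse(m, pulse: RFPulse, b_i, gamma: float = GAMMA_HYDROGEN) -> np.ndarray:
    """Excite magnetization with an RF pulse.

    For a rectangular pulse the result is the three-rotation composition
    ``Ry(beta) @ Rx(theta) @ Ry(-beta)`` with the effective-field tilt
    ``beta`` and flip ``theta`` evaluated per isochromat from its local
    field ``b_i``.  Piecewise (shaped) pulses apply the rectangular
    operator segment by segment, in order.  Relaxation is not applied:
    the pulse is assumed much shorter than T1 and T2.  Norm-preserving.

    Parameters
    ----------
    m : array_like, shape (..., 3)
        Magnetization immediately before the pulse.
    pulse : RFPulse
    b_i : float or array_like
        Local field at each isochromat during the pulse, tesla.
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1.
    """
    m = np.asarray(m, dtype=float)
    if pulse.segments:
        for b1, tau in pulse.segments:
            m = _apply_rect(m, b1, tau, pulse.b_target, b_i, gamma)
        return m
    return _apply_rect(m, pulse.b1, pulse.tau, pulse.b_target, b_i, gamma)
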