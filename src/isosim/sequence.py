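"""Pulse-sequence event timelines and the standard spin-echo builder.

A pulse sequence is modeled as a list of repetitions, each a list of
`SequenceEvent` items executed in order.  Three event kinds exist:

* ``rf`` — an RF pulse (zero duration on the timeline; the physical
  pulse length ``tau`` lives on the pulse and is assumed much shorter
  than T1/T2),
* ``evolve`` — free precession/relaxation for ``duration`` seconds with
  the event's gradients active,
* ``acquire`` — readout: ``n_samples`` samples separated by ``dwell``
  seconds, gradients active throughout; sample 0 is recorded at the
  start of the event.

Spin-echo encoding
------------------
Each repetition acquires one phase-encode line:

    90x -> [phase encode + read prephase] -> 180x -> echo readout -> rest

The 180° pulse negates accumulated phase, so a *positive* prephaser of
area ``G_read * dwell * n_freq / 2`` lands sample 0 at k-index
``-n_freq/2``; the readout gradient then steps kx by ``1/FOV_x`` per
dwell so sample ``m`` sits at k-index ``m - n_freq/2``.  The
phase-encode gradient of line ``n`` is sized (with the same sign
negation) so the line sits at k-index ``n - n_phase/2``: the symmetric
half-open grid {-N/2, ..., N/2-1} per axis with DC at index N/2, one
line per repetition, increasing line index = increasing ky.  3D
acquisitions add a second phase-encode loop along z in place of slice
selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .physics import GAMMA_HYDROGEN, RFPulse

__all__ = [
    "SequenceEvent",
    "SpinEchoConfig",
    "SequenceTimingError",
    "build_spin_echo",
    "validate_sequence",
    "phase_encode_amplitudes",
    "readout_gradient",
]

_ZERO_G = (0.0, 0.0, 0.0)


class SequenceTimingError(ValueError):
    """Raised when the requested timing cannot be realized."""


@dataclass(frozen=True)
class SequenceEvent:
    """One step of a pulse-sequence timeline."""

    kind: str  # "rf" | "evolve" | "acquire"
    duration: float = 0.0
    gradients: tuple[float, float, float] = _ZERO_G
    rf: RFPulse | None = None
    n_samples: int = 0
    dwell: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("rf", "evolve", "acquire"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration < 0:
            raise ValueError(f"event duration must be >= 0, got {self.duration}")
        if self.kind == "rf" and self.rf is None:
            raise ValueError("rf event needs a pulse")
        if self.kind == "acquire":
            if self.n_samples < 1:
                raise ValueError("acquire needs n_samples >= 1")
            if self.dwell <= 0:
                raise ValueError("acquire needs dwell > 0")


@dataclass(frozen=True)
class SpinEchoConfig:
    """Scan parameters for a standard (90°–180°) spin-echo acquisition.

    Parameters
    ----------
    te : float
        Echo time, seconds; the echo-center sample is recorded at TE.
    tr : float
        Repetition time, seconds (> te).
    matrix : tuple of int
        ``(n_freq, n_phase)`` or ``(n_freq, n_phase, n_phase2)``; each
        dimension >= 2. Frequency encoding runs along x, phase encoding
        along y (and z for 3D).
    fov : tuple of float
        Field of view, meters per encoded axis (scalar broadcasts).
    flip, refocus : float
        Excitation / refocusing flip angles, radians.
    dwell : float
        Readout sample spacing, seconds. Default 20 us (50 kHz
        bandwidth), keeping the readout window much shorter than
        typical T2 so the echo envelope is flat across it.
    rf_duration : float
        Hard-pulse length, seconds. Default 10 us: short enough that
        B1 dominates realistic off-resonance terms and the no-relaxation
        assumption holds for millisecond-scale T2.
    encode_fraction : float
        Fraction of TE/2 used for the simultaneous phase-encode /
        read-prephase interval (default 0.5, i.e. TE/4).
    """

    te: float
    tr: float
    matrix: tuple[int, ...]
    fov: tuple[float, ...] | float
    flip: float = np.pi / 2
    refocus: float = np.pi
    dwell: float = 2.0e-5
    rf_duration: float = 1.0e-5
    encode_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.te < self.tr:
            raise ValueError(f"need 0 < te < tr, got te={self.te}, tr={self.tr}")
        if len(self.matrix) not in (2, 3) or any(n < 2 for n in self.matrix):
            raise ValueError(f"matrix must be 2 or 3 dims, each >= 2: {self.matrix}")
        if self.dwell <= 0 or self.rf_duration <= 0:
            raise ValueError("dwell and rf_duration must be positive")
        if not 0 < self.encode_fraction <= 1:
            raise ValueError("encode_fraction must be in (0, 1]")
        object.__setattr__(self, "matrix", tuple(int(n) for n in self.matrix))
        fov = np.broadcast_to(np.asarray(self.fov, dtype=float), (len(self.matrix),))
        object.__setattr__(self, "fov", tuple(float(f) for f in fov))


def readout_gradient(cfg: SpinEchoConfig, gamma: float = GAMMA_HYDROGEN) -> float:
    """Frequency-encode gradient (T/m) giving dkx = 1/FOV_x per dwell."""
    return 2 * np.pi / (gamma * cfg.dwell * cfg.fov[0])


def phase_encode_amplitudes(
    n_phase: int, fov: float, tau_enc: float, gamma: float = GAMMA_HYDROGEN
) -> np.ndarray:
    """Phase-encode gradient amplitude per line (T/m).

    Line ``n`` must land at ky = (n - n_phase/2) / FOV after the 180°
    pulse negates the encode-interval phase, hence the leading minus.
    """
    k_index = np.arange(n_phase) - n_phase // 2
    return -2 * np.pi * k_index / (gamma * tau_enc * fov)


def build_spin_echo(
    cfg: SpinEchoConfig, b0: float, gamma: float = GAMMA_HYDROGEN
) -> list[list[SequenceEvent]]:
    """Build the event timelines for a spin-echo acquisition.

    Returns one repetition (list of events) per phase-encode line; for a
    3D matrix the repetitions iterate the second phase-encode axis (z)
    in the outer loop, ``n_phase2 * n_phase`` lines in total. Each
    repetition lasts exactly TR.

    Parameters
    ----------
    b0 : float
        Main field, tesla; sets the RF pulse target field (no slice
        selection — pulses are tuned to the isocenter).
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1.
    """
    n_freq = cfg.matrix[0]
    n_phase = cfg.matrix[1]
    n_phase2 = cfg.matrix[2] if len(cfg.matrix) == 3 else 1

    half_te = cfg.te / 2.0
    tau_enc = cfg.encode_fraction * half_te
    t_readout_half = (n_freq // 2) * cfg.dwell
    t_acq = n_freq * cfg.dwell
    # timeline: 90 | encode (tau_enc) | rest to TE/2 | 180 | to echo start |
    #           acquire (t_acq) | rest to TR
    pre_echo = half_te - t_readout_half
    post_acq = cfg.tr - cfg.te - (t_acq - t_readout_half)
    if pre_echo < 0:
        raise SequenceTimingError(
            f"TE={cfg.te} too short for the readout window ({t_acq} s)"
        )
    if tau_enc > half_te:
        raise SequenceTimingError("encode interval exceeds TE/2")
    if post_acq < 0:
        raise SequenceTimingError(f"TR={cfg.tr} too short for TE + readout")

    g_read = readout_gradient(cfg, gamma)
    # prephaser: half the total readout area, applied over tau_enc
    g_pre = g_read * (n_freq // 2) * cfg.dwell / tau_enc
    g_pe = phase_encode_amplitudes(n_phase, cfg.fov[1], tau_enc, gamma)
    if n_phase2 > 1:
        g_pe2 = phase_encode_amplitudes(n_phase2, cfg.fov[2], tau_enc, gamma)
    else:
        g_pe2 = np.zeros(1)

    exc = RFPulse.hard(cfg.flip, cfg.rf_duration, b_target=b0, gamma=gamma)
    ref = RFPulse.hard(cfg.refocus, cfg.rf_duration, b_target=b0, gamma=gamma)

    repetitions: list[list[SequenceEvent]] = []
    for n2 in range(n_phase2):
        for n in range(n_phase):
            events = [
                SequenceEvent("rf", rf=exc),
                SequenceEvent(
                    "evolve",
                    duration=tau_enc,
                    gradients=(g_pre, float(g_pe[n]), float(g_pe2[n2])),
                ),
                SequenceEvent("evolve", duration=half_te - tau_enc),
                SequenceEvent("rf", rf=ref),
                SequenceEvent("evolve", duration=pre_echo),
                SequenceEvent(
                    "acquire",
                    duration=t_acq,
                    gradients=(g_read, 0.0, 0.0),
                    n_samples=n_freq,
                    dwell=cfg.dwell,
                ),
                SequenceEvent("evolve", duration=post_acq),
            ]
            repetitions.append(events)
    return repetitions


def validate_sequence(
    events: list[SequenceEvent], min_t1: float | None = None, min_t2: float | None = None
) -> list[str]:
    """Check timeline invariants; returns a list of diagnostic strings.

    Errors reported: negative durations (unreachable through the
    `SequenceEvent` constructor but checked for externally built
    events), acquire events whose duration differs from
    ``n_samples * dwell``.  Warnings reported: RF pulses violating the
    no-relaxation assumption ``tau < min(T1, T2) / 100`` when tissue
    relaxation times are provided.
    """
    diags: list[str] = []
    for i, ev in enumerate(events):
        if ev.duration < 0:
            diags.append(f"event {i}: negative duration {ev.duration}")
        if ev.kind == "acquire":
            expected = ev.n_samples * ev.dwell
            if abs(ev.duration - expected) > 1e-12:
                diags.append(
                    f"event {i}: acquire duration {ev.duration} != "
                    f"n_samples*dwell = {expected}"
                )
        if ev.kind == "rf" and ev.rf is not None:
            limit = min(x for x in (min_t1, min_t2) if x is not None) if (
                min_t1 is not None or min_t2 is not None
            ) else None
            tau = (
                sum(t for _, t in ev.rf.segments) if ev.rf.segments else ev.rf.tau
            )
            if limit is not None and tau >= limit / 100.0:
                diags.append(
                    f"event {i}: warning: rf duration {tau} not << min(T1,T2)="
                    f"{limit} (threshold {limit / 100.0})"
                )
    return diags
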