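"""Analytic signal-equation simulator.

The classic closed-form contrast model for the standard spin-echo
sequence,

    S = rho * (1 - exp(-TR/T1)) * exp(-TE/T2),

predicts the per-voxel signal directly from tissue properties and the
scan timing.  It ignores spatial encoding entirely (no k-space, no
artifacts) — it is a fast image synthesizer and, within its validity
regime TE << T1, the independent contrast oracle against which the
Bloch engine is validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import Phantom

__all__ = ["ContrastParams", "spin_echo_signal", "analytic_image"]


@dataclass(frozen=True)
class ContrastParams:
    """Spin-echo contrast timing: echo time and repetition time, seconds."""

    te: float
    tr: float

    def __post_init__(self) -> None:
        if not 0 < self.te < self.tr:
            raise ValueError(f"need 0 < te < tr, got te={self.te}, tr={self.tr}")


def spin_echo_signal(rho, t1, t2, te, tr):
    """Spin-echo signal ``rho * (1 - exp(-tr/t1)) * exp(-te/t2)``.

    Strictly increasing in ``tr`` and strictly decreasing in ``te`` for
    positive parameters; accepts scalars or broadcasting arrays.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("t1 and t2 must be positive")
    return (
        np.asarray(rho, dtype=float)
        * (1.0 - np.exp(-np.asarray(tr, float) / t1))
        * np.exp(-np.asarray(te, float) / t2)
    )


def analytic_image(phantom: Phantom, contrast: ContrastParams) -> np.ndarray:
    """Per-voxel signal-equation image of a fuzzy phantom.

    Each voxel mixes its tissues linearly:
    ``sum_t fraction_t * spin_echo_signal(tissue_t)`` — the
    partial-volume rule of isochromat summation, without encoding.
    Returns a float volume of the phantom's shape.
    """
    image = np.zeros(phantom.shape)
    for t, tissue in enumerate(phantom.tissues):
        s = spin_echo_signal(tissue.rho, tissue.t1, tissue.t2, contrast.te, contrast.tr)
        image += phantom.fractions[t] * s
    return image
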