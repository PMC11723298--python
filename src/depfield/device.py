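"""Device geometry, drive settings, and the cubic gap approximation constant.

The separation channel is a parallel-plate microchannel of height ``H`` whose
floor carries interdigitated finger electrodes (alternating powered / grounded)
and whose lid is a planar grounded counter-electrode.  Because the fingers are
long, the field is modelled in the 2-D cross-section.  By mirror symmetry the
computational cell spans one powered half-finger, one gap, and one grounded
half-finger:

* ``L``  — centre-to-centre pitch of adjacent fingers (m),
* ``2w`` — finger width, so ``w`` is the electrode half-width (m),
* ``d = L - 2w`` — inter-finger spacing (m),
* ``H``  — channel height (m).

Dimensionless coordinates: ``x* = x/L`` in [0, 1], ``y* = y/H`` in [0, 1].
The electrode plane is ``y* = 1`` (powered finger centre at ``x* = 0``,
grounded finger centre at ``x* = 1``); the grounded lid is ``y* = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DEFAULT_GAP_CONSTANT",
    "DeviceGeometry",
    "DriveSettings",
    "GapApproximation",
]

#: least-squares optimum of the cubic gap-profile constant for aspect ratios
#: H/L = 5, w/L = 0.25 (reconstructed in :mod:`depfield.calibrate`)
DEFAULT_GAP_CONSTANT = 0.75480


@dataclass(frozen=True)
class DeviceGeometry:
    """Cross-section geometry of one interdigitated-electrode period.

    Parameters
    ----------
    L : float
        Centre-to-centre pitch of adjacent fingers, m.
    H : float
        Channel height, m.
    w : float
        Electrode half-width, m.  Requires ``0 < 2w < L``.
    """

    L: float
    H: float
    w: float

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"L must be > 0, got {self.L}")
        if not self.H > 0:
            raise ValueError(f"H must be > 0, got {self.H}")
        if not 0 < 2.0 * self.w < self.L:
            raise ValueError(
                f"require 0 < 2w < L, got w={self.w}, L={self.L}"
            )

    @classmethod
    def from_width_spacing(cls, width: float, spacing: float, H: float
                           ) -> "DeviceGeometry":
        """Build from finger width ``2w`` and spacing ``d`` (all metres)."""
        return cls(L=width + spacing, H=H, w=0.5 * width)

    @property
    def d(self) -> float:
        """Electrode spacing ``d = L - 2w`` (m)."""
        return self.L - 2.0 * self.w

    @property
    def rho(self) -> float:
        """Dimensionless electrode half-width ``w/L`` in (0, 1/2)."""
        return self.w / self.L

    @property
    def aspect(self) -> float:
        """Channel aspect ratio ``H/L``."""
        return self.H / self.L

    @property
    def half_gap(self) -> float:
        """Dimensionless half gap width ``1/2 - w/L``."""
        return 0.5 - self.rho


@dataclass(frozen=True)
class DriveSettings:
    """AC drive: RMS amplitude (V) and field frequency (Hz).

    The electrostatic model is formulated in RMS quantities; the frequency
    enters only through the Clausius–Mossotti factor.
    """

    V_rms: float
    f: float = 8.5e6

    def __post_init__(self) -> None:
        if not self.V_rms > 0:
            raise ValueError(f"V_rms must be > 0, got {self.V_rms}")
        if not self.f > 0:
            raise ValueError(f"f must be > 0, got {self.f}")

    @classmethod
    def from_vpp(cls, V_pp: float, f: float = 8.5e6) -> "DriveSettings":
        """From a sinusoidal peak-to-peak amplitude: ``V_rms = V_pp/(2*sqrt(2))``."""
        return cls(V_rms=V_pp / (2.0 * math.sqrt(2.0)), f=f)


@dataclass(frozen=True)
class GapApproximation:
    """Cubic Dirichlet profile imposed on the inter-electrode gap.

    With ``t = (x* - 1/2)/(1/2 - w/L)`` the profile is::

        phi = (V_rms/pi) * [pi/2 - C*t - (pi/2 - C) * t**3 / s]

    where ``s = 6`` for the published form (``edge_continuous=False``, the
    default) and ``s = 1`` for the edge-continuous variant.  The published
    form carries a jump discontinuity against the electrode potentials at
    the gap edges (value ``(V/pi)(pi/2 + C + (pi/2-C)/6) ~ 0.78 V_rms``
    instead of ``V_rms``); the ``s = 1`` variant equals the electrode
    potentials exactly at both edges for *every* ``C`` and is the family
    under which the canonical constant ``C = 0.75480`` arises as the
    least-squares fit to the ideal conformal gap solution (see
    :mod:`depfield.calibrate` and docs/methods.md).

    ``C`` must lie in ``(0, pi/2)``: outside this interval the cubic-term
    coefficient ``(pi/2 - C)`` changes sign meaninglessly.
    """

    C: float = DEFAULT_GAP_CONSTANT
    edge_continuous: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.C < math.pi / 2:
            raise ValueError(f"C must lie in (0, pi/2), got {self.C}")

    @property
    def cubic_scale(self) -> float:
        """Denominator of the cubic term: 6 (published) or 1 (continuous)."""
        return 1.0 if self.edge_continuous else 6.0
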