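"""Clausius–Mossotti factor and DEP force prefactor for single-shell cells.

A polarizable sphere of complex permittivity ``eps_c*`` suspended in a medium
of complex permittivity ``eps_l*`` acquires an induced dipole in an AC field.
The time-averaged dielectrophoretic (DEP) force on a cell of diameter ``d_c``
is

    F_DEP = 2*pi*eps_l*(d_c/2)**3 * Re(beta) * grad|E|**2

where ``beta = (eps_c* - eps_l*)/(eps_c* + 2*eps_l*)`` is the Clausius–
Mossotti (CM) factor.  ``Re(beta) > 0`` means positive DEP (attraction to
high-field regions); the physical range is ``-0.5 <= Re(beta) <= 1``.

Complex permittivities follow the physics sign convention used throughout
this package::

    eps* = eps + sigma/(j*omega)  =  eps - j*sigma/omega

(many engineering texts use the conjugate convention; spectra computed here
are the complex conjugates of those).

Live mammalian cells are modelled as a conducting interior (effective
permittivity ``epsilon_c_eff``, conductivity ``sigma_c_eff``) wrapped in a
thin insulating membrane of capacitance per unit area ``c_m``.  Combining the
membrane capacitance in series with the interior gives the effective particle
permittivity

    eps_p* = (a*c_m*eps_c*) / (a*c_m + eps_c*),    a = d_c/2,

and substituting into the two-phase CM factor yields a rational function of
``j*omega`` expressible in four time constants:

    tau_c* = c_m*d_c/(2*sigma_c_eff)   membrane charging via the interior
    tau_c  = eps_c_eff/sigma_c_eff     interior charge relaxation
    tau_l* = c_m*d_c/(2*sigma_l)       membrane charging via the medium
    tau_l  = eps_l/sigma_l             medium charge relaxation

That time-constant form (``form="shell"``, the default of
:func:`cm_single_shell`) satisfies the DC limit ``beta -> -1/2`` of a
membrane-insulated particle.  A variant of the same expression circulates in
the literature with typographically corrupted denominator signs whose DC
limit is ``+1/2`` and which can leave the physical band entirely; it is kept
available as ``form="as-printed"`` purely for comparison and is never used by
the rest of the package.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "VACUUM_PERMITTIVITY",
    "MediumProperties",
    "CellDielectricModel",
    "CMSpectrum",
    "complex_permittivity",
    "cm_two_phase",
    "shell_effective_permittivity",
    "cm_single_shell",
    "re_beta_spectrum",
    "peak_frequency",
    "dep_prefactor",
]

#: vacuum permittivity, F/m (CODATA 2018)
VACUUM_PERMITTIVITY = 8.8541878128e-12


@dataclass(frozen=True)
class MediumProperties:
    """Suspension-medium dielectric properties.

    Parameters
    ----------
    epsilon_l : float
        Absolute electric permittivity of the solution, F/m.
    sigma_l : float
        Electric conductivity of the solution, S/m.
    """

    epsilon_l: float
    sigma_l: float

    def __post_init__(self) -> None:
        if not self.epsilon_l > 0:
            raise ValueError(f"epsilon_l must be > 0, got {self.epsilon_l}")
        if self.sigma_l < 0:
            raise ValueError(f"sigma_l must be >= 0, got {self.sigma_l}")

    @property
    def tau_l(self) -> float:
        """Charge-relaxation time of the medium, ``eps_l/sigma_l`` (s)."""
        if self.sigma_l == 0:
            raise ZeroDivisionError("tau_l undefined for a non-conducting medium")
        return self.epsilon_l / self.sigma_l


@dataclass(frozen=True)
class CellDielectricModel:
    """Single-shell cell: conducting interior plus thin capacitive membrane.

    Parameters
    ----------
    d_c : float
        Spherical cell diameter, m.
    c_m : float
        Membrane capacitance per unit area, F/m^2.
    epsilon_c_eff : float
        Effective absolute permittivity of the cell interior, F/m.
    sigma_c_eff : float
        Effective conductivity of the cell interior, S/m.
    """

    d_c: float
    c_m: float
    epsilon_c_eff: float
    sigma_c_eff: float

    def __post_init__(self) -> None:
        for name in ("d_c", "c_m", "epsilon_c_eff", "sigma_c_eff"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def tau_c(self) -> float:
        """Interior charge-relaxation time, s."""
        return self.epsilon_c_eff / self.sigma_c_eff

    @property
    def tau_c_star(self) -> float:
        """Membrane charging time through the interior, ``c_m*d_c/(2*sigma_c)`` (s)."""
        return self.c_m * self.d_c / (2.0 * self.sigma_c_eff)

    def tau_l_star(self, medium: MediumProperties) -> float:
        """Membrane charging time through the medium, ``c_m*d_c/(2*sigma_l)`` (s)."""
        if medium.sigma_l == 0:
            raise ZeroDivisionError("tau_l_star undefined for a non-conducting medium")
        return self.c_m * self.d_c / (2.0 * medium.sigma_l)


@dataclass(frozen=True)
class CMSpectrum:
    """CM factor sampled on a frequency grid.

    Attributes
    ----------
    frequencies : ndarray
        Strictly increasing field frequencies, Hz.
    beta : ndarray
        Complex CM factor at each frequency.
    """

    frequencies: np.ndarray
    beta: np.ndarray
    re_beta: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        b = np.asarray(self.beta, dtype=complex)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequencies must be a nonempty 1-D array")
        if f.shape != b.shape:
            raise ValueError("frequencies and beta must have matching shapes")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "re_beta", b.real.copy())


def complex_permittivity(epsilon, sigma, omega):
    """Complex permittivity ``eps* = eps + sigma/(j*omega)``.

    Parameters
    ----------
    epsilon : float or ndarray
        Real permittivity, F/m.
    sigma : float or ndarray
        Conductivity, S/m.
    omega : float or ndarray
        Angular frequency, rad/s; must be positive.

    Returns
    -------
    complex or ndarray
        ``eps - j*sigma/omega``.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    out = np.asarray(epsilon, dtype=float) - 1j * np.asarray(sigma, dtype=float) / omega
    return out if out.ndim else complex(out)


def cm_two_phase(eps_c_star, eps_l_star):
    """Generic two-phase CM factor ``(eps_c* - eps_l*)/(eps_c* + 2*eps_l*)``."""
    eps_c_star = np.asarray(eps_c_star, dtype=complex)
    eps_l_star = np.asarray(eps_l_star, dtype=complex)
    den = eps_c_star + 2.0 * eps_l_star
    if np.any(den == 0):
        raise ZeroDivisionError("CM factor singular: eps_c* + 2*eps_l* vanishes")
    out = (eps_c_star - eps_l_star) / den
    return out if out.ndim else complex(out)


def shell_effective_permittivity(cell: CellDielectricModel, omega):
    """Effective complex permittivity of the shelled sphere.

    Series combination of the membrane sheet capacitance ``c_m`` (per area,
    conductance neglected) with the interior complex permittivity, for a
    membrane much thinner than the cell radius ``a = d_c/2``::

        eps_p* = a*c_m * eps_c* / (a*c_m + eps_c*)
    """
    a_cm = 0.5 * cell.d_c * cell.c_m
    eps_c = complex_permittivity(cell.epsilon_c_eff, cell.sigma_c_eff, omega)
    return a_cm * eps_c / (a_cm + eps_c)


def _cm_time_constant_form(cell, medium, omega, printed: bool):
    tl = medium.tau_l
    tc = cell.tau_c
    tcs = cell.tau_c_star
    tls = cell.tau_l_star(medium)
    w2 = omega * omega
    jw = 1j * omega
    if printed:
        num = w2 * (tl * tcs - tc * tls) + jw * (tls - tl - tcs) - 1.0
        den = w2 * (2.0 * tl * tcs - tc * tls) - jw * (tls - 2.0 * tl - tcs) - 2.0
    else:
        num = w2 * (tl * tcs + tl * tc - tls * tc) + jw * (tls - tl - tcs - tc) - 1.0
        den = (
            -w2 * (2.0 * tl * tcs + tls * tc + 2.0 * tl * tc)
            + jw * (tls + 2.0 * tl + 2.0 * tcs + 2.0 * tc)
            + 2.0
        )
    return num / den


def cm_single_shell(cell: CellDielectricModel, medium: MediumProperties, f,
                    form: str = "shell"):
    """CM factor of a single-shell cell at field frequency ``f`` (Hz).

    Parameters
    ----------
    cell, medium :
        Dielectric models of the cell and the suspending solution.
    f : float or ndarray
        Field frequency, Hz; must be positive.
    form : {"shell", "as-printed"}
        ``"shell"`` (default) evaluates the time-constant form derived from
        the thin-membrane series combination; it agrees with
        :func:`cm_two_phase` applied to :func:`shell_effective_permittivity`
        to machine precision and satisfies ``-0.5 <= Re(beta) <= 1``.
        ``"as-printed"`` evaluates the typographically corrupted variant
        found in print (DC limit +1/2, can exit the physical band); retained
        only for documentation of the discrepancy.

    Returns
    -------
    complex or ndarray
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("f must be positive")
    if medium.sigma_l <= 0:
        raise ValueError("sigma_l must be positive for the single-shell form")
    if form not in ("shell", "as-printed"):
        raise ValueError(f"unknown form {form!r}")
    out = _cm_time_constant_form(cell, medium, 2.0 * np.pi * f,
                                 printed=(form == "as-printed"))
    return out if out.ndim else complex(out)


def re_beta_spectrum(cell: CellDielectricModel, medium: MediumProperties,
                     f_grid) -> CMSpectrum:
    """Evaluate the CM spectrum pointwise on a strictly increasing grid."""
    f_grid = np.atleast_1d(np.asarray(f_grid, dtype=float))
    if f_grid.size == 0:
        raise ValueError("f_grid must be nonempty")
    if np.any(f_grid <= 0) or not np.all(np.diff(f_grid) > 0):
        raise ValueError("f_grid must be positive and strictly increasing")
    beta = cm_single_shell(cell, medium, f_grid)
    return CMSpectrum(frequencies=f_grid, beta=np.atleast_1d(beta))


def peak_frequency(cell: CellDielectricModel, medium: MediumProperties,
                   f_range=(1e3, 1e9), rtol: float = 1e-4) -> float:
    """Frequency in ``[f_lo, f_hi]`` maximizing ``Re(beta)``.

    A 200-point log-spaced scan brackets the maximum, then bounded Brent
    search on log10(f) refines it.  Ties (flat spectra) resolve to the lowest
    frequency.
    """
    f_lo, f_hi = float(f_range[0]), float(f_range[1])
    if not (0 < f_lo < f_hi):
        raise ValueError(f"invalid frequency range {f_range}")
    grid = np.logspace(np.log10(f_lo), np.log10(f_hi), 200)
    vals = cm_single_shell(cell, medium, grid).real
    if np.ptp(vals) < 1e-13:  # flat: tie-break toward the lowest frequency
        return f_lo
    i = int(np.argmax(vals))
    lo = np.log10(grid[max(i - 1, 0)])
    hi = np.log10(grid[min(i + 1, grid.size - 1)])

    def neg(logf):
        return -cm_single_shell(cell, medium, 10.0 ** logf).real

    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": rtol / 10.0})
    return float(10.0 ** res.x)


def dep_prefactor(medium: MediumProperties, d_c: float, re_beta: float) -> float:
    """Scalar DEP prefactor ``2*pi*eps_l*(d_c/2)**3*Re(beta)`` (F*m).

    Multiplying by ``grad|E|**2`` (V^2/m^3) gives the DEP force in newtons.
    """
    if not d_c > 0:
        raise ValueError(f"d_c must be > 0, got {d_c}")
    return 2.0 * np.pi * medium.epsilon_l * (0.5 * d_c) ** 3 * re_beta
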