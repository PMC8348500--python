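"""Giaever–Keese cell-covered electrode impedance model.

Forward evaluation and nonlinear least-squares inversion of the specific
impedance of a confluent cell layer on a gold film microelectrode.  The model
resolves the measured impedance into three barrier parameters:

``Rb``
    paracellular (cell–cell junction) resistance, Ω·cm²;
``alpha``
    cell–substrate constraint parameter, Ω·cm^½, encoding cell radius,
    solution resistivity and the cell–substrate gap;
``Cm``
    specific membrane capacitance, µF/cm², assumed identical for the apical
    and basal membranes (so the transcellular path is two equal capacitors
    in series).

All impedances in this module are *specific* impedances in Ω·cm²; conversion
to whole-well ohms divides by the electrode area (see
:class:`ElectrodeModel.electrode_area`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "ComplexSpectrum",
    "BarrierParameters",
    "ElectrodeModel",
    "FitResult",
    "membrane_impedance",
    "naked_impedance",
    "covered_impedance",
    "fit_electrode_model",
    "fit_barrier_parameters",
    "series_resistance",
    "series_capacitance",
]

# threshold below which a fitted Rb is reported as exactly zero and the
# companion parameters are flagged not-calculable
RB_ZERO_THRESHOLD = 1e-3  # Ω·cm²

# |s| beyond which the Bessel ratio I0/I1 switches to its asymptotic form
_BESSEL_ASYMPTOTIC_CUTOFF = 30.0


@dataclass(frozen=True)
class ComplexSpectrum:
    """Complex specific impedance sampled on a frequency grid at one time.

    Parameters
    ----------
    frequencies : array of float
        AC frequencies in Hz, strictly increasing, all positive.
    impedance : array of complex
        Specific impedance in Ω·cm² per frequency; real part is the
        resistance component, imaginary part the reactance component.
    time : float
        Hours relative to treatment (negative during spreading).
    well_id : str
        Opaque well label.
    """

    frequencies: np.ndarray
    impedance: np.ndarray
    time: float = 0.0
    well_id: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.impedance, dtype=complex)
        if f.ndim != 1 or z.shape != f.shape:
            raise ValueError("frequencies and impedance must be 1-D and equal length")
        if f.size == 0 or np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing and > 0")
        if np.any(z.real <= 0):
            raise ValueError("impedance real part must be > 0 (passive system)")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "impedance", z)

    def __len__(self) -> int:
        return int(self.frequencies.size)


@dataclass(frozen=True)
class BarrierParameters:
    """The (Rb, alpha, Cm) triple with calculability flags.

    When ``Rb`` is zero the inversion cannot attribute impedance between the
    cell–substrate and transcellular paths, so ``alpha`` and ``Cm`` are
    flagged not-calculable (``alpha_valid``/``Cm_valid`` false).
    """

    Rb: float  # Ω·cm²
    alpha: float  # Ω·cm^(1/2)
    Cm: float  # µF/cm²
    alpha_valid: bool = True
    Cm_valid: bool = True

    def __post_init__(self) -> None:
        if self.Rb < 0:
            raise ValueError("Rb must be >= 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.Cm_valid and self.Cm <= 0:
            raise ValueError("Cm must be > 0 when Cm_valid")
        if self.Rb == 0 and (self.alpha_valid or self.Cm_valid):
            raise ValueError("alpha/Cm are not calculable when Rb == 0")


@dataclass(frozen=True)
class ElectrodeModel:
    """Cell-free (naked) electrode equivalent circuit.

    A constant-phase element (CPE) in series with a solution/spreading
    resistance, the standard description of a gold film electrode double
    layer: ``Zn = R_solution + 1 / (Q_cpe * (i 2 pi f)**n_cpe)``.

    ``electrode_area`` (cm²) converts between specific impedance (Ω·cm²) and
    measured whole-well impedance (Ω); it has no default because it is a
    property of the electrode array in use.
    """

    R_solution: float  # Ω·cm²
    Q_cpe: float  # Ω⁻¹·cm⁻²·s^n
    n_cpe: float  # dimensionless, in (0, 1]
    electrode_area: float  # cm²

    def __post_init__(self) -> None:
        if self.R_solution <= 0 or self.Q_cpe <= 0 or self.electrode_area <= 0:
            raise ValueError("R_solution, Q_cpe and electrode_area must be > 0")
        if not 0 < self.n_cpe <= 1:
            raise ValueError("n_cpe must be in (0, 1]")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one barrier-parameter inversion."""

    params: BarrierParameters
    residual: float  # weighted sum of squares, dimensionless
    converged: bool
    n_iterations: int = 0
    raw_params: tuple = field(default=None, repr=False)  # pre-masking optimum

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValueError("residual must be >= 0")
        if self.converged and not math.isfinite(self.residual):
            raise ValueError("a converged fit must report a finite residual")


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def membrane_impedance(f, Cm):
    """Specific impedance of the transcellular path, Ω·cm².

    Two identical purely capacitive membranes (apical and basal) in series:
    ``Zm = 2 / (i 2 pi f Cm)``.

    Parameters
    ----------
    f : float or array
        Frequency in Hz, > 0.
    Cm : float
        Membrane capacitance in µF/cm², > 0.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("f must be > 0")
    if Cm <= 0:
        raise ValueError("Cm must be > 0")
    omega = 2.0 * np.pi * f
    zm = 2.0 / (1j * omega * Cm * 1e-6)
    return complex(zm) if np.ndim(zm) == 0 else zm


def naked_impedance(f, electrode: ElectrodeModel):
    """Specific impedance of the cell-free electrode, Ω·cm² (CPE + series R)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("f must be > 0")
    omega = 2.0 * np.pi * f
    zn = electrode.R_solution + 1.0 / (electrode.Q_cpe * (1j * omega) ** electrode.n_cpe)
    return complex(zn) if np.ndim(zn) == 0 else zn


def _bessel_ratio(s):
    """I0(s)/I1(s) for complex s, stable for large |s|.

    For |s| above the cutoff the asymptotic expansion I0/I1 -> 1 + 1/(2s)
    avoids overflow of the individual Bessel functions.
    """
    s = np.asarray(s, dtype=complex)
    out = np.empty_like(s)
    big = np.abs(s) > _BESSEL_ASYMPTOTIC_CUTOFF
    small = ~big
    if np.any(small):
        ss = s[small]
        i1 = special.iv(1, ss)
        out[small] = special.iv(0, ss) / i1
    if np.any(big):
        out[big] = 1.0 + 0.5 / s[big]
    return out


def covered_impedance(f, params: BarrierParameters | tuple, electrode: ElectrodeModel):
    """Specific impedance of the cell-covered electrode, Ω·cm².

    Evaluates the Giaever–Keese relation combining the current path under
    the cells (constrained by ``alpha``), through the paracellular junctions
    (``Rb``) and across the two cell membranes (``Cm``):

        1/Zc = (1/Zn) * [ Zn/(Zn+Zm)
                          + (Zm/(Zn+Zm)) / ( (s/2)*(I0(s)/I1(s))
                                             + Rb*(1/Zn + 1/Zm) ) ]

    with ``s = alpha * sqrt(1/Zn + 1/Zm)`` (principal branch) and I0, I1 the
    modified Bessel functions of the first kind.  At ``s = 0`` the term
    ``(s/2)*(I0/I1)`` takes its limit value 1.
    """
    if isinstance(params, BarrierParameters):
        rb, alpha, cm = params.Rb, params.alpha, params.Cm
    else:
        rb, alpha, cm = params
    if rb < 0 or alpha < 0 or cm <= 0:
        raise ValueError("require Rb >= 0, alpha >= 0, Cm > 0")
    f = np.asarray(f, dtype=float)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    zn = np.atleast_1d(naked_impedance(f, electrode))
    zm = np.atleast_1d(membrane_impedance(f, cm))
    ysum = 1.0 / zn + 1.0 / zm
    s = alpha * np.sqrt(ysum)
    # (s/2) * I0(s)/I1(s), with the s -> 0 limit equal to 1
    shalf = np.where(np.abs(s) < 1e-9, 1.0, 0.5 * s * _bessel_ratio(np.where(np.abs(s) < 1e-9, 1.0, s)))
    denom = shalf + rb * ysum
    yc = (1.0 / zn) * (zn / (zn + zm) + (zm / (zn + zm)) / denom)
    zc = 1.0 / yc
    return complex(zc[0]) if scalar else zc


# ---------------------------------------------------------------------------
# series (RC) readouts
# ---------------------------------------------------------------------------


def series_resistance(Z):
    """Series-RC resistance of a measured impedance: ``R = Re(Z)``, Ω."""
    return np.real(Z)


def series_capacitance(Z, f):
    """Series-RC capacitance of a measured impedance, in nF.

    ``C = -1 / (2 pi f Im(Z))``; defined only for capacitive impedance
    (``Im(Z) < 0``), otherwise NaN is returned as the undefined flag.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("f must be > 0")
    im = np.imag(np.asarray(Z, dtype=complex))
    with np.errstate(divide="ignore"):
        c = np.where(im < 0, -1.0 / (2.0 * np.pi * f * im), np.nan)
    c_nf = c * 1e9
    return float(c_nf) if c_nf.ndim == 0 else c_nf


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------


def fit_electrode_model(
    spectrum: ComplexSpectrum, electrode_area: float = 1.0
) -> ElectrodeModel:
    """Fit the naked-electrode circuit (R_solution, Q_cpe, n_cpe) to a
    cell-free spectrum by relative-weighted least squares.

    Raises ``ValueError`` for fewer than 3 frequencies (3 free parameters).
    """
    if len(spectrum) < 3:
        raise ValueError("need at least 3 frequencies to fit the electrode model")
    f = spectrum.frequencies
    z = spectrum.impedance
    w = 1.0 / np.abs(z)

    def resid(theta):
        r_sol, log_q, n = theta
        el = ElectrodeModel(max(r_sol, 1e-12), math.exp(log_q), min(max(n, 1e-6), 1.0), electrode_area)
        zm = naked_impedance(f, el)
        d = (zm - z) * w
        return np.concatenate([d.real, d.imag])

    # crude initial guess: R from the high-f real part, Q from low-f reactance
    r0 = max(float(z.real[-1]) * 0.9, 1e-3)
    q0 = 1.0 / (2.0 * np.pi * f[0] * max(-float(z.imag[0]), 1e-9))
    sol = optimize.least_squares(
        resid,
        x0=[r0, math.log(q0), 0.9],
        bounds=([1e-12, -60.0, 1e-6], [np.inf, 60.0, 1.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    r_sol, log_q, n = sol.x
    return ElectrodeModel(float(r_sol), float(math.exp(log_q)), float(min(n, 1.0)), electrode_area)


_DEFAULT_START = (5.0, 5.0, 2.0)
# 3x3x3 log-spaced multi-start grid
_START_GRID = [
    (rb, a, cm)
    for rb in (0.5, 4.0, 32.0)
    for a in (1.0, 6.0, 36.0)
    for cm in (0.5, 2.0, 8.0)
]


def fit_barrier_parameters(
    spectrum: ComplexSpectrum,
    electrode: ElectrodeModel,
    init: BarrierParameters | tuple | None = None,
    rb_zero_threshold: float = RB_ZERO_THRESHOLD,
    good_enough: float = 1e-16,
) -> FitResult:
    """Invert one spectrum into (Rb, alpha, Cm).

    Minimises the relative-weighted residual
    ``sum_f |Zc(model) - Z(meas)|^2 / |Z(meas)|^2`` over Rb >= 0, alpha >= 0,
    Cm > 0.  Starts from ``init`` when given (warm start from the previous
    time point), then from a default point and a 3x3x3 log-spaced grid,
    stopping early once the residual falls below ``good_enough``.

    A fitted Rb below ``rb_zero_threshold`` is reported as exactly 0 with
    ``alpha_valid = Cm_valid = False`` — the inversion cannot attribute the
    remaining impedance when the paracellular path is fully open.

    Never raises on non-convergence; returns ``converged=False`` instead.
    """
    if len(spectrum) < 3:
        raise ValueError("need at least 3 frequencies to fit barrier parameters")
    f = spectrum.frequencies
    z = spectrum.impedance
    w = 1.0 / np.abs(z)

    def resid(theta):
        rb, alpha, cm = theta
        zc = covered_impedance(f, (rb, alpha, max(cm, 1e-9)), electrode)
        d = (zc - z) * w
        return np.concatenate([d.real, d.imag])

    starts: list[tuple[float, float, float]] = []
    if init is not None:
        if isinstance(init, BarrierParameters):
            starts.append((init.Rb, init.alpha, max(init.Cm, 1e-3)))
        else:
            starts.append(tuple(init))
    starts.append(_DEFAULT_START)
    starts.extend(_START_GRID)

    best = None
    total_nfev = 0
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                resid,
                x0=np.maximum(x0, [0.0, 0.0, 1e-6]),
                bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        total_nfev += sol.nfev
        cost = 2.0 * sol.cost  # least_squares cost is 0.5 * sum sq
        if best is None or cost < best[0]:
            best = (cost, sol)
        if cost < good_enough:
            break

    if best is None:
        params = BarrierParameters(0.0, 0.0, 1.0, alpha_valid=False, Cm_valid=False)
        return FitResult(params, float("inf"), converged=False, n_iterations=total_nfev)

    cost, sol = best
    rb, alpha, cm = (float(v) for v in sol.x)
    raw = (rb, alpha, cm)
    if rb < rb_zero_threshold:
        params = BarrierParameters(0.0, alpha, cm, alpha_valid=False, Cm_valid=False)
    else:
        params = BarrierParameters(rb, alpha, cm)
    return FitResult(params, float(cost), converged=bool(sol.success), n_iterations=total_nfev, raw_params=raw)
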