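"""Landauer thermal transport through the phonon junction.

Heat flow between reservoirs at temperatures theta_0 and theta_{N+1}:

    J = int_0^inf (hbar w / 2 pi) tr(T)(w) [N_0(w) - N_{N+1}(w)] dw

with Bose-Einstein occupations N_j(w) = 1/(exp(hbar w / kB theta_j) - 1),
and conductance sigma = J / (theta_0 - theta_{N+1}).  In the classical limit
hbar w << kB theta the occupation difference becomes (kB/ hbar w) Dtheta and
with ballistic transmission (unity over the acoustic and optical bands) the
integral collapses to sigma = kB (w_r - w_q + w_p) / 2 pi, which is
kB w_r / 2 pi when the narrow optical band is neglected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .constants import PhysicalConstants
from .errors import (
    EqualTemperatureError,
    QuadratureError,
    TemperatureRangeError,
    ZeroFrequencyError,
)
from .negf import DeviceModel, transmission
from .lattice import band_structure

#: integration extends to omega_p * (1 + OMEGA_MARGIN); tr(T) vanishes above
OMEGA_MARGIN = 0.05


@dataclass(frozen=True)
class ThermalPair:
    """Left and right reservoir temperatures (K), both positive."""

    theta_left: float
    theta_right: float

    def __post_init__(self) -> None:
        if self.theta_left <= 0 or self.theta_right <= 0:
            raise TemperatureRangeError("reservoir temperatures must be positive")

    @property
    def delta(self) -> float:
        return self.theta_left - self.theta_right

    @property
    def mean(self) -> float:
        return 0.5 * (self.theta_left + self.theta_right)


@dataclass(frozen=True)
class ConductanceResult:
    """Heat flow J (W) and conductance sigma (W/K) for one temperature pair."""

    J: float
    sigma: float
    pair: ThermalPair
    quadrature_points: int
    quadrature_error: float  # estimated absolute error on J (W)


def bose_einstein(
    omega: float, theta: float, constants: PhysicalConstants | None = None
) -> float:
    """Equilibrium phonon occupation 1/(exp(hbar w / kB theta) - 1).

    Switches to the Laurent series 1/x - 1/2 + x/12 below x = 1e-6 for
    numerical stability; omega = 0 raises :class:`ZeroFrequencyError`
    because the occupation diverges (heat-flow integrands take the omega -> 0
    limit analytically instead).
    """
    if theta <= 0:
        raise TemperatureRangeError("theta must be positive")
    if omega == 0:
        raise ZeroFrequencyError("occupation diverges at omega = 0")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    constants = constants or PhysicalConstants.paper()
    x = constants.hbar * omega / (constants.kB * theta)
    if x < 1e-6:
        return 1.0 / x - 0.5 + x / 12.0
    if x > 700.0:
        return math.exp(-x)
    return 1.0 / math.expm1(x)


def _occupation_difference(
    omega: float, pair: ThermalPair, constants: PhysicalConstants
) -> float:
    return bose_einstein(omega, pair.theta_left, constants) - bose_einstein(
        omega, pair.theta_right, constants
    )


def _panel_edges(device: DeviceModel, pair: ThermalPair,
                 constants: PhysicalConstants) -> list[float]:
    bands = band_structure(device.left)
    omega_top = bands.omega_p * (1.0 + OMEGA_MARGIN)
    edges = {0.0, bands.omega_r, bands.omega_q, bands.omega_p, omega_top}
    # resolve the thermal tail: at low temperature only omega up to a few
    # kB theta / hbar contributes, far below the acoustic band top
    w_th = constants.kB * max(pair.theta_left, pair.theta_right) / constants.hbar
    for mult in (5.0, 30.0):
        w = mult * w_th
        if 0 < w < bands.omega_r:
            edges.add(w)
    return sorted(e for e in edges if e <= omega_top)


def heat_flow(
    device: DeviceModel,
    pair: ThermalPair,
    constants: PhysicalConstants | None = None,
    eta: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-15,
) -> tuple[float, int, float]:
    """Heat flow J (W) through the device by adaptive panel quadrature.

    The integrand (hbar w/2 pi) tr(T)(w) [N_0 - N_{N+1}] is integrated over
    (0, 1.05 w_p] with panels split at the band edges and at the thermal
    scale kB theta/hbar; its w -> 0 limit, (kB/2 pi) Dtheta tr(T)(0+), is
    finite and handled by the limiting form.  Returns (J, evaluations,
    estimated absolute error).
    """
    constants = constants or PhysicalConstants.paper()
    if pair.delta == 0.0:
        return 0.0, 0, 0.0
    pref = constants.hbar / (2.0 * math.pi)
    neval = 0
    # classical ballistic J is a strict upper bound on |J|; anchoring the
    # per-panel absolute target to it keeps the quadrature relative even
    # deep in the quantum regime where |J| is orders of magnitude smaller
    bands = band_structure(device.left)
    j_bound = (
        constants.kB
        * (bands.omega_r - bands.omega_q + bands.omega_p)
        / (2.0 * math.pi)
        * abs(pair.delta)
    )
    epsabs = max(rtol * j_bound * 1e-2, 1e-300)

    eta_top = eta if eta is not None else device.eta_value()

    def eta_at(w: float) -> float:
        # broadening proportional to omega below the optical-band top keeps
        # eta << eps = omega^2 uniformly down the acoustic tail, where a
        # constant eta would swamp eps and fake extra attenuation
        return eta_top * min(1.0, w / bands.omega_p)

    def integrand(w: float) -> float:
        nonlocal neval
        neval += 1
        if w <= 0.0:
            return 0.0  # measure-zero endpoint; quadrature never lands here
        x_small = constants.hbar * w / (constants.kB * min(pair.theta_left, pair.theta_right))
        if x_small < 1e-12:
            # analytic w -> 0 limit of the full integrand
            return constants.kB / (2.0 * math.pi) * pair.delta * transmission(
                device, w, eta=eta_at(w)
            )
        return pref * w * transmission(device, w, eta=eta_at(w)) * _occupation_difference(
            w, pair, constants
        )

    edges = _panel_edges(device, pair, constants)
    total = 0.0
    err_total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        val, err = quad(integrand, a, b, epsabs=epsabs, epsrel=rtol, limit=200)
        total += val
        err_total += err
    if err_total > max(1e-3 * abs(total), atol):
        raise QuadratureError(
            f"heat-flow quadrature error {err_total:.3e} W exceeds tolerance "
            f"(0.1% of |J| = {abs(total):.3e} W or {atol:.0e} W)"
        )
    return total, neval, err_total


def conductance(
    device: DeviceModel,
    pair: ThermalPair,
    constants: PhysicalConstants | None = None,
    eta: float | None = None,
) -> ConductanceResult:
    """Thermal conductance sigma = J/(theta_0 - theta_{N+1})."""
    if pair.delta == 0.0:
        raise EqualTemperatureError(
            "sigma is undefined at equal temperatures; use a small finite "
            "difference (e.g. conductance_curve with a small delta)"
        )
    J, neval, err = heat_flow(device, pair, constants=constants, eta=eta)
    return ConductanceResult(
        J=J, sigma=J / pair.delta, pair=pair,
        quadrature_points=neval, quadrature_error=err,
    )


def conductance_curve(
    device: DeviceModel,
    thetas: "np.ndarray | list[float]",
    deltas: "np.ndarray | list[float]",
    constants: PhysicalConstants | None = None,
    eta: float | None = None,
) -> pd.DataFrame:
    """sigma as a function of mean temperature for one or more differences.

    For each mean theta and difference Dtheta the reservoirs are set to
    theta +/- Dtheta/2.  Returns a DataFrame with columns theta_K,
    delta_theta_K, J_W, sigma_W_per_K.
    """
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    deltas = np.atleast_1d(np.asarray(deltas, dtype=float))
    if thetas.size == 0 or deltas.size == 0:
        raise ValueError("theta grid and delta list must be non-empty")
    rows = []
    for th in thetas:
        for d in deltas:
            if d >= 2.0 * th:
                raise TemperatureRangeError(
                    f"delta_theta = {d} K >= 2 theta = {2 * th} K gives a "
                    "non-positive reservoir temperature"
                )
            pair = ThermalPair(th + 0.5 * d, th - 0.5 * d)
            res = conductance(device, pair, constants=constants, eta=eta)
            rows.append(
                {"theta_K": th, "delta_theta_K": d, "J_W": res.J,
                 "sigma_W_per_K": res.sigma}
            )
    return pd.DataFrame(rows)


def classical_conductance(
    omega_r: float, constants: PhysicalConstants | None = None
) -> float:
    """Classical-limit conductance kB w_r / 2 pi (acoustic band only)."""
    if omega_r <= 0:
        raise ValueError("omega_r must be positive")
    constants = constants or PhysicalConstants.paper()
    return constants.kB * omega_r / (2.0 * math.pi)


def classical_conductance_full(
    omega_r: float,
    omega_q: float,
    omega_p: float,
    constants: PhysicalConstants | None = None,
) -> float:
    """Classical-limit conductance kB (w_r - w_q + w_p) / 2 pi.

    Counts both ballistic bands; reduces to :func:`classical_conductance`
    when the optical band has zero width (w_p = w_q).
    """
    if not (0 < omega_r <= omega_q <= omega_p):
        raise ValueError("band edges must satisfy 0 < omega_r <= omega_q <= omega_p")
    constants = constants or PhysicalConstants.paper()
    return constants.kB * (omega_r - omega_q + omega_p) / (2.0 * math.pi)


def thermal_quantum(theta: float, constants: PhysicalConstants | None = None) -> float:
    """Universal one-channel thermal conductance quantum pi^2 kB^2 theta / 3 h.

    The low-temperature limit of a single ballistic channel; used as an
    independent check of the full quadrature on the acoustic tail.
    """
    constants = constants or PhysicalConstants.paper()
    return math.pi**2 * constants.kB**2 * theta / (3.0 * constants.h)
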