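"""Nonequilibrium Green's function machinery for the reservoir-water-reservoir chain.

The device is N unit cells (2N scalar sites in the mass-weighted basis)
coupled to two semi-infinite periodic diatomic reservoirs.  Everything is
expressed in the squared-frequency energy variable eps = omega^2 (s^-2):
on-site values are (sum of attached springs)/mass and hoppings are
-K/sqrt(m_a m_b), so the Bloch reduction of a homogeneous chain reproduces
the lattice dispersion exactly.  Reservoirs enter through surface Green's
functions computed by decimation; the transmission is the Caroli trace
tr(Gamma_L G_D Gamma_R G_D^dagger).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .errors import DecimationError, SingularDeviceError
from .lattice import BandStructure, UnitCell, band_structure

#: default spectral broadening as a fraction of omega_p^2
DEFAULT_ETA_SCALE = 1e-8

InterfaceSpring = Literal["device", "reservoir", "mean"]


@dataclass(frozen=True)
class DeviceModel:
    """Two semi-infinite periodic reservoirs sandwiching N device cells.

    Device cells may differ cell-to-cell (an aperiodic liquid layer);
    reservoirs are strictly periodic.  ``eta`` is the positive spectral
    broadening in eps = omega^2 units; if None it defaults to
    1e-8 * omega_p^2 of the left reservoir.
    """

    left: UnitCell
    right: UnitCell
    cells: tuple[UnitCell, ...]
    eta: float | None = None
    interface_spring: InterfaceSpring = "device"
    # explicit interface-spring overrides (N/m); None = derive from
    # interface_spring mode.  Set by reversed() so a mirrored device keeps
    # the exact original junction springs.
    interface_K_left: float | None = None
    interface_K_right: float | None = None

    def __post_init__(self) -> None:
        if len(self.cells) < 1:
            raise ValueError("need at least one device cell")
        if self.eta is not None and self.eta <= 0:
            raise ValueError("eta must be positive")
        object.__setattr__(self, "cells", tuple(self.cells))

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def eta_value(self) -> float:
        if self.eta is not None:
            return self.eta
        wp = band_structure(self.left).omega_p
        return DEFAULT_ETA_SCALE * wp * wp

    def left_interface_spring(self) -> float:
        if self.interface_K_left is not None:
            return self.interface_K_left
        return _pick_spring(self.left.K2, self.cells[0].K2, self.interface_spring)

    def right_interface_spring(self) -> float:
        if self.interface_K_right is not None:
            return self.interface_K_right
        return _pick_spring(self.right.K2, self.cells[-1].K2, self.interface_spring)

    def reversed(self) -> "DeviceModel":
        """Physical mirror image of the junction.

        Mirroring reverses the full site/spring sequence: reservoirs swap
        (with their H2/O elements exchanged), each device cell's elements
        are exchanged, the cell order reverses, inter-cell springs shift
        accordingly, and the two interface springs trade places.  By
        reciprocity the mirrored junction has the same transmission at
        every frequency.
        """

        def mirror(c: UnitCell) -> UnitCell:
            return replace(c, M1=c.M2, M2=c.M1)

        old = self.cells
        n = len(old)
        kL, kR = self.left_interface_spring(), self.right_interface_spring()
        new_cells = []
        for j in range(n):
            src = old[n - 1 - j]
            # inter-cell spring of new cell j is the spring that sat between
            # old cells (n-2-j, n-1-j); the last one is unused for coupling
            k2 = old[n - 2 - j].K2 if j < n - 1 else kL
            new_cells.append(replace(src, M1=src.M2, M2=src.M1, K2=k2))
        return replace(
            self,
            left=mirror(self.right),
            right=mirror(self.left),
            cells=tuple(new_cells),
            interface_K_left=kR,
            interface_K_right=kL,
        )

    def to_json(self) -> str:
        def cell_d(c: UnitCell) -> dict:
            return {"M1_kg": c.M1, "M2_kg": c.M2, "K1_N_m": c.K1,
                    "K2_N_m": c.K2, "l_m": c.l}

        return json.dumps(
            {
                "left": cell_d(self.left),
                "right": cell_d(self.right),
                "cells": [cell_d(c) for c in self.cells],
                "eta": self.eta,
                "interface_spring": self.interface_spring,
                "interface_K_left": self.interface_K_left,
                "interface_K_right": self.interface_K_right,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "DeviceModel":
        d = json.loads(s)

        def cell(cd: dict) -> UnitCell:
            return UnitCell(M1=cd["M1_kg"], M2=cd["M2_kg"], K1=cd["K1_N_m"],
                            K2=cd["K2_N_m"], l=cd["l_m"])

        return cls(
            left=cell(d["left"]), right=cell(d["right"]),
            cells=tuple(cell(c) for c in d["cells"]),
            eta=d.get("eta"), interface_spring=d.get("interface_spring", "device"),
            interface_K_left=d.get("interface_K_left"),
            interface_K_right=d.get("interface_K_right"),
        )


def _pick_spring(reservoir_k: float, device_k: float, mode: InterfaceSpring) -> float:
    if mode == "device":
        return device_k
    if mode == "reservoir":
        return reservoir_k
    if mode == "mean":
        return 0.5 * (reservoir_k + device_k)
    raise ValueError(f"unknown interface_spring mode {mode!r}")


@dataclass(frozen=True)
class DynamicalBlocks:
    """Mass-weighted site-basis operator of the device region at one frequency.

    ``onsite`` are the 2N diagonal values (s^-2), ``hopping`` the 2N-1
    nearest-neighbour couplings; the first/last on-site values include the
    interface springs to the reservoirs.
    """

    onsite: np.ndarray  # (2N,)
    hopping: np.ndarray  # (2N-1,)
    v_left: float  # coupling device site 1 <-> left-reservoir surface O site
    v_right: float  # coupling device site 2N <-> right-reservoir surface H2 site
    eps: float  # omega^2

    def dense_hamiltonian(self) -> np.ndarray:
        n = self.onsite.size
        h = np.diag(self.onsite).astype(complex)
        idx = np.arange(n - 1)
        h[idx, idx + 1] = self.hopping
        h[idx + 1, idx] = self.hopping
        return h


@dataclass(frozen=True)
class GreenFunctionSet:
    """Reservoir surface GFs, device GF and broadening matrices at one frequency."""

    gL: np.ndarray  # 2x2 left-reservoir surface GF (element [1,1] = "22" used)
    gR: np.ndarray  # 2x2 right-reservoir surface GF (element [0,0] = "11" used)
    GD: np.ndarray  # 2N x 2N retarded device GF
    gamma_L: np.ndarray
    gamma_R: np.ndarray


@dataclass(frozen=True)
class TransmissionSpectrum:
    """Caroli trace on an omega grid, raw and normalized by its maximum."""

    omega: np.ndarray
    trace: np.ndarray

    @property
    def probability(self) -> np.ndarray:
        m = float(np.max(self.trace))
        if m <= 0:
            return np.zeros_like(self.trace)
        return self.trace / m

    def at(self, omega: float) -> float:
        """Normalized probability at the grid point nearest omega."""
        i = int(np.argmin(np.abs(self.omega - omega)))
        return float(self.probability[i])


def build_dynamical_blocks(device: DeviceModel, omega: float) -> DynamicalBlocks:
    """Assemble the mass-weighted on-site/hopping values of the device at omega.

    For cell j: on-site of the H2 site is (K_{j,1} + K_{j-1,2})/M_{j,1} and of
    the O site (K_{j,1} + K_{j,2})/M_{j,2}; boundary cells use the interface
    spring across the reservoir junction.  Hoppings are -K divided by the
    geometric mean of the coupled masses.
    """
    cells = device.cells
    n = len(cells)
    kL = device.left_interface_spring()
    kR = device.right_interface_spring()
    onsite = np.empty(2 * n)
    hopping = np.empty(2 * n - 1)
    for j, c in enumerate(cells):
        k_prev = kL if j == 0 else cells[j - 1].K2
        k_next = kR if j == n - 1 else c.K2
        onsite[2 * j] = (c.K1 + k_prev) / c.M1
        onsite[2 * j + 1] = (c.K1 + k_next) / c.M2
        hopping[2 * j] = -c.K1 / math.sqrt(c.M1 * c.M2)
        if j < n - 1:
            hopping[2 * j + 1] = -c.K2 / math.sqrt(c.M2 * cells[j + 1].M1)
    v_left = -kL / math.sqrt(device.left.M2 * cells[0].M1)
    v_right = -kR / math.sqrt(cells[-1].M2 * device.right.M1)
    return DynamicalBlocks(
        onsite=onsite, hopping=hopping, v_left=v_left, v_right=v_right,
        eps=omega * omega,
    )


def _lead_blocks(cell: UnitCell) -> tuple[np.ndarray, np.ndarray]:
    """Bulk cell Hamiltonian H00 and forward hopping H01 of a periodic lead."""
    s = math.sqrt(cell.M1 * cell.M2)
    h00 = np.array(
        [
            [(cell.K1 + cell.K2) / cell.M1, -cell.K1 / s],
            [-cell.K1 / s, (cell.K1 + cell.K2) / cell.M2],
        ],
        dtype=complex,
    )
    h01 = np.zeros((2, 2), dtype=complex)
    h01[1, 0] = -cell.K2 / s  # O of cell j couples to H2 of cell j+1
    return h00, h01


def _decimate(E: complex, h00: np.ndarray, v: np.ndarray,
              tol: float, max_iter: int) -> np.ndarray:
    """Sancho-Rubio decimation: solve g = [E - h00 - v g v^dagger]^(-1).

    ``v`` is the hopping from the surface cell into the bulk; each iteration
    doubles the effective chain length, so convergence is geometric even for
    small broadening.
    """
    eye = np.eye(h00.shape[0], dtype=complex)
    eps_s = h00.copy()
    eps_b = h00.copy()
    alpha = v.astype(complex).copy()
    beta = v.conj().T.copy()
    scale = max(float(np.linalg.norm(h00)), 1.0)
    for _ in range(max_iter):
        gb = np.linalg.inv(E * eye - eps_b)
        agb = alpha @ gb
        bgb = beta @ gb
        eps_s = eps_s + agb @ beta
        eps_b = eps_b + agb @ beta + bgb @ alpha
        alpha = agb @ alpha
        beta = bgb @ beta
        if np.linalg.norm(alpha) + np.linalg.norm(beta) < tol * scale:
            return np.linalg.inv(E * eye - eps_s)
    raise DecimationError(
        f"surface GF decimation did not converge in {max_iter} iterations"
    )


def surface_gf(
    omega: float,
    eta: float,
    reservoir: UnitCell,
    side: Literal["left", "right"],
    tol: float = 1e-12,
    max_iter: int = 200,
) -> np.ndarray:
    """Retarded surface Green's function (2x2) of a semi-infinite reservoir.

    For the left reservoir the chain extends to -infinity and terminates on
    its O site; element [1,1] is the one seen by the device.  For the right
    reservoir the chain extends to +infinity and terminates on its H2 site;
    element [0,0] is used.  Retarded convention: Im(diagonal) <= 0.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    h00, h01 = _lead_blocks(reservoir)
    E = omega * omega + 1j * eta
    if side == "left":
        v = h01.conj().T  # surface cell couples leftward into the bulk
    elif side == "right":
        v = h01
    else:
        raise ValueError("side must be 'left' or 'right'")
    return _decimate(E, h00, v, tol, max_iter)


def self_energies(
    blocks: DynamicalBlocks, gL: np.ndarray, gR: np.ndarray
) -> tuple[complex, complex, float, float]:
    """Lead self-energies and broadenings on the boundary device sites.

    Returns (sigma_L, sigma_R, gamma_L, gamma_R) where sigma_L acts only on
    the first device site and sigma_R on the last.  gamma = i(sigma -
    sigma*) reduces to -2 v^2 Im(g_surface) for these scalar couplings.
    """
    sigma_L = blocks.v_left**2 * gL[1, 1]
    sigma_R = blocks.v_right**2 * gR[0, 0]
    gamma_L = -2.0 * blocks.v_left**2 * float(np.imag(gL[1, 1]))
    gamma_R = -2.0 * blocks.v_right**2 * float(np.imag(gR[0, 0]))
    return sigma_L, sigma_R, gamma_L, gamma_R


def device_gf(
    blocks: DynamicalBlocks,
    sigma_L: complex,
    sigma_R: complex,
    eta: float,
) -> np.ndarray:
    """Retarded device Green's function by dense inversion.

    G_D = [(eps + i eta) I - H_D - Sigma_L - Sigma_R]^(-1) on the 2N-site
    device space.
    """
    h = blocks.dense_hamiltonian()
    n = h.shape[0]
    op = (blocks.eps + 1j * eta) * np.eye(n, dtype=complex) - h
    op[0, 0] -= sigma_L
    op[-1, -1] -= sigma_R
    try:
        return np.linalg.inv(op)
    except np.linalg.LinAlgError as exc:
        raise SingularDeviceError(
            "device resolvent is singular; use a positive broadening eta"
        ) from exc


def device_gf_corner(
    blocks: DynamicalBlocks,
    sigma_L: complex,
    sigma_R: complex,
    eta: float,
) -> complex:
    """G_D[first, last] by the recursive (left-sweep) Green's function method.

    Scalar forward recursion over the 2N-site chain; O(N) per frequency and
    the cross-check for the dense route.
    """
    h = blocks.onsite
    t = blocks.hopping
    n = h.size
    E = blocks.eps + 1j * eta
    g_prev = 1.0 / (E - h[0] - sigma_L)
    corner = g_prev
    for i in range(1, n):
        sig = sigma_R if i == n - 1 else 0.0
        g_i = 1.0 / (E - h[i] - t[i - 1] ** 2 * g_prev - sig)
        corner = corner * t[i - 1] * g_i
        g_prev = g_i
    return complex(corner)


# threshold between dense inversion and the O(N) recursive sweep
DENSE_N_MAX = 64


def transmission(
    device: DeviceModel,
    omega: float,
    eta: float | None = None,
    method: Literal["auto", "dense", "recursive"] = "auto",
) -> float:
    """Caroli transmission trace tr(Gamma_L G_D Gamma_R G_D^dagger) at omega.

    Because each broadening matrix has a single non-zero (corner) entry the
    trace collapses to gamma_L * gamma_R * |G_D[first, last]|^2, which for a
    single water molecule is the closed-form scalar expression.  Tiny
    negative values from round-off are clipped to zero.
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    eta_v = eta if eta is not None else device.eta_value()
    blocks = build_dynamical_blocks(device, omega)
    gL = surface_gf(omega, eta_v, device.left, "left")
    gR = surface_gf(omega, eta_v, device.right, "right")
    sigma_L, sigma_R, gamma_L, gamma_R = self_energies(blocks, gL, gR)
    if method == "auto":
        method = "dense" if blocks.onsite.size <= DENSE_N_MAX else "recursive"
    if method == "dense":
        GD = device_gf(blocks, sigma_L, sigma_R, eta_v)
        corner = GD[0, -1]
    else:
        corner = device_gf_corner(blocks, sigma_L, sigma_R, eta_v)
    tr = gamma_L * gamma_R * abs(corner) ** 2
    return max(float(tr), 0.0)


def green_function_set(
    device: DeviceModel, omega: float, eta: float | None = None
) -> GreenFunctionSet:
    """All Green's-function ingredients at one frequency (diagnostics)."""
    eta_v = eta if eta is not None else device.eta_value()
    blocks = build_dynamical_blocks(device, omega)
    gL = surface_gf(omega, eta_v, device.left, "left")
    gR = surface_gf(omega, eta_v, device.right, "right")
    sigma_L, sigma_R, gamma_L, gamma_R = self_energies(blocks, gL, gR)
    GD = device_gf(blocks, sigma_L, sigma_R, eta_v)
    n = GD.shape[0]
    GL = np.zeros((n, n))
    GL[0, 0] = gamma_L
    GR = np.zeros((n, n))
    GR[-1, -1] = gamma_R
    return GreenFunctionSet(gL=gL, gR=gR, GD=GD, gamma_L=GL, gamma_R=GR)


def transmission_n1_closed_form(
    device: DeviceModel, omega: float, eta: float | None = None
) -> float:
    """Scalar N = 1 transmission: gamma_L gamma_R |G_D,12|^2 with

    G_D,12 = -t / [(eps + i eta - e1 - sigma_L)(eps + i eta - e2 - sigma_R)
                    - t^2].

    Independent of the matrix route; valid only for a single device cell.
    """
    if device.n_cells != 1:
        raise ValueError("closed form is defined for N = 1 only")
    eta_v = eta if eta is not None else device.eta_value()
    blocks = build_dynamical_blocks(device, omega)
    gL = surface_gf(omega, eta_v, device.left, "left")
    gR = surface_gf(omega, eta_v, device.right, "right")
    sigma_L, sigma_R, gamma_L, gamma_R = self_energies(blocks, gL, gR)
    E = blocks.eps + 1j * eta_v
    t = blocks.hopping[0]
    gd12 = -t / (
        (E - blocks.onsite[0] - sigma_L) * (E - blocks.onsite[1] - sigma_R) - t * t
    )
    return max(float(gamma_L * gamma_R * abs(gd12) ** 2), 0.0)


def _edge_refined_grid(
    omega_max: float,
    npoints: int,
    edges: Sequence[float],
    window_frac: float = 0.02,
    edge_points: int = 40,
) -> np.ndarray:
    grid = [np.linspace(0.0, omega_max, npoints)]
    for e in edges:
        if 0 < e < omega_max:
            half = window_frac * e
            grid.append(np.linspace(max(e - half, 0.0), min(e + half, omega_max), edge_points))
    return np.unique(np.concatenate(grid))


def transmission_spectrum(
    device: DeviceModel,
    omega_max: float | None = None,
    npoints: int = 400,
    eta: float | None = None,
    edge_window_frac: float = 0.02,
) -> TransmissionSpectrum:
    """Transmission trace over [0, omega_max] with refinement near band edges.

    ``omega_max`` defaults to 1.05 * omega_p of the left reservoir; extra
    points are inserted within ``edge_window_frac`` of each band edge where
    the trace varies fastest.
    """
    if npoints < 10:
        raise ValueError("npoints must be >= 10")
    bands = band_structure(device.left)
    if omega_max is None:
        omega_max = 1.05 * bands.omega_p
    grid = _edge_refined_grid(
        omega_max, npoints, (bands.omega_r, bands.omega_q, bands.omega_p),
        edge_window_frac,
    )
    tr = np.array([transmission(device, float(w), eta=eta) for w in grid])
    return TransmissionSpectrum(omega=grid, trace=tr)
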