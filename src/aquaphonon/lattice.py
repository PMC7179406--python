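"""Diatomic-chain lattice dynamics of the H2-O model.

One unit cell holds a lumped H2 element (mass M1) and an O element (mass
M2), coupled by the intramolecular spring K1; the O couples to the next
cell's H2 by the intermolecular (hydrogen-bond) spring K2.  The dispersion
relation of the infinite chain is

    cos(k l) = [2 K1 K2/(M1 M2) - (1/M1 + 1/M2)(K1 + K2) w^2 + w^4]
               / (2 K1 K2/(M1 M2))

with an acoustic band [0, w_r], a gap (w_r, w_q) carrying only evanescent
(complex-k) solutions, and an optical band [w_q, w_p].  Given the measured
band edges w_q and w_r and the masses, the force constants follow in closed
form from the zone-boundary quadratic; w_p then follows from
w_p^2 = (K1 + K2)(1/M1 + 1/M2).
"""

from __future__ import annotations

import cmath
import json
import math
from dataclasses import dataclass

import numpy as np

from .constants import AMU, CELL_LENGTH_M, M1_H2_U, M2_O_U
from .errors import BandEdgeError


@dataclass(frozen=True)
class UnitCell:
    """Masses, springs and length of one H2-O unit cell (SI units).

    K1 couples H2-O within the cell; K2 couples O to the next cell's H2.
    The labelling convention puts the larger root of the zone-boundary
    quadratic into K1, so K1 >= K2 for cells built by
    :func:`invert_band_edges`.
    """

    M1: float  # kg, H2 element
    M2: float  # kg, O element
    K1: float  # N/m, intra-cell spring
    K2: float  # N/m, inter-cell spring
    l: float = CELL_LENGTH_M  # m

    def __post_init__(self) -> None:
        for name in ("M1", "M2", "K1", "K2", "l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"UnitCell.{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {"M1_kg": self.M1, "M2_kg": self.M2, "K1_N_m": self.K1,
             "K2_N_m": self.K2, "l_m": self.l}
        )

    @classmethod
    def from_json(cls, s: str) -> "UnitCell":
        d = json.loads(s)
        return cls(M1=d["M1_kg"], M2=d["M2_kg"], K1=d["K1_N_m"],
                   K2=d["K2_N_m"], l=d["l_m"])


@dataclass(frozen=True)
class BandStructure:
    """Band edges of the diatomic chain (rad/s).

    omega_r: acoustic-band top; omega_q: optical-band bottom;
    omega_p: optical-band top.  0 < omega_r <= omega_q <= omega_p, with
    equality of the first two only when the gap closes (M1 = M2, K1 = K2).
    """

    omega_r: float
    omega_q: float
    omega_p: float
    cell: UnitCell

    def __post_init__(self) -> None:
        if not (0 < self.omega_r <= self.omega_q <= self.omega_p):
            raise ValueError("band edges must satisfy 0 < omega_r <= omega_q <= omega_p")

    @property
    def gap(self) -> tuple[float, float]:
        return (self.omega_r, self.omega_q)


@dataclass(frozen=True)
class ComplexWavevector:
    """Both Bloch-phase solutions k+ l and k- l at one frequency.

    ``kl_plus`` is the forward solution: propagating with positive group
    velocity in a band, or decaying (|exp(i kl)| < 1) in a gap and above the
    optical band; ``kl_minus`` is its reverse.  Gap solutions carry
    Re(kl) = pi; solutions above the optical band carry Re(kl) = 0.
    """

    kl_plus: complex
    kl_minus: complex
    branch: str  # "acoustic" | "optical" | "evanescent-gap" | "evanescent-above"


def dispersion_coskl(omega: float | np.ndarray, cell: UnitCell) -> float | np.ndarray:
    """Evaluate cos(k l) of the dispersion relation at angular frequency omega.

    Pure evaluation; values outside [-1, 1] signal evanescent regimes.
    """
    w2 = np.asarray(omega, dtype=float) ** 2
    a2 = 2.0 * cell.K1 * cell.K2 / (cell.M1 * cell.M2)
    b = (1.0 / cell.M1 + 1.0 / cell.M2) * (cell.K1 + cell.K2)
    out = (a2 - b * w2 + w2 * w2) / a2
    return float(out) if np.isscalar(omega) else out


def band_structure(cell: UnitCell) -> BandStructure:
    """Band edges from the closed-form zone-boundary quadratic.

    omega_r^2 and omega_q^2 are the roots of
    M1 M2 e^2 - (M1+M2)(K1+K2) e + 4 K1 K2 = 0 (cos(kl) = -1);
    omega_p^2 = (K1+K2)(1/M1 + 1/M2) (cos(kl) = +1, optical zone centre).
    """
    M1, M2, K1, K2 = cell.M1, cell.M2, cell.K1, cell.K2
    b = (M1 + M2) * (K1 + K2) / (M1 * M2)
    c = 4.0 * K1 * K2 / (M1 * M2)
    # b^2 - 4c rewritten as a sum of non-negative terms (exact when the gap
    # closes), avoiding catastrophic cancellation for near-degenerate cells
    dM, dK = M1 - M2, K1 - K2
    disc_num = (dM * dK) ** 2 + 4.0 * K1 * K2 * dM * dM + 4.0 * M1 * M2 * dK * dK
    root = math.sqrt(disc_num) / (M1 * M2)
    eps_q = 0.5 * (b + root)
    # product of roots = c; stable when eps_r << eps_q.  The min() absorbs
    # the 1-ulp inversion possible when the gap closes exactly.
    eps_r = min(c / eps_q, eps_q)
    omega_p = math.sqrt((K1 + K2) * (1.0 / M1 + 1.0 / M2))
    return BandStructure(
        omega_r=math.sqrt(eps_r), omega_q=math.sqrt(eps_q), omega_p=omega_p, cell=cell
    )


def invert_band_edges(
    omega_q: float, omega_r: float, M1: float, M2: float
) -> tuple[float, float]:
    """Force constants (K1, K2) from the band edges and masses.

    With A = M1 M2 (wq^2 + wr^2)/(M1 + M2):

        K1 = [A + sqrt(A^2 - M1 M2 wq^2 wr^2)] / 2
        K2 = [A - sqrt(A^2 - M1 M2 wq^2 wr^2)] / 2

    Exact algebraic inverse of :func:`band_structure`; raises
    :class:`BandEdgeError` when the discriminant is negative, i.e. the given
    edges cannot arise from any positive springs with these masses.
    """
    if not (omega_q >= omega_r > 0):
        raise BandEdgeError("need omega_q >= omega_r > 0")
    if M1 <= 0 or M2 <= 0:
        raise ValueError("masses must be positive")
    A = M1 * M2 * (omega_q**2 + omega_r**2) / (M1 + M2)
    P, R = omega_q**2, omega_r**2
    # A^2 - M1 M2 P R recast to cancel exactly in the degenerate case
    # (wq = wr, M1 = M2) instead of going spuriously negative
    disc_inner = M1 * M2 * (P - R) ** 2 - (M1 - M2) ** 2 * P * R
    if disc_inner < 0:
        raise BandEdgeError(
            "inconsistent band edges for given masses (negative discriminant)"
        )
    root = math.sqrt(disc_inner * M1 * M2) / (M1 + M2)
    K1 = 0.5 * (A + root)
    K2 = M1 * M2 * P * R / (4.0 * K1)  # from K1 K2 = M1 M2 wq^2 wr^2 / 4
    if K2 <= 0:
        raise BandEdgeError("band edges imply a non-positive spring constant")
    return K1, K2


def water_cell(
    omega_q: float = 642.8e12,
    omega_r: float = 35.8e12,
    M1: float = M1_H2_U * AMU,
    M2: float = M2_O_U * AMU,
    l: float = CELL_LENGTH_M,
) -> UnitCell:
    """The liquid-water unit cell built from the tabulated band edges."""
    K1, K2 = invert_band_edges(omega_q, omega_r, M1, M2)
    return UnitCell(M1=M1, M2=M2, K1=K1, K2=K2, l=l)


def complex_wavevector(omega: float, cell: UnitCell, tol: float = 1e-12) -> ComplexWavevector:
    """Both Bloch phases (k+ l, k- l) at omega by analytic continuation of arccos.

    In a band the two solutions are +/- the real phase, the forward one
    chosen by positive group velocity; in the gap kl = pi +/- i arccosh|cos|;
    above the optical band kl = +/- i arccosh(cos).  In all evanescent
    regimes the forward solution satisfies |exp(i kl)| < 1.
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    c = dispersion_coskl(omega, cell)
    bands = band_structure(cell)
    if c < -1.0 - tol:
        # band gap: cos(pi + i y) = -cosh(y)
        y = math.acosh(-c)
        return ComplexWavevector(
            kl_plus=complex(math.pi, y), kl_minus=complex(math.pi, -y),
            branch="evanescent-gap",
        )
    if c > 1.0 + tol:
        # above the optical band: cos(i y) = cosh(y)
        y = math.acosh(c)
        return ComplexWavevector(
            kl_plus=complex(0.0, y), kl_minus=complex(0.0, -y),
            branch="evanescent-above",
        )
    kl = math.acos(min(1.0, max(-1.0, c)))  # real, in [0, pi]
    branch = "acoustic" if omega <= bands.omega_r * (1 + tol) else "optical"
    # group-velocity sign: on the acoustic branch omega grows with kl, so
    # +kl is forward; on the optical branch omega falls with kl (top of band
    # at kl = 0), so the forward-propagating solution is -kl.
    if branch == "acoustic":
        return ComplexWavevector(kl_plus=complex(kl), kl_minus=complex(-kl), branch=branch)
    return ComplexWavevector(kl_plus=complex(-kl), kl_minus=complex(kl), branch=branch)


def dispersion_table(cell: UnitCell, omega_max: float, npoints: int = 500) -> "np.ndarray":
    """Sample the complex dispersion on a uniform omega grid.

    Returns a structured array with fields omega_rad_s, Re_kl, Im_kl, branch.
    """
    omegas = np.linspace(0.0, omega_max, npoints)
    rows = np.zeros(
        npoints,
        dtype=[("omega_rad_s", float), ("Re_kl", float), ("Im_kl", float), ("branch", "U16")],
    )
    for i, w in enumerate(omegas):
        kv = complex_wavevector(float(w), cell)
        rows[i] = (w, kv.kl_plus.real, kv.kl_plus.imag, kv.branch)
    return rows


def bloch_matrix(kl: float | complex, cell: UnitCell) -> np.ndarray:
    """Mass-weighted 2x2 Bloch dynamical matrix at phase kl.

    Its eigenvalues are the squared band frequencies at that wavevector;
    used as the independent cross-check of :func:`dispersion_coskl`.
    """
    M1, M2, K1, K2 = cell.M1, cell.M2, cell.K1, cell.K2
    s = math.sqrt(M1 * M2)
    off = -(K1 + K2 * cmath.exp(-1j * kl)) / s
    return np.array(
        [[(K1 + K2) / M1, off], [np.conj(off), (K1 + K2) / M2]], dtype=complex
    )
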