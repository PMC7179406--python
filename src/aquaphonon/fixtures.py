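"""Seeded generators for synthetic spectra and disordered devices.

Everything downstream of the spectrum loader is testable without external
data: `synthetic_spectrum` plants Gaussian or Lorentzian absorption bands at
known centres (emulating the qualitative shape of a liquid-water IR
spectrum), and `disordered_device` perturbs device cells with lognormal
disorder while keeping the reservoirs clean.  All generators are pure
functions of (recipe, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CellSamplingError
from .lattice import UnitCell, water_cell
from .negf import DeviceModel
from .spectra import Spectrum


@dataclass(frozen=True)
class SpectrumRecipe:
    """Recipe for a synthetic absorption spectrum.

    Defaults emulate liquid water: dominant OH-stretch band near 3410 cm^-1,
    intermolecular band near 190 cm^-1, plus weaker bending and libration
    features.  Noise is additive uniform with the given amplitude.
    """

    centers_cm1: tuple[float, ...] = (190.0, 700.0, 1660.0, 3410.0)
    widths_cm1: tuple[float, ...] = (60.0, 120.0, 50.0, 120.0)
    amplitudes: tuple[float, ...] = (0.55, 0.35, 0.30, 1.00)
    line_shape: str = "gaussian"  # or "lorentzian"
    grid_min_cm1: float = 20.0
    grid_max_cm1: float = 4000.0
    grid_step_cm1: float = 2.0
    noise_amplitude: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.centers_cm1)
        if len(self.widths_cm1) != n or len(self.amplitudes) != n:
            raise ValueError("centers, widths and amplitudes must have equal length")
        if any(w <= 0 for w in self.widths_cm1):
            raise ValueError("widths must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")
        if self.line_shape not in ("gaussian", "lorentzian"):
            raise ValueError("line_shape must be 'gaussian' or 'lorentzian'")
        for c in self.centers_cm1:
            if not (self.grid_min_cm1 <= c <= self.grid_max_cm1):
                raise ValueError(f"peak center {c} outside grid range")


def synthetic_spectrum(recipe: SpectrumRecipe) -> Spectrum:
    """Generate a spectrum from a recipe; identical arrays for a fixed seed."""
    k = np.arange(recipe.grid_min_cm1, recipe.grid_max_cm1 + 0.5 * recipe.grid_step_cm1,
                  recipe.grid_step_cm1)
    a = np.zeros_like(k)
    for c, w, amp in zip(recipe.centers_cm1, recipe.widths_cm1, recipe.amplitudes):
        if recipe.line_shape == "gaussian":
            a += amp * np.exp(-0.5 * ((k - c) / w) ** 2)
        else:
            a += amp / (1.0 + ((k - c) / w) ** 2)
    if recipe.noise_amplitude > 0:
        rng = np.random.default_rng(recipe.seed)
        a = a + recipe.noise_amplitude * rng.uniform(0.0, 1.0, size=k.size)
    return Spectrum(wavenumbers=k, absorbance=np.clip(a, 0.0, None))


@dataclass(frozen=True)
class DisorderRecipe:
    """Lognormal disorder applied to the device cells of a chain.

    Relative standard deviations apply multiplicative lognormal factors to
    masses, springs and lengths; lognormal sampling keeps every parameter
    positive.  Reservoirs stay at the clean base cell.
    """

    base: UnitCell = field(default_factory=water_cell)
    n_cells: int = 8
    mass_rel_sd: float = 0.0
    spring_rel_sd: float = 0.0
    length_rel_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("mass_rel_sd", "spring_rel_sd", "length_rel_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _lognormal_factor(rng: np.random.Generator, rel_sd: float) -> float:
    if rel_sd == 0.0:
        return 1.0
    # mean-one lognormal: exp(N(-s^2/2, s^2)) with s = sqrt(ln(1 + rel_sd^2))
    s = np.sqrt(np.log1p(rel_sd**2))
    return float(np.exp(rng.normal(-0.5 * s * s, s)))


def table1_device(
    n_cells: int = 1,
    eta: float | None = None,
    omega_q: float = 642.8e12,
    omega_r: float = 35.8e12,
) -> DeviceModel:
    """Homogeneous water device built from the tabulated band edges.

    Masses M1 = 2.016 u (lumped H2) and M2 = 15.999 u (O); force constants
    from the band-edge inversion of (642.8, 35.8) Trad/s; cell length
    0.319 nm; reservoirs identical to the device cells.
    """
    cell = water_cell(omega_q=omega_q, omega_r=omega_r)
    return DeviceModel(left=cell, right=cell, cells=(cell,) * n_cells, eta=eta)


def disordered_device(recipe: DisorderRecipe, eta: float | None = None,
                      max_attempts: int = 100) -> DeviceModel:
    """Disordered device from a recipe; reservoirs remain the clean base cell.

    Each device cell gets independent lognormal factors on M1, M2, K1, K2
    and l.  A sampled cell that fails validation is resampled, with a hard
    error after ``max_attempts`` tries.
    """
    rng = np.random.default_rng(recipe.seed)
    base = recipe.base
    cells = []
    for _ in range(recipe.n_cells):
        for attempt in range(max_attempts):
            try:
                cell = replace(
                    base,
                    M1=base.M1 * _lognormal_factor(rng, recipe.mass_rel_sd),
                    M2=base.M2 * _lognormal_factor(rng, recipe.mass_rel_sd),
                    K1=base.K1 * _lognormal_factor(rng, recipe.spring_rel_sd),
                    K2=base.K2 * _lognormal_factor(rng, recipe.spring_rel_sd),
                    l=base.l * _lognormal_factor(rng, recipe.length_rel_sd),
                )
                break
            except ValueError:
                continue
        else:
            raise CellSamplingError(
                f"could not sample a valid cell in {max_attempts} attempts"
            )
        cells.append(cell)
    return DeviceModel(left=base, right=base, cells=tuple(cells), eta=eta)
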