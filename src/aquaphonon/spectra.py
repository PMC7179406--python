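"""IR absorption spectra: loading, peak picking and mode assignment.

The chain model takes exactly two numbers from experiment: the wavenumber of
the OH symmetric-stretch absorbance maximum (mode *b*, the optical-band
bottom) and of the intermolecular-vibration maximum (mode *e*, the
acoustic-band top).  This module finds those peaks in a two-column spectrum,
applies the anti-symmetric-stretch correction ka = ka' - kb' + kb built from
the isolated-molecule references, and converts spectroscopic wavenumbers
(cm^-1) to angular frequencies (rad/s).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

from .constants import PhysicalConstants
from .errors import (
    EmptyWindowError,
    NoPeaksError,
    SpectrumFileError,
    SpectrumFormatError,
    TooFewPointsError,
)

#: isolated-molecule gas-phase references for the OH stretches (cm^-1)
KA_ISOLATED_CM1 = 3756.0
KB_ISOLATED_CM1 = 3657.0

#: default spectral windows for mode assignment (cm^-1)
INTERMOLECULAR_WINDOW = (50.0, 400.0)
OH_STRETCH_WINDOW = (2800.0, 3800.0)
BENDING_WINDOW = (1400.0, 1800.0)
LIBRATION_WINDOW = (400.0, 1000.0)


@dataclass(frozen=True)
class Spectrum:
    """An absorption spectrum: wavenumber (cm^-1) vs absorbance (a.u.).

    Wavenumbers are strictly increasing; absorbance is non-negative.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if k.ndim != 1 or a.ndim != 1 or k.size != a.size:
            raise SpectrumFormatError("wavenumbers and absorbance must be 1-D and equal length")
        if k.size < 3:
            raise TooFewPointsError(f"need at least 3 points, got {k.size}")
        if not np.all(np.diff(k) > 0):
            raise SpectrumFormatError("wavenumbers must be strictly increasing")
        if np.any(a < 0):
            raise SpectrumFormatError("absorbance must be non-negative")
        object.__setattr__(self, "wavenumbers", k)
        object.__setattr__(self, "absorbance", a)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)


@dataclass(frozen=True)
class Peak:
    """A detected absorbance maximum."""

    wavenumber_cm1: float  # parabolically refined position
    absorbance: float  # height at the grid maximum
    prominence: float


@dataclass
class ModeTable:
    """Wavenumbers and angular frequencies of the assigned vibration modes.

    Modes are labelled a (OH anti-symmetric stretch), b (OH symmetric
    stretch), c (bending), d (libration) and e (intermolecular vibration).
    """

    k_cm1: dict[str, float]
    constants: PhysicalConstants = field(default_factory=PhysicalConstants.paper)
    ka_isolated_cm1: float = KA_ISOLATED_CM1
    kb_isolated_cm1: float = KB_ISOLATED_CM1

    @property
    def omega_rad_s(self) -> dict[str, float]:
        return {m: wavenumber_to_omega(k, self.constants) for m, k in self.k_cm1.items()}

    def to_frame(self) -> pd.DataFrame:
        """Mode table as a DataFrame (k to integer cm^-1, omega to 0.1 Trad/s)."""
        rows = [
            {
                "mode": m,
                "k_cm1": round(self.k_cm1[m]),
                "omega_Trad_s": round(self.omega_rad_s[m] / 1e12, 1),
            }
            for m in sorted(self.k_cm1)
        ]
        return pd.DataFrame(rows)


def load_spectrum(path: str | os.PathLike) -> Spectrum:
    """Read a two-column CSV (wavenumber_cm1, absorbance) into a Spectrum.

    A header row is optional and lines starting with ``#`` are ignored.
    Rows are sorted by wavenumber if needed.
    """
    if not os.path.exists(path):
        raise SpectrumFileError(f"spectrum file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#", header=None, skip_blank_lines=True)
    except Exception as exc:  # malformed CSV
        raise SpectrumFormatError(f"could not parse {path}: {exc}") from exc
    # tolerate a text header row
    first = df.iloc[0]
    if first.apply(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:]
    if df.shape[1] != 2:
        raise SpectrumFormatError(f"expected 2 columns, got {df.shape[1]}")
    try:
        data = df.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise SpectrumFormatError(f"non-numeric cell in {path}: {exc}") from exc
    if data.shape[0] < 3:
        raise TooFewPointsError(f"too few points: {data.shape[0]} < 3")
    order = np.argsort(data[:, 0])
    return Spectrum(data[order, 0], data[order, 1])


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    # reflect-pad so the moving average does not bias the edges
    pad = window // 2
    ypad = np.concatenate([y[pad:0:-1], y, y[-2 : -pad - 2 : -1]])
    return np.convolve(ypad, kernel, mode="valid")


def _parabolic_refine(k: np.ndarray, y: np.ndarray, i: int) -> float:
    """Refine a grid maximum by a 3-point parabola; falls back to the grid point."""
    if i == 0 or i == len(y) - 1:
        return float(k[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not a strict local maximum of the parabola
        return float(k[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(k[i] + delta * (k[i + 1] - k[i - 1]) / 2.0)


def find_peaks(
    spectrum: Spectrum,
    min_prominence: float = 0.02,
    smoothing_window: int = 1,
) -> list[Peak]:
    """Locate absorbance maxima.

    Parameters
    ----------
    min_prominence : required peak prominence as a fraction of the maximum
        absorbance, in (0, 1).
    smoothing_window : odd moving-average width in points (1 = no smoothing).

    Returns peaks in increasing wavenumber order, each refined by a 3-point
    parabolic interpolation around its grid maximum.  Raises
    :class:`NoPeaksError` if nothing passes the threshold.
    """
    if not 0.0 < min_prominence < 1.0:
        raise ValueError("min_prominence must be in (0, 1)")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be an odd integer >= 1")
    if smoothing_window >= len(spectrum):
        raise ValueError("smoothing_window must be smaller than the spectrum length")

    y = _smooth(spectrum.absorbance, smoothing_window)
    threshold = min_prominence * float(np.max(y))
    idx, props = _scipy_find_peaks(y, prominence=threshold)
    if idx.size == 0:
        raise NoPeaksError(
            f"no peaks with prominence >= {min_prominence:g} x max absorbance"
        )
    peaks = [
        Peak(
            wavenumber_cm1=_parabolic_refine(spectrum.wavenumbers, y, int(i)),
            absorbance=float(y[i]),
            prominence=float(p),
        )
        for i, p in zip(idx, props["prominences"])
    ]
    peaks.sort(key=lambda p: p.wavenumber_cm1)
    return peaks


def _best_in_window(peaks: Sequence[Peak], window: tuple[float, float]) -> Peak | None:
    lo, hi = window
    inside = [p for p in peaks if lo <= p.wavenumber_cm1 <= hi]
    if not inside:
        return None
    return max(inside, key=lambda p: p.absorbance)


def assign_modes(
    peaks: Sequence[Peak],
    intermolecular_window: tuple[float, float] = INTERMOLECULAR_WINDOW,
    oh_stretch_window: tuple[float, float] = OH_STRETCH_WINDOW,
    constants: PhysicalConstants | None = None,
    include_optional: bool = True,
) -> ModeTable:
    """Assign modes b and e from detected peaks using fixed spectral windows.

    Mode e is the highest-absorbance peak in the intermolecular window
    (default 50-400 cm^-1); mode b the highest in the OH-stretch window
    (default 2800-3800 cm^-1).  Fixed windows mean the libration and bending
    features cannot displace the assignment.  Mode a is reconstructed by
    :func:`correct_antisymmetric`; modes c and d are filled in when a peak
    falls in their windows and ``include_optional`` is set.
    """
    if not peaks:
        raise EmptyWindowError("no peaks supplied")
    constants = constants or PhysicalConstants.paper()

    e = _best_in_window(peaks, intermolecular_window)
    if e is None:
        raise EmptyWindowError(
            f"no intermolecular-vibration peak in window {intermolecular_window} cm^-1"
        )
    b = _best_in_window(peaks, oh_stretch_window)
    if b is None:
        raise EmptyWindowError(
            f"no OH-stretch peak in window {oh_stretch_window} cm^-1"
        )

    k = {
        "b": b.wavenumber_cm1,
        "e": e.wavenumber_cm1,
        "a": correct_antisymmetric(KA_ISOLATED_CM1, KB_ISOLATED_CM1, b.wavenumber_cm1),
    }
    if include_optional:
        c = _best_in_window(peaks, BENDING_WINDOW)
        d = _best_in_window(peaks, LIBRATION_WINDOW)
        if c is not None:
            k["c"] = c.wavenumber_cm1
        if d is not None:
            k["d"] = d.wavenumber_cm1
    return ModeTable(k_cm1=k, constants=constants)


def correct_antisymmetric(ka_iso: float, kb_iso: float, kb_liquid: float) -> float:
    """Liquid-phase anti-symmetric stretch ka = ka' - kb' + kb.

    The gas-phase splitting between the two OH stretches (ka' - kb') is
    carried over to the liquid, where only the symmetric stretch kb is
    resolved in absorption.
    """
    if ka_iso <= 0 or kb_iso <= 0 or kb_liquid <= 0:
        raise ValueError("wavenumbers must be positive")
    return ka_iso - kb_iso + kb_liquid


def wavenumber_to_omega(k_cm1: float, constants: PhysicalConstants | None = None) -> float:
    """Convert a spectroscopic wavenumber (cm^-1) to angular frequency (rad/s).

    omega = 2 pi * (k in m^-1) * c.
    """
    if k_cm1 < 0:
        raise ValueError("wavenumber must be non-negative")
    constants = constants or PhysicalConstants.paper()
    return 2.0 * math.pi * (k_cm1 * 100.0) * constants.c


def omega_to_wavenumber(omega: float, constants: PhysicalConstants | None = None) -> float:
    """Inverse of :func:`wavenumber_to_omega` (rad/s -> cm^-1)."""
    if omega < 0:
        raise ValueError("omega must be non-negative")
    constants = constants or PhysicalConstants.paper()
    return omega / (2.0 * math.pi * 100.0 * constants.c)


def water_mode_table(constants: PhysicalConstants | None = None) -> ModeTable:
    """The reference liquid-water mode table (wavenumbers in cm^-1).

    ka is reconstructed from the isolated-molecule references and the liquid
    kb = 3410 cm^-1 via :func:`correct_antisymmetric`.
    """
    constants = constants or PhysicalConstants.paper()
    kb, ke = 3410.0, 190.0
    return ModeTable(
        k_cm1={
            "a": correct_antisymmetric(KA_ISOLATED_CM1, KB_ISOLATED_CM1, kb),
            "b": kb,
            "c": 1660.0,
            "d": 700.0,
            "e": ke,
        },
        constants=constants,
    )
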