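"""Core data model for far-UV CD spectra and secondary-structure fractions.

Everything downstream (reference sets, the self-organising map, the
derandomization sweep) trades in three currencies defined here:

* :class:`CDSpectrum` — Δε per molar residue sampled on a common,
  descending :class:`WavelengthGrid` (default 240→190 nm, 1 nm step,
  51 points);
* :class:`StructureFractions5` — the five-class crystal-structure
  annotation (α-helix, β-sheet, bonded turn, bend, loop);
* :class:`StructureFractions3` — the three-class reporting unit
  (α-helix, β-sheet, other), the most that a far-UV CD spectrum can
  actually resolve.

The module also provides the NRMSD goodness-of-fit statistic used to gate
fits throughout the package, linear resampling between wavelength grids,
and the 5→3 structure-class collapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WavelengthGrid",
    "CDSpectrum",
    "StructureFractions5",
    "StructureFractions3",
    "GridMismatchError",
    "SpanError",
    "resample_to_grid",
    "nrmsd",
    "collapse_structure",
]

_FRACTION_TOL = 1e-6


class GridMismatchError(ValueError):
    """Two spectra were combined but live on different wavelength grids."""


class SpanError(ValueError):
    """A spectrum does not cover the wavelength span it is resampled onto."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform, descending far-UV wavelength grid.

    Parameters
    ----------
    start_nm : float
        First (longest) wavelength, default 240 nm.
    end_nm : float
        Last (shortest) wavelength, default 190 nm.
    step_nm : float
        Positive spacing, default 1 nm. ``(start_nm - end_nm) / step_nm``
        must be integral, so the default grid has 51 points.
    """

    start_nm: float = 240.0
    end_nm: float = 190.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        if self.start_nm <= self.end_nm:
            raise ValueError(
                "grid must be descending: start_nm "
                f"{self.start_nm} <= end_nm {self.end_nm}"
            )
        span = self.start_nm - self.end_nm
        n = span / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"span {span} nm is not an integer multiple of step {self.step_nm} nm"
            )

    def __len__(self) -> int:
        return int(round((self.start_nm - self.end_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        """Grid points in descending order (start → end)."""
        return self.start_nm - self.step_nm * np.arange(len(self))

    @classmethod
    def from_wavelengths(cls, wavelengths: np.ndarray) -> "WavelengthGrid":
        """Build a grid from an explicit descending, uniform wavelength array."""
        w = np.asarray(wavelengths, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("need a 1-D array of at least 2 wavelengths")
        steps = np.diff(w)
        if np.any(steps >= 0):
            raise ValueError("wavelengths must be strictly descending")
        step = -steps[0]
        if not np.allclose(-steps, step, rtol=0, atol=1e-6):
            raise ValueError("wavelength spacing is not uniform")
        return cls(start_nm=float(w[0]), end_nm=float(w[-1]), step_nm=float(step))


@dataclass(frozen=True)
class CDSpectrum:
    """A far-UV CD spectrum in Δε per molar residue units.

    ``values`` holds one Δε value per grid point, in the grid's descending
    wavelength order. ``temperature_C`` is carried along for melting-series
    bookkeeping and never interpreted numerically here.
    """

    grid: WavelengthGrid
    values: np.ndarray
    label: str = ""
    temperature_C: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != len(self.grid):
            raise ValueError(
                f"expected {len(self.grid)} values for grid "
                f"{self.grid.start_nm}-{self.grid.end_nm} nm, got {v.size}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError(f"spectrum {self.label!r} contains non-finite values")
        object.__setattr__(self, "values", v)

    def with_values(self, values: np.ndarray, label: str | None = None) -> "CDSpectrum":
        return CDSpectrum(
            grid=self.grid,
            values=values,
            label=self.label if label is None else label,
            temperature_C=self.temperature_C,
        )


def _check_fraction(name: str, x: float) -> float:
    x = float(x)
    if not (-_FRACTION_TOL <= x <= 1 + _FRACTION_TOL):
        raise ValueError(f"{name} fraction {x} outside [0, 1]")
    return min(max(x, 0.0), 1.0)


@dataclass(frozen=True)
class StructureFractions5:
    """Five-class secondary-structure annotation.

    The five classes follow the crystal-structure annotation convention:
    α-helix, β-sheet, bonded turn, bend and loop. Their sum may fall short
    of 1; the shortfall is unannotated structure and is folded into "other"
    by :func:`collapse_structure`.
    """

    helix: float
    sheet: float
    turn: float
    bend: float
    loop: float

    def __post_init__(self) -> None:
        for name in ("helix", "sheet", "turn", "bend", "loop"):
            object.__setattr__(self, name, _check_fraction(name, getattr(self, name)))
        total = self.helix + self.sheet + self.turn + self.bend + self.loop
        if total > 1 + _FRACTION_TOL:
            raise ValueError(f"structure fractions sum to {total} > 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.helix, self.sheet, self.turn, self.bend, self.loop])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "StructureFractions5":
        return cls(*(float(x) for x in np.asarray(a, dtype=float)))


@dataclass(frozen=True)
class StructureFractions3:
    """Three-class reporting fractions: α-helix, β-sheet, other; sum to 1."""

    helix: float
    sheet: float
    other: float

    def __post_init__(self) -> None:
        for name in ("helix", "sheet", "other"):
            object.__setattr__(self, name, _check_fraction(name, getattr(self, name)))
        total = self.helix + self.sheet + self.other
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(f"three-class fractions sum to {total} != 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.helix, self.sheet, self.other])


def resample_to_grid(spectrum: CDSpectrum, grid: WavelengthGrid) -> CDSpectrum:
    """Linearly interpolate a spectrum onto a target grid.

    Extrapolation is refused: the spectrum's wavelength span must cover the
    target grid, otherwise a :class:`SpanError` names the missing
    wavelengths. Returns the input values unchanged when the grids already
    coincide.
    """
    if spectrum.grid == grid:
        return spectrum
    src_w = spectrum.grid.wavelengths
    tgt_w = grid.wavelengths
    lo, hi = src_w.min(), src_w.max()
    missing = tgt_w[(tgt_w < lo - 1e-9) | (tgt_w > hi + 1e-9)]
    if missing.size:
        raise SpanError(
            f"spectrum {spectrum.label!r} spans {hi:g}-{lo:g} nm and cannot "
            f"supply target wavelengths {', '.join(f'{m:g}' for m in missing)} nm"
        )
    # np.interp needs ascending abscissae; grids are stored descending.
    new_values = np.interp(tgt_w[::-1], src_w[::-1], spectrum.values[::-1])[::-1]
    return CDSpectrum(
        grid=grid,
        values=new_values,
        label=spectrum.label,
        temperature_C=spectrum.temperature_C,
    )


def nrmsd(observed: CDSpectrum, fitted: CDSpectrum) -> float:
    """Normalised root-mean-square deviation between two spectra.

    NRMSD = sqrt( Σ_λ (obs_λ − fit_λ)² / Σ_λ obs_λ² ), the CD-field
    convention in which good fits to far-UV data score ~0.01 and the usual
    acceptance gate is 0.03. Zero iff the spectra are identical.
    """
    if observed.grid != fitted.grid:
        raise GridMismatchError(
            f"observed grid {observed.grid} != fitted grid {fitted.grid}"
        )
    denom = float(np.sum(observed.values**2))
    if denom == 0.0:
        raise ValueError("observed spectrum is identically zero; NRMSD undefined")
    num = float(np.sum((observed.values - fitted.values) ** 2))
    return math.sqrt(num / denom)


def collapse_structure(s5: StructureFractions5) -> StructureFractions3:
    """Collapse five annotation classes to the three CD can resolve.

    Helix and sheet pass through; turn, bend, loop and any unannotated
    residual all count as "other", so the output sums to exactly 1.
    """
    other = s5.turn + s5.bend + s5.loop + (
        1.0 - (s5.helix + s5.sheet + s5.turn + s5.bend + s5.loop)
    )
    # Guard against float residue pushing `other` a hair outside [0, 1].
    other = min(max(other, 0.0), 1.0)
    return StructureFractions3(helix=s5.helix, sheet=s5.sheet, other=other)
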