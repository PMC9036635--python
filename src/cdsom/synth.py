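"""Synthetic far-UV CD data with known ground truth.

Real reference sets (structure-annotated spectra of folded proteins) and
melting series are experimental data this package cannot ship, so the
generator builds spectra from Gaussian band models of the canonical
secondary-structure shapes:

====== ==================================================================
basis  bands (centre nm, 1/e half-width nm, amplitude Δε per residue)
====== ==================================================================
helix  (193, 5.0, +24.0), (208, 6.0, −11.5), (222, 7.0, −12.0)
sheet  (196, 5.5, +8.0), (218, 7.0, −6.5)
turn   (190, 6.0, −3.0), (205, 6.5, +2.5), (225, 8.0, +1.0)
coil   (198, 5.5, −17.0), (222, 9.0, +1.2)
====== ==================================================================

These reproduce the textbook features — the α-helix double minimum at
208/222 nm with a strong positive band near 193 nm, the β-sheet minimum
near 218 nm, and the disordered (random-coil) deep minimum near 198 nm
with a weak positive shoulder above 215 nm. A synthetic spectrum is the
fraction-weighted combination of these bases plus optional white Gaussian
noise; five-class annotations map helix→helix, sheet→sheet, turn and
bend→turn basis, loop and unannotated residue→coil basis.

A melting series mixes a fixed folded "core" spectrum with growing
fractions of the coil basis, recording the schedule as ground truth, so
the derandomization pipeline can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .refset_io import ReferenceEntry, ReferenceSet
from .spectra import (
    CDSpectrum,
    StructureFractions3,
    StructureFractions5,
    WavelengthGrid,
)

__all__ = [
    "GaussianBand",
    "BasisSet",
    "MeltSeries",
    "default_basis",
    "make_reference_set",
    "make_rc_spectrum",
    "make_melting_series",
    "DEFAULT_MELT_SCHEDULE",
    "DEFAULT_MELT_CORE",
]


@dataclass(frozen=True)
class GaussianBand:
    center_nm: float
    width_nm: float
    amplitude: float  # Δε per molar residue at the band centre


DEFAULT_BANDS: dict[str, tuple[GaussianBand, ...]] = {
    "helix": (
        GaussianBand(193.0, 5.0, 24.0),
        GaussianBand(208.0, 6.0, -11.5),
        GaussianBand(222.0, 7.0, -12.0),
    ),
    "sheet": (
        GaussianBand(196.0, 5.5, 8.0),
        GaussianBand(218.0, 7.0, -6.5),
    ),
    "turn": (
        GaussianBand(190.0, 6.0, -3.0),
        GaussianBand(205.0, 6.5, 2.5),
        GaussianBand(225.0, 8.0, 1.0),
    ),
    "coil": (
        GaussianBand(198.0, 5.5, -17.0),
        GaussianBand(222.0, 9.0, 1.2),
    ),
}


@dataclass(frozen=True)
class BasisSet:
    """Pure-structure basis spectra on a shared grid."""

    grid: WavelengthGrid
    bands: Mapping[str, tuple[GaussianBand, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def spectrum(self, name: str) -> np.ndarray:
        """Evaluate one basis spectrum on the grid."""
        wl = self.grid.wavelengths
        out = np.zeros_like(wl)
        for b in self.bands[name]:
            out += b.amplitude * np.exp(-((wl - b.center_nm) ** 2) / (2 * b.width_nm**2))
        return out

    def combine(self, helix: float, sheet: float, turn: float, coil: float) -> np.ndarray:
        return (
            helix * self.spectrum("helix")
            + sheet * self.spectrum("sheet")
            + turn * self.spectrum("turn")
            + coil * self.spectrum("coil")
        )

    def from_fractions5(self, s5: StructureFractions5) -> np.ndarray:
        """Render a five-class annotation: turn+bend → turn basis,
        loop + unannotated residue → coil basis."""
        residual = 1.0 - (s5.helix + s5.sheet + s5.turn + s5.bend + s5.loop)
        return self.combine(s5.helix, s5.sheet, s5.turn + s5.bend, s5.loop + residual)

    def from_core3(self, s3: StructureFractions3) -> np.ndarray:
        """Render a folded three-class core: "other" uses the turn basis
        (structured, non-coil), keeping the random-coil fraction of a
        melting series identifiable."""
        return self.combine(s3.helix, s3.sheet, s3.other, 0.0)


def default_basis(grid: WavelengthGrid | None = None) -> BasisSet:
    return BasisSet(grid=grid or WavelengthGrid())


#: Default thermal-melt coil schedule: spectra every 10 °C from 20–100 °C,
#: random-coil fraction rising from 0 to 0.6 — the trajectory of a
#: serum-albumin-style gradual melt, where even the fully heated protein
#: keeps a folded core. Above ~0.6 the spectrum is coil-dominated and the
#: coil fraction stops being spectroscopically identifiable (coil,
#: polyproline II and β_II shapes coincide), so higher fractions are not a
#: regime this generator's default emulates.
DEFAULT_MELT_SCHEDULE: dict[float, float] = {
    20.0: 0.0, 30.0: 0.0, 40.0: 0.1, 50.0: 0.2, 60.0: 0.2,
    70.0: 0.3, 80.0: 0.4, 90.0: 0.5, 100.0: 0.6,
}

#: Default melting core: a helix-rich folded protein.
DEFAULT_MELT_CORE = StructureFractions3(helix=0.6, sheet=0.1, other=0.3)


# Dirichlet concentration over (helix, sheet, turn, bend, loop, unannotated)
# for the folded bulk of a synthetic reference set: helix/sheet rich,
# modest turn/bend, little loop — the composition profile of a typical
# folded-protein reference collection.
_DIRICHLET_ALPHA = np.array([4.0, 3.0, 1.2, 1.2, 0.8, 0.8])


def make_reference_set(
    n: int,
    seed: int = 0,
    noise_sd: float = 0.0,
    basis: BasisSet | None = None,
) -> ReferenceSet:
    """Generate a structure-annotated synthetic reference set.

    Compositions are Dirichlet-sampled to favour realistic folded
    proteins; when ``n >= 8`` the first two entries are fully helical
    (1,0,0,0,0) and the next four fully unfolded (0,0,0,0,1), mirroring
    the helix/unfolded augmentation a CD reference set needs to span the
    far-UV shape space. Spectra are basis combinations plus white
    Gaussian noise of standard deviation ``noise_sd`` (Δε units).
    """
    if n < 1:
        raise ValueError(f"need at least one reference entry, got {n}")
    basis = basis or default_basis()
    rng = np.random.default_rng(seed)

    fracs: list[np.ndarray] = []
    if n >= 8:
        fracs += [np.array([1.0, 0, 0, 0, 0, 0])] * 2
        fracs += [np.array([0, 0, 0, 0, 1.0, 0])] * 4
    while len(fracs) < n:
        fracs.append(rng.dirichlet(_DIRICHLET_ALPHA))

    entries = []
    for i, f in enumerate(fracs, start=1):
        s5 = StructureFractions5(*(float(x) for x in f[:5]))
        values = basis.from_fractions5(s5)
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=values.size)
        name = f"synthetic_ref_{i:02d}"
        entries.append(
            ReferenceEntry(
                spectrum=CDSpectrum(grid=basis.grid, values=values, label=name),
                structure=s5,
                name=name,
                index=i,
            )
        )
    return ReferenceSet(entries=tuple(entries), grid=basis.grid)


def make_rc_spectrum(basis: BasisSet | None = None) -> CDSpectrum:
    """The random-coil reference spectrum: the coil basis, labelled "RC".

    Stands in for an experimentally measured unfolded-peptide spectrum;
    synthetic, with the canonical deep negative band near 198 nm.
    """
    basis = basis or default_basis()
    return CDSpectrum(grid=basis.grid, values=basis.spectrum("coil"), label="RC")


@dataclass(frozen=True)
class MeltSeries:
    """Temperature-indexed spectra with optional generation ground truth.

    ``truth[i]`` is the (core three-class structure, random-coil fraction)
    pair used to generate ``spectra[i]``; absent for experimental data.
    """

    temperatures_C: tuple[float, ...]
    spectra: tuple[CDSpectrum, ...]
    truth: tuple[tuple[StructureFractions3, float], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.temperatures_C) != len(self.spectra):
            raise ValueError("temperatures and spectra lengths differ")
        if self.truth is not None and len(self.truth) != len(self.spectra):
            raise ValueError("truth length differs from spectra")
        t = np.asarray(self.temperatures_C)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spectra)

    @classmethod
    def from_spectra(cls, spectra: Sequence[CDSpectrum]) -> "MeltSeries":
        """Assemble a series from labelled spectra carrying temperatures."""
        pairs = []
        for s in spectra:
            if s.temperature_C is None:
                raise ValueError(f"spectrum {s.label!r} has no temperature")
            pairs.append((s.temperature_C, s))
        pairs.sort(key=lambda p: p[0])
        return cls(
            temperatures_C=tuple(p[0] for p in pairs),
            spectra=tuple(p[1] for p in pairs),
        )


def make_melting_series(
    core: StructureFractions3,
    f_schedule: Mapping[float, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    basis: BasisSet | None = None,
    helix_melt: float = 0.0,
) -> MeltSeries:
    """Simulate a thermal melt as a two-state core/random-coil mixture.

    ``f_schedule`` maps temperature (°C) to the random-coil fraction f at
    that temperature; spectrum(T) = (1−f)·core + f·RC + noise. With
    ``helix_melt`` > 0 the core itself loses that fraction of its helix
    (linearly in temperature rank, moved into "other"), emulating
    proteins whose folded remainder also degrades on heating.
    """
    basis = basis or default_basis()
    rng = np.random.default_rng(seed)
    rc = basis.spectrum("coil")
    temps = sorted(f_schedule)
    spectra, truth = [], []
    for k, T in enumerate(temps):
        f = float(f_schedule[T])
        if not (0.0 <= f < 1.0):
            raise ValueError(f"random-coil fraction {f} at {T} °C outside [0, 1)")
        decay = helix_melt * (k / max(len(temps) - 1, 1))
        core_T = StructureFractions3(
            helix=core.helix * (1.0 - decay),
            sheet=core.sheet,
            other=core.other + core.helix * decay,
        )
        values = (1.0 - f) * basis.from_core3(core_T) + f * rc
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=values.size)
        spectra.append(
            CDSpectrum(
                grid=basis.grid,
                values=values,
                label=f"melt_{T:g}C",
                temperature_C=float(T),
            )
        )
        truth.append((core_T, f))
    return MeltSeries(
        temperatures_C=tuple(float(t) for t in temps),
        spectra=tuple(spectra),
        truth=tuple(truth),
    )
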