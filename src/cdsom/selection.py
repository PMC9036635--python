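"""Candidate filtering, ranking, and the β_II ambiguity inspection.

The sweep leaves several low-NRMSD candidates whose structures can
differ sharply; an expert resolves such ties by overlaying spectra
between 210 and 190 nm (where is the zero crossing? do the extrema
align?) and by asking *which* reference proteins the best matching units
actually are. β_II proteins are the critical case: their β-sheet CD looks
like an unfolded/polyproline-II spectrum, so whenever a β_II protein is a
BMU the apparent β-sheet may equally be random coil or PPII. This module
automates the bookkeeping for that judgement: an inclusive NRMSD gate, a
ranking that surfaces near-ties as "co-optimal" rather than silently
resolving them, and an :class:`InspectionReport` with BMU neighbour
names, the β_II flag and shape diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .derand import DerandCandidate
from .refset_io import DEFAULT_BETA2_NAMES, ReferenceSet
from .som import TrainedMap
from .spectra import CDSpectrum

__all__ = [
    "ShapeDiagnostics",
    "InspectionReport",
    "BETA2_CAVEAT",
    "filter_candidates",
    "rank_candidates",
    "zero_crossings",
    "inspect",
]

BETA2_CAVEAT = (
    "β-sheet here may be β_II, random coil or polyproline II — "
    "spectroscopically indistinguishable"
)

#: window (nm) over which shape diagnostics are computed
SHAPE_WINDOW = (190.0, 210.0)


@dataclass(frozen=True)
class ShapeDiagnostics:
    """Where the spectra cross zero and peak between 190 and 210 nm."""

    zero_crossings_exp: tuple[float, ...]
    zero_crossings_fit: tuple[float, ...]
    max_exp: tuple[float, float]  # (wavelength nm, Δε)
    min_exp: tuple[float, float]
    max_fit: tuple[float, float]
    min_fit: tuple[float, float]


@dataclass(frozen=True)
class InspectionReport:
    """What a reviewer needs to accept or override an automatic choice."""

    candidate: DerandCandidate
    bmu_reference_names: tuple[str, ...]
    beta2_flag: bool
    shape: ShapeDiagnostics
    caveat: str | None

    def to_dict(self) -> dict:
        return {
            "f_rc": self.candidate.f_rc,
            "nrmsd": self.candidate.fit.nrmsd_value,
            "regenerated": {
                "helix": self.candidate.regenerated_structure.helix,
                "sheet": self.candidate.regenerated_structure.sheet,
                "other": self.candidate.regenerated_structure.other,
            },
            "bmu_reference_names": list(self.bmu_reference_names),
            "beta2_flag": self.beta2_flag,
            "zero_crossings_exp_nm": list(self.shape.zero_crossings_exp),
            "zero_crossings_fit_nm": list(self.shape.zero_crossings_fit),
            "max_exp": self.shape.max_exp,
            "min_exp": self.shape.min_exp,
            "max_fit": self.shape.max_fit,
            "min_fit": self.shape.min_fit,
            "caveat": self.caveat,
        }


def filter_candidates(
    candidates: Sequence[DerandCandidate], threshold: float = 0.03
) -> list[DerandCandidate]:
    """Keep candidates with NRMSD ≤ threshold, order preserved.

    The bound is inclusive: the convention is to *discount* fits with
    NRMSD strictly above the gate, so a fit at exactly 0.03 survives.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return [c for c in candidates if c.fit.nrmsd_value <= threshold]


def rank_candidates(
    candidates: Sequence[DerandCandidate], co_optimal_rtol: float = 0.15
) -> list[DerandCandidate]:
    """Sort ascending by NRMSD, near-ties surfaced rather than hidden.

    Exact NRMSD ties break toward the smaller RC fraction. Candidates
    whose NRMSD is within ``co_optimal_rtol`` (relative) of the best are
    marked ``co_optimal`` so a reviewer knows the automatic minimum was
    not a clear-cut choice.
    """
    ranked = sorted(candidates, key=lambda c: (c.fit.nrmsd_value, c.f_rc))
    if ranked:
        bound = ranked[0].fit.nrmsd_value * (1.0 + co_optimal_rtol)
        for c in ranked:
            c.co_optimal = c.fit.nrmsd_value <= bound
    return ranked


def zero_crossings(
    spectrum: CDSpectrum, lo_nm: float = SHAPE_WINDOW[0], hi_nm: float = SHAPE_WINDOW[1]
) -> list[float]:
    """Wavelengths where Δε crosses zero in [lo, hi], by linear interpolation.

    A grid point exactly at zero counts once; crossings are returned in
    ascending wavelength order.
    """
    wl = spectrum.grid.wavelengths[::-1]
    v = spectrum.values[::-1]
    sel = (wl >= lo_nm - 1e-9) & (wl <= hi_nm + 1e-9)
    wl, v = wl[sel], v[sel]
    out: list[float] = []
    for i in range(len(v) - 1):
        a, b = v[i], v[i + 1]
        if a == 0.0:
            out.append(float(wl[i]))
        elif a * b < 0:
            out.append(float(wl[i] + (wl[i + 1] - wl[i]) * a / (a - b)))
    if len(v) and v[-1] == 0.0:
        out.append(float(wl[-1]))
    return out


def _extrema(spectrum: CDSpectrum) -> tuple[tuple[float, float], tuple[float, float]]:
    wl = spectrum.grid.wavelengths
    sel = (wl >= SHAPE_WINDOW[0] - 1e-9) & (wl <= SHAPE_WINDOW[1] + 1e-9)
    if not sel.any():  # spectrum lies outside the diagnostic window
        sel = np.ones(wl.size, dtype=bool)
    w, v = wl[sel], spectrum.values[sel]
    i_max, i_min = int(np.argmax(v)), int(np.argmin(v))
    return (float(w[i_max]), float(v[i_max])), (float(w[i_min]), float(v[i_min]))


def inspect(
    candidate: DerandCandidate,
    beta2_names: Iterable[str] = DEFAULT_BETA2_NAMES,
    refset: ReferenceSet | None = None,
    trained: TrainedMap | None = None,
) -> InspectionReport:
    """Build the ambiguity report for one candidate.

    BMU neighbour names come from the candidate's fit; the β_II flag is
    set when any of them appears in ``beta2_names`` (case-insensitive, or
    in the reference set's own flags when ``refset``/``trained`` carry
    them). Shape diagnostics compare the derandomized (experimental)
    spectrum against the predicted one in the 190–210 nm window.
    """
    names = tuple(candidate.fit.neighbour_references)
    listed = {n.strip().lower() for n in beta2_names}
    if refset is not None:
        listed |= {e.name.strip().lower() for e in refset.entries if e.beta2}
    if trained is not None:
        listed |= {
            n.strip().lower()
            for n, b in zip(trained.ref_names, trained.ref_beta2)
            if b
        }
    flag = any(n.strip().lower() in listed for n in names)

    exp_s = candidate.derand_spectrum
    fit_s = candidate.fit.predicted_spectrum
    max_e, min_e = _extrema(exp_s)
    max_f, min_f = _extrema(fit_s)
    shape = ShapeDiagnostics(
        zero_crossings_exp=tuple(zero_crossings(exp_s)),
        zero_crossings_fit=tuple(zero_crossings(fit_s)),
        max_exp=max_e,
        min_exp=min_e,
        max_fit=max_f,
        min_fit=min_f,
    )
    return InspectionReport(
        candidate=candidate,
        bmu_reference_names=names,
        beta2_flag=flag,
        shape=shape,
        caveat=BETA2_CAVEAT if flag else None,
    )
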