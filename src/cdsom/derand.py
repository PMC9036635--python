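"""Random-coil derandomization, the fraction sweep, and regeneration.

A spectrum of a partially unfolded protein is modelled as a mixture

    Δε_exp(λ) = (1 − f)·Δε_core(λ) + f·Δε_RC(λ)

of a folded "core" and a random-coil (RC) component, all in per-molar-
residue units so chain lengths cancel. Derandomization inverts the
mixture for a trial fraction f:

    Δε_derand(λ) = (Δε_exp(λ) − f·Δε_RC(λ)) / (1 − f)

The sweep tries f = 0%, 10%, …, 90%, fits each derandomized spectrum on
the trained map, and keeps the NRMSD of every fit. Regeneration converts
the core's fitted three-class structure back to the original protein:

    helix' = (1−f)·helix,  sheet' = (1−f)·sheet,  other' = (1−f)·other + f

so e.g. a 77%-helix core seen after removing 20% RC regenerates to a
62%-helix original. Applied per temperature of a melting series this
produces the standard results table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .som import FitResult, TrainedMap, predict
from .spectra import CDSpectrum, GridMismatchError, StructureFractions3
from .synth import MeltSeries

__all__ = [
    "DEFAULT_FRACTIONS",
    "DerandCandidate",
    "TemperatureResult",
    "derandomize",
    "regenerate",
    "sweep",
    "refine_fractions",
    "analyze_series",
]

#: 0% is included so the plain, un-derandomized fit always competes.
DEFAULT_FRACTIONS: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(10))

DEFAULT_NRMSD_THRESHOLD = 0.03


@dataclass
class DerandCandidate:
    """One sweep point: trial RC fraction, its fit, and both structures.

    ``derand_structure`` describes the derandomized (core) spectrum;
    ``regenerated_structure`` the original protein after the RC fraction
    is added back. At f_rc = 0 the two coincide.
    """

    f_rc: float
    derand_spectrum: CDSpectrum
    fit: FitResult
    derand_structure: StructureFractions3
    regenerated_structure: StructureFractions3
    co_optimal: bool = False


@dataclass(frozen=True)
class TemperatureResult:
    """Per-temperature outcome of a melting-series analysis."""

    temperature_C: float
    candidates: tuple[DerandCandidate, ...]
    accepted: tuple[DerandCandidate, ...]
    best: DerandCandidate | None
    status: str  # "ok" or "no acceptable fit"


def derandomize(exp: CDSpectrum, rc: CDSpectrum, f_rc: float) -> CDSpectrum:
    """Subtract an RC fraction and renormalise: (exp − f·rc)/(1 − f)."""
    if exp.grid != rc.grid:
        raise GridMismatchError(f"spectrum grid {exp.grid} != RC grid {rc.grid}")
    if not (0.0 <= f_rc < 1.0):
        raise ValueError(f"random-coil fraction must be in [0, 1), got {f_rc}")
    if f_rc == 0.0:
        return exp
    values = (exp.values - f_rc * rc.values) / (1.0 - f_rc)
    pct = int(round(f_rc * 100))
    return CDSpectrum(
        grid=exp.grid,
        values=values,
        label=f"{exp.label}-{pct}%RC" if exp.label else f"-{pct}%RC",
        temperature_C=exp.temperature_C,
    )


def regenerate(derand: StructureFractions3, f_rc: float) -> StructureFractions3:
    """Add the RC fraction back into a fitted core structure.

    Helix and sheet scale by (1 − f); the removed coil returns as
    "other", so the output still sums to 1.
    """
    if not (0.0 <= f_rc < 1.0):
        raise ValueError(f"random-coil fraction must be in [0, 1), got {f_rc}")
    return StructureFractions3(
        helix=(1.0 - f_rc) * derand.helix,
        sheet=(1.0 - f_rc) * derand.sheet,
        other=(1.0 - f_rc) * derand.other + f_rc,
    )


def sweep(
    exp: CDSpectrum,
    rc: CDSpectrum,
    trained: TrainedMap,
    fractions: Sequence[float] | None = None,
) -> list[DerandCandidate]:
    """Derandomize → fit → regenerate at every trial fraction, in order."""
    if fractions is None:
        fractions = DEFAULT_FRACTIONS
    out = []
    for f in fractions:
        ds = derandomize(exp, rc, f)
        fit = predict(trained, ds)
        d3 = fit.structure3
        out.append(
            DerandCandidate(
                f_rc=float(f),
                derand_spectrum=ds,
                fit=fit,
                derand_structure=d3,
                regenerated_structure=regenerate(d3, f),
            )
        )
    return out


def refine_fractions(center: float, halfwidth: float = 0.1, step: float = 0.05) -> list[float]:
    """A fine sweep grid around a winning fraction, clipped to [0, 1)."""
    lo = max(center - halfwidth, 0.0)
    hi = min(center + halfwidth, 0.999)
    n = int(round((hi - lo) / step))
    return [round(lo + i * step, 10) for i in range(n + 1)]


def analyze_series(
    series: MeltSeries,
    rc: CDSpectrum,
    trained: TrainedMap,
    fractions: Sequence[float] | None = None,
    nrmsd_threshold: float = DEFAULT_NRMSD_THRESHOLD,
    refine: bool = False,
) -> list[TemperatureResult]:
    """Run the sweep at every temperature of a melting series.

    Per temperature: full sweep, threshold filter (inclusive at the
    bound), automatic best = lowest NRMSD among accepted candidates with
    co-optimal near-ties marked for human review. When nothing passes the
    gate the row is flagged "no acceptable fit" and carries no structures.
    With ``refine`` a second sweep at 5% steps around the winner is
    appended and the selection redone.
    """
    from .selection import filter_candidates, rank_candidates  # cycle-free at call time

    results = []
    for T, spectrum in zip(series.temperatures_C, series.spectra):
        cands = sweep(spectrum, rc, trained, fractions)
        if refine:
            ranked = rank_candidates(cands)
            fine = refine_fractions(ranked[0].f_rc)
            known = {round(c.f_rc, 10) for c in cands}
            extra = [f for f in fine if round(f, 10) not in known]
            cands = cands + sweep(spectrum, rc, trained, extra)
        accepted = filter_candidates(cands, nrmsd_threshold)
        if accepted:
            best = rank_candidates(accepted)[0]
            status = "ok"
        else:
            best, status = None, "no acceptable fit"
        results.append(
            TemperatureResult(
                temperature_C=float(T),
                candidates=tuple(cands),
                accepted=tuple(accepted),
                best=best,
                status=status,
            )
        )
    return results
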