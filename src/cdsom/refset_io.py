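"""Column-oriented CSV/TXT I/O for reference sets, test spectra and results.

File dialect
------------
Both reference and test files are comma-separated with one spectrum per
column:

* row 1 is a header: ``wavelength_nm`` followed by one name per spectrum;
* the next ``len(grid)`` rows are spectral rows, first cell the wavelength
  (descending), remaining cells Δε per molar residue;
* reference files append ``n_structures`` structure rows (default 5, in
  the fixed order helix, sheet, turn, bend, loop), labelled in the first
  cell.

Test-spectrum column headers ending in a temperature (``BSA_70C``,
``70 C``, ``70°C``) have it parsed into ``CDSpectrum.temperature_C``.

β_II membership is supplied as a sidecar text file, one reference name per
line (``#`` comments allowed); the default list holds the classic β_II
proteins α-chymotrypsin, chymotrypsinogen and elastase.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra import (
    CDSpectrum,
    StructureFractions5,
    WavelengthGrid,
    resample_to_grid,
)

__all__ = [
    "ReferenceEntry",
    "ReferenceSet",
    "DEFAULT_BETA2_NAMES",
    "read_reference_set",
    "write_reference_set",
    "read_test_spectra",
    "write_test_spectra",
    "read_beta2_names",
    "write_results_table",
]

STRUCTURE_ROW_LABELS = ("helix", "sheet", "turn", "bend", "loop")
WAVELENGTH_HEADER = "wavelength_nm"

#: β_II proteins whose CD spectra resemble unfolded/polyproline-II spectra.
DEFAULT_BETA2_NAMES = ("alpha-chymotrypsin", "chymotrypsinogen", "elastase")

_TEMPERATURE_RE = re.compile(r"(\d+(?:\.\d+)?)\s*°?\s*C$", re.IGNORECASE)


@dataclass(frozen=True)
class ReferenceEntry:
    """One reference protein: spectrum + 5-class annotation + identity."""

    spectrum: CDSpectrum
    structure: StructureFractions5
    name: str
    index: int  # 1-based position in the input file; drives map legends
    beta2: bool = False

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"reference index must be >= 1, got {self.index}")


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered collection of reference entries on one shared grid."""

    entries: tuple[ReferenceEntry, ...]
    grid: WavelengthGrid
    n_structures: int = 5

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("reference set is empty")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("reference entry names are not unique")
        for e in self.entries:
            if e.spectrum.grid != self.grid:
                raise ValueError(
                    f"entry {e.name!r} is on grid {e.spectrum.grid}, "
                    f"reference set expects {self.grid}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def spectra_matrix(self) -> np.ndarray:
        """(n_entries, n_wavelengths) matrix of Δε values."""
        return np.stack([e.spectrum.values for e in self.entries])

    def structures_matrix(self) -> np.ndarray:
        """(n_entries, 5) matrix of structure fractions."""
        return np.stack([e.structure.as_array() for e in self.entries])

    def with_beta2(self, beta2_names: Iterable[str]) -> "ReferenceSet":
        """Return a copy with β_II flags set from a name list (case-insensitive)."""
        wanted = {n.strip().lower() for n in beta2_names}
        entries = tuple(
            ReferenceEntry(
                spectrum=e.spectrum,
                structure=e.structure,
                name=e.name,
                index=e.index,
                beta2=e.name.strip().lower() in wanted,
            )
            for e in self.entries
        )
        return ReferenceSet(entries=entries, grid=self.grid, n_structures=self.n_structures)


def _read_columns(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, header=0, dtype=str, skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a wavelength column plus spectra")
    return df

def _numeric_block(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    data = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if data.isna().any().any():
        col = data.columns[data.isna().any()][0]
        row = int(data.index[data[col].isna()][0])
        raise ValueError(
            f"{path}: non-numeric cell in column {col!r}, data row {row + 1}"
        )
    return data


def _infer_grid(wl_cells: Sequence[str], path: Path) -> WavelengthGrid:
    try:
        wl = np.array([float(c) for c in wl_cells])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric wavelength cell: {exc}") from None
    return WavelengthGrid.from_wavelengths(wl)


def read_reference_set(
    path: str | Path,
    n_structures: int = 5,
    grid: WavelengthGrid | None = None,
    beta2_names: Iterable[str] = DEFAULT_BETA2_NAMES,
) -> ReferenceSet:
    """Read a column-oriented reference file.

    Each column must carry ``len(grid) + n_structures`` numeric rows;
    ragged or non-numeric columns and out-of-range structure fractions are
    reported with column name and row. The grid is inferred from the
    wavelength column when present, otherwise taken from ``grid``.
    """
    path = Path(path)
    df = _read_columns(path)
    has_wl = df.columns[0].strip().lower() in {"wavelength", "wavelength_nm", "lambda", "nm"}
    if not has_wl:
        raise ValueError(
            f"{path}: first column must be the wavelength column "
            f"(header {WAVELENGTH_HEADER!r}), got {df.columns[0]!r}"
        )
    n_rows = df.shape[0]
    n_spec = n_rows - n_structures
    if grid is not None and n_spec != len(grid):
        raise ValueError(
            f"{path}: column has {n_spec} spectral rows, grid demands {len(grid)}"
        )
    if n_spec < 2:
        raise ValueError(f"{path}: too few spectral rows ({n_spec})")
    file_grid = _infer_grid(df.iloc[:n_spec, 0].tolist(), path)
    if grid is None:
        grid = file_grid
    elif file_grid != grid:
        raise ValueError(f"{path}: wavelength column {file_grid} != requested {grid}")

    data = _numeric_block(df, path)
    wanted_beta2 = {n.strip().lower() for n in beta2_names}
    entries = []
    for j, name in enumerate(data.columns, start=1):
        col = data[name].to_numpy()
        spec = CDSpectrum(grid=grid, values=col[:n_spec], label=str(name))
        frac = col[n_spec:]
        bad = np.where((frac < -1e-6) | (frac > 1 + 1e-6))[0]
        if bad.size:
            k = int(bad[0])
            raise ValueError(
                f"{path}: structure fraction {frac[k]} outside [0,1] in column "
                f"{name!r}, structure row {STRUCTURE_ROW_LABELS[k] if k < 5 else k + 1}"
            )
        structure = StructureFractions5.from_array(frac) if n_structures == 5 else None
        if structure is None:
            raise ValueError("only 5-class structure annotations are supported")
        entries.append(
            ReferenceEntry(
                spectrum=spec,
                structure=structure,
                name=str(name),
                index=j,
                beta2=str(name).strip().lower() in wanted_beta2,
            )
        )
    return ReferenceSet(entries=tuple(entries), grid=grid, n_structures=n_structures)


def write_reference_set(refset: ReferenceSet, path: str | Path) -> None:
    """Write the column dialect read by :func:`read_reference_set`.

    Round-trips losslessly: values survive to better than 1e-12 and names,
    order and indices exactly.
    """
    path = Path(path)
    wl = refset.grid.wavelengths
    first_col = [f"{w:g}" for w in wl] + list(STRUCTURE_ROW_LABELS[: refset.n_structures])
    cols = {WAVELENGTH_HEADER: first_col}
    for e in refset.entries:
        cols[e.name] = np.concatenate([e.spectrum.values, e.structure.as_array()])
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def _parse_temperature(label: str) -> float | None:
    m = _TEMPERATURE_RE.search(label.strip())
    return float(m.group(1)) if m else None


def read_test_spectra(path: str | Path, grid: WavelengthGrid) -> list[CDSpectrum]:
    """Read test spectra (no structure rows) onto the reference grid.

    The file's wavelength range must cover the target grid; a finer or
    coarser step is linearly resampled, an insufficient span raises
    :class:`~cdsom.spectra.SpanError`. Column headers become labels and a
    trailing temperature (``70C``) is parsed into ``temperature_C``.
    """
    path = Path(path)
    df = _read_columns(path)
    file_grid = _infer_grid(df.iloc[:, 0].tolist(), path)
    data = _numeric_block(df, path)
    out = []
    for name in data.columns:
        spec = CDSpectrum(
            grid=file_grid,
            values=data[name].to_numpy(),
            label=str(name),
            temperature_C=_parse_temperature(str(name)),
        )
        out.append(resample_to_grid(spec, grid))
    return out


def write_test_spectra(spectra: Sequence[CDSpectrum], path: str | Path) -> None:
    """Write test spectra in the same column dialect (no structure rows)."""
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0].grid
    for s in spectra:
        if s.grid != grid:
            raise ValueError("all spectra must share one grid")
    cols = {WAVELENGTH_HEADER: [f"{w:g}" for w in grid.wavelengths]}
    for s in spectra:
        cols[s.label or f"spectrum_{len(cols)}"] = s.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_beta2_names(path: str | Path) -> list[str]:
    """Read a β_II sidecar: one reference name per line, ``#`` comments."""
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            names.append(line)
    return names


RESULTS_COLUMNS = [
    "temperature_C",
    "best_nrmsd",
    "rc_added_pct",
    "derand_helix",
    "derand_sheet",
    "derand_other",
    "regen_helix",
    "regen_sheet",
    "regen_other",
    "status",
]


def write_results_table(rows: Sequence, path: str | Path) -> None:
    """Write a melting-series results table.

    ``rows`` are per-temperature summaries (``derand.TemperatureResult``).
    Columns: temperature, best NRMSD, RC added (%), derandomized
    helix/sheet/other, regenerated helix/sheet/other, status. The
    derandomized cells are left empty when RC added is 0% — at 0% the
    "derandomized" spectrum is just the original, so the regenerated
    columns already carry its structure.
    """
    records = []
    for row in rows:
        rec = dict.fromkeys(RESULTS_COLUMNS, "")
        rec["temperature_C"] = row.temperature_C
        rec["status"] = row.status
        best = row.best
        if best is not None:
            rec["best_nrmsd"] = round(best.fit.nrmsd_value, 4)
            rec["rc_added_pct"] = int(round(best.f_rc * 100))
            if best.f_rc > 0:
                rec["derand_helix"] = round(best.derand_structure.helix, 2)
                rec["derand_sheet"] = round(best.derand_structure.sheet, 2)
                rec["derand_other"] = round(best.derand_structure.other, 2)
            rec["regen_helix"] = round(best.regenerated_structure.helix, 2)
            rec["regen_sheet"] = round(best.regenerated_structure.sheet, 2)
            rec["regen_other"] = round(best.regenerated_structure.other, 2)
        records.append(rec)
    pd.DataFrame(records, columns=RESULTS_COLUMNS).to_csv(path, index=False)
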