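"""Self-organising map (Kohonen) engine for CD spectral fitting.

A rectangular map of prototype spectra is trained with the classical
online Kohonen rule so that similar spectral shapes land on nearby nodes.
Each node then receives a five-class structure annotation as an
inverse-map-distance weighted mean of the structures of the reference
proteins occupying its neighbourhood. An unknown spectrum is fitted by its
``k`` best matching units (BMUs): the predicted structure and predicted
spectrum are inverse-distance weighted means over those nodes, and the
fit quality is the NRMSD between query and predicted spectrum.

Determinism contract: given the same seed, configuration and reference
set, training produces a bit-identical map; ties in every distance sort
are broken lexicographically by (row, col).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .refset_io import ReferenceSet
from .spectra import (
    CDSpectrum,
    GridMismatchError,
    StructureFractions3,
    StructureFractions5,
    WavelengthGrid,
    collapse_structure,
    nrmsd,
)

__all__ = [
    "SOMConfig",
    "TrainedMap",
    "BMUMatch",
    "FitResult",
    "train_som",
    "assign_node_structures",
    "find_bmus",
    "predict",
    "map_layout",
    "save_map",
    "load_map",
]


@dataclass(frozen=True)
class SOMConfig:
    """Training and prediction settings.

    Defaults follow the standard workflow for CD fitting: a 50×50 map,
    5 BMUs per prediction, 100 passes over the reference set with learning
    rate decaying 0.5 → 0.01 and Gaussian neighbourhood radius decaying
    from half the map size to 1 node.
    """

    rows: int = 50
    cols: int = 50
    k_bmu: int = 5
    epochs: int = 100
    lr_initial: float = 0.5
    lr_final: float = 0.01
    radius_initial: float | None = None  # None -> max(rows, cols) / 2
    radius_final: float = 1.0
    seed: int = 0
    n_structure_neighbours: int = 5
    neighbour_radius: float = 3.0  # map radius for BMU neighbour reporting

    def __post_init__(self) -> None:
        if min(self.rows, self.cols, self.k_bmu, self.epochs) < 1:
            raise ValueError("rows, cols, k_bmu and epochs must all be >= 1")
        if not (self.lr_initial >= self.lr_final > 0):
            raise ValueError("need lr_initial >= lr_final > 0")
        r0 = self.effective_radius_initial
        if not (r0 >= self.radius_final >= 0):
            raise ValueError("need radius_initial >= radius_final >= 0")

    @property
    def effective_radius_initial(self) -> float:
        if self.radius_initial is not None:
            return self.radius_initial
        # half the map span, but never below the final radius (tiny maps)
        return max(self.rows, self.cols, 2 * self.radius_final) / 2.0


@dataclass
class TrainedMap:
    """A trained map: prototype spectra, node structures, occupancy.

    ``node_weights`` has shape (rows, cols, n_wavelengths);
    ``node_structures`` (rows, cols, 5) or None before
    :func:`assign_node_structures`; ``occupancy[i]`` is the (row, col)
    winning node of reference entry ``i`` (file order), which is what the
    numbered map layouts display.
    """

    config: SOMConfig
    grid: WavelengthGrid
    node_weights: np.ndarray
    node_structures: np.ndarray | None
    occupancy: np.ndarray  # (n_refs, 2) int
    ref_names: tuple[str, ...]
    ref_beta2: tuple[bool, ...]
    quantization_error: float = float("nan")

    @property
    def n_nodes(self) -> int:
        return self.config.rows * self.config.cols

    def flat_weights(self) -> np.ndarray:
        return self.node_weights.reshape(self.n_nodes, -1)

    def node_coords(self) -> np.ndarray:
        """(n_nodes, 2) array of (row, col) in row-major (lexicographic) order."""
        r, c = np.unravel_index(
            np.arange(self.n_nodes), (self.config.rows, self.config.cols)
        )
        return np.column_stack([r, c])


@dataclass(frozen=True)
class BMUMatch:
    node: tuple[int, int]
    distance: float
    rank: int


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one query spectrum against a trained map."""

    predicted_spectrum: CDSpectrum
    structure5: StructureFractions5
    structure3: StructureFractions3
    nrmsd_value: float
    bmus: tuple[BMUMatch, ...]
    neighbour_references: tuple[str, ...]


def _check_refset(refset: ReferenceSet) -> np.ndarray:
    X = refset.spectra_matrix()
    if not np.all(np.isfinite(X)):
        raise ValueError("reference set contains non-finite spectra")
    return X


def train_som(refset: ReferenceSet, config: SOMConfig) -> TrainedMap:
    """Train the map with online Kohonen updates.

    Per sample: find the BMU, then pull every node toward the sample with
    strength lr(t)·exp(−d²_map / 2σ(t)²), where d_map is Euclidean
    distance in node coordinates and both the learning rate lr and the
    radius σ decay exponentially from their initial to final values over
    the run. Weights are initialised uniformly within the per-wavelength
    min/max envelope of the reference spectra (seeded), and sample order
    is reshuffled each epoch (same RNG stream).
    """
    X = _check_refset(refset)
    n, L = X.shape
    rng = np.random.default_rng(config.seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    W = rng.uniform(size=(config.rows * config.cols, L)) * (hi - lo) + lo
    coords = np.column_stack(
        np.unravel_index(np.arange(W.shape[0]), (config.rows, config.cols))
    ).astype(float)

    total = config.epochs * n
    lr0, lr1 = config.lr_initial, config.lr_final
    s0 = max(config.effective_radius_initial, 1e-6)
    s1 = max(config.radius_final, 1e-6)
    t = 0
    for _ in range(config.epochs):
        for i in rng.permutation(n):
            frac = t / max(total - 1, 1)
            lr = lr0 * (lr1 / lr0) ** frac
            sigma = s0 * (s1 / s0) ** frac
            x = X[i]
            d2 = np.einsum("ij,ij->i", W - x, W - x)
            bmu = int(np.argmin(d2))  # row-major argmin == (row, col) lexicographic
            d2map = np.einsum("ij,ij->i", coords - coords[bmu], coords - coords[bmu])
            h = lr * np.exp(-d2map / (2.0 * sigma * sigma))
            W += h[:, None] * (x - W)
            t += 1

    # Final occupancy and quantisation error from the converged weights.
    d2_all = (
        np.einsum("ij,ij->i", X, X)[:, None]
        - 2.0 * X @ W.T
        + np.einsum("ij,ij->i", W, W)[None, :]
    )
    winners = np.argmin(d2_all, axis=1)
    occupancy = np.column_stack(
        np.unravel_index(winners, (config.rows, config.cols))
    ).astype(int)
    qe = float(np.mean(np.sqrt(np.maximum(d2_all[np.arange(n), winners], 0.0))))

    trained = TrainedMap(
        config=config,
        grid=refset.grid,
        node_weights=W.reshape(config.rows, config.cols, L),
        node_structures=None,
        occupancy=occupancy,
        ref_names=tuple(e.name for e in refset.entries),
        ref_beta2=tuple(e.beta2 for e in refset.entries),
        quantization_error=qe,
    )
    return assign_node_structures(
        trained, refset, n_neighbours=min(config.n_structure_neighbours, n)
    )


def assign_node_structures(
    trained: TrainedMap, refset: ReferenceSet, n_neighbours: int = 5
) -> TrainedMap:
    """Attach a five-class structure to every node.

    Each node's structure is the inverse-map-distance weighted mean of the
    structures of the ``n_neighbours`` reference entries whose occupancy
    nodes lie nearest in map coordinates; ties in map distance are broken
    by spectral distance between the node's prototype and the reference
    spectrum. References at map distance 0 (the node hosts them) take all
    the weight, shared equally if several coincide.
    """
    if n_neighbours > len(refset):
        raise ValueError(
            f"n_neighbours {n_neighbours} exceeds reference set size {len(refset)}"
        )
    X = refset.spectra_matrix()
    S = refset.structures_matrix()
    occ = trained.occupancy.astype(float)
    coords = trained.node_coords().astype(float)
    W = trained.flat_weights()

    # (n_nodes, n_refs) squared distances, in map space and spectral space.
    d2map = (
        np.einsum("ij,ij->i", coords, coords)[:, None]
        - 2.0 * coords @ occ.T
        + np.einsum("ij,ij->i", occ, occ)[None, :]
    )
    d2map = np.maximum(d2map, 0.0)
    d2spec = (
        np.einsum("ij,ij->i", W, W)[:, None]
        - 2.0 * W @ X.T
        + np.einsum("ij,ij->i", X, X)[None, :]
    )

    structures = np.empty((trained.n_nodes, S.shape[1]))
    for node in range(trained.n_nodes):
        order = np.lexsort((d2spec[node], d2map[node]))[:n_neighbours]
        d = np.sqrt(d2map[node, order])
        zero = d < 1e-12
        if zero.any():
            w = zero.astype(float)
        else:
            w = 1.0 / d
        w /= w.sum()
        structures[node] = w @ S[order]

    return replace(
        trained,
        node_structures=structures.reshape(
            trained.config.rows, trained.config.cols, -1
        ),
    )


def _query_distances(trained: TrainedMap, query: CDSpectrum) -> np.ndarray:
    if query.grid != trained.grid:
        raise GridMismatchError(
            f"query grid {query.grid} != map grid {trained.grid}"
        )
    diff = trained.flat_weights() - query.values
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def find_bmus(trained: TrainedMap, query: CDSpectrum, k: int) -> list[BMUMatch]:
    """The ``k`` nodes nearest the query in spectral (Euclidean) distance.

    Ties are broken lexicographically by (row, col), which for row-major
    node order is simply the node index.
    """
    if k > trained.n_nodes:
        raise ValueError(f"k={k} exceeds node count {trained.n_nodes}")
    d = _query_distances(trained, query)
    order = np.lexsort((np.arange(d.size), d))[:k]
    coords = trained.node_coords()
    return [
        BMUMatch(node=(int(coords[i, 0]), int(coords[i, 1])), distance=float(d[i]), rank=r)
        for r, i in enumerate(order, start=1)
    ]


def _inverse_distance_weights(distances: np.ndarray) -> np.ndarray:
    zero = distances < 1e-12
    if zero.any():
        w = zero.astype(float)
    else:
        w = 1.0 / distances
    return w / w.sum()


def predict(trained: TrainedMap, query: CDSpectrum) -> FitResult:
    """Fit a query spectrum via its ``k_bmu`` best matching units.

    The predicted structure and spectrum are inverse-distance weighted
    means over the BMU nodes (weight_i = (1/d_i)/Σ(1/d_j); a zero
    distance takes all the weight). ``neighbour_references`` lists the
    reference proteins whose occupancy nodes fall within
    ``config.neighbour_radius`` map units of any BMU — the information a
    β_II inspection needs.
    """
    if trained.node_structures is None:
        raise ValueError("map has no node structures; call assign_node_structures")
    bmus = find_bmus(trained, query, trained.config.k_bmu)
    idx = np.array(
        [b.node[0] * trained.config.cols + b.node[1] for b in bmus], dtype=int
    )
    d = np.array([b.distance for b in bmus])
    w = _inverse_distance_weights(d)

    flat_struct = trained.node_structures.reshape(trained.n_nodes, -1)
    s5 = StructureFractions5.from_array(w @ flat_struct[idx])
    pred_values = w @ trained.flat_weights()[idx]
    pred = CDSpectrum(
        grid=trained.grid,
        values=pred_values,
        label=f"fit:{query.label}" if query.label else "fit",
        temperature_C=query.temperature_C,
    )

    bmu_coords = np.array([b.node for b in bmus], dtype=float)
    occ = trained.occupancy.astype(float)
    neighbour: list[tuple[float, str]] = []
    for i, name in enumerate(trained.ref_names):
        dmap = np.sqrt(((bmu_coords - occ[i]) ** 2).sum(axis=1)).min()
        if dmap <= trained.config.neighbour_radius:
            neighbour.append((dmap, name))
    neighbour.sort(key=lambda t: t[0])

    return FitResult(
        predicted_spectrum=pred,
        structure5=s5,
        structure3=collapse_structure(s5),
        nrmsd_value=nrmsd(query, pred),
        bmus=tuple(bmus),
        neighbour_references=tuple(name for _, name in neighbour),
    )


def map_layout(
    trained: TrainedMap, fit: FitResult | None = None
) -> dict:
    """Plottable layout records for the numbered map figure.

    Returns ``references`` as (index, name, row, col) for every reference
    entry (indices are the 1-based file order), ``bmus`` as
    (rank, row, col) when a fit is supplied, and the map ``extent``.
    """
    refs = [
        (i + 1, name, int(trained.occupancy[i, 0]), int(trained.occupancy[i, 1]))
        for i, name in enumerate(trained.ref_names)
    ]
    bmus = (
        [(b.rank, b.node[0], b.node[1]) for b in fit.bmus] if fit is not None else []
    )
    return {
        "references": refs,
        "bmus": bmus,
        "extent": (trained.config.rows, trained.config.cols),
    }


def save_map(trained: TrainedMap, path: str | Path) -> None:
    """Persist a trained map to a single portable JSON file."""
    payload = {
        "format": "cdsom-map-v1",
        "config": asdict(trained.config),
        "grid": {
            "start_nm": trained.grid.start_nm,
            "end_nm": trained.grid.end_nm,
            "step_nm": trained.grid.step_nm,
        },
        "node_weights": trained.node_weights.tolist(),
        "node_structures": (
            trained.node_structures.tolist()
            if trained.node_structures is not None
            else None
        ),
        "occupancy": trained.occupancy.tolist(),
        "ref_names": list(trained.ref_names),
        "ref_beta2": list(trained.ref_beta2),
        "quantization_error": trained.quantization_error,
    }
    Path(path).write_text(json.dumps(payload))


def load_map(path: str | Path) -> TrainedMap:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "cdsom-map-v1":
        raise ValueError(f"{path}: not a cdsom map file")
    return TrainedMap(
        config=SOMConfig(**payload["config"]),
        grid=WavelengthGrid(**payload["grid"]),
        node_weights=np.asarray(payload["node_weights"], dtype=float),
        node_structures=(
            np.asarray(payload["node_structures"], dtype=float)
            if payload["node_structures"] is not None
            else None
        ),
        occupancy=np.asarray(payload["occupancy"], dtype=int),
        ref_names=tuple(payload["ref_names"]),
        ref_beta2=tuple(payload["ref_beta2"]),
        quantization_error=float(payload["quantization_error"]),
    )
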