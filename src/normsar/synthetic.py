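"""Synthetic surface-modifier molecules with planted structure-activity labels.

Real nano-SAR datasets pair small organic surface modifiers (5-30 heavy
atoms of C/N/O/S plus hydrogens, tree-like with occasional rings) with a
measured cellular-uptake endpoint.  This module emulates that shape with
known ground truth: molecules are random valence-respecting trees with
optional ring closures, embedded in 3D at standard bond lengths, and labels
are drawn from a logistic model on a small planted subset of the norm-index
descriptors plus noise.  Every stage of the pipeline can then be tested
against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import DESCRIPTOR_NAMES, descriptor_table
from .pipeline import LabeledDataset, SplitResult, binarize_uptake, split_dataset
from .structure_io import EndpointTable, Molecule, assign_charges, _TABLE

__all__ = [
    "LabelModel",
    "SyntheticConfig",
    "StudyShapedData",
    "generate_molecules",
    "plant_labels",
    "emulate_study_shape",
]

# standard single-bond lengths in Angstrom; other pairs fall back to the sum
# of covalent radii
_BOND_LENGTHS = {
    frozenset({"C", "C"}): 1.54,
    frozenset({"C", "N"}): 1.47,
    frozenset({"C", "O"}): 1.43,
    frozenset({"C", "S"}): 1.81,
}
_H_BOND_LENGTH = 1.09
_COORD_JITTER_SD = 0.05  # Angstrom


@dataclass(frozen=True)
class LabelModel:
    """Planted logistic structure-activity relationship.

    Labels depend on standardized values of the named descriptors through
    ``logistic(intercept + coefficients . z)``, then flip with probability
    ``flip_probability`` (label noise).
    """

    descriptors: tuple[str, ...] = (
        "EM3_DM1_P4_norm1",
        "EM3_DM2_P1_norm1",
        "EM3_DM1_P1_norm1",
    )
    coefficients: tuple[float, ...] = (6.0, 4.0, 4.0)
    intercept: float = 0.0
    flip_probability: float = 0.05

    def __post_init__(self) -> None:
        if len(self.descriptors) != len(self.coefficients):
            raise ValueError("descriptors and coefficients must align")
        if not 0 <= self.flip_probability < 0.5:
            raise ValueError("flip probability must be in [0, 0.5)")
        unknown = set(self.descriptors) - set(DESCRIPTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown planted descriptor(s): {sorted(unknown)}")


@dataclass(frozen=True)
class SyntheticConfig:
    n_molecules: int = 109
    heavy_atom_range: tuple[int, int] = (5, 30)
    element_weights: dict = field(
        default_factory=lambda: {"C": 0.6, "N": 0.15, "O": 0.15, "S": 0.1}
    )
    ring_probability: float = 0.3
    seed: int = 0
    label_model: LabelModel = field(default_factory=LabelModel)

    def __post_init__(self) -> None:
        if abs(sum(self.element_weights.values()) - 1.0) > 1e-9:
            raise ValueError("element weights must sum to 1")
        lo, hi = self.heavy_atom_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid heavy-atom range")


def _bond_length(a: str, b: str) -> float:
    if "H" in (a, b):
        return _H_BOND_LENGTH
    key = frozenset({a, b})
    if key in _BOND_LENGTHS:
        return _BOND_LENGTHS[key]
    return _TABLE[a]["covalent_radius"] + _TABLE[b]["covalent_radius"]


def _random_direction(rng: np.random.Generator, avoid: list[np.ndarray], tries: int = 24) -> np.ndarray:
    """Unit vector, rejection-sampled away from already used directions."""
    best, best_score = None, -np.inf
    for _ in range(tries):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        score = -max((float(v @ u) for u in avoid), default=-1.0)
        if score > best_score:
            best, best_score = v, score
        if best_score > 0.5:  # > 60 degrees from every existing neighbor
            break
    return best


def _graph_distances(n: int, adj: list[set[int]], source: int) -> np.ndarray:
    d = np.full(n, -1)
    d[source] = 0
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if d[v] < 0:
                    d[v] = d[u] + 1
                    nxt.append(v)
        frontier = nxt
    return d


def _build_one(rng: np.random.Generator, cfg: SyntheticConfig, mol_id: str) -> Molecule:
    lo, hi = cfg.heavy_atom_range
    n_heavy = int(rng.integers(lo, hi + 1))
    symbols = list(cfg.element_weights)
    weights = np.array([cfg.element_weights[s] for s in symbols])

    elements: list[str] = []
    bonds: set[tuple[int, int]] = set()
    free: list[int] = []  # remaining valence per heavy atom

    def draw_element() -> str:
        return symbols[int(rng.choice(len(symbols), p=weights))]

    # random tree by uniform attachment to an atom with spare valence
    elements.append(draw_element())
    free.append(_TABLE[elements[0]]["valence"])
    for _ in range(1, n_heavy):
        candidates = [i for i, f in enumerate(free) if f > 0]
        if not candidates:
            break  # all valences saturated (e.g. early O-O chain); molecule stays smaller
        parent = int(rng.choice(candidates))
        el = draw_element()
        idx = len(elements)
        elements.append(el)
        free.append(_TABLE[el]["valence"] - 1)
        free[parent] -= 1
        bonds.add((parent, idx))

    n_heavy = len(elements)
    adj: list[set[int]] = [set() for _ in range(n_heavy)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)

    # optional ring closure between spare-valence atoms at graph distance >= 3
    if n_heavy >= 4 and rng.random() < cfg.ring_probability:
        spare = [i for i, f in enumerate(free) if f > 0]
        rng.shuffle(spare)
        for a in spare:
            dist = _graph_distances(n_heavy, adj, a)
            partners = [b for b in spare if b != a and dist[b] >= 3]
            if partners:
                b = int(rng.choice(partners))
                bonds.add((min(a, b), max(a, b)))
                adj[a].add(b)
                adj[b].add(a)
                free[a] -= 1
                free[b] -= 1
                break

    # hydrogens fill the remaining valences
    heavy_count = n_heavy
    for i in range(heavy_count):
        for _ in range(free[i]):
            idx = len(elements)
            elements.append("H")
            bonds.add((i, idx))

    coords = _embed(rng, elements, bonds)
    mol = Molecule(id=mol_id, elements=elements, bonds=bonds, coords=coords)
    return assign_charges(mol.validate())


def _embed(rng: np.random.Generator, elements: list[str], bonds: set[tuple[int, int]]) -> np.ndarray:
    """Deterministic tree-walk placement at standard bond lengths with jitter.

    Atoms are placed breadth-first from atom 0; each atom sits at its
    parent's position plus a direction chosen away from the parent's already
    placed neighbors.  Ring-closing bonds do not constrain the geometry —
    the layout aims for physical plausibility, not a relaxed conformer.
    """
    n = len(elements)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in sorted(bonds):
        adj[i].append(j)
        adj[j].append(i)
    coords = np.zeros((n, 3))
    placed = np.zeros(n, dtype=bool)
    placed[0] = True
    frontier = [0]
    while frontier:
        u = frontier.pop(0)
        used = [
            (coords[v] - coords[u]) / np.linalg.norm(coords[v] - coords[u])
            for v in adj[u]
            if placed[v] and np.linalg.norm(coords[v] - coords[u]) > 1e-9
        ]
        for v in adj[u]:
            if placed[v]:
                continue
            direction = _random_direction(rng, used)
            used.append(direction)
            length = _bond_length(elements[u], elements[v])
            coords[v] = coords[u] + direction * length + rng.normal(0.0, _COORD_JITTER_SD, 3)
            placed[v] = True
            frontier.append(v)
    return coords


def generate_molecules(cfg: SyntheticConfig) -> list[Molecule]:
    """Generate ``cfg.n_molecules`` validated molecules, reproducibly per seed."""
    rng = np.random.default_rng(cfg.seed)
    return [_build_one(rng, cfg, f"syn{idx:04d}") for idx in range(cfg.n_molecules)]


def _standardized_scores(X: pd.DataFrame, model: LabelModel) -> np.ndarray:
    """Linear predictor of the planted model on column-standardized descriptors."""
    score = np.full(len(X), model.intercept, dtype=float)
    for name, coef in zip(model.descriptors, model.coefficients):
        col = X[name].to_numpy(float)
        sd = col.std(ddof=0)
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        score += coef * z
    return score


def plant_labels(
    molecules: list[Molecule],
    cfg: SyntheticConfig,
    max_retries: int = 8,
    descriptors: pd.DataFrame | None = None,
) -> LabeledDataset:
    """Descriptor matrix plus labels drawn from the planted logistic model.

    If a draw collapses to a single class, the intercept is re-centered on
    the median score and the draw repeated (bounded retries).  Pass a
    precomputed ``descriptors`` table to avoid recomputing it when drawing
    many label realizations for the same molecules.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    X = descriptor_table(molecules) if descriptors is None else descriptors
    model = cfg.label_model
    base = _standardized_scores(X, model) - model.intercept
    intercept = model.intercept
    for _ in range(max_retries):
        p = 1.0 / (1.0 + np.exp(-(base + intercept)))
        y = (rng.random(len(p)) < p).astype(int)
        flips = rng.random(len(p)) < model.flip_probability
        y[flips] = 1 - y[flips]
        if 0 < y.sum() < len(y):
            return LabeledDataset(
                X=X.reset_index(drop=True),
                y=y,
                ids=list(X.index),
                planted=tuple(model.descriptors),
            )
        intercept = -float(np.median(base))
    raise RuntimeError("could not plant a two-class labeling within the retry budget")


def calibrate_intercept(base_scores: np.ndarray, target_positive_fraction: float) -> float:
    """Bisection on the intercept so expected positives hit the target."""
    lo, hi = -50.0, 50.0
    target = target_positive_fraction * len(base_scores)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        expected = (1.0 / (1.0 + np.exp(-(base_scores + mid)))).sum()
        if expected < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class StudyShapedData:
    """A 109-sample stand-in with the study's exact shape and class balance."""

    dataset: LabeledDataset
    split: SplitResult
    endpoint_table: EndpointTable
    planted: tuple[str, ...]


_UPTAKE_MIN, _UPTAKE_MAX = 2.23, 4.44
_UPTAKE_CUT = np.log10(5000.0)


def emulate_study_shape(seed: int, cfg: SyntheticConfig | None = None) -> StudyShapedData:
    """109 molecules, exactly 59 positive / 50 negative, pre-split 89 / 20.

    The 59 samples with the largest planted linear scores are labeled
    positive (a rank threshold — the exact realization of tuning the
    intercept to the target balance), then label noise flips a matched
    number of positives and negatives (rate ~ ``flip_probability``) so the
    balance stays exact.  A continuous uptake value (log10 particles per
    cell) is emitted alongside, affinely mapped from the noisy label side
    so that binarization at 5000 particles per cell recovers the same
    59 / 50 labels inside the study's 2.23-4.44 range.
    """
    if cfg is None:
        cfg = SyntheticConfig(n_molecules=109, seed=seed)
    elif cfg.n_molecules != 109:
        raise ValueError("the study shape has exactly 109 samples")
    molecules = generate_molecules(cfg)
    X = descriptor_table(molecules)
    rng = np.random.default_rng(cfg.seed + 1)
    score = _standardized_scores(X, cfg.label_model) - cfg.label_model.intercept
    order = np.argsort(-score)
    y = np.zeros(len(score), dtype=int)
    y[order[:59]] = 1
    # balance-preserving label noise: flip k positives and k negatives, with
    # 2k/109 matching the configured flip probability in expectation
    k = int(rng.binomial(54, cfg.label_model.flip_probability))
    if k:
        pos = rng.choice(np.where(y == 1)[0], size=k, replace=False)
        neg = rng.choice(np.where(y == 0)[0], size=k, replace=False)
        y[pos], y[neg] = 0, 1

    uptake = np.empty(len(score))
    pos, neg = y == 1, y == 0
    uptake[pos] = _rescale(score[pos], _UPTAKE_CUT + 0.01, _UPTAKE_MAX)
    uptake[neg] = _rescale(score[neg], _UPTAKE_MIN, _UPTAKE_CUT - 0.01)
    assert (binarize_uptake(uptake) == y).all()

    dataset = LabeledDataset(
        X=X.reset_index(drop=True), y=y, ids=list(X.index), planted=tuple(cfg.label_model.descriptors)
    )
    split = split_dataset(dataset, test_fraction=20 / 109, seed=seed, stratified=True)
    table = EndpointTable(ids=list(X.index), uptake=uptake)
    return StudyShapedData(dataset=dataset, split=split, endpoint_table=table,
                           planted=tuple(cfg.label_model.descriptors))


def _rescale(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    vmin, vmax = values.min(), values.max()
    if vmax - vmin < 1e-12:
        return np.full_like(values, 0.5 * (lo + hi))
    return lo + (values - vmin) * (hi - lo) / (vmax - vmin)
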