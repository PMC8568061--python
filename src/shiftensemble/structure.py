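"""Conformer ensembles: contact maps, secondary structure, clustering.

The analyses here validate a weighted ensemble after regression: residue
contact maps from Cα–Cα distances (7.5 Å cutoff), per-residue secondary-
structure proportions P_i(ζ) over the five STRIDE-style classes, the
β-core set B (residues with >50 % β-sheet) and per-conformer β fractions
P_n, the AB-loop distance observable, and PCA + k-means clustering of the
predicted ensemble in contact-map space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

# Secondary-structure classes (STRIDE-style five-state alphabet).
ALPHA = "alpha-helix"
BETA = "beta-sheet"
HELIX310 = "310-helix"
COIL = "coil"
TURN = "turn"
SS_CLASSES: tuple[str, ...] = (ALPHA, BETA, HELIX310, COIL, TURN)

#: Default one-letter code mapping (STRIDE/DSSP) onto the five classes.
DEFAULT_SS_CODE_MAP: dict[str, str] = {
    "H": ALPHA, "G": HELIX310, "E": BETA, "B": BETA, "b": BETA,
    "T": TURN, "I": ALPHA,
}

#: Cα–Cα contact cutoff in Å.
DEFAULT_CONTACT_CUTOFF: float = 7.5

BACKBONE_ATOMS: tuple[str, ...] = ("N", "H", "CA", "C", "O", "CB")


@dataclass
class ConformerEnsemble:
    """Ordered set of conformers sharing one residue list.

    ``coords[atom]`` has shape ``(n_conformers, n_residues, 3)`` in Å;
    missing atoms are NaN.  Cα must be present and finite everywhere.
    """

    conformer_ids: tuple[str, ...]
    residues: tuple[tuple[int, str], ...]
    coords: dict[str, np.ndarray]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if "CA" not in self.coords:
            raise ValueError("ensemble must carry CA coordinates")
        shape = (len(self.conformer_ids), len(self.residues), 3)
        for atom, arr in self.coords.items():
            if arr.shape != shape:
                raise ValueError(f"{atom} coordinate array has shape {arr.shape}, "
                                 f"expected {shape}")
        if not np.isfinite(self.coords["CA"]).all():
            raise ValueError("CA coordinates contain non-finite entries")

    @property
    def n_conformers(self) -> int:
        return len(self.conformer_ids)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def residue_numbers(self) -> tuple[int, ...]:
        return tuple(r for r, _ in self.residues)

    def residue_index(self, number: int) -> int:
        try:
            return self.residue_numbers.index(number)
        except ValueError:
            raise KeyError(f"residue {number} not in ensemble") from None

    def conformer(self, i: int) -> dict[str, np.ndarray]:
        return {atom: arr[i] for atom, arr in self.coords.items()}

    def subset(self, indices: Sequence[int],
               ids: Sequence[str] | None = None) -> "ConformerEnsemble":
        indices = list(indices)
        return ConformerEnsemble(
            conformer_ids=tuple(ids) if ids is not None
            else tuple(self.conformer_ids[i] for i in indices),
            residues=self.residues,
            coords={a: arr[indices] for a, arr in self.coords.items()},
            weights=None if self.weights is None else self.weights[indices],
        )


@dataclass(frozen=True)
class ContactMap:
    """Boolean residue-contact matrix from Cα–Cα distances."""

    residue_numbers: tuple[int, ...]
    matrix: np.ndarray
    cutoff: float = DEFAULT_CONTACT_CUTOFF

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or not np.array_equal(m, m.T):
            raise ValueError("contact matrix must be square and symmetric")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        return self.matrix[iu].astype(float)


@dataclass(frozen=True)
class SecondaryStructureProfile:
    """Per-residue class proportions and β-core statistics."""

    residue_numbers: tuple[int, ...]
    proportions: pd.DataFrame            # residues x SS_CLASSES
    beta_core: tuple[int, ...]           # B = {i : P_i(beta) > 0.5}
    per_conformer_beta: np.ndarray       # P_n over the core
    class_proportions: Mapping[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Ensemble I/O (multi-model PDB via biotite)
# ---------------------------------------------------------------------------

def read_ensemble(path: str | Path, chain: str | None = None) -> ConformerEnsemble:
    """Read a multi-model PDB file into a :class:`ConformerEnsemble`."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if stack.array_length() == 0:
        raise ValueError(f"{path}: no atoms")
    mask = bst.filter_amino_acids(stack)
    stack = stack[..., mask]
    if chain is None:
        chain = str(stack.chain_id[0])
    stack = stack[..., stack.chain_id == chain]

    res_ids = stack.res_id
    order = sorted(set(int(r) for r in res_ids))
    names = {}
    for r in order:
        names[r] = str(stack.res_name[res_ids == r][0])
    residues = tuple((r, names[r]) for r in order)
    n_models, n_res = stack.stack_depth(), len(order)
    coords: dict[str, np.ndarray] = {
        a: np.full((n_models, n_res, 3), np.nan) for a in BACKBONE_ATOMS}
    for k, r in enumerate(order):
        res_mask = res_ids == r
        for atom in BACKBONE_ATOMS:
            sel = res_mask & (stack.atom_name == atom)
            idx = np.flatnonzero(sel)
            if idx.size:
                coords[atom][:, k, :] = stack.coord[:, idx[0], :]
    coords = {a: arr for a, arr in coords.items() if np.isfinite(arr).any()}
    if "CA" not in coords or not np.isfinite(coords["CA"]).all():
        raise ValueError(f"{path}: CA missing for some residue/model")
    ids = tuple(f"model{m + 1}" for m in range(n_models))
    return ConformerEnsemble(conformer_ids=ids, residues=residues, coords=coords)


def write_ensemble(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB file."""
    atoms_per_res = [a for a in BACKBONE_ATOMS if a in ensemble.coords]
    records = []
    for k, (rnum, rname) in enumerate(ensemble.residues):
        for atom in atoms_per_res:
            if np.isfinite(ensemble.coords[atom][0, k]).all():
                records.append((k, rnum, rname, atom))
    n_atoms = len(records)
    array = bst.AtomArray(n_atoms)
    array.chain_id = np.array(["A"] * n_atoms)
    array.res_id = np.array([r for _, r, _, _ in records])
    array.res_name = np.array([n for _, _, n, _ in records])
    array.atom_name = np.array([a for _, _, _, a in records])
    array.element = np.array([a[0] for _, _, _, a in records])
    array.hetero = np.zeros(n_atoms, dtype=bool)
    stack = bst.stack([array] * ensemble.n_conformers)
    coord = np.empty((ensemble.n_conformers, n_atoms, 3))
    for j, (k, _, _, atom) in enumerate(records):
        coord[:, j, :] = ensemble.coords[atom][:, k, :]
    stack.coord = coord
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

def contact_map(conformer: Mapping[str, np.ndarray] | ConformerEnsemble,
                index: int = 0,
                cutoff: float = DEFAULT_CONTACT_CUTOFF) -> ContactMap:
    """Cα–Cα contact map; entry true iff distance < cutoff (strict)."""
    if isinstance(conformer, ConformerEnsemble):
        ca = conformer.coords["CA"][index]
        residue_numbers = conformer.residue_numbers
    else:
        ca = np.asarray(conformer["CA"], dtype=float)
        residue_numbers = tuple(range(1, ca.shape[0] + 1))
    diff = ca[:, None, :] - ca[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    return ContactMap(residue_numbers=tuple(residue_numbers),
                      matrix=dist < cutoff, cutoff=cutoff)


def loop_distance(conformer: Mapping[str, np.ndarray] | ConformerEnsemble,
                  res_a: int = 17, res_b: int = 24, atom: str = "CA",
                  index: int = 0) -> float:
    """Distance (Å) between one atom of two residues — the AB-loop observable.

    Defaults to the Cα separation of residues 17 and 24.
    """
    if isinstance(conformer, ConformerEnsemble):
        ia, ib = conformer.residue_index(res_a), conformer.residue_index(res_b)
        xa = conformer.coords[atom][index, ia]
        xb = conformer.coords[atom][index, ib]
    else:
        xa = np.asarray(conformer[atom], dtype=float)[res_a - 1]
        xb = np.asarray(conformer[atom], dtype=float)[res_b - 1]
    if not (np.isfinite(xa).all() and np.isfinite(xb).all()):
        raise ValueError(f"{atom} missing for residue {res_a} or {res_b}")
    return float(np.linalg.norm(xa - xb))


# ---------------------------------------------------------------------------
# Secondary structure: external parsers
# ---------------------------------------------------------------------------

def read_ss_assignments(path: str | Path, format: str,
                        code_map: Mapping[str, str] | None = None) -> np.ndarray:
    """Parse STRIDE or DSSP report(s) into per-conformer class labels.

    Several conformer blocks may be concatenated in one file (STRIDE: a
    residue-number reset starts a new block; DSSP: each ``#  RESIDUE``
    header starts a new block).  Returns an array of shape
    ``(n_conformers, n_residues)`` with labels from the five-class
    alphabet; unknown one-letter codes map to coil with a warning.
    """
    code_map = dict(DEFAULT_SS_CODE_MAP if code_map is None else code_map)
    text = Path(path).read_text()
    if format == "stride":
        blocks = _parse_stride(text)
    elif format == "dssp":
        blocks = _parse_dssp(text)
    else:
        raise ValueError(f"unknown assignment format {format!r}")
    if not blocks:
        raise ValueError(f"{path}: no assignment records found")
    lengths = {len(b) for b in blocks}
    if len(lengths) != 1:
        raise ValueError(f"{path}: conformer blocks disagree on residue count "
                         f"({sorted(lengths)})")

    def to_label(code: str) -> str:
        label = code_map.get(code)
        if label is None and code not in (" ", "C", "-", "~"):
            logger.warning("unknown secondary-structure code %r -> coil", code)
        return label or COIL

    return np.array([[to_label(code) for _, code in block] for block in blocks])


def _parse_stride(text: str) -> list[list[tuple[int, str]]]:
    blocks: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    last = None
    for line in text.splitlines():
        if not line.startswith("ASG"):
            continue
        fields = line.split()
        resnum, code = int(fields[3]), fields[5]
        if last is not None and resnum <= last:
            blocks.append(current)
            current = []
        current.append((resnum, code))
        last = resnum
    if current:
        blocks.append(current)
    return blocks


def _parse_dssp(text: str) -> list[list[tuple[int, str]]]:
    blocks: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] | None = None
    for line in text.splitlines():
        if line.lstrip().startswith("#") and "RESIDUE" in line:
            if current:
                blocks.append(current)
            current = []
            continue
        if current is None or len(line) < 17:
            continue
        resnum_field = line[5:10].strip()
        if not resnum_field:           # chain break line
            continue
        code = line[16] if len(line) > 16 else " "
        current.append((int(resnum_field), code))
    if current:
        blocks.append(current)
    return blocks


# ---------------------------------------------------------------------------
# Secondary structure: built-in geometric assigner
# ---------------------------------------------------------------------------

# Cα distance windows (Å) derived from ideal backbone geometry:
# alpha-helix  d(i,i+3) ~ 5.2, d(i,i+4) ~ 6.4
# 3_10-helix   d(i,i+3) ~ 6.0, d(i,i+4) ~ 8.6
# extended     d(i,i+2) ~ 6.6
_ALPHA_D3 = (4.4, 5.7)
_ALPHA_D4 = (5.5, 7.3)
_H310_D3 = (5.7, 6.5)
_H310_D4 = (7.6, 9.6)
_EXTENDED_D2_MIN = 6.2
_BRIDGE_CUTOFF = 5.5
_TURN_D3_MAX = 7.0


def assign_ss_builtin(conformer: Mapping[str, np.ndarray] | ConformerEnsemble,
                      index: int = 0) -> np.ndarray:
    """Approximate secondary-structure labels from Cα geometry alone.

    Helices are detected from (i, i+3)/(i, i+4) Cα distance signatures;
    β-sheet requires an extended residue *and* a nonlocal spatial bridge
    partner that is itself extended, so an isolated extended chain is
    never labelled sheet; chain reversals without helical geometry are
    turns; everything else is coil.  Approximate by construction — not a
    STRIDE/DSSP replacement.
    """
    if isinstance(conformer, ConformerEnsemble):
        ca = conformer.coords["CA"][index]
    else:
        ca = np.asarray(conformer["CA"], dtype=float)
    n = ca.shape[0]
    labels = np.array([COIL] * n, dtype=object)

    def d(i, j):
        return float(np.linalg.norm(ca[i] - ca[j]))

    helical = np.zeros(n, dtype=bool)
    helix_type = np.array([""] * n, dtype=object)
    for j in range(n - 4):
        d3, d4 = d(j, j + 3), d(j, j + 4)
        if _ALPHA_D3[0] <= d3 <= _ALPHA_D3[1] and _ALPHA_D4[0] <= d4 <= _ALPHA_D4[1]:
            helical[j:j + 5] = True
            helix_type[j:j + 5] = ALPHA
        elif _H310_D3[0] <= d3 <= _H310_D3[1] and _H310_D4[0] <= d4 <= _H310_D4[1]:
            for k in range(j, j + 5):
                if helix_type[k] != ALPHA:
                    helix_type[k] = HELIX310
            helical[j:j + 5] = True

    extended = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        if d(i - 1, i + 1) > _EXTENDED_D2_MIN:
            extended[i] = True

    dist = np.sqrt(((ca[:, None, :] - ca[None, :, :]) ** 2).sum(-1))
    sheet = np.zeros(n, dtype=bool)
    for i in range(n):
        if not extended[i] or helical[i]:
            continue
        partners = np.flatnonzero((dist[i] < _BRIDGE_CUTOFF)
                                  & (np.abs(np.arange(n) - i) >= 3))
        if any(extended[j] and not helical[j] for j in partners):
            sheet[i] = True

    for i in range(n):
        if helical[i]:
            labels[i] = helix_type[i]
        elif sheet[i]:
            labels[i] = BETA
    for i in range(n - 3):
        if d(i, i + 3) < _TURN_D3_MAX:
            for k in range(i, i + 4):
                if labels[k] == COIL:
                    labels[k] = TURN
    return labels


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

def ss_proportions(assignments: np.ndarray,
                   residue_numbers: Sequence[int] | None = None,
                   weights: np.ndarray | None = None,
                   core: Iterable[int] | None = None) -> SecondaryStructureProfile:
    """Per-residue class proportions P_i(ζ) and β-core statistics.

    ``assignments`` is ``(n_conformers, n_residues)`` labels.  With
    *weights*, P_i(ζ) is the weight-fraction of conformers in class ζ
    (weights normalised to sum 1); otherwise the plain count fraction.
    B is the set of residues with P_i(β-sheet) strictly above 0.5; the
    per-conformer β fraction P_n is counted over B (or over *core*, a
    user-supplied residue subset, when given).
    """
    assignments = np.asarray(assignments, dtype=object)
    n_conf, n_res = assignments.shape
    if residue_numbers is None:
        residue_numbers = tuple(range(1, n_res + 1))
    residue_numbers = tuple(int(r) for r in residue_numbers)
    if weights is None:
        w = np.full(n_conf, 1.0 / n_conf)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    props = pd.DataFrame(0.0, index=list(residue_numbers), columns=list(SS_CLASSES))
    for cls in SS_CLASSES:
        props[cls] = ((assignments == cls) * w[:, None]).sum(axis=0)
    beta_core = tuple(r for r, p in zip(residue_numbers, props[BETA]) if p > 0.5)
    core_set = tuple(core) if core is not None else beta_core
    if core_set:
        cols = [residue_numbers.index(r) for r in core_set]
        per_conf = (assignments[:, cols] == BETA).mean(axis=1)
    else:
        per_conf = np.zeros(n_conf)
    class_props = {cls: float((props[cls] * 1.0).mean()) for cls in SS_CLASSES}
    return SecondaryStructureProfile(
        residue_numbers=residue_numbers, proportions=props,
        beta_core=beta_core, per_conformer_beta=per_conf,
        class_proportions=class_props)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

class ContactMapClusterer(BaseEstimator):
    """PCA + k-means clustering of an ensemble in contact-map space.

    Each supported conformer is flattened to the upper triangle of its
    Cα–Cα contact map; a weighted PCA (rows weighted by the ensemble
    weights) projects onto ``n_components`` axes and k-means partitions
    the scores.  Deterministic given ``random_state``.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster label per supported conformer.
    embedding_ : ndarray of shape (n_supported, n_components)
        PCA scores.
    explained_variance_ : ndarray
        Weighted variance captured by each component (non-increasing).
    representatives_ : dict
        ``label -> index`` of the highest-weight member of each cluster
        (index into the supported set).
    """

    def __init__(self, n_clusters: int = 2, n_components: int = 2,
                 cutoff: float = DEFAULT_CONTACT_CUTOFF, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_components = n_components
        self.cutoff = cutoff
        self.random_state = random_state

    def fit(self, X, sample_weight: np.ndarray | None = None):
        """Fit on an ensemble or a precomputed (n, d) contact-feature matrix."""
        if isinstance(X, ConformerEnsemble):
            features = np.stack([
                contact_map(X, i, cutoff=self.cutoff).upper_triangle()
                for i in range(X.n_conformers)])
            if sample_weight is None and X.weights is not None:
                sample_weight = X.weights
        else:
            features = np.asarray(X, dtype=float)
        n = features.shape[0]
        if sample_weight is None:
            w = np.full(n, 1.0 / n)
        else:
            w = np.asarray(sample_weight, dtype=float)
        supported = np.flatnonzero(w > 0)
        if self.n_clusters > supported.size:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds the {supported.size} "
                "supported conformers")
        feats, w = features[supported], w[supported]
        w = w / w.sum()

        mean = w @ feats
        centred = feats - mean
        _, s, vt = np.linalg.svd(np.sqrt(w)[:, None] * centred,
                                 full_matrices=False)
        k = min(self.n_components, vt.shape[0])
        self.components_ = vt[:k]
        self.explained_variance_ = (s[:k] ** 2)
        self.mean_ = mean
        embedding = centred @ vt[:k].T
        km = KMeans(n_clusters=self.n_clusters, n_init=10,
                    random_state=self.random_state)
        km.fit(embedding, sample_weight=w)
        self.supported_indices_ = supported
        self.embedding_ = embedding
        self.labels_ = km.labels_
        self.cluster_centers_ = km.cluster_centers_
        self.cluster_weights_ = np.array([
            w[km.labels_ == c].sum() for c in range(self.n_clusters)])
        self.representatives_ = {
            int(c): int(np.flatnonzero(km.labels_ == c)[
                np.argmax(w[km.labels_ == c])])
            for c in range(self.n_clusters)}
        return self

    def fit_predict(self, X, sample_weight=None) -> np.ndarray:
        return self.fit(X, sample_weight=sample_weight).labels_


def cluster_ensemble(ensemble: ConformerEnsemble, weights, k: int,
                     n_components: int = 2,
                     cutoff: float = DEFAULT_CONTACT_CUTOFF,
                     seed: int = 0) -> ContactMapClusterer:
    """Functional wrapper over :class:`ContactMapClusterer`."""
    w = np.asarray(getattr(weights, "weights", weights), dtype=float)
    return ContactMapClusterer(n_clusters=k, n_components=n_components,
                               cutoff=cutoff, random_state=seed
                               ).fit(ensemble, sample_weight=w)


def silhouette(embedding: np.ndarray, labels: np.ndarray) -> float:
    """Silhouette score helper for choosing k (never applied automatically)."""
    return float(silhouette_score(embedding, labels))
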