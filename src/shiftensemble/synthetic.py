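"""Synthetic fixtures for every stage of the pipeline.

Stands in for the enhanced-sampling structural library, the shift
predictor and the NMR reference: toy backbone ensembles built from ideal
helix/strand/coil segments, per-conformer shift tables generated from a
random-coil baseline plus secondary-structure offsets, regression targets
constructed as known convex mixtures plus Gaussian noise, and
diffusion-in-a-cone N–H vector ensembles with known motional amplitude
(closed-form S² = [cos α (1 + cos α) / 2]²).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .io import NUCLEI, ShiftLibrary, ShiftTable
from .structure import (ALPHA, BETA, COIL, HELIX310, TURN, ConformerEnsemble,
                        assign_ss_builtin)

# Representative random-coil backbone shifts (ppm): HN, NH, CA, CB.
# Values are typical literature-style coil shifts; tests rely only on the
# relative structure (offset signs, per-nucleus scales), not exact ppm.
RANDOM_COIL_SHIFTS: dict[str, tuple[float, float, float, float]] = {
    "ALA": (8.24, 123.8, 52.5, 19.1),
    "ARG": (8.23, 120.5, 56.0, 30.9),
    "ASN": (8.40, 118.7, 53.1, 38.9),
    "ASP": (8.34, 120.4, 54.2, 41.1),
    "CYS": (8.32, 118.8, 58.2, 28.0),
    "GLN": (8.32, 119.8, 55.7, 29.4),
    "GLU": (8.42, 120.2, 56.6, 29.9),
    "HIS": (8.42, 118.2, 55.0, 29.0),
    "ILE": (8.00, 120.9, 61.1, 38.8),
    "LEU": (8.16, 121.8, 55.1, 42.4),
    "LYS": (8.29, 120.4, 56.2, 33.1),
    "MET": (8.28, 119.6, 55.4, 32.9),
    "PHE": (8.30, 120.3, 57.7, 39.6),
    "SER": (8.31, 115.7, 58.3, 63.8),
    "THR": (8.15, 113.6, 61.8, 69.8),
    "TRP": (8.25, 121.3, 57.5, 29.6),
    "TYR": (8.12, 120.3, 57.9, 38.8),
    "VAL": (8.03, 120.3, 62.2, 32.9),
}

# Secondary-structure shift offsets (ppm) per nucleus: helices raise Cα and
# lower Cβ; sheets do the opposite.
SS_OFFSETS: dict[str, dict[str, float]] = {
    ALPHA: {"HN": -0.25, "NH": -1.5, "CA": 2.6, "CB": -0.4},
    HELIX310: {"HN": -0.15, "NH": -1.0, "CA": 1.5, "CB": -0.3},
    BETA: {"HN": 0.35, "NH": 2.0, "CA": -1.4, "CB": 2.2},
    TURN: {"HN": 0.05, "NH": 0.3, "CA": 0.2, "CB": 0.1},
    COIL: {"HN": 0.0, "NH": 0.0, "CA": 0.0, "CB": 0.0},
}

_SEQUENCE_CYCLE = ("ALA", "GLU", "LEU", "LYS", "ASP", "PHE", "SER", "VAL",
                   "THR", "ARG", "ILE", "GLN")

_DIHEDRALS = {"helix": (-57.0, -47.0), "strand": (-120.0, 120.0),
              "310": (-49.0, -26.0)}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for synthetic problems.

    Defaults describe a desk-scale analogue of the real setting: a library
    of 50 candidate conformers over 30 residues, three active states with
    populations (0.5, 0.3, 0.2), per-nucleus measurement noise a few
    percent of each nucleus's natural range, and 20° cone motion.
    """

    n_conformers: int = 50
    n_residues: int = 30
    active_weights: tuple[float, ...] = (0.5, 0.3, 0.2)
    noise_sigma: Mapping[str, float] = field(default_factory=lambda: {
        "HN": 0.02, "NH": 0.2, "CA": 0.1, "CB": 0.1})
    structural_sigma: Mapping[str, float] = field(default_factory=lambda: {
        "HN": 0.25, "NH": 2.0, "CA": 0.8, "CB": 0.8})
    #: spread of the static per-residue environment field shared by all
    #: conformers (sequence/context dispersion of real spectra)
    environment_sigma: Mapping[str, float] = field(default_factory=lambda: {
        "HN": 0.45, "NH": 3.5, "CA": 1.2, "CB": 1.5})
    motion: float = 20.0               # cone semi-angle, degrees
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.active_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("active_weights must lie on the simplex")
        if any(float(v) < 0 for v in dict(self.noise_sigma).values()):
            raise ValueError("noise_sigma must be non-negative")


# ---------------------------------------------------------------------------
# Backbone construction
# ---------------------------------------------------------------------------

def _place(a, b, c, bond, angle_deg, dihedral_deg):
    ang, dih = np.deg2rad(angle_deg), np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(dih),
                  bond * np.sin(ang) * np.sin(dih)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phis: Sequence[float], psis: Sequence[float]
                   ) -> dict[str, np.ndarray]:
    """Ideal-geometry backbone (N, H, CA, C, O, CB) from φ/ψ sequences."""
    n_res = len(phis)
    if len(psis) != n_res:
        raise ValueError("phi/psi length mismatch")
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([1.458, 0.0, 0.0])]
    C = [_place(np.array([0.0, 1.0, 0.0]), N[0], CA[0], 1.525, 111.0, 0.0)]
    for i in range(1, n_res):
        N.append(_place(N[-1], CA[-1], C[-1], 1.329, 116.6, psis[i - 1]))
        CA.append(_place(CA[-1], C[-1], N[-1], 1.458, 121.9, 180.0))
        C.append(_place(C[-1], N[-1], CA[-1], 1.525, 111.0, phis[i]))
    N, CA, C = np.array(N), np.array(CA), np.array(C)

    H = np.empty_like(N)
    for i in range(n_res):
        prev = C[i - 1] if i > 0 else CA[i] + np.array([0.0, 0.0, 1.0])
        bisector = ((N[i] - prev) / np.linalg.norm(N[i] - prev)
                    + (N[i] - CA[i]) / np.linalg.norm(N[i] - CA[i]))
        H[i] = N[i] + 1.02 * bisector / np.linalg.norm(bisector)
    O = np.empty_like(C)
    for i in range(n_res):
        # carbonyl O trans to the next amide N across the peptide plane
        O[i] = _place(N[i], CA[i], C[i], 1.23, 120.8, psis[i] + 180.0)
    CB = np.empty_like(CA)
    for i in range(n_res):
        u = (N[i] - CA[i]) / np.linalg.norm(N[i] - CA[i])
        v = (C[i] - CA[i]) / np.linalg.norm(C[i] - CA[i])
        bis = -(u + v)
        bis /= np.linalg.norm(bis)
        perp = np.cross(v, u)
        perp /= np.linalg.norm(perp)
        direction = bis * np.cos(np.deg2rad(54.75)) + perp * np.sin(np.deg2rad(54.75))
        CB[i] = CA[i] + 1.53 * direction
    return {"N": N, "H": H, "CA": CA, "C": C, "O": O, "CB": CB}


def plan_dihedrals(plan: Sequence[tuple[str, int]],
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Expand a segment plan [(kind, length), ...] into φ/ψ arrays.

    Kinds: ``helix``, ``strand``, ``310`` (fixed ideal dihedrals) and
    ``coil`` (dihedrals drawn from broad allowed regions).
    """
    phis, psis = [], []
    for kind, length in plan:
        if kind in _DIHEDRALS:
            phi, psi = _DIHEDRALS[kind]
            phis.extend([phi] * length)
            psis.extend([psi] * length)
        elif kind == "coil":
            for _ in range(length):
                phis.append(rng.uniform(-150.0, -60.0))
                psis.append(rng.choice([rng.uniform(100.0, 170.0),
                                        rng.uniform(-60.0, -20.0)]))
        else:
            raise ValueError(f"unknown segment kind {kind!r}")
    return np.asarray(phis), np.asarray(psis)


def default_plan(n_residues: int) -> list[tuple[str, int]]:
    third = n_residues // 3
    return [("helix", third), ("coil", n_residues - 2 * third), ("strand", third)]


def _adjust_pair_distance(atoms: dict[str, np.ndarray], ia: int, ib: int,
                          target: float, rng: np.random.Generator,
                          tol: float = 0.4) -> dict[str, np.ndarray]:
    """Hinge-rotate the chain tail so that |CA[ia] - CA[ib]| hits *target*.

    Scans rotation angles about random axes through a hinge Cα between the
    two residues (tracking only the moving Cα, via the Rodrigues formula),
    trying alternative hinges if the target distance is unreachable.
    """
    mid = (ia + ib) // 2
    hinges = [h for h in (mid, mid - 1, mid + 1, mid - 2, mid + 2)
              if ia <= h < ib]
    angles = np.deg2rad(np.arange(0.0, 360.0, 0.5))
    cos_t, sin_t = np.cos(angles), np.sin(angles)

    best: tuple[float, int, np.ndarray, float] | None = None  # err, hinge, axis, angle
    for hinge in hinges:
        pivot = atoms["CA"][hinge]
        p = atoms["CA"][ib] - pivot
        q = atoms["CA"][ia] - pivot
        for _ in range(20):
            k = rng.normal(size=3)
            k /= np.linalg.norm(k)
            kxp = np.cross(k, p)
            kdp = k @ p
            rotated = (np.outer(cos_t, p) + np.outer(sin_t, kxp)
                       + np.outer(1.0 - cos_t, kdp * k))
            errs = np.abs(np.linalg.norm(rotated - q, axis=1) - target)
            j = int(np.argmin(errs))
            if best is None or errs[j] < best[0]:
                best = (float(errs[j]), hinge, k, float(angles[j]))
            if best[0] <= tol:
                break
        if best is not None and best[0] <= tol:
            break

    _, hinge, axis, angle = best
    pivot = atoms["CA"][hinge]
    rot = Rotation.from_rotvec(angle * axis)
    out = {}
    for name, arr in atoms.items():
        arr = arr.copy()
        arr[hinge + 1:] = rot.apply(arr[hinge + 1:] - pivot) + pivot
        out[name] = arr
    return out


def make_toy_ensemble(spec: SyntheticSpec,
                      plan: Sequence[tuple[str, int]] | None = None,
                      loop_target: tuple[int, int, float] | None = None,
                      dihedral_jitter: float = 6.0,
                      coordinate_noise: float = 0.03) -> ConformerEnsemble:
    """Toy conformer ensemble from a secondary-structure segment plan.

    Each conformer shares the plan's helix/strand scaffold but redraws its
    coil dihedrals and adds small dihedral jitter and Gaussian coordinate
    noise, emulating a structurally diverse candidate pool.  With
    ``loop_target=(res_a, res_b, distance)`` each conformer's tail is
    hinge-rotated so the Cα pair distance matches the request.
    """
    rng = np.random.default_rng(spec.seed)
    if plan is None:
        plan = default_plan(spec.n_residues)
    n_res = sum(length for _, length in plan)
    residues = tuple((i + 1, _SEQUENCE_CYCLE[i % len(_SEQUENCE_CYCLE)])
                     for i in range(n_res))
    coords = {a: np.empty((spec.n_conformers, n_res, 3))
              for a in ("N", "H", "CA", "C", "O", "CB")}
    for c in range(spec.n_conformers):
        phis, psis = plan_dihedrals(plan, rng)
        phis = phis + rng.normal(0.0, dihedral_jitter, n_res)
        psis = psis + rng.normal(0.0, dihedral_jitter, n_res)
        atoms = build_backbone(phis, psis)
        if loop_target is not None:
            ia, ib, target = loop_target
            atoms = _adjust_pair_distance(atoms, ia - 1, ib - 1, target, rng)
        for a in coords:
            coords[a][c] = atoms[a] + rng.normal(0.0, coordinate_noise,
                                                 (n_res, 3))
    ids = tuple(f"conf{c + 1:04d}" for c in range(spec.n_conformers))
    return ConformerEnsemble(conformer_ids=ids, residues=residues, coords=coords)


# ---------------------------------------------------------------------------
# Shift tables
# ---------------------------------------------------------------------------

def _predict_shifts(ensemble: ConformerEnsemble, index: int,
                    rng: np.random.Generator,
                    structural_sigma: Mapping[str, float],
                    environment: Mapping[tuple[int, str], float]) -> ShiftTable:
    labels = assign_ss_builtin(ensemble, index)
    values: dict[tuple[int, str], float] = {}
    for k, (rnum, rname) in enumerate(ensemble.residues):
        base = RANDOM_COIL_SHIFTS.get(rname)
        if base is None:
            continue
        offsets = SS_OFFSETS[labels[k]]
        for nucleus, base_value in zip(NUCLEI, base):
            values[(rnum, nucleus)] = (
                base_value + offsets[nucleus] + environment[(rnum, nucleus)]
                + rng.normal(0.0, float(structural_sigma[nucleus])))
    return ShiftTable(entity_id=ensemble.conformer_ids[index],
                      residues=ensemble.residues, values=values)


def make_shift_library(ensemble: ConformerEnsemble,
                       spec: SyntheticSpec) -> ShiftLibrary:
    """Predictor-style shift tables, one per conformer.

    Each table is a random-coil baseline per (residue name, nucleus) plus
    a static per-residue environment field shared by all conformers
    (``environment_sigma`` — the sequence/context dispersion that gives
    real spectra their spread), the conformer's secondary-structure offset
    (from the built-in geometric assigner), and Gaussian conformational
    diversity of scale ``structural_sigma`` — the cross-conformer
    variation that makes the regression identifiable.
    """
    rng = np.random.default_rng(spec.seed + 1_000_003)
    environment = {
        (rnum, nucleus): rng.normal(0.0, float(spec.environment_sigma[nucleus]))
        for rnum, _ in ensemble.residues for nucleus in NUCLEI}
    tables = tuple(_predict_shifts(ensemble, i, rng, spec.structural_sigma,
                                   environment)
                   for i in range(ensemble.n_conformers))
    return ShiftLibrary(conformer_ids=ensemble.conformer_ids, tables=tables,
                        source="synthetic predictor")


def make_reference(library: ShiftLibrary, spec: SyntheticSpec,
                   mixture_space: str = "scaled"
                   ) -> tuple[ShiftTable, np.ndarray]:
    """Regression target built as a known convex mixture plus noise.

    Active conformers are drawn (deterministically from the seed) and the
    reference is the mixture Σ w_i X_i plus N(0, noise_sigma) per nucleus.
    With ``mixture_space="scaled"`` (default) the mixture is composed in
    the projection space of the scaling function and mapped back to ppm
    (a fixed-point iteration, since the scaling ranges derive from the
    reference itself); the noiseless target is then *exactly* recoverable
    by the regression.  ``mixture_space="ppm"`` mixes raw ppm values
    instead, in which case the log map's curvature leaves a small
    irreducible recovery bias.  Returns the reference table and the full
    ground-truth weight vector.
    """
    from .scaling import ShiftScaler

    if mixture_space not in ("scaled", "ppm"):
        raise ValueError("mixture_space must be 'scaled' or 'ppm'")
    rng = np.random.default_rng(spec.seed + 2_000_003)
    n = len(library)
    k = len(spec.active_weights)
    if k > n:
        raise ValueError("more active weights than conformers")
    active = rng.choice(n, size=k, replace=False)
    w = np.zeros(n)
    w[active] = np.asarray(spec.active_weights, dtype=float)
    noise = dict(spec.noise_sigma)
    residues = library.tables[0].residues

    keys = [(rnum, nuc) for rnum, _ in residues for nuc in NUCLEI
            if all(t.is_assigned(rnum, nuc) for t in library.tables)]
    columns = {key: np.array([t.values[key] for t in library.tables])
               for key in keys}
    mixed = {key: float(w @ col) for key, col in columns.items()}

    if mixture_space == "scaled":
        current = dict(mixed)
        for _ in range(60):
            table = ShiftTable(entity_id="tmp", residues=residues,
                               values=current)
            scaler = ShiftScaler().fit(table)
            updated = {}
            for nucleus in NUCLEI:
                nuc_keys = [key for key in keys if key[1] == nucleus]
                scaled_cols = np.stack([
                    scaler.transform(columns[key], nucleus)
                    for key in nuc_keys])          # (n_keys, n_conformers)
                target = scaler.inverse_transform(scaled_cols @ w, nucleus)
                updated.update(dict(zip(nuc_keys, target.tolist())))
            delta = max(abs(updated[key] - current[key]) for key in keys)
            current = updated
            if delta < 1e-13:
                break
        mixed = current

    values = {key: mixed[key] + rng.normal(0.0, float(noise[key[1]]))
              for key in keys}
    table = ShiftTable(entity_id="synthetic reference", residues=residues,
                       values=values)
    return table, w


# ---------------------------------------------------------------------------
# Motion models
# ---------------------------------------------------------------------------

def cone_model_s2(semi_angle_deg: float) -> float:
    """Closed-form S² of uniform wobbling in a cone of given semi-angle."""
    c = np.cos(np.deg2rad(semi_angle_deg))
    return float((c * (1.0 + c) / 2.0) ** 2)


def make_cone_ensemble(n_frames: int, semi_angles_deg: Sequence[float],
                       seed: int = 0,
                       global_rotations: bool = True) -> np.ndarray:
    """Per-frame N–H unit vectors wobbling uniformly in per-residue cones.

    Each residue has a fixed axis in the molecular frame; per frame its
    vector is drawn uniformly from the spherical cap of the given
    semi-angle, and (optionally) one uniform random global rotation is
    applied to the whole frame, emulating isotropic tumbling.  Returns an
    array of shape ``(n_frames, n_residues, 3)``.
    """
    rng = np.random.default_rng(seed)
    semi = np.deg2rad(np.asarray(semi_angles_deg, dtype=float))
    n_res = semi.size
    axes = rng.normal(size=(n_res, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    # orthonormal frames per residue
    helper = np.where(np.abs(axes[:, [0]]) < 0.9,
                      np.tile([1.0, 0.0, 0.0], (n_res, 1)),
                      np.tile([0.0, 1.0, 0.0], (n_res, 1)))
    e1 = np.cross(axes, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(axes, e1)

    cos_min = np.cos(semi)
    u = rng.uniform(cos_min, 1.0, size=(n_frames, n_res))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=(n_frames, n_res))
    sin_t = np.sqrt(np.clip(1.0 - u ** 2, 0.0, None))
    vectors = (sin_t[..., None] * (np.cos(phi)[..., None] * e1
                                   + np.sin(phi)[..., None] * e2)
               + u[..., None] * axes)
    if global_rotations:
        rots = Rotation.random(n_frames, random_state=rng)
        mats = rots.as_matrix()
        vectors = np.einsum("fab,frb->fra", mats, vectors)
    return vectors
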