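"""iRED order parameters S² for N–H bond vectors of weighted ensembles.

The weighted ensemble is first expanded into a fixed-size frame multiset
(each conformer duplicated in proportion to its weight, 1,000 frames by
default).  The isotropic reorientational eigenmode dynamics (iRED) method
then builds the matrix of ensemble-averaged second Legendre polynomials of
the inter-vector angles, M_ij = <P2(mu_i . mu_j)>, diagonalises it, and
attributes the five largest eigenmodes to overall reorientation; the
per-residue order parameter is

    S²_i = 1 - sum_{m>5} lambda_m (m_i)²

with modes sorted by descending eigenvalue.  S² is 1 for a rigid ensemble
(M has rank <= 5) and decreases with internal motion.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure import ConformerEnsemble

logger = logging.getLogger(__name__)

#: Number of eigenmodes attributed to overall reorientation.
N_OVERALL_MODES: int = 5
#: Default expanded-ensemble size.
DEFAULT_TOTAL_FRAMES: int = 1000


@dataclass(frozen=True)
class OrderParameterProfile:
    """Per-residue S² values with provenance."""

    residue_numbers: tuple[int, ...]
    s2: np.ndarray
    source: str = "ensemble"
    excluded: tuple[int, ...] = ()

    def clamped(self) -> "OrderParameterProfile":
        """Copy with S² clamped into [0, 1]."""
        return OrderParameterProfile(
            residue_numbers=self.residue_numbers,
            s2=np.clip(self.s2, 0.0, 1.0),
            source=self.source, excluded=self.excluded)

    def write_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["residue_number", "s2"])
            for r, v in zip(self.residue_numbers, self.s2):
                writer.writerow([r, repr(float(v))])

    @classmethod
    def read_csv(cls, path: str | Path,
                 source: str = "experimental") -> "OrderParameterProfile":
        residues, values = [], []
        with Path(path).open() as fh:
            for row in csv.DictReader(fh):
                residues.append(int(row["residue_number"]))
                values.append(float(row["s2"]))
        return cls(residue_numbers=tuple(residues),
                   s2=np.asarray(values), source=source)


# ---------------------------------------------------------------------------
# Ensemble expansion
# ---------------------------------------------------------------------------

def apportion_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of *total* copies to *weights*.

    Counts sum to *total* and each count is within one of ``total * w_i``;
    any conformer with weight at least ``1 / (2 * total)`` receives at
    least one copy.
    """
    w = np.asarray(weights, dtype=float)
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = total - counts.sum()
    # ties broken by index for determinism
    order = np.lexsort((np.arange(w.size), -remainder))
    counts[order[:short]] += 1
    floor_half = (quota >= 0.5) & (counts == 0)
    for i in np.flatnonzero(floor_half):
        donor = int(np.argmax(counts))
        counts[donor] -= 1
        counts[i] = 1
    return counts


def expand_ensemble(ensemble: ConformerEnsemble, weights,
                    total: int = DEFAULT_TOTAL_FRAMES) -> ConformerEnsemble:
    """Duplicate conformers in proportion to their weights.

    Returns a frame multiset of exactly *total* structures, the input the
    iRED calculation expects for a regression-weighted ensemble.
    """
    w = np.asarray(getattr(weights, "weights", weights), dtype=float)
    if w.shape[0] != ensemble.n_conformers:
        raise ValueError("weight vector length does not match ensemble")
    if not np.any(w > 0):
        raise ValueError("no supported conformer to expand")
    counts = apportion_counts(w, total)
    indices = np.repeat(np.arange(ensemble.n_conformers), counts)
    ids = []
    seen: dict[int, int] = {}
    for i in indices:
        seen[i] = seen.get(i, 0) + 1
        ids.append(f"{ensemble.conformer_ids[i]}.copy{seen[i]}")
    return ensemble.subset(indices, ids=ids)


# ---------------------------------------------------------------------------
# N-H vectors and iRED
# ---------------------------------------------------------------------------

def nh_unit_vectors(ensemble: ConformerEnsemble
                    ) -> tuple[np.ndarray, tuple[int, ...], tuple[int, ...]]:
    """Unit N→H bond vectors for every usable residue of every frame.

    Prolines (no amide proton) and residues lacking N or H coordinates are
    excluded.  Returns ``(vectors, residue_numbers, excluded)`` with
    vectors of shape ``(n_frames, n_kept, 3)`` and unit norm.
    """
    if "H" not in ensemble.coords or "N" not in ensemble.coords:
        raise ValueError("ensemble lacks N/H coordinates")
    keep, excluded = [], []
    for k, (rnum, rname) in enumerate(ensemble.residues):
        finite = (rname != "PRO"
                  and np.isfinite(ensemble.coords["N"][:, k]).all()
                  and np.isfinite(ensemble.coords["H"][:, k]).all())
        (keep if finite else excluded).append(rnum)
    idx = [ensemble.residue_index(r) for r in keep]
    v = ensemble.coords["H"][:, idx, :] - ensemble.coords["N"][:, idx, :]
    norms = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate N-H vector (zero length)")
    return v / norms, tuple(keep), tuple(excluded)


def ired_s2(vectors: np.ndarray,
            residue_numbers: Sequence[int] | None = None,
            n_overall_modes: int = N_OVERALL_MODES,
            chunk: int = 512) -> OrderParameterProfile:
    """Per-residue iRED order parameters from unit bond vectors.

    Parameters
    ----------
    vectors : ndarray of shape (n_frames, n_residues, 3)
        Unit N-H vectors.
    n_overall_modes : int, default 5
        Largest-eigenvalue modes treated as overall reorientation.
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 3 or v.shape[2] != 3:
        raise ValueError("vectors must have shape (n_frames, n_residues, 3)")
    n_frames, n_res = v.shape[:2]
    if n_res <= n_overall_modes:
        raise ValueError(
            f"need more than {n_overall_modes} residues to separate internal "
            f"from overall modes (got {n_res})")
    if n_frames < 2:
        raise ValueError("need at least two frames")
    acc = np.zeros((n_res, n_res))
    for start in range(0, n_frames, chunk):
        block = v[start:start + chunk]
        dots = np.einsum("fik,fjk->fij", block, block)
        acc += (1.5 * dots ** 2 - 0.5).sum(axis=0)
    m = acc / n_frames
    eigvals, eigvecs = np.linalg.eigh(m)
    order = np.argsort(-eigvals, kind="stable")
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    internal = slice(n_overall_modes, None)
    s2 = 1.0 - (eigvecs[:, internal] ** 2 * eigvals[internal]).sum(axis=1)
    if residue_numbers is None:
        residue_numbers = tuple(range(1, n_res + 1))
    return OrderParameterProfile(
        residue_numbers=tuple(int(r) for r in residue_numbers),
        s2=s2, source="ensemble")


def ensemble_s2(ensemble: ConformerEnsemble, weights=None,
                total: int = DEFAULT_TOTAL_FRAMES) -> OrderParameterProfile:
    """S² of an ensemble; weighted ensembles are expanded first."""
    frames = ensemble if weights is None else expand_ensemble(ensemble, weights,
                                                              total=total)
    vectors, residues, excluded = nh_unit_vectors(frames)
    profile = ired_s2(vectors, residue_numbers=residues)
    return OrderParameterProfile(residue_numbers=profile.residue_numbers,
                                 s2=profile.s2, source=profile.source,
                                 excluded=excluded)


def delta_s2(reg: OrderParameterProfile,
             ref: OrderParameterProfile) -> OrderParameterProfile:
    """Per-residue |S²_reg - S²_ref| on the shared residue set."""
    shared = [r for r in reg.residue_numbers if r in set(ref.residue_numbers)]
    missing = (set(reg.residue_numbers) ^ set(ref.residue_numbers))
    if missing:
        logger.warning("delta_s2: %d residue(s) present on one side only",
                       len(missing))
    if not shared:
        raise ValueError("profiles share no residues")
    reg_map = dict(zip(reg.residue_numbers, reg.s2))
    ref_map = dict(zip(ref.residue_numbers, ref.s2))
    diff = np.array([abs(reg_map[r] - ref_map[r]) for r in shared])
    return OrderParameterProfile(residue_numbers=tuple(shared), s2=diff,
                                 source="delta")
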