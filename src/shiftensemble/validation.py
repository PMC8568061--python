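"""Projection-space chemical-shift errors and cross-observable reports.

The regression-predicted shift table is compared against the experimental
reference *in the projection space of the scaling function*: the
per-nucleus error is f(δ_reg) − f(δ_ref), which puts all four nuclei on a
common scale, and the per-residue combined error ‖f(Δδ)‖ aggregates the
four nuclei.  The combined error defaults to the Euclidean
(root-sum-square) norm; ``norm="sum"`` gives the l1 alternative (sum of
magnitudes), kept for compatibility with the additive form of the error
some descriptions use.  The report can be joined with per-residue |ΔS²|
to ask whether residues with poor shift prediction are also the residues
whose order parameters disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io import NUCLEI, ShiftTable
from .order_parameters import OrderParameterProfile
from .scaling import ShiftScaler


@dataclass
class ValidationReport:
    """Per-residue shift errors (scaled space) and optional |ΔS²| track."""

    per_nucleus: pd.DataFrame          # residues x nuclei, f(delta) signed
    combined: pd.Series                # per-residue combined norm
    norm: str = "l2"
    delta_s2: pd.Series | None = None
    summary: dict = field(default_factory=dict)

    def attach_delta_s2(self, profile: OrderParameterProfile) -> "ValidationReport":
        series = pd.Series(profile.s2, index=list(profile.residue_numbers))
        shared = self.combined.index.intersection(series.index)
        self.delta_s2 = series.loc[shared]
        return self

    def to_frame(self) -> pd.DataFrame:
        frame = self.per_nucleus.copy()
        frame["combined"] = self.combined
        if self.delta_s2 is not None:
            frame["abs_delta_s2"] = self.delta_s2
        frame.index.name = "residue_number"
        return frame

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path))


def shift_error(reg: ShiftTable, ref: ShiftTable, scaler: ShiftScaler,
                norm: str = "l2") -> ValidationReport:
    """Scaled-space shift error between regression and reference tables.

    Per nucleus, residues assigned on both sides contribute
    ``f(δ_reg) − f(δ_ref)``; residues missing a nucleus on either side are
    dropped from that nucleus.  The combined per-residue error is the
    Euclidean norm over the available nuclei (``norm="l2"``) or the sum of
    their magnitudes (``norm="sum"``).
    """
    if norm not in ("l2", "sum"):
        raise ValueError(f"norm must be 'l2' or 'sum', got {norm!r}")
    residues = sorted(set(reg.residue_numbers) & set(ref.residue_numbers))
    if not residues:
        raise ValueError("tables share no residues")
    errors = pd.DataFrame(np.nan, index=residues, columns=list(NUCLEI))
    for nucleus in NUCLEI:
        shared = [r for r in residues
                  if reg.is_assigned(r, nucleus) and ref.is_assigned(r, nucleus)]
        if not shared:
            continue
        reg_v = np.array([reg.values[(r, nucleus)] for r in shared])
        ref_v = np.array([ref.values[(r, nucleus)] for r in shared])
        f_reg = scaler.transform(reg_v, nucleus, residues=shared)
        f_ref = scaler.transform(ref_v, nucleus, residues=shared)
        errors.loc[shared, nucleus] = f_reg - f_ref
    if norm == "l2":
        combined = np.sqrt((errors ** 2).sum(axis=1, min_count=1))
    else:
        combined = errors.abs().sum(axis=1, min_count=1)
    combined = combined.dropna()
    report = ValidationReport(per_nucleus=errors, combined=combined, norm=norm)
    report.summary = {
        "mean_combined_error": float(combined.mean()),
        "max_combined_error": float(combined.max()),
        "norm": norm,
    }
    return report


def error_correlation(report: ValidationReport) -> tuple[float, pd.DataFrame]:
    """Spearman rank correlation between ‖f(Δδ)‖ and |ΔS²|.

    Returns the correlation together with the aligned per-residue table
    (for plotting).  Requires :meth:`ValidationReport.attach_delta_s2`
    to have been called.
    """
    if report.delta_s2 is None:
        raise ValueError("report has no |ΔS²| track attached")
    shared = report.combined.index.intersection(report.delta_s2.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared residues for a correlation")
    paired = pd.DataFrame({
        "shift_error": report.combined.loc[shared],
        "abs_delta_s2": report.delta_s2.loc[shared],
    })
    rho = float(spearmanr(paired["shift_error"], paired["abs_delta_s2"]).statistic)
    report.summary["spearman_rho"] = rho
    return rho, paired
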