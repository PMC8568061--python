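"""Reading, writing and masking of backbone chemical-shift tables.

Experimental references (NMR-STAR deposits) and per-conformer predictor
output (UCBShift / SHIFTX2 / SPARTA+ style tables) are normalised into one
representation, :class:`ShiftTable`, keyed by ``(residue_number, nucleus)``
with nucleus labels drawn from the canonical backbone set
``{"HN", "NH", "CA", "CB"}`` (amide proton, amide nitrogen, Cα, Cβ).
Unassigned entries are simply absent — there are no sentinel values.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Canonical backbone nuclei, in deterministic order.
NUCLEI: tuple[str, ...] = ("HN", "NH", "CA", "CB")

#: Atom-name synonyms mapped onto the canonical labels on read.
ATOM_SYNONYMS: dict[str, str] = {
    "H": "HN", "HN": "HN",
    "N": "NH", "NH": "NH",
    "CA": "CA",
    "CB": "CB",
}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class ShiftFormatError(ValueError):
    """A file does not conform to the expected layout."""


class ShiftDataError(ValueError):
    """A file parses but carries inconsistent data."""


def _canonical_residue_name(name: str) -> str:
    name = name.strip().upper()
    if len(name) == 1:
        return _ONE_TO_THREE.get(name, name)
    return name


@dataclass(frozen=True)
class ShiftTable:
    """Per-residue, per-nucleus chemical shifts (ppm) for one entity.

    Parameters
    ----------
    entity_id : str
        Free-text label (conformer id, BMRB entry, ...).
    residues : tuple of (int, str)
        ``(residue_number, residue_name)`` pairs, numbers strictly
        increasing.
    values : mapping
        ``(residue_number, nucleus) -> shift (ppm)``.  Presence of a key is
        the assignment mask; absent keys are unassigned.
    """

    entity_id: str
    residues: tuple[tuple[int, str], ...]
    values: Mapping[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        numbers = [r for r, _ in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ShiftDataError("residue numbers must be strictly increasing")
        known = set(numbers)
        for (res, nuc) in self.values:
            if nuc not in NUCLEI:
                raise ShiftDataError(f"unknown nucleus label {nuc!r}")
            if res not in known:
                raise ShiftDataError(f"value for residue {res} not in residue list")

    @property
    def residue_numbers(self) -> tuple[int, ...]:
        return tuple(r for r, _ in self.residues)

    def residue_name(self, number: int) -> str:
        for r, name in self.residues:
            if r == number:
                return name
        raise KeyError(number)

    def is_assigned(self, residue: int, nucleus: str) -> bool:
        return (residue, nucleus) in self.values

    def fully_assigned_residues(self, nuclei: Sequence[str] = NUCLEI) -> tuple[int, ...]:
        """Residues carrying a value for every nucleus in *nuclei*."""
        return tuple(
            r for r in self.residue_numbers
            if all((r, nuc) in self.values for nuc in nuclei)
        )

    def nucleus_values(self, nucleus: str) -> tuple[np.ndarray, np.ndarray]:
        """(residue numbers, shifts) assigned for one nucleus, in order."""
        res = [r for r in self.residue_numbers if (r, nucleus) in self.values]
        vals = [self.values[(r, nucleus)] for r in res]
        return np.asarray(res, dtype=int), np.asarray(vals, dtype=float)

    def restrict(self, residues: Iterable[int]) -> "ShiftTable":
        keep = set(residues)
        return ShiftTable(
            entity_id=self.entity_id,
            residues=tuple((r, n) for r, n in self.residues if r in keep),
            values={k: v for k, v in self.values.items() if k[0] in keep},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"residue_number": r, "residue_name": self.residue_name(r),
             "nucleus": nuc, "shift_ppm": self.values[(r, nuc)]}
            for r in self.residue_numbers for nuc in NUCLEI
            if (r, nuc) in self.values
        ]
        return pd.DataFrame(rows, columns=["residue_number", "residue_name",
                                           "nucleus", "shift_ppm"])


@dataclass(frozen=True)
class ShiftLibrary:
    """Ordered collection of per-conformer shift tables sharing one residue
    list — the candidate pool over which ensemble weights are assigned."""

    conformer_ids: tuple[str, ...]
    tables: tuple[ShiftTable, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.tables) < 1:
            raise ShiftDataError("library must contain at least one conformer")
        if len(self.conformer_ids) != len(self.tables):
            raise ShiftDataError("conformer_ids and tables length mismatch")
        ref_res = self.tables[0].residue_numbers
        for t in self.tables[1:]:
            if t.residue_numbers != ref_res:
                raise ShiftDataError("library tables disagree on residue list")

    def __len__(self) -> int:
        return len(self.tables)

    @property
    def residue_numbers(self) -> tuple[int, ...]:
        return self.tables[0].residue_numbers

    def restrict(self, residues: Iterable[int]) -> "ShiftLibrary":
        keep = tuple(residues)
        return ShiftLibrary(
            conformer_ids=self.conformer_ids,
            tables=tuple(t.restrict(keep) for t in self.tables),
            source=self.source,
        )


# ---------------------------------------------------------------------------
# NMR-STAR 3.1 (Atom_chem_shift loop only)
# ---------------------------------------------------------------------------

def read_nmrstar_shifts(path: str | Path, entity_id: str | None = None) -> ShiftTable:
    """Read one chemical-shift loop from an NMR-STAR 3.1 file.

    Only the ``_Atom_chem_shift`` loop is consumed (sequence id, residue
    name, atom name, shift value); nuclei outside the backbone set are
    dropped with a log note, and ambiguity codes are ignored.
    """
    path = Path(path)
    text = path.read_text()
    tags, rows = _parse_star_loop(text, "Atom_chem_shift")
    if tags is None:
        raise ShiftFormatError(f"{path}: no _Atom_chem_shift loop found")

    def col(*names: str) -> int:
        for n in names:
            key = f"_Atom_chem_shift.{n}".lower()
            if key in tags:
                return tags[key]
        raise ShiftFormatError(f"{path}: missing Atom_chem_shift tag {names[0]}")

    i_seq = col("Comp_index_ID", "Seq_ID")
    i_name = col("Comp_ID")
    i_atom = col("Atom_ID")
    i_val = col("Val")

    values: dict[tuple[int, str], float] = {}
    names: dict[int, str] = {}
    for row in rows:
        atom = row[i_atom].upper()
        nucleus = ATOM_SYNONYMS.get(atom)
        if nucleus is None:
            logger.info("dropping non-backbone nucleus %s", atom)
            continue
        if row[i_val] in (".", "?"):
            continue
        res = int(row[i_seq])
        key = (res, nucleus)
        if key in values:
            raise ShiftDataError(
                f"{path}: duplicate shift for residue {res} nucleus {nucleus}")
        values[key] = float(row[i_val])
        names[res] = _canonical_residue_name(row[i_name])

    residues = tuple((r, names[r]) for r in sorted(names))
    return ShiftTable(entity_id=entity_id or path.stem, residues=residues,
                      values=values)


def _parse_star_loop(text: str, category: str):
    """Return (tag->index map, data rows) for the first loop of *category*."""
    tokens = _star_tokens(text)
    i = 0
    while i < len(tokens):
        if tokens[i].lower() == "loop_":
            j = i + 1
            tags: dict[str, int] = {}
            while j < len(tokens) and tokens[j].startswith("_"):
                tags[tokens[j].lower()] = len(tags)
                j += 1
            if any(t.lower().startswith(f"_{category.lower()}.") for t in tags):
                data: list[str] = []
                while j < len(tokens) and tokens[j].lower() != "stop_":
                    data.append(tokens[j])
                    j += 1
                ncol = len(tags)
                if ncol == 0 or len(data) % ncol:
                    raise ShiftFormatError(
                        f"ragged {category} loop ({len(data)} tokens, {ncol} tags)")
                rows = [data[k:k + ncol] for k in range(0, len(data), ncol)]
                return tags, rows
            i = j
        else:
            i += 1
    return None, None


def _star_tokens(text: str) -> list[str]:
    tokens: list[str] = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        k = 0
        while k < len(stripped):
            if stripped[k] in "'\"":
                quote = stripped[k]
                end = stripped.find(quote, k + 1)
                if end < 0:
                    raise ShiftFormatError("unterminated quoted STAR token")
                tokens.append(stripped[k + 1:end])
                k = end + 1
            elif stripped[k].isspace():
                k += 1
            else:
                end = k
                while end < len(stripped) and not stripped[end].isspace():
                    end += 1
                tokens.append(stripped[k:end])
                k = end
    return tokens


# ---------------------------------------------------------------------------
# Predictor output tables
# ---------------------------------------------------------------------------

def _dialect_config() -> dict:
    with resources.files("shiftensemble.data").joinpath("dialects.yaml").open() as fh:
        return yaml.safe_load(fh)


def read_predictor_table(path: str | Path, dialect: str,
                         entity_id: str | None = None) -> ShiftTable:
    """Read a chemical-shift prediction table in a known dialect.

    Supported dialects: ``ucbshift`` (wide CSV, one column per atom),
    ``shiftx2`` (long CSV), ``spartaplus`` (whitespace table with a VARS
    header line) and ``generic-csv`` (normalised long CSV).  Column
    mappings live in ``data/dialects.yaml``.
    """
    path = Path(path)
    config = _dialect_config()
    if dialect not in config:
        raise ShiftFormatError(
            f"unknown dialect {dialect!r}; expected one of {sorted(config)}")
    spec = config[dialect]
    entity = entity_id or path.stem

    if path.stat().st_size == 0:
        raise ShiftFormatError(f"{path}: empty file")

    if spec["layout"] == "sparta":
        return _read_sparta(path, spec, entity)
    frame = pd.read_csv(path, sep=spec.get("sep", ","), engine="python",
                        skipinitialspace=True)
    if frame.empty:
        raise ShiftFormatError(f"{path}: no data rows")
    if spec["layout"] == "wide":
        return _table_from_wide(frame, spec, entity, path)
    return _table_from_long(frame, spec, entity, path)


def _require(frame: pd.DataFrame, column: str, path: Path) -> pd.Series:
    if column not in frame.columns:
        raise ShiftFormatError(f"{path}: missing required column {column!r}")
    return frame[column]


def _table_from_wide(frame, spec, entity, path) -> ShiftTable:
    resnum = _require(frame, spec["residue_number"], path).astype(int)
    resname = _require(frame, spec["residue_name"], path).map(_canonical_residue_name)
    values: dict[tuple[int, str], float] = {}
    for nucleus, column in spec["nuclei"].items():
        if column not in frame.columns:
            continue
        for r, v in zip(resnum, frame[column]):
            if pd.notna(v):
                values[(int(r), nucleus)] = float(v)
    residues = tuple(sorted(zip(resnum, resname)))
    return ShiftTable(entity_id=entity, residues=residues, values=values)


def _table_from_long(frame, spec, entity, path) -> ShiftTable:
    resnum = _require(frame, spec["residue_number"], path).astype(int)
    resname = _require(frame, spec["residue_name"], path).map(_canonical_residue_name)
    atoms = _require(frame, spec["nucleus"], path).astype(str).str.upper()
    shift_col = spec["shift"]
    if shift_col not in frame.columns and "shift_ppm" in frame.columns:
        shift_col = "shift_ppm"  # normalised round-trip header
    shifts = _require(frame, shift_col, path).astype(float)
    atom_map = {k.upper(): v for k, v in spec["atom_map"].items()}
    values: dict[tuple[int, str], float] = {}
    names: dict[int, str] = {}
    for r, name, atom, shift in zip(resnum, resname, atoms, shifts):
        nucleus = atom_map.get(atom)
        if nucleus is None:
            logger.info("dropping atom %s in %s", atom, path)
            continue
        key = (int(r), nucleus)
        if key in values:
            raise ShiftDataError(f"{path}: duplicate row for {key}")
        values[key] = float(shift)
        names[int(r)] = name
    residues = tuple((r, names[r]) for r in sorted(names))
    return ShiftTable(entity_id=entity, residues=residues, values=values)


def _read_sparta(path: Path, spec, entity) -> ShiftTable:
    columns: list[str] | None = None
    rows = []
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("VARS"):
            columns = stripped.split()[1:]
        elif stripped.startswith(("FORMAT", "REMARK", "DATA")):
            continue
        elif columns is not None:
            rows.append(stripped.split())
    if columns is None or not rows:
        raise ShiftFormatError(f"{path}: no VARS header / data rows")
    frame = pd.DataFrame(rows, columns=columns)
    long_spec = {
        "residue_number": spec.get("residue_number", "RESID"),
        "residue_name": spec.get("residue_name", "RESNAME"),
        "nucleus": spec.get("nucleus", "ATOMNAME"),
        "shift": spec.get("shift", "SHIFT"),
        "atom_map": spec["atom_map"],
    }
    return _table_from_long(frame, long_spec, entity, path)


# ---------------------------------------------------------------------------
# Normalised CSV round trip
# ---------------------------------------------------------------------------

def write_table(table: ShiftTable, path: str | Path) -> None:
    """Write the normalised long CSV (residue_number,residue_name,nucleus,shift_ppm)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["residue_number", "residue_name", "nucleus", "shift_ppm"])
        for r in table.residue_numbers:
            for nuc in NUCLEI:
                if (r, nuc) in table.values:
                    writer.writerow([r, table.residue_name(r), nuc,
                                     repr(table.values[(r, nuc)])])


def read_table(path: str | Path, entity_id: str | None = None) -> ShiftTable:
    """Read the normalised long CSV written by :func:`write_table`."""
    return read_predictor_table(path, "generic-csv", entity_id=entity_id)


# ---------------------------------------------------------------------------
# Residue exclusion
# ---------------------------------------------------------------------------

def apply_exclusion_mask(
    library: ShiftLibrary, reference: ShiftTable
) -> tuple[ShiftLibrary, ShiftTable, tuple[int, ...]]:
    """Drop residues not fully assigned for all four backbone nuclei.

    A residue is retained only if the reference carries HN, NH, CA and CB
    values for it *and* every library table does too.  Prolines (no amide
    proton) and glycines (no Cβ) therefore always fall out, as do partially
    assigned residues.  Returns the restricted library and reference plus
    the list of excluded residue numbers for reporting.
    """
    ref_full = set(reference.fully_assigned_residues())
    keep = set(library.residue_numbers) & ref_full
    for t in library.tables:
        keep &= set(t.fully_assigned_residues())
    all_residues = sorted(set(library.residue_numbers) | set(reference.residue_numbers))
    excluded = tuple(r for r in all_residues if r not in keep)
    if not keep:
        raise ShiftDataError(
            "no residues remain after exclusion: reference and library share "
            "no residue fully assigned for HN, NH, CA and CB")
    for r in sorted(keep):
        try:
            ref_name = reference.residue_name(r)
        except KeyError:
            continue
        lib_name = library.tables[0].residue_name(r)
        if ref_name != lib_name:
            logger.warning("residue %d name mismatch: reference %s vs library %s",
                           r, ref_name, lib_name)
    kept = sorted(keep)
    return library.restrict(kept), reference.restrict(kept), excluded
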