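import numpy as np
import pytest

from shiftensemble.io import NUCLEI, ShiftLibrary, ShiftTable
from shiftensemble.regression import RegressionProblem
from shiftensemble.scaling import ShiftScaler

# typical ppm ranges per nucleus used to draw realistic random tables
PPM_RANGES = {"HN": (7.5, 9.5), "NH": (105.0, 130.0),
              "CA": (45.0, 65.0), "CB": (18.0, 70.0)}

RESIDUE_CYCLE = ("ALA", "GLU", "LEU", "LYS", "ASP", "PHE", "SER", "VAL")


def make_residues(n, start=1, names=None):
    names = names or RESIDUE_CYCLE
    return tuple((start + i, names[i % len(names)]) for i in range(n))


def random_table(rng, n_res=8, entity="t", start=1, drop=()):
    """Fully assigned table with nucleus-realistic random shifts."""
    residues = make_residues(n_res, start=start)
    values = {}
    for r, _ in residues:
        for nuc in NUCLEI:
            if (r, nuc) in drop:
                continue
            lo, hi = PPM_RANGES[nuc]
            values[(r, nuc)] = float(rng.uniform(lo, hi))
    return ShiftTable(entity_id=entity, residues=residues, values=values)


def random_library(rng, n_conformers=5, n_res=8):
    tables = tuple(random_table(rng, n_res, entity=f"c{i}")
                   for i in range(n_conformers))
    return ShiftLibrary(conformer_ids=tuple(f"c{i}" for i in range(n_conformers)),
                        tables=tables)


def array_problem(X, y):
    """Wrap raw (already scaled) arrays into a RegressionProblem."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    index = tuple((k + 1, NUCLEI[k % 4]) for k in range(X.shape[0]))
    ids = tuple(f"c{i}" for i in range(X.shape[1]))
    return RegressionProblem(design=X, target=y, feature_index=index,
                             conformer_ids=ids, scaler=ShiftScaler())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
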