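import numpy as np
import pandas as pd
import pytest

import cytovar as cv


def table_from_cells(y_by_cell, experiment="exp", exponent=0.25):
    """Build a transformed ColonyTable with given transformed-scale values
    per genotype cell (keys (x1, x2) in {0,1}^2)."""
    rows = []
    for (x1, x2), ys in y_by_cell.items():
        for rep, y in enumerate(ys, start=1):
            rows.append({
                "experiment": experiment,
                "chrom": ("wt", "del")[x1],
                "nonchrom": ("absent", "present")[x2],
                "replicate": rep,
                "colony_size": float(y) ** (1.0 / exponent),
            })
    return cv.box_cox_transform(cv.ColonyTable(pd.DataFrame(rows)), exponent)


@pytest.fixture
def factorial_table():
    """One replicate per cell with distinct transformed means 2, 3, 4, 6."""
    return table_from_cells({(0, 0): [2.0], (0, 1): [3.0],
                             (1, 0): [4.0], (1, 1): [6.0]})


@pytest.fixture
def balanced_table():
    """Six noisy replicates per cell around an interaction-structured mean."""
    rng = np.random.default_rng(42)
    cells = {}
    for x1, x2 in ((0, 0), (0, 1), (1, 0), (1, 1)):
        mean = 4.0 - 0.8 * x1 + 0.3 * x2 + 1.0 * x1 * x2
        cells[(x1, x2)] = list(mean + 0.2 * rng.standard_normal(6))
    return table_from_cells(cells)


def random_design(rng, n, p, form="interaction"):
    """A small random continuous design for solver oracles (not factorial)."""
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    names = ("X1", "X2", "X1X2")[:p]
    form = {1: "simple", 2: "additive", 3: "interaction"}[p]
    if p == 3:
        X[:, 2] = X[:, 0] * X[:, 1]
    return cv.DesignMatrix(model_form=form, X=X, y=y, coding={},
                           column_names=names)
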