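"""Colony-size tables, the power transform, and design matrices.

The study design is a 2x2 factorial per gene-deletion experiment: a binary
chromosomal factor (gene deleted vs. wild-type allele) crossed with a binary
non-chromosomal factor (killer-virus state [kil-k]/[kil-0], or the source of
the mitochondrial genome, Sigma vs. S288c).  Each cell holds replicate colony
size measurements ``c_ij > 0``; the response analysed everywhere downstream is
the variance-stabilised ``y_ij = c_ij ** 0.25``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, SchemaError, ValidationError

#: canonical column names used throughout the package
COLUMNS = ("experiment", "chrom", "nonchrom", "replicate", "colony_size")

#: factor levels treated as the reference (coded 0) when no coding is given
DEFAULT_REFERENCE_LEVELS = frozenset(
    {
        "wt", "WT", "wild-type", "wildtype",
        "S288c", "[rho+]S288c", "rho+S288c",
        "kil-0", "[kil-0]", "no-killer", "non-killer", "absent",
    }
)

MODEL_FORMS = ("intercept_only", "simple", "additive", "interaction")

#: number of non-intercept predictors per model form
MODEL_SIZE = {"intercept_only": 0, "simple": 1, "additive": 2, "interaction": 3}

PREDICTOR_NAMES = ("X1", "X2", "X1X2")


@dataclass(frozen=True)
class ColonyTable:
    """Long-format replicate-level colony measurements.

    ``data`` holds one row per replicate with the canonical columns and,
    once :func:`box_cox_transform` has run, the transformed response ``y``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_table(self.data)

    @property
    def has_response(self) -> bool:
        return "y" in self.data.columns

    @property
    def experiments(self) -> list[str]:
        return sorted(self.data["experiment"].unique().tolist())

    def subset(self, experiment: str) -> "ColonyTable":
        sub = self.data[self.data["experiment"] == experiment]
        if sub.empty:
            raise ValidationError(f"no rows for experiment {experiment!r}")
        return ColonyTable(sub.reset_index(drop=True))

    def to_csv(self, path) -> None:
        """Write the table (including ``y`` if present) back to CSV."""
        self.data.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.data)


def _validate_table(df: pd.DataFrame) -> None:
    for col in COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    size = pd.to_numeric(df["colony_size"], errors="coerce")
    if size.isna().any():
        rows = df.index[size.isna()].tolist()
        raise ValidationError(f"non-numeric or missing colony_size in rows {rows}")
    if (size <= 0).any():
        rows = df.index[size <= 0].tolist()
        raise ValidationError(
            f"colony_size must be positive (power transform); offending rows {rows}"
        )
    for exp, sub in df.groupby("experiment"):
        for col in ("chrom", "nonchrom"):
            levels = sorted(map(str, sub[col].unique()))
            if len(levels) > 2:
                raise ValidationError(
                    f"experiment {exp!r}: factor {col!r} has {len(levels)} levels "
                    f"{levels}; exactly 2 expected"
                )
        dup = sub.duplicated(subset=["chrom", "nonchrom", "replicate"])
        if dup.any():
            raise ValidationError(
                f"experiment {exp!r}: duplicate replicate index within a genotype cell "
                f"(rows {sub.index[dup].tolist()})"
            )


def read_colony_table(path, schema: Mapping[str, str] | None = None) -> ColonyTable:
    """Read a long-format colony-size CSV into a validated :class:`ColonyTable`.

    Parameters
    ----------
    path:
        CSV file with a header row (comma separated, UTF-8).
    schema:
        Optional map from canonical names (``experiment``, ``chrom``,
        ``nonchrom``, ``replicate``, ``colony_size``) to the column names used
        in the file, so published data files need no editing.

    Raises
    ------
    SchemaError
        if a mapped column is absent.
    ValidationError
        if a colony size is missing, non-numeric or non-positive, or a factor
        has more than two levels within one experiment.
    """
    raw = pd.read_csv(path)
    schema = dict(schema or {})
    rename = {}
    for canonical in COLUMNS:
        source = schema.get(canonical, canonical)
        if source not in raw.columns:
            raise SchemaError(
                f"column {source!r} (for {canonical!r}) not found in {path}; "
                f"available: {list(raw.columns)}"
            )
        rename[source] = canonical
    df = raw.rename(columns=rename)[list(COLUMNS)].copy()
    if df["colony_size"].isna().any():
        rows = df.index[df["colony_size"].isna()].tolist()
        raise ValidationError(f"missing colony_size in rows {rows}; rows are rejected, not dropped")
    df["colony_size"] = pd.to_numeric(df["colony_size"], errors="coerce")
    return ColonyTable(df)


def box_cox_transform(table: ColonyTable, exponent: float = 0.25) -> ColonyTable:
    """Apply the variance-stabilising power transform ``y = c ** exponent``.

    The pure power form is used rather than ``(c**l - 1)/l``: the two differ by
    a fixed affine map, which leaves R^2, adjusted R^2, MSE ranking and every
    selection event invariant.  Raw sizes are retained alongside ``y``.
    """
    if exponent <= 0:
        raise ValidationError(f"exponent must be positive, got {exponent}")
    df = table.data.copy()
    if (df["colony_size"] <= 0).any():
        raise ValidationError("colony_size must be positive for the power transform")
    df["y"] = np.asarray(df["colony_size"], dtype=float) ** exponent
    return ColonyTable(df)


@dataclass(frozen=True)
class DesignMatrix:
    """Numeric predictors and response for one model form.

    Columns are 0/1 coded per ``coding`` (factor name -> level coded 1); the
    interaction column is the elementwise product of the two main-effect
    columns.  ``p`` excludes the intercept.
    """

    model_form: str
    X: np.ndarray
    y: np.ndarray
    coding: dict = field(default_factory=dict)
    column_names: tuple = ()

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def __post_init__(self) -> None:
        if self.model_form not in MODEL_FORMS:
            raise ValidationError(f"unknown model form {self.model_form!r}")
        if self.X.shape[1] != MODEL_SIZE[self.model_form]:
            raise ValidationError(
                f"{self.model_form} design must have {MODEL_SIZE[self.model_form]} "
                f"columns, got {self.X.shape[1]}"
            )
        if self.X.shape[0] != self.y.shape[0]:
            raise ValidationError("X and y row counts differ")


def _code_factor(values: pd.Series, factor: str, coding: Mapping[str, str] | None):
    levels = sorted(map(str, values.unique()))
    if coding and factor in coding:
        one = str(coding[factor])
        if one not in levels:
            raise ValidationError(
                f"coding maps {factor!r} level {one!r} to 1 but observed levels are {levels}"
            )
    else:
        ref = [lv for lv in levels if lv in DEFAULT_REFERENCE_LEVELS]
        if len(levels) == 2 and len(ref) == 1:
            one = next(lv for lv in levels if lv != ref[0])
        else:
            # fall back to lexicographic order: larger level coded 1
            one = levels[-1]
    col = (values.astype(str) == one).to_numpy(dtype=float)
    return col, one


def build_design(
    table: ColonyTable,
    model_form: str,
    coding: Mapping[str, str] | None = None,
) -> DesignMatrix:
    """Build the 0/1-coded design matrix for one of the nested model forms.

    ``X1`` codes the chromosomal factor, ``X2`` the non-chromosomal factor and
    ``X1X2`` their product.  The factor level coded 1 is taken from ``coding``
    (``{"chrom": level, "nonchrom": level}``) or, by default, the non-reference
    level (deletion / virus-present / Sigma mitochondria).

    Raises
    ------
    DegenerateDesignError
        if a factor the form uses is constant in the table.
    ValidationError
        if the transform has not been applied yet.
    """
    if model_form not in MODEL_FORMS:
        raise ValidationError(f"unknown model form {model_form!r}")
    if not table.has_response:
        raise ValidationError("apply box_cox_transform before building designs")
    df = table.data
    y = df["y"].to_numpy(dtype=float)

    used = {
        "intercept_only": (),
        "simple": ("chrom",),
        "additive": ("chrom", "nonchrom"),
        "interaction": ("chrom", "nonchrom"),
    }[model_form]
    cols, names, code = [], [], {}
    for factor, xname in zip(("chrom", "nonchrom"), ("X1", "X2")):
        if factor not in used:
            continue
        if df[factor].nunique() < 2:
            raise DegenerateDesignError(
                f"factor {factor!r} is constant (level {df[factor].iloc[0]!r}); "
                f"{model_form} design is degenerate"
            )
        col, one = _code_factor(df[factor], factor, coding)
        cols.append(col)
        names.append(xname)
        code[factor] = one
    if model_form == "interaction":
        cols.append(cols[0] * cols[1])
        names.append("X1X2")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return DesignMatrix(model_form=model_form, X=X, y=y, coding=code,
                        column_names=tuple(names))


def split_design(design: DesignMatrix, rows: Sequence[int]) -> DesignMatrix:
    """Restrict a design to a row subset, preserving form and coding."""
    idx = np.asarray(rows, dtype=int)
    return replace(design, X=design.X[idx], y=design.y[idx])
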