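"""The repeated-resampling harness.

For each gene-deletion experiment the replicates of every genotype cell are
split at random into equally sized training and test halves, the three nested
linear models (and the LASSO/BIC and hierarchy-lasso selections) are run on
the training half, and the choices are tallied over many repeats.  The
resulting frequency tables — which model form wins on test MSE, how many
predictors the BIC keeps, how often each of X1, X2 and X1*X2 is selected —
are the pipeline's evidentiary output, together with per-form adjusted-R2
means and SDs across the sampled test sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .hier import check_strong_hierarchy, cross_validate_hier
from .io import ColonyTable, DesignMatrix, MODEL_SIZE, build_design, split_design
from .lasso import estimate_sigma2, lasso_path, select_by_bic, standardize
from .linear import compare_models_by_mse, evaluate_on_test, fit_ols

FORMS = ("simple", "additive", "interaction")
PREDICTORS = ("X1", "X2", "X1X2")


def seed_schedule(master_seed: int, repeat_index: int) -> int:
    """Injective counter-based per-repeat seed, so any repeat can be re-run
    in isolation (``SeedSequence([master_seed, repeat_index])``)."""
    ss = np.random.SeedSequence([int(master_seed), int(repeat_index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SplitScheme:
    """Per-cell train/test partition of one experiment's replicates.

    Indices refer to the canonical row order of the experiment subset
    (sorted by chrom level, nonchrom level, replicate), which makes the
    scheme independent of the input row order.
    """

    seed: int
    cells: dict                 # (chrom, nonchrom) -> (train_idx, test_idx)
    train_rows: np.ndarray
    test_rows: np.ndarray


def canonical_order(table: ColonyTable) -> ColonyTable:
    df = table.data.sort_values(["experiment", "chrom", "nonchrom", "replicate"],
                                kind="mergesort").reset_index(drop=True)
    return ColonyTable(df)


def split_half(table: ColonyTable, experiment: str, seed: int) -> SplitScheme:
    """Seeded equal half-split of every genotype cell (odd counts: the extra
    replicate goes to training)."""
    sub = canonical_order(table.subset(experiment))
    rng = np.random.default_rng(seed)
    cells, train, test = {}, [], []
    for key, grp in sub.data.groupby(["chrom", "nonchrom"], sort=True):
        idx = grp.index.to_numpy()
        if idx.size < 2:
            raise ValidationError(
                f"cell {key} of experiment {experiment!r} has {idx.size} replicate(s); "
                "need at least 2 to split"
            )
        perm = rng.permutation(idx)
        k = (idx.size + 1) // 2
        cells[key] = (np.sort(perm[:k]), np.sort(perm[k:]))
        train.append(cells[key][0])
        test.append(cells[key][1])
    return SplitScheme(seed, cells, np.concatenate(train), np.concatenate(test))


@dataclass
class SelectionSummary:
    """Frequency tables over modelling repeats for one experiment."""

    experiment_id: str
    method: str
    repeats: int
    master_seed: int
    model_freq: dict | None = None        # {form: count}
    size_freq: dict | None = None         # {0..3: count}
    predictor_freq: dict | None = None    # {X1, X2, X1X2: count}
    ra2_mean: dict | None = None          # per form, out-of-sample
    ra2_sd: dict | None = None
    ra2_train_mean: dict | None = None
    ra2_train_sd: dict | None = None
    resamples: int = 0                    # redrawn degenerate splits
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("model_freq", "size_freq", "predictor_freq"):
            table = getattr(self, name)
            if table is not None:
                for key, count in table.items():
                    rows.append({"experiment": self.experiment_id, "table": name,
                                 "category": str(key), "count": count,
                                 "repeats": self.repeats})
        if self.ra2_mean is not None:
            for form in self.ra2_mean:
                rows.append({"experiment": self.experiment_id, "table": "ra2",
                             "category": form, "mean": self.ra2_mean[form],
                             "sd": self.ra2_sd[form], "repeats": self.repeats})
        return pd.DataFrame(rows)


def _prepared(table: ColonyTable, experiment: str, coding):
    sub = canonical_order(table.subset(experiment))
    if not sub.has_response:
        raise ValidationError("apply box_cox_transform before running the pipeline")
    designs = {form: build_design(sub, form, coding) for form in FORMS}
    return sub, designs


def _draw_split(sub, experiment, master_seed, r, min_train, max_retries=20):
    """A half-split whose training part keeps all designs estimable."""
    attempt = 0
    extra = 0
    while True:
        seed = seed_schedule(master_seed, r) if extra == 0 else seed_schedule(
            master_seed + 1_000_003 * extra, r)
        scheme = split_half(sub, experiment, seed)
        if scheme.train_rows.size >= min_train:
            return scheme, attempt
        attempt += 1
        extra += 1
        if attempt > max_retries:
            raise ValidationError(
                f"experiment {experiment!r}: training halves keep only "
                f"{scheme.train_rows.size} rows (< {min_train}); too few replicates"
            )


def run_linear_comparison(
    table: ColonyTable,
    experiment: str,
    repeats: int = 1000,
    master_seed: int = 0,
    coding=None,
) -> SelectionSummary:
    """Half-split, fit simple/additive/interaction on the training half,
    pick the test-MSE winner, and average the out-of-sample adjusted R2."""
    sub, designs = _prepared(table, experiment, coding)
    model_freq = {form: 0 for form in FORMS}
    ra2 = {form: np.empty(repeats) for form in FORMS}
    ra2_train = {form: np.empty(repeats) for form in FORMS}
    resamples = 0
    for r in range(repeats):
        scheme, retried = _draw_split(sub, experiment, master_seed, r, min_train=5)
        resamples += retried
        results = []
        for form in FORMS:
            fit = fit_ols(split_design(designs[form], scheme.train_rows))
            ev = evaluate_on_test(fit, split_design(designs[form], scheme.test_rows))
            results.append(ev)
            ra2[form][r] = ev.ra2_test
            ra2_train[form][r] = fit.ra2
        model_freq[compare_models_by_mse(results)] += 1
    return SelectionSummary(
        experiment, "linear_mse", repeats, master_seed,
        model_freq=model_freq,
        ra2_mean={f: float(np.nanmean(ra2[f])) for f in FORMS},
        ra2_sd={f: float(np.nanstd(ra2[f], ddof=1)) if repeats > 1 else float("nan")
                for f in FORMS},
        ra2_train_mean={f: float(np.mean(ra2_train[f])) for f in FORMS},
        ra2_train_sd={f: float(np.std(ra2_train[f], ddof=1)) if repeats > 1
                      else float("nan") for f in FORMS},
        resamples=resamples,
        config={"coding": dict(designs["interaction"].coding)},
    )


def run_lasso_bic(
    table: ColonyTable,
    experiment: str,
    repeats: int = 1000,
    master_seed: int = 0,
    coding=None,
    use_splits: bool = True,
    rss_mode: str = "lasso",
    sigma2_mode: str = "full_ols",
    n_lambda: int = 100,
    eps: float = 1e-3,
) -> SelectionSummary:
    """LASSO path + BIC selection per repeat; tallies the selected model size
    and the selected predictors."""
    sub, designs = _prepared(table, experiment, coding)
    design = designs["interaction"]
    size_freq = {k: 0 for k in range(4)}
    predictor_freq = {p: 0 for p in PREDICTORS}
    resamples = 0
    for r in range(repeats):
        if use_splits:
            scheme, retried = _draw_split(sub, experiment, master_seed, r, min_train=5)
            resamples += retried
            train = split_design(design, scheme.train_rows)
        else:
            train = design
        sd = standardize(train)
        path = lasso_path(sd, n_lambda=n_lambda, eps=eps)
        if sigma2_mode == "full_ols":
            sigma2 = estimate_sigma2(train)
        elif sigma2_mode == "per_support":
            sigma2 = None
        else:
            raise ValidationError(f"unknown sigma2_mode {sigma2_mode!r}")
        sel = select_by_bic(path, sigma2, rss_mode=rss_mode, sd=sd)
        size_freq[sel.size] += 1
        for name in sel.chosen.support:
            predictor_freq[name] += 1
        if not use_splits:
            # identical data every repeat: the tally is deterministic
            for k in size_freq:
                size_freq[k] *= repeats if size_freq[k] else 1
            for p_ in predictor_freq:
                predictor_freq[p_] *= repeats if predictor_freq[p_] else 1
            break
    return SelectionSummary(
        experiment, "lasso_bic", repeats, master_seed,
        size_freq=size_freq, predictor_freq=predictor_freq, resamples=resamples,
        config={"use_splits": use_splits, "rss_mode": rss_mode,
                "sigma2_mode": sigma2_mode, "n_lambda": n_lambda, "eps": eps,
                "coding": dict(design.coding)},
    )


def run_hier(
    table: ColonyTable,
    experiment: str,
    repeats: int = 1000,
    master_seed: int = 0,
    coding=None,
    use_splits: bool = False,
    folds: int = 5,
    n_lambda: int = 20,
    eps: float = 0.01,
) -> SelectionSummary:
    """Strong-hierarchy interaction lasso with CV/1-SE selection per repeat.

    By default the full per-experiment data are refit with re-randomised fold
    assignments each repeat; ``use_splits=True`` runs on training halves
    instead."""
    sub, designs = _prepared(table, experiment, coding)
    design = designs["interaction"]
    size_freq = {k: 0 for k in range(4)}
    predictor_freq = {p: 0 for p in PREDICTORS}
    resamples = 0
    for r in range(repeats):
        seed = seed_schedule(master_seed, r)
        if use_splits:
            scheme, retried = _draw_split(sub, experiment, master_seed, r, min_train=8)
            resamples += retried
            train = split_design(design, scheme.train_rows)
        else:
            train = design
        cv = cross_validate_hier(train, n_lambda=n_lambda, folds=folds, seed=seed,
                                 eps=eps)
        fit = cv.chosen_fit
        if not check_strong_hierarchy(fit):
            raise AssertionError("solver returned a hierarchy-violating fit")
        size_freq[fit.size] += 1
        for name in fit.support:
            predictor_freq[name] += 1
    return SelectionSummary(
        experiment, "hier_cv", repeats, master_seed,
        size_freq=size_freq, predictor_freq=predictor_freq, resamples=resamples,
        config={"use_splits": use_splits, "folds": folds, "n_lambda": n_lambda,
                "eps": eps, "coding": dict(design.coding)},
    )
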