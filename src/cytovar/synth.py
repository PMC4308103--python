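"""Synthetic colony-size tables with the structure the analysis assumes.

The generator inverts the modelling chain: on the transformed scale the
response of a replicate in genotype cell ``(x1, x2)`` is drawn as

    y ~ Normal(beta0 + beta1*x1 + beta2*x2 + beta3*x1*x2, sigma^2)

and the raw colony size is ``c = y ** (1/exponent)``, so that applying the
power transform with the same exponent recovers exactly the linear-Gaussian
model the pipeline fits.  Per-cell replicate counts default to the 9-20
range typical of the gene-deletion experiments this design emulates.

``reference_conditions`` provides named effect-size regimes (all synthetic
stand-ins, not measured data) spanning the qualitative behaviours seen in
such experiments: a near-null control, configurations with strong main and
interaction effects, and an interaction-dominant configuration whose main
effects sit at the detection limit of half-split sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ColonyTable, box_cox_transform
from .pipeline import run_lasso_bic, run_linear_comparison, run_hier, seed_schedule

CELLS = ((0, 0), (0, 1), (1, 0), (1, 1))

#: factor levels written into generated tables (coded 1: "del", "present")
CHROM_LEVELS = ("wt", "del")
NONCHROM_LEVELS = ("absent", "present")


@dataclass(frozen=True)
class SynthConfig:
    """Effect sizes on the transformed scale for one simulated experiment.

    ``beta0`` is the baseline cell mean, ``beta1``/``beta2`` the chromosomal
    and non-chromosomal main effects, ``beta3`` the interaction, ``sigma``
    the replicate noise SD — all on the ``y = c**exponent`` scale.
    ``replicates_per_cell`` may be a single count or one per cell in the
    order (0,0), (0,1), (1,0), (1,1); ``None`` draws each uniformly from
    9..20.
    """

    beta0: float = 4.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    sigma: float = 0.2
    replicates_per_cell: tuple | int | None = None
    exponent: float = 0.25
    seed: int = 0
    experiment_id: str = "synthetic"

    def cell_mean(self, x1: int, x2: int) -> float:
        return self.beta0 + self.beta1 * x1 + self.beta2 * x2 + self.beta3 * x1 * x2

    def validate(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")
        if self.exponent <= 0:
            raise ValidationError("exponent must be positive")
        for x1, x2 in CELLS:
            if self.cell_mean(x1, x2) <= 0:
                raise ValidationError(
                    f"cell ({x1},{x2}) mean {self.cell_mean(x1, x2)} is not positive "
                    "on the transformed scale; increase beta0"
                )


def _replicate_counts(config: SynthConfig, rng: np.random.Generator) -> list[int]:
    r = config.replicates_per_cell
    if r is None:
        counts = [int(rng.integers(9, 21)) for _ in CELLS]
    elif np.isscalar(r):
        counts = [int(r)] * 4
    else:
        counts = [int(v) for v in r]
        if len(counts) != 4:
            raise ValidationError("replicates_per_cell needs one count per cell")
    if any(c < 2 for c in counts):
        raise ValidationError("every cell needs at least 2 replicates")
    return counts


def generate_experiment(config: SynthConfig, max_redraws: int = 100) -> ColonyTable:
    """Draw one experiment table (raw sizes plus the transformed response).

    Deterministic given ``config.seed``.  Draws whose transformed value is
    non-positive (impossible colony size) are redrawn up to ``max_redraws``
    times, then an error advises a larger ``beta0`` or smaller ``sigma``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = _replicate_counts(config, rng)
    rows = []
    for (x1, x2), k in zip(CELLS, counts):
        mean = config.cell_mean(x1, x2)
        for rep in range(1, k + 1):
            y = mean + config.sigma * rng.standard_normal()
            redraws = 0
            while y <= 0:
                redraws += 1
                if redraws > max_redraws:
                    raise ValidationError(
                        "could not draw a positive transformed response; "
                        "increase beta0 or decrease sigma"
                    )
                y = mean + config.sigma * rng.standard_normal()
            rows.append({
                "experiment": config.experiment_id,
                "chrom": CHROM_LEVELS[x1],
                "nonchrom": NONCHROM_LEVELS[x2],
                "replicate": rep,
                "colony_size": y ** (1.0 / config.exponent),
            })
    table = ColonyTable(pd.DataFrame(rows))
    return box_cox_transform(table, config.exponent)


def reference_conditions(seed: int = 0) -> dict[str, SynthConfig]:
    """Named synthetic regimes used as fixtures throughout the package.

    Effect sizes are fixture choices on the transformed scale (sigma = 0.2
    unless noted), spanning a weak-chromosomal control, strong-effect
    experiments, an interaction-dominant experiment with near-threshold main
    effects, and a near-null experiment.
    """
    base = SynthConfig(beta0=4.0, sigma=0.2)
    conds = {
        "control_weak_chromosomal": replace(base, beta1=0.10),
        "strong_interaction": replace(base, beta1=-0.80, beta2=0.30, beta3=1.00),
        "main_plus_interaction": replace(base, beta1=-1.00, beta2=0.02, beta3=0.80),
        "interaction_dominant": replace(base, beta1=-0.12, beta2=0.06, beta3=0.50),
        "near_null": replace(base, sigma=0.25, beta1=0.03, beta2=0.02),
    }
    out = {}
    for i, (name, cfg) in enumerate(conds.items()):
        out[name] = replace(cfg, seed=seed_schedule(seed, i), experiment_id=name)
    return out


def recovery_suite(
    effect_grid: list[SynthConfig],
    repeats: int = 200,
    master_seed: int = 0,
    methods: tuple = ("linear", "lasso"),
) -> pd.DataFrame:
    """Selection frequency of the interaction term over a grid of effect sizes.

    Unlike the resampling pipeline — which resamples splits of one fixed
    table, as the colony analysis does — each repeat here draws a *fresh*
    experiment from the generator and runs one modelling pass, so the
    frequencies estimate the procedure's operating characteristics (type-I
    rate under ``beta3 = 0``, power against ``beta3 > 0``) over the generator
    distribution rather than properties of a single realisation.

    Returns one row per (config, method) with the frequency of the
    interaction model (``linear``: test-MSE winner) or of the X1X2 predictor
    (``lasso``: BIC support; ``hier``: CV/1-SE support).
    """
    if not effect_grid:
        raise ValidationError("effect grid is empty")
    rows = []
    for i, cfg in enumerate(effect_grid):
        exp = cfg.experiment_id
        base_seed = seed_schedule(master_seed, i)
        for m, method in enumerate(methods):
            hits = 0
            for r in range(repeats):
                draw = seed_schedule(base_seed + m + 1, r)
                table = generate_experiment(replace(cfg, seed=draw))
                if method == "linear":
                    s = run_linear_comparison(table, exp, 1, draw)
                    hits += s.model_freq["interaction"]
                elif method == "lasso":
                    s = run_lasso_bic(table, exp, 1, draw)
                    hits += 1 if s.predictor_freq["X1X2"] else 0
                elif method == "hier":
                    s = run_hier(table, exp, 1, draw)
                    hits += 1 if s.predictor_freq["X1X2"] else 0
                else:
                    raise ValidationError(f"unknown method {method!r}")
            rows.append({"experiment": exp, "method": method,
                         "beta1": cfg.beta1, "beta2": cfg.beta2,
                         "beta3": cfg.beta3, "sigma": cfg.sigma,
                         "interaction_freq": hits / repeats, "repeats": repeats})
    return pd.DataFrame(rows)
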