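"""Simulation studies that calibrate and validate the estimators.

Each routine generates data with the synthetic-data module, runs the
corresponding analysis, and measures a frequentist property against the
generator's ground truth: CI coverage of the tilt, type-I error rates of the
tilt and Gehan-Breslow-Wilcoxon tests, the sign of the aging/treatment
anti-correlation, and recovery of the senescent fraction by gating.  The
same routines back both the test suite and the reproduction script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .gating import default_gating_config, senescent_fraction
from .rejuvenation import anti_correlation, tilt_regression
from .simulate import (
    CellSimConfig,
    ExpressionSimConfig,
    SurvivalSimConfig,
    WeibullGroup,
    simulate_cell_features,
    simulate_counts,
    simulate_effects,
    simulate_survival,
)
from .survival import gehan_breslow_wilcoxon
from .expression import fold_change_table, log_expression, size_factors


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def tilt_ci_coverage(
    kappa: float,
    n_reps: int,
    config: ExpressionSimConfig | None = None,
    seed: int = 0,
    conf_level: float = 0.95,
    generate_counts: bool = True,
) -> float:
    """Fraction of per-tissue tilt CIs covering the true tilt 1 - kappa.

    Parameter recovery is measured on the generator's true per-gene fold
    changes (x = beta, y = beta + gamma over age-affected genes): the
    count-estimated fold changes carry errors-in-variables attenuation that
    is a property of the estimator, not of the CI (see the methods note).
    When ``generate_counts`` is true the full count matrices are drawn as
    well, so each replicate is a complete simulated study.
    """
    base = config or ExpressionSimConfig()
    base = dataclasses.replace(base, rejuvenation_kappa=kappa)
    seeds = _child_seeds(seed, n_reps)
    covered = total = 0
    for s in seeds:
        cfg = dataclasses.replace(base, seed=int(s))
        if generate_counts:
            _, truth = simulate_counts(cfg)
        else:
            truth, _ = simulate_effects(cfg)
        for tissue in cfg.tissues:
            t = truth.tissue_truth(tissue)
            aff = t[t["affected_by_age"]]
            res = tilt_regression(
                aff["beta"].to_numpy(),
                aff["beta"].to_numpy() + aff["gamma"].to_numpy(),
                conf_level=conf_level,
            )
            covered += int(res.ci_low <= truth.true_tilt <= res.ci_high)
            total += 1
    return covered / total


def tilt_type_i_rate(
    n_reps: int = 2000,
    config: ExpressionSimConfig | None = None,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the tilt-vs-1 test under kappa = 0 on true fold changes."""
    base = config or ExpressionSimConfig(n_genes=2000, tissues=("kidney",))
    base = dataclasses.replace(base, rejuvenation_kappa=0.0)
    seeds = _child_seeds(seed, n_reps)
    rejections = 0
    for s in seeds:
        cfg = dataclasses.replace(base, seed=int(s))
        truth, _ = simulate_effects(cfg)
        t = truth.tissue_truth(cfg.tissues[0])
        aff = t[t["affected_by_age"]]
        res = tilt_regression(
            aff["beta"].to_numpy(), aff["beta"].to_numpy() + aff["gamma"].to_numpy()
        )
        rejections += int(res.p_value <= alpha)
    return rejections / n_reps


def estimated_fold_changes(cfg: ExpressionSimConfig):
    """Simulate counts and return {tissue: (FoldChangeTable, tissue truth)}."""
    cm, truth = simulate_counts(cfg)
    factors = size_factors(cm.counts)
    log_mat = log_expression(cm.counts, factors)
    out = {}
    for tissue in cfg.tissues:
        fct = fold_change_table(log_mat, cm.metadata, tissue)
        out[tissue] = (fct, truth.tissue_truth(tissue))
    return out


def anticorrelation_negative_rate(
    n_reps: int = 200,
    config: ExpressionSimConfig | None = None,
    seed: int = 0,
) -> float:
    """Fraction of (replicate, tissue) runs with Spearman rho < 0.

    rho is computed between the count-estimated aging fold change
    log2(vehicle/young) and treatment fold change log2(treated/vehicle) over
    age-affected genes, mirroring the per-tissue analysis.
    """
    base = config or ExpressionSimConfig(
        n_genes=2000, tissues=("kidney",), rejuvenation_kappa=0.5
    )
    seeds = _child_seeds(seed, n_reps)
    negative = total = 0
    for s in seeds:
        cfg = dataclasses.replace(base, seed=int(s))
        for tissue, (fct, t) in estimated_fold_changes(cfg).items():
            genes = t.index[t["affected_by_age"]]
            sub = fct.table.loc[genes]
            res = anti_correlation(sub["lfc_age"].to_numpy(), sub["lfc_treat"].to_numpy())
            negative += int(res.rho < 0)
            total += 1
    return negative / total


def gbw_type_i_rate(
    n_reps: int = 2000,
    n_per_group: int = 30,
    seed: int = 0,
    alpha: float = 0.05,
    n_groups: int = 2,
) -> float:
    """Rejection rate of the GBW test with all groups drawn identically."""
    seeds = _child_seeds(seed, n_reps)
    groups = {
        f"g{i}": WeibullGroup(shape=1.5, scale_days=400.0) for i in range(n_groups)
    }
    rejections = 0
    for s in seeds:
        cfg = SurvivalSimConfig(
            groups=groups, n_per_group=n_per_group, censor_time_days=700.0, seed=int(s)
        )
        table = simulate_survival(cfg)
        res = gehan_breslow_wilcoxon(table)
        rejections += int(res.p_value <= alpha)
    return rejections / n_reps


def gating_recovery(
    fractions=(0.02, 0.1, 0.4), n_cells: int = 30_000, seed: int = 0
) -> pd.DataFrame:
    """Recovered vs true senescent fraction with a binomial 99% CI per run."""
    from scipy import stats

    rows = []
    seeds = _child_seeds(seed, len(fractions))
    for f, s in zip(fractions, seeds):
        cfg = CellSimConfig(n_cells=n_cells, senescent_fraction=f, seed=int(s))
        cells, truth = simulate_cell_features(cfg)
        res = senescent_fraction(cells, default_gating_config())
        denom = int(res.stages.set_index("stage").loc["cd45_negative", "n_out"])
        lo, hi = stats.binom.interval(0.99, denom, truth.senescent_fraction)
        rows.append(
            {
                "target_fraction": f,
                "true_fraction": truth.senescent_fraction,
                "recovered_fraction": res.senescent_fraction,
                "n_denominator": denom,
                "ci99_low": lo / denom,
                "ci99_high": hi / denom,
                "within_ci": lo / denom <= res.senescent_fraction <= hi / denom,
            }
        )
    return pd.DataFrame(rows)
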