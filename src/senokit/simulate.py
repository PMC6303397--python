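"""Synthetic-data generators with recorded ground truth.

Three simulators emulate the data structures behind a senolytic intervention
study in aged, immune-compromised mice:

* ``simulate_counts`` — bulk RNA-seq-like negative-binomial counts for four
  tissues and three groups (young, old vehicle-treated, old senolytic-treated).
  Each age-affected gene g carries an aging log2 effect ``beta_g``; treatment
  reverses a fraction ``kappa`` of it (``gamma_g = -kappa * beta_g + noise``),
  so the true regression tilt of log2(treated/young) on log2(vehicle/young)
  over age-affected genes is ``1 - kappa``.
* ``simulate_survival`` — per-group Weibull lifetimes with administrative
  censoring.
* ``simulate_cell_features`` — imaging-cytometry-like per-cell feature tables
  (brightfield area/aspect ratio, focus features, CD45 and SA-beta-Gal
  intensities, HMGB1 spot counts) with a known senescent fraction.

All simulators are deterministic given their config (which includes the
seed); ground truth is returned separately from the observable tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import CountMatrix

DEFAULT_TISSUES = ("kidney", "liver", "lung", "skin")
GROUPS = ("young", "old_vehicle", "old_treated")

PRNG_ALGORITHM = "numpy PCG64 (default_rng)"


def _check(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field_name}: {message}")


# ---------------------------------------------------------------------------
# Expression


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Configuration for the bulk-count simulator.

    ``baseline_mean_log2`` are the (location, scale) of the normal
    distribution of per-gene baseline log2 expression mu_g.  ``dispersion``
    is the NB dispersion phi in the mean/variance parameterization
    ``var = m + phi * m**2``.  ``rejuvenation_kappa`` is the fraction of the
    aging effect reversed by treatment.
    """

    n_genes: int = 10_000
    n_replicates_per_group: int = 5
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    baseline_mean_log2: tuple[float, float] = (5.0, 2.0)
    dispersion: float = 0.1
    frac_age_affected: float = 0.2
    age_effect_sd: float = 1.0
    rejuvenation_kappa: float = 0.5
    treatment_noise_sd: float = 0.2
    sasp_genes: int = 56
    sasp_age_up_bias: float = 0.8
    libsize_log2_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_genes >= 1, "n_genes", "must be >= 1")
        _check(self.n_replicates_per_group >= 2, "n_replicates_per_group", "must be >= 2")
        _check(len(self.tissues) >= 1, "tissues", "must be non-empty")
        _check(self.dispersion > 0, "dispersion", "must be > 0")
        _check(self.baseline_mean_log2[1] >= 0, "baseline_mean_log2", "scale must be >= 0")
        _check(0 <= self.frac_age_affected <= 1, "frac_age_affected", "must be in [0, 1]")
        _check(0 <= self.rejuvenation_kappa <= 1, "rejuvenation_kappa", "must be in [0, 1]")
        _check(self.treatment_noise_sd >= 0, "treatment_noise_sd", "must be >= 0")
        _check(self.age_effect_sd >= 0, "age_effect_sd", "must be >= 0")
        _check(0 <= self.sasp_genes <= self.n_genes, "sasp_genes", "must be in [0, n_genes]")
        _check(0 <= self.sasp_age_up_bias <= 1, "sasp_age_up_bias", "must be in [0, 1]")
        _check(self.libsize_log2_sd >= 0, "libsize_log2_sd", "must be >= 0")


@dataclass
class ExpressionTruth:
    """Ground truth behind a simulated count matrix.

    ``table`` has one row per (tissue, gene) with the aging effect ``beta``,
    the treatment effect ``gamma``, and the ``affected_by_age`` / ``sasp``
    flags.  ``true_tilt`` is the implied regression slope 1 - kappa.
    """

    table: pd.DataFrame
    true_tilt: float
    sasp_gene_ids: list[str]

    def tissue_truth(self, tissue: str) -> pd.DataFrame:
        sub = self.table[self.table["tissue"] == tissue]
        return sub.set_index("gene_id")


def simulate_effects(config: ExpressionSimConfig, rng: np.random.Generator | None = None):
    """Draw per-(tissue, gene) effects and flags without generating counts.

    Returns (truth, baselines) where baselines maps tissue -> mu_g array.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(n)])
    sasp_idx = rng.choice(n, size=config.sasp_genes, replace=False)
    sasp_flag = np.zeros(n, dtype=bool)
    sasp_flag[sasp_idx] = True

    loc, scale = config.baseline_mean_log2
    rows = []
    baselines = {}
    for tissue in config.tissues:
        mu = rng.normal(loc, scale, size=n)
        affected = rng.random(n) < config.frac_age_affected
        beta = np.where(affected, rng.normal(0.0, config.age_effect_sd, size=n), 0.0)
        # SASP genes are biased toward age-upregulation so the enrichment
        # analysis has signal: with probability sasp_age_up_bias a SASP gene
        # is forced age-affected with a positive effect.
        forced = sasp_flag & (rng.random(n) < config.sasp_age_up_bias)
        beta = np.where(forced, np.abs(rng.normal(0.0, config.age_effect_sd, size=n)), beta)
        # guard against a forced SASP gene drawing an exactly-zero effect
        beta = np.where(forced & (beta == 0), config.age_effect_sd, beta)
        affected = affected | forced
        beta = np.where(affected, beta, 0.0)
        noise = rng.normal(0.0, config.treatment_noise_sd, size=n) if config.treatment_noise_sd else 0.0
        gamma = np.where(affected, -config.rejuvenation_kappa * beta + noise, 0.0)
        baselines[tissue] = mu
        rows.append(
            pd.DataFrame(
                {
                    "tissue": tissue,
                    "gene_id": gene_ids,
                    "baseline_log2": mu,
                    "beta": beta,
                    "gamma": gamma,
                    "affected_by_age": affected,
                    "sasp": sasp_flag,
                }
            )
        )
    truth = ExpressionTruth(
        table=pd.concat(rows, ignore_index=True),
        true_tilt=1.0 - config.rejuvenation_kappa,
        sasp_gene_ids=list(gene_ids[sasp_flag]),
    )
    return truth, baselines


def simulate_counts(config: ExpressionSimConfig) -> tuple[CountMatrix, ExpressionTruth]:
    """Negative-binomial counts with mean s_j * 2**(mu + beta*I[old] + gamma*I[treated]).

    ``s_j`` is a per-sample library-size multiplier drawn log-normal
    (sd ``libsize_log2_sd`` in log2 units) to exercise normalization.
    Identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    truth, baselines = simulate_effects(config, rng)
    reps = config.n_replicates_per_group
    inv_phi = 1.0 / config.dispersion

    blocks, meta_rows = [], []
    for tissue in config.tissues:
        t = truth.tissue_truth(tissue)
        mu = baselines[tissue]
        log2_mean = np.empty((config.n_genes, 3 * reps))
        col = 0
        for group in GROUPS:
            expr = mu.copy()
            if group != "young":
                expr = expr + t["beta"].to_numpy()
            if group == "old_treated":
                expr = expr + t["gamma"].to_numpy()
            for r in range(reps):
                log2_mean[:, col] = expr
                meta_rows.append(
                    {
                        "sample_id": f"{tissue}_{group}_r{r + 1}",
                        "tissue": tissue,
                        "group": group,
                        "replicate": r + 1,
                    }
                )
                col += 1
        s = 2.0 ** rng.normal(0.0, config.libsize_log2_sd, size=3 * reps)
        m = (2.0 ** log2_mean) * s[None, :]
        p = inv_phi / (inv_phi + m)
        blocks.append(rng.negative_binomial(inv_phi, p))

    gene_index = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene_id")
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    counts = pd.DataFrame(np.hstack(blocks), index=gene_index, columns=meta.index)
    return CountMatrix(counts=counts, metadata=meta), truth


# ---------------------------------------------------------------------------
# Survival


@dataclass(frozen=True)
class WeibullGroup:
    shape: float
    scale_days: float


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Per-group Weibull lifetimes with administrative censoring."""

    groups: dict = field(
        default_factory=lambda: {
            "wildtype": WeibullGroup(shape=4.0, scale_days=850.0),
            "immune_deficient": WeibullGroup(shape=4.0, scale_days=680.0),
        }
    )
    n_per_group: int = 30
    censor_time_days: float = 1100.0
    seed: int = 0

    def validate(self) -> None:
        _check(len(self.groups) >= 1, "groups", "must define at least one group")
        _check(self.n_per_group >= 2, "n_per_group", "must be >= 2")
        _check(self.censor_time_days >= 0, "censor_time_days", "must be >= 0")
        for name, g in self.groups.items():
            g = _as_weibull(g)
            _check(g.shape > 0, f"groups[{name}].shape", "must be > 0")
            _check(g.scale_days > 0, f"groups[{name}].scale_days", "must be > 0")


def _as_weibull(g) -> WeibullGroup:
    if isinstance(g, WeibullGroup):
        return g
    if isinstance(g, dict):
        return WeibullGroup(**g)
    return WeibullGroup(*g)


def simulate_survival(config: SurvivalSimConfig) -> pd.DataFrame:
    """Survival table (subject_id, group, time_days, event), censored at the horizon."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for name, g in config.groups.items():
        g = _as_weibull(g)
        times = g.scale_days * rng.weibull(g.shape, size=config.n_per_group)
        event = (times <= config.censor_time_days).astype(int)
        times = np.minimum(times, config.censor_time_days)
        for i, (t, e) in enumerate(zip(times, event)):
            rows.append(
                {
                    "subject_id": f"{name}_{i + 1:03d}",
                    "group": name,
                    "time_days": float(t),
                    "event": int(e),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cell features


@dataclass(frozen=True)
class CellSimConfig:
    """Imaging-cytometry feature-table simulator.

    Cells fall into debris/doublets, out-of-focus cells, immune (CD45-high)
    cells, and clean non-immune cells; among the latter a fraction
    ``senescent_fraction`` is senescent (high SA-beta-Gal, zero-centered
    HMGB1 spot count, CD45-low).  Feature distributions are normal (Poisson
    for spot counts) with defaults giving well-separated populations.
    """

    n_cells: int = 30_000
    senescent_fraction: float = 0.1
    debris_fraction: float = 0.08
    out_of_focus_fraction: float = 0.05
    immune_fraction: float = 0.15
    # (mean, sd) per feature; spot counts are Poisson(lambda)
    features: dict = field(
        default_factory=lambda: {
            "bf_area": {"single": (120.0, 20.0), "debris": (25.0, 8.0)},
            "bf_aspect_ratio": {"single": (0.9, 0.05), "debris": (0.45, 0.1)},
            "contrast": {"focused": (60.0, 15.0), "unfocused": (6.0, 2.0)},
            "gradient_rms": {"focused": (80.0, 20.0), "unfocused": (12.0, 4.0)},
            "cd45_intensity": {"immune": (900.0, 150.0), "other": (80.0, 30.0)},
            "sabgal_intensity": {"senescent": (1000.0, 120.0), "other": (150.0, 50.0)},
            "hmgb1_spot_count": {"senescent": 0.0, "other": 8.0},
        }
    )
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_cells >= 1, "n_cells", "must be >= 1")
        for name in ("senescent_fraction", "debris_fraction", "out_of_focus_fraction", "immune_fraction"):
            _check(0 <= getattr(self, name) <= 1, name, "must be in [0, 1]")
        _check(
            self.debris_fraction + self.out_of_focus_fraction + self.immune_fraction <= 1,
            "debris_fraction + out_of_focus_fraction + immune_fraction",
            "must sum to <= 1",
        )


@dataclass
class CellTruth:
    """Per-cell population labels and the realized senescent fraction.

    ``senescent_fraction`` is the fraction of senescent cells among clean
    (single, focused) non-immune cells — the denominator the gating analysis
    targets.
    """

    labels: pd.Series
    senescent_fraction: float


def simulate_cell_features(config: CellSimConfig) -> tuple[pd.DataFrame, CellTruth]:
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    u = rng.random(n)
    p_debris = config.debris_fraction
    p_oof = config.out_of_focus_fraction
    # immune/senescent fractions are defined within the clean compartment
    labels = np.full(n, "healthy", dtype=object)
    labels[u < p_debris] = "debris"
    labels[(u >= p_debris) & (u < p_debris + p_oof)] = "out_of_focus"
    clean = u >= p_debris + p_oof
    v = rng.random(n)
    immune = clean & (v < config.immune_fraction)
    labels[immune] = "immune"
    clean_nonimmune = clean & ~immune
    w = rng.random(n)
    senescent = clean_nonimmune & (w < config.senescent_fraction)
    labels[senescent] = "senescent"

    f = config.features

    def draw(spec, key_map):
        out = np.empty(n)
        for key, mask in key_map.items():
            mu, sd = spec[key]
            out[mask] = rng.normal(mu, sd, size=int(mask.sum()))
        return out

    is_debris = labels == "debris"
    is_oof = labels == "out_of_focus"
    is_immune = labels == "immune"
    is_sen = labels == "senescent"
    not_debris = ~is_debris
    table = pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(n)],
            "bf_area": draw(f["bf_area"], {"debris": is_debris, "single": not_debris}),
            "bf_aspect_ratio": np.clip(
                draw(f["bf_aspect_ratio"], {"debris": is_debris, "single": not_debris}), 0.0, 1.0
            ),
            "contrast": draw(f["contrast"], {"unfocused": is_oof, "focused": ~is_oof}),
            "gradient_rms": draw(f["gradient_rms"], {"unfocused": is_oof, "focused": ~is_oof}),
            "cd45_intensity": draw(f["cd45_intensity"], {"immune": is_immune, "other": ~is_immune}),
            "sabgal_intensity": draw(
                f["sabgal_intensity"], {"senescent": is_sen, "other": ~is_sen}
            ),
        }
    ).set_index("cell_id")
    lam = np.where(is_sen, f["hmgb1_spot_count"]["senescent"], f["hmgb1_spot_count"]["other"])
    table["hmgb1_spot_count"] = rng.poisson(lam)

    n_clean_nonimmune = int(clean_nonimmune.sum())
    frac = float(senescent.sum() / n_clean_nonimmune) if n_clean_nonimmune else float("nan")
    truth = CellTruth(
        labels=pd.Series(labels, index=table.index, name="population"),
        senescent_fraction=frac,
    )
    return table, truth
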