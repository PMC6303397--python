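"""Transcriptomic rejuvenation statistics.

Four statistics quantify whether a senolytic treatment moves the old
transcriptome back toward the young one:

* **Affected-gene overlap** — upper-tail hypergeometric enrichment of the
  intersection of the treatment-affected and age-affected gene sets, with the
  overlap reported as a fraction of the treatment-affected set.
* **SASP score** — mean log2 ratio (old over young) across detected genes of
  the senescence-associated secretory phenotype set, for both the vehicle and
  the treated arm, compared by a paired Wilcoxon signed-rank test.
* **Tilt regression** — OLS of log2(treated/young) on log2(vehicle/young)
  over age-affected genes; the slope ("tilt") is tested against the null
  tilt = 1.  A tilt below 1 means treatment pulled expression of age-affected
  genes back toward young levels.
* **Anti-correlation** — Spearman correlation between the aging fold change
  log2(vehicle/young) and the treatment fold change log2(treated/vehicle); a
  negative rho means treatment opposes the aging signature gene-by-gene.

All logs are base 2 (tilt and rho are invariant to the common log base; the
SASP score's units are therefore declared log2).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError, StageError
from .expression import (
    CountMatrix,
    FoldChangeTable,
    call_affected,
    fold_change_table,
    log_expression,
    size_factors,
)

REPORT_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Gene sets (GMT)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataValidationError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    lines = ["\t".join([name, description, *genes]) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Hypergeometric overlap


@dataclass
class OverlapResult:
    """Hypergeometric overlap of two gene sets within a finite universe.

    ``p_value`` is the upper tail P(X >= k) for X ~ Hypergeom(N=|universe|,
    K=|set_a|, n=|set_b|); ``overlap_fraction_of_b`` is k/|set_b| (the
    fraction of treatment-affected genes that are also age-affected, in the
    headline usage).
    """

    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    overlap_fraction_of_b: float
    p_value: float

    def to_dict(self) -> dict:
        return asdict(self)


def overlap_enrichment(set_a, set_b, universe) -> OverlapResult:
    """Upper-tail hypergeometric test for the overlap of two gene sets."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    for name, s in (("set_a", set_a), ("set_b", set_b)):
        stray = s - universe
        if stray:
            shown = ", ".join(sorted(map(str, stray))[:5])
            raise DataValidationError(f"{name} not a subset of the universe: {shown}")
    N, K, n = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    frac = k / n if n else float("nan")
    return OverlapResult(
        n_universe=N, n_set_a=K, n_set_b=n, n_overlap=k,
        overlap_fraction_of_b=frac, p_value=min(p, 1.0),
    )


def sasp_enrichment(affected, sasp, universe) -> OverlapResult:
    """Enrichment of SASP genes among affected genes.

    The SASP set is first restricted to the universe (only detected SASP
    genes can be enriched); otherwise identical to :func:`overlap_enrichment`.
    """
    universe = set(universe)
    return overlap_enrichment(set(sasp) & universe, affected, universe)


# ---------------------------------------------------------------------------
# SASP score


@dataclass
class SaspScore:
    """Mean log2 ratio over detected SASP genes for one contrast.

    When no SASP gene is detected in the tissue the score is undefined
    (``defined`` False, ``score`` NaN) rather than 0.
    """

    tissue: str | None
    contrast: str
    score: float
    n_detected: int
    per_gene: pd.Series

    @property
    def defined(self) -> bool:
        return self.n_detected > 0

    def to_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "contrast": self.contrast,
            "score": None if not self.defined else self.score,
            "n_detected": self.n_detected,
            "defined": self.defined,
        }


_CONTRAST_COLUMNS = {
    "vehicle_vs_young": "lfc_age",
    "treated_vs_young": "lfc_treat_vs_young",
}


def sasp_score(fold_changes: FoldChangeTable, sasp, contrast: str) -> SaspScore:
    """Unweighted mean of per-gene log2 ratios over detected SASP genes."""
    if contrast not in _CONTRAST_COLUMNS:
        raise DataValidationError(
            f"contrast must be one of {sorted(_CONTRAST_COLUMNS)}, got {contrast!r}"
        )
    table = fold_changes.table
    genes = table.index.intersection(pd.Index(sorted(set(sasp))))
    detected = table.loc[genes, "detected"]
    genes = genes[detected.to_numpy(dtype=bool)]
    per_gene = table.loc[genes, _CONTRAST_COLUMNS[contrast]]
    score = float(per_gene.mean()) if len(per_gene) else float("nan")
    return SaspScore(
        tissue=fold_changes.tissue,
        contrast=contrast,
        score=score,
        n_detected=int(len(per_gene)),
        per_gene=per_gene,
    )


def compare_sasp_scores(vehicle_ratios: pd.Series, treated_ratios: pd.Series) -> float:
    """Two-sided paired Wilcoxon signed-rank p on per-gene SASP ratios.

    Pairs are aligned on the gene index; scipy's exact null distribution is
    used for small samples (no zeros/ties), otherwise the normal
    approximation.
    """
    common = vehicle_ratios.index.intersection(treated_ratios.index)
    if len(common) == 0:
        raise DataValidationError("no paired SASP genes to compare")
    v = vehicle_ratios.loc[common].to_numpy(dtype=float)
    t = treated_ratios.loc[common].to_numpy(dtype=float)
    if np.allclose(v, t):
        return 1.0
    return float(stats.wilcoxon(t, v, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Tilt regression


@dataclass
class TiltResult:
    """OLS slope of log2(treated/young) on log2(vehicle/young), tested vs 1."""

    tilt: float
    intercept: float
    slope_se: float
    t_statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    conf_level: float
    n_genes: int

    def to_dict(self) -> dict:
        return asdict(self)


def tilt_regression(
    x,
    y=None,
    genes=None,
    conf_level: float = 0.95,
) -> TiltResult:
    """Fit y = a + tilt * x by OLS and test tilt against the null tilt = 1.

    ``x`` may be a :class:`FoldChangeTable` (then x = lfc_age and
    y = lfc_treat_vs_young, optionally restricted to ``genes``) or a plain
    array with ``y`` given explicitly.  Degenerate perfect fits follow the
    limit behavior of the t-test: SE = 0 and tilt = 1 gives p = 1; SE = 0 and
    tilt != 1 gives p = 0.
    """
    if isinstance(x, FoldChangeTable):
        table = x.table
        if genes is not None:
            table = table.loc[table.index.intersection(pd.Index(list(genes)))]
        xv = table["lfc_age"].to_numpy(dtype=float)
        yv = table["lfc_treat_vs_young"].to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise DataValidationError("x and y must have equal length")
    n = xv.size
    if n < 3:
        raise DataValidationError(f"tilt regression needs >= 3 genes, got {n}")
    if np.ptp(xv) == 0:
        raise DataValidationError("constant x: no aging signal to regress on")
    fit = stats.linregress(xv, yv)
    slope, se = float(fit.slope), float(fit.stderr)
    if se == 0.0 or not math.isfinite(se):
        exact_one = math.isclose(slope, 1.0, abs_tol=1e-12)
        return TiltResult(
            tilt=slope,
            intercept=float(fit.intercept),
            slope_se=se,
            t_statistic=0.0 if exact_one else math.copysign(math.inf, slope - 1.0),
            p_value=1.0 if exact_one else 0.0,
            ci_low=slope,
            ci_high=slope,
            conf_level=conf_level,
            n_genes=n,
        )
    t_stat = (slope - 1.0) / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), n - 2))
    tcrit = float(stats.t.ppf(0.5 + conf_level / 2.0, n - 2))
    return TiltResult(
        tilt=slope,
        intercept=float(fit.intercept),
        slope_se=se,
        t_statistic=t_stat,
        p_value=min(p, 1.0),
        ci_low=slope - tcrit * se,
        ci_high=slope + tcrit * se,
        conf_level=conf_level,
        n_genes=n,
    )


# ---------------------------------------------------------------------------
# Spearman anti-correlation


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p_value: float
    method: str  # "exact_permutation" | "asymptotic_t"

    def to_dict(self) -> dict:
        return asdict(self)


EXACT_PERMUTATION_MAX_N = 8


def anti_correlation(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    For n <= 8 the two-sided p-value is exact: the full n! permutation
    distribution of rho is enumerated.  For larger n the usual t
    approximation is used.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise DataValidationError("x and y must have equal length")
    n = xv.size
    if n < 3:
        raise DataValidationError(f"correlation needs n >= 3, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DataValidationError("constant input vector: Spearman rho undefined")
    rho = float(stats.spearmanr(xv, yv).statistic)
    if n <= EXACT_PERMUTATION_MAX_N:
        rx = stats.rankdata(xv)
        ry = stats.rankdata(yv)
        perms = np.array(list(itertools.permutations(ry)))
        rx_c = rx - rx.mean()
        p_c = perms - perms.mean(axis=1, keepdims=True)
        num = p_c @ rx_c
        den = np.sqrt((p_c**2).sum(axis=1) * (rx_c**2).sum())
        rhos = num / den
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return CorrelationResult(rho=rho, n=n, p_value=p, method="exact_permutation")
    p = float(stats.spearmanr(xv, yv).pvalue)
    return CorrelationResult(rho=rho, n=n, p_value=p, method="asymptotic_t")


# ---------------------------------------------------------------------------
# Full report


def rejuvenation_report(
    cm: CountMatrix,
    sasp: set | list,
    alpha: float = 0.05,
    lfc_min: float = 0.0,
    detection_threshold: float = 1.0,
    pseudocount: float = 1.0,
    conf_level: float = 0.95,
) -> dict:
    """Assemble the per-tissue rejuvenation statistics into one report.

    Per tissue: affected-gene sets for the aging (old_vehicle vs young) and
    treatment (old_treated vs old_vehicle) contrasts, their hypergeometric
    overlap (universe = detected genes), SASP enrichment and scores with the
    paired comparison, the tilt regression over age-affected genes, and the
    Spearman anti-correlation between aging and treatment fold changes.
    Cross-tissue: Euler counts of the unions of affected sets, plus a pooled
    tilt over all tissues' age-affected genes.
    """
    sasp = set(sasp)
    tissues = sorted(cm.metadata["tissue"].unique())
    try:
        factors = size_factors(cm.counts)
        log_mat = log_expression(cm.counts, factors, pseudocount)
    except DataValidationError as exc:
        raise StageError("normalization", str(exc)) from exc

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "parameters": {
            "alpha": alpha,
            "lfc_min": lfc_min,
            "detection_threshold": detection_threshold,
            "pseudocount": pseudocount,
            "conf_level": conf_level,
            "log_base": 2,
            "sasp_set_size": len(sasp),
        },
        "tissues": {},
    }

    union_age: set = set()
    union_treat: set = set()
    union_universe: set = set()
    pooled_x: list[np.ndarray] = []
    pooled_y: list[np.ndarray] = []

    for tissue in tissues:
        try:
            de_age = call_affected(
                log_mat, cm.metadata, ("old_vehicle", "young"), tissue, alpha, lfc_min
            )
            de_treat = call_affected(
                log_mat, cm.metadata, ("old_treated", "old_vehicle"), tissue, alpha, lfc_min
            )
            fct = fold_change_table(
                log_mat, cm.metadata, tissue, detection_threshold, pseudocount
            )
        except DataValidationError as exc:
            raise StageError(f"differential_expression:{tissue}", str(exc)) from exc

        universe = set(fct.detected_genes)
        age_set = set(de_age.affected_genes) & universe
        treat_set = set(de_treat.affected_genes) & universe
        union_age |= age_set
        union_treat |= treat_set
        union_universe |= universe

        overlap = overlap_enrichment(age_set, treat_set, universe)
        sasp_enr = sasp_enrichment(age_set | treat_set, sasp, universe)
        score_vehicle = sasp_score(fct, sasp, "vehicle_vs_young")
        score_treated = sasp_score(fct, sasp, "treated_vs_young")
        if score_vehicle.defined and score_treated.defined:
            comparison_p = compare_sasp_scores(score_vehicle.per_gene, score_treated.per_gene)
        else:
            comparison_p = None

        entry: dict = {
            "n_detected_genes": len(universe),
            "n_age_affected": len(age_set),
            "n_treatment_affected": len(treat_set),
            "overlap": overlap.to_dict(),
            "sasp_enrichment": sasp_enr.to_dict(),
            "sasp_scores": {
                "vehicle_vs_young": score_vehicle.to_dict(),
                "treated_vs_young": score_treated.to_dict(),
                "comparison_p": comparison_p,
            },
        }

        tilt_genes = sorted(age_set)
        if len(tilt_genes) >= 3:
            sub = fct.table.loc[tilt_genes]
            tilt = tilt_regression(fct, genes=tilt_genes, conf_level=conf_level)
            entry["tilt"] = tilt.to_dict()
            pooled_x.append(sub["lfc_age"].to_numpy())
            pooled_y.append(sub["lfc_treat_vs_young"].to_numpy())
            xv = sub["lfc_age"].to_numpy()
            yv = sub["lfc_treat"].to_numpy()
            if np.ptp(xv) > 0 and np.ptp(yv) > 0:
                entry["anti_correlation"] = anti_correlation(xv, yv).to_dict()
            else:
                entry["anti_correlation"] = None
        else:
            entry["tilt"] = None
            entry["anti_correlation"] = None
        report["tissues"][tissue] = entry

    both = union_age & union_treat
    combined: dict = {
        "euler": {
            "age_only": len(union_age - union_treat),
            "treatment_only": len(union_treat - union_age),
            "both": len(both),
        },
        "overlap": overlap_enrichment(union_age, union_treat, union_universe).to_dict()
        if union_universe
        else None,
    }
    if pooled_x:
        xs = np.concatenate(pooled_x)
        ys = np.concatenate(pooled_y)
        combined["pooled_tilt"] = (
            tilt_regression(xs, ys, conf_level=conf_level).to_dict() if xs.size >= 3 else None
        )
    else:
        combined["pooled_tilt"] = None
    report["combined"] = combined
    return report


def serialize_report(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def parse_report(text: str) -> dict:
    return json.loads(text)
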