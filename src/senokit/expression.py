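"""Bulk expression handling: counts I/O, normalization, and affected-gene calls.

The rejuvenation analysis consumes a gene x sample integer count matrix with
per-sample metadata (tissue, group, replicate).  Groups follow the three-arm
design of a senolytic intervention study in aged animals: ``young``,
``old_vehicle`` (aged, vehicle-treated) and ``old_treated`` (aged,
senolytic-treated).

The differential-expression procedure here is deliberately simple and fully
declared: median-of-ratios size factors, ``log2(count/factor + pseudocount)``,
per-gene Welch two-sample t-tests on log expression, Benjamini-Hochberg
adjustment, and an affected call at ``q <= alpha`` and ``|lfc| >= lfc_min``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataValidationError

GROUPS = ("young", "old_vehicle", "old_treated")

METADATA_COLUMNS = ("sample_id", "tissue", "group", "replicate")


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus per-sample metadata.

    ``counts`` is a DataFrame indexed by gene ID with sample IDs as columns;
    ``metadata`` is indexed by sample ID with columns ``tissue``, ``group``
    and ``replicate``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        counts, meta = self.counts, self.metadata
        dup = counts.index[counts.index.duplicated()].unique()
        if len(dup):
            raise DataValidationError(f"duplicate gene IDs: {', '.join(map(str, dup[:5]))}")
        dup = counts.columns[counts.columns.duplicated()].unique()
        if len(dup):
            raise DataValidationError(f"duplicate sample IDs: {', '.join(map(str, dup[:5]))}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataValidationError("counts must be numeric")
        if np.any(arr < 0):
            raise DataValidationError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise DataValidationError("counts must be integers")
        missing = counts.columns.difference(meta.index)
        if len(missing):
            raise DataValidationError(
                f"samples without metadata: {', '.join(map(str, missing[:5]))}"
            )
        for col in ("tissue", "group", "replicate"):
            if col not in meta.columns:
                raise DataValidationError(f"metadata missing required column '{col}'")
        bad = set(meta["group"]) - set(GROUPS)
        if bad:
            raise DataValidationError(
                f"unknown group labels {sorted(bad)}; expected one of {GROUPS}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_for(self, tissue: str | None = None, group: str | None = None) -> list[str]:
        meta = self.metadata.loc[self.counts.columns]
        mask = pd.Series(True, index=meta.index)
        if tissue is not None:
            mask &= meta["tissue"] == tissue
        if group is not None:
            mask &= meta["group"] == group
        return list(meta.index[mask])


# ---------------------------------------------------------------------------
# I/O


def _read_metadata(metadata_path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise DataValidationError(f"metadata file missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise DataValidationError("duplicate sample_id entries in metadata")
    return meta.set_index("sample_id")


def read_counts(count_path, metadata_path) -> CountMatrix:
    """Read a count matrix (dense TSV or MatrixMarket) with its metadata CSV.

    TSV format: first column ``gene_id``, remaining columns one per sample.
    MatrixMarket format: ``<stem>.mtx`` with sidecar line-per-entry index
    files ``<stem>.genes.txt`` and ``<stem>.samples.txt``.
    """
    count_path = Path(count_path)
    if count_path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(count_path).toarray()
        genes = count_path.with_suffix(".genes.txt").read_text().split()
        samples = count_path.with_suffix(".samples.txt").read_text().split()
        if mat.shape != (len(genes), len(samples)):
            raise DataValidationError(
                f"matrix shape {mat.shape} does not match sidecar indices "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=samples)
    else:
        counts = pd.read_csv(count_path, sep="\t", index_col=0, comment="#")
        counts.index.name = "gene_id"
    counts = counts.astype(np.int64, errors="ignore")
    meta = _read_metadata(metadata_path)
    extra = counts.columns.difference(meta.index)
    if len(extra):
        raise DataValidationError(
            f"samples without metadata: {', '.join(map(str, extra[:5]))}"
        )
    return CountMatrix(counts=counts, metadata=meta.loc[counts.columns])


def write_counts(cm: CountMatrix, count_path, metadata_path, fmt: str = "tsv") -> None:
    """Write counts as dense TSV (default) or MatrixMarket triplets."""
    count_path = Path(count_path)
    if fmt == "mtx" or count_path.suffix == ".mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(count_path), coo_matrix(cm.counts.to_numpy()))
        count_path.with_suffix(".genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
        count_path.with_suffix(".samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        out = cm.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(count_path, sep="\t")
    meta = cm.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path)


# ---------------------------------------------------------------------------
# Normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean across samples, computed over
    genes with nonzero counts in every sample; each sample's factor is the
    median of its count/reference ratios.
    """
    arr = counts.to_numpy(dtype=float)
    zero_samples = counts.columns[(arr.sum(axis=0) == 0)]
    if len(zero_samples):
        raise DataValidationError(
            f"sample(s) with all-zero counts: {', '.join(map(str, zero_samples[:5]))}"
        )
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise DataValidationError("no gene has nonzero counts in every sample")
    logc = np.log(arr[positive])
    ref = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - ref, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log_expression(
    counts: pd.DataFrame, factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), gene x sample."""
    if pseudocount <= 0:
        raise DataValidationError(f"pseudocount must be positive, got {pseudocount}")
    norm = counts.to_numpy(dtype=float) / factors.loc[counts.columns].to_numpy()
    return pd.DataFrame(np.log2(norm + pseudocount), index=counts.index, columns=counts.columns)


def group_log_ratio(
    log_mat: pd.DataFrame,
    metadata: pd.DataFrame,
    numerator: str,
    denominator: str,
    tissue: str | None = None,
) -> pd.Series:
    """Per-gene log2 ratio: difference of per-group means of log expression."""
    num = _group_samples(log_mat, metadata, numerator, tissue)
    den = _group_samples(log_mat, metadata, denominator, tissue)
    return log_mat[num].mean(axis=1) - log_mat[den].mean(axis=1)


def _group_samples(log_mat, metadata, group, tissue, min_n=1):
    meta = metadata.loc[log_mat.columns]
    mask = meta["group"] == group
    if tissue is not None:
        mask &= meta["tissue"] == tissue
    samples = list(meta.index[mask])
    where = f"tissue '{tissue}'" if tissue else "data"
    if len(samples) < min_n:
        raise DataValidationError(
            f"group '{group}' has {len(samples)} sample(s) in {where}; need >= {min_n}"
        )
    return samples


# ---------------------------------------------------------------------------
# Affected-gene calls


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise DataValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-gene differential-expression calls for one contrast."""

    table: pd.DataFrame  # mean_num, mean_den, log2_ratio, statistic, p_value, q_value, affected
    contrast: tuple[str, str]
    tissue: str | None
    alpha: float
    lfc_min: float

    @property
    def affected_genes(self) -> list[str]:
        return list(self.table.index[self.table["affected"]])


def call_affected(
    log_mat: pd.DataFrame,
    metadata: pd.DataFrame,
    contrast: tuple[str, str],
    tissue: str | None = None,
    alpha: float = 0.05,
    lfc_min: float = 0.0,
) -> DEResult:
    """Welch t per gene on log expression, BH adjustment, affected call.

    ``contrast = (numerator_group, denominator_group)``.  Genes with zero
    variance in both groups get p = 1 when the means agree and p = 0 when
    they differ (continuity of the decision rule at degenerate inputs).
    """
    num = _group_samples(log_mat, metadata, contrast[0], tissue, min_n=2)
    den = _group_samples(log_mat, metadata, contrast[1], tissue, min_n=2)
    a = log_mat[num].to_numpy()
    b = log_mat[den].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    same = degenerate & np.isclose(mean_a, mean_b)
    diff = degenerate & ~np.isclose(mean_a, mean_b)
    stat = np.where(degenerate, 0.0, stat)
    p = np.where(same, 1.0, p)
    p = np.where(diff, 0.0, p)
    q = bh_adjust(p)
    lfc = mean_a - mean_b
    table = pd.DataFrame(
        {
            "mean_num": mean_a,
            "mean_den": mean_b,
            "log2_ratio": lfc,
            "statistic": stat,
            "p_value": p,
            "q_value": q,
            "affected": (q <= alpha) & (np.abs(lfc) >= lfc_min),
        },
        index=log_mat.index,
    )
    return DEResult(table=table, contrast=contrast, tissue=tissue, alpha=alpha, lfc_min=lfc_min)


@dataclass
class FoldChangeTable:
    """Per-gene log2 ratios for the three contrasts of one tissue.

    Columns: ``lfc_age`` = log2(old_vehicle/young), ``lfc_treat_vs_young`` =
    log2(old_treated/young), ``lfc_treat`` = log2(old_treated/old_vehicle),
    plus a boolean ``detected`` flag (mean normalized count above threshold
    in at least one group).
    """

    table: pd.DataFrame
    tissue: str | None
    detection_threshold: float

    @property
    def detected_genes(self) -> list[str]:
        return list(self.table.index[self.table["detected"]])


def fold_change_table(
    log_mat: pd.DataFrame,
    metadata: pd.DataFrame,
    tissue: str | None = None,
    detection_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> FoldChangeTable:
    """Three-contrast fold-change table with detection flags.

    The identity ``lfc_treat_vs_young - lfc_age == lfc_treat`` holds exactly
    because all three columns derive from the same per-group means.
    """
    means = {}
    for group in GROUPS:
        samples = _group_samples(log_mat, metadata, group, tissue)
        means[group] = log_mat[samples].mean(axis=1)
    norm = 2.0 ** pd.DataFrame(means) - pseudocount
    detected = (norm >= detection_threshold).any(axis=1)
    table = pd.DataFrame(
        {
            "lfc_age": means["old_vehicle"] - means["young"],
            "lfc_treat_vs_young": means["old_treated"] - means["young"],
            "lfc_treat": means["old_treated"] - means["old_vehicle"],
            "detected": detected,
        },
        index=log_mat.index,
    )
    return FoldChangeTable(table=table, tissue=tissue, detection_threshold=detection_threshold)
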