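"""Per-study preprocessing for cross-platform expression meta-analysis.

The chain applied to every study, in order: log2 transform (if the matrix is
not already on the log scale), quantile normalization, KNN imputation of
missing cells, probe-to-gene collapse by the arithmetic mean, per-gene
standardization to mean 0 / unit variance, and finally restriction of all
studies to their common gene intersection.  A numeric relative-log-expression
(RLE) summary is available as a per-sample quality check; it is reported, not
used to drop samples automatically.

Fold changes must be computed on the gene-level matrix *before* per-gene
standardization (standardizing rescales every gene, destroying the log-ratio
interpretation); test statistics and effect sizes are scale-invariant and may
use either matrix.  :class:`PreprocessedStudy` therefore carries both.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .manifest_io import StudyExpression, ValidationError

logger = logging.getLogger("xmeta")

ProbeGeneMap = Mapping[str, str]


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping probe id -> gene symbol."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: probe map needs two columns")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].tolist()[:5]
        raise ValidationError(f"{path}: probes mapped more than once, e.g. {dup}")
    return dict(zip(probes, genes.str.upper()))


def log2_transform(study: StudyExpression) -> StudyExpression:
    """Elementwise log2; identity when the matrix is flagged already-log."""
    if study.is_log2:
        return study
    values = study.values
    bad = (values <= 0) & values.notna()
    if bad.any().any():
        g = bad.any(axis=1)
        gene = g.index[g][0]
        s = bad.loc[gene]
        sample = s.index[s][0]
        raise ValidationError(
            f"{study.study_id}: non-positive intensity at ({gene}, {sample}); "
            "cannot log2-transform"
        )
    return study.with_values(np.log2(values), is_log2=True)


def quantile_normalize(x: pd.DataFrame) -> pd.DataFrame:
    """Force all columns to share one value distribution.

    The reference distribution is the vector of row means of the
    column-sorted matrix; each value is replaced by the reference value at
    its within-column rank, with ties receiving the mean of the reference
    values over their tied ranks.  Matrices with missing cells are handled
    by building the reference from per-column empirical quantiles on a
    common grid and assigning observed values by rank interpolation (the
    complete-data path is exact and unchanged).
    """
    single = isinstance(x, pd.DataFrame)
    values = x.to_numpy(dtype=float) if single else np.asarray(x, dtype=float)
    if values.ndim != 2:
        raise ValidationError("quantile_normalize expects a 2-D matrix")
    n, m = values.shape
    if m <= 1:
        return x.copy() if single else values.copy()
    if not np.isnan(values).any():
        out = _quantile_normalize_complete(values)
    else:
        out = _quantile_normalize_incomplete(values)
    if single:
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    return out


def _quantile_normalize_complete(values: np.ndarray) -> np.ndarray:
    n, m = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        assigned = reference.copy()
        # average the reference over runs of tied values
        start = 0
        for end in range(1, n + 1):
            if end == n or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    assigned[start:end] = reference[start:end].mean()
                start = end
        out[order, j] = assigned
    return out


def _quantile_normalize_incomplete(values: np.ndarray) -> np.ndarray:
    n, m = values.shape
    grid = (np.arange(n) + 0.5) / n
    cols_q = []
    for j in range(m):
        obs = values[~np.isnan(values[:, j]), j]
        if obs.size == 0:
            raise ValidationError(f"column {j} is entirely missing")
        cols_q.append(np.quantile(obs, grid))
    reference = np.mean(cols_q, axis=0)
    out = values.copy()
    for j in range(m):
        mask = ~np.isnan(values[:, j])
        obs = values[mask, j]
        ranks = rankdata(obs, method="average")
        q = (ranks - 0.5) / obs.size
        out[mask, j] = np.interp(q, grid, reference)
    return out


def knn_impute(x: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing cells from the k nearest rows.

    Distance between two rows is the Euclidean distance over their mutually
    observed columns, rescaled by sqrt(n_total / n_shared) so rows sharing
    few columns are not spuriously close.  A missing cell (g, j) is replaced
    by the mean of the column-j values of the k nearest rows observed at j.
    Observed entries are returned bit-identical.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    single = isinstance(x, pd.DataFrame)
    values = x.to_numpy(dtype=float) if single else np.asarray(x, dtype=float)
    n, m = values.shape
    missing = np.isnan(values)
    if not missing.any():
        return x.copy() if single else values.copy()
    if missing.all(axis=1).any():
        rows = np.flatnonzero(missing.all(axis=1))
        names = list(x.index[rows]) if single else rows.tolist()
        raise ValidationError(f"rows entirely missing, cannot impute: {names[:5]}")
    out = values.copy()
    obs = ~missing
    warned = False
    for g in np.flatnonzero(missing.any(axis=1)):
        row = values[g]
        shared = obs & obs[g]  # (n, m) columns both rows observe
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, values - row, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            d2 = np.einsum("ij,ij->i", diff, diff) * (m / n_shared)
        d2[n_shared == 0] = np.inf
        d2[g] = np.inf
        for j in np.flatnonzero(missing[g]):
            cand = np.flatnonzero(obs[:, j] & np.isfinite(d2))
            if cand.size == 0:
                raise ValidationError(
                    f"no candidate neighbor observed at column {j} for row {g}"
                )
            if cand.size < k and not warned:
                warnings.warn(
                    f"fewer than k={k} candidate neighbors available; using all",
                    stacklevel=2,
                )
                warned = True
            nearest = cand[np.argsort(d2[cand], kind="stable")[:k]]
            out[g, j] = values[nearest, j].mean()
    if single:
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    return out


def collapse_probes(study: StudyExpression, probe_map: ProbeGeneMap) -> StudyExpression:
    """Collapse probe-level rows to gene symbols by the arithmetic mean.

    Probes absent from the map are dropped (counted in the log, not fatal).
    Symbols are upper-cased for cross-species and gene-set matching.
    """
    if study.level != "probe":
        raise ValidationError(f"{study.study_id}: already at gene level")
    mapped = study.values.index.map(lambda p: probe_map.get(p))
    n_unmapped = int(pd.isna(mapped).sum())
    if n_unmapped:
        logger.info("%s: dropping %d unmapped probes", study.study_id, n_unmapped)
    keep = ~pd.isna(mapped)
    values = study.values.loc[keep]
    genes = pd.Index([str(g).upper() for g in mapped[keep]], name="gene")
    collapsed = values.groupby(genes).mean()
    return study.with_values(collapsed, level="gene")


def standardize_genes(x: pd.DataFrame, tol: float = 0.0) -> pd.DataFrame:
    """Scale each row to mean 0 and unit sample variance (denominator n-1)."""
    single = isinstance(x, pd.DataFrame)
    values = x.to_numpy(dtype=float) if single else np.asarray(x, dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd <= tol).ravel()
    if constant.any():
        names = (list(x.index[constant]) if single
                 else np.flatnonzero(constant).tolist())
        raise ValidationError(f"constant rows cannot be standardized: {names[:10]}")
    out = (values - mean) / sd
    if single:
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    return out


def common_genes(studies: Sequence[StudyExpression]) -> list[str]:
    """Sorted intersection of all studies' gene sets (gene level required)."""
    if not studies:
        raise ValidationError("no studies supplied")
    for st in studies:
        if st.level != "gene":
            raise ValidationError(f"{st.study_id}: still at probe level")
    inter: set[str] | None = None
    for st in studies:
        genes = set(st.values.index)
        inter = genes if inter is None else inter & genes
    if not inter:
        raise ValidationError("studies share no genes")
    return sorted(inter)


def qc_rle(x: pd.DataFrame) -> pd.DataFrame:
    """Relative log expression per sample: median and IQR of x[g, j] minus the
    gene-wise median.  Well-behaved samples have RLE medians near 0."""
    values = x.to_numpy(dtype=float)
    med = np.nanmedian(values, axis=1, keepdims=True)
    rle = values - med
    q1, q2, q3 = np.nanpercentile(rle, [25, 50, 75], axis=0)
    return pd.DataFrame(
        {"rle_median": q2, "rle_iqr": q3 - q1},
        index=list(x.columns),
    )


@dataclass
class PreprocessedStudy:
    """Gene-level matrices of one study after the preprocessing chain.

    ``gene_values``: log2-scale gene-level matrix (fold changes live here);
    ``standardized``: the same matrix after per-gene standardization (test
    statistics and effect sizes live here); both restricted to the common
    gene intersection in the same row order.
    """

    study_id: str
    gene_values: pd.DataFrame
    standardized: pd.DataFrame
    groups: pd.Series
    species: str | None = None

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def preprocess_collection(
    studies: Sequence[StudyExpression],
    probe_map: ProbeGeneMap | None = None,
    k_impute: int = 10,
) -> tuple[list[PreprocessedStudy], list[str]]:
    """Run the full preprocessing chain and intersect studies on common genes."""
    gene_level: list[StudyExpression] = []
    for st in studies:
        st = log2_transform(st)
        values = quantile_normalize(st.values)
        values = knn_impute(values, k=k_impute)
        st = st.with_values(values)
        if st.level == "probe":
            pmap = probe_map if probe_map is not None else {
                p: p.upper() for p in st.values.index
            }
            st = collapse_probes(st, pmap)
        gene_level.append(st)
    genes = common_genes(gene_level)
    out: list[PreprocessedStudy] = []
    for st in gene_level:
        gene_values = st.values.loc[genes]
        out.append(
            PreprocessedStudy(
                study_id=st.study_id,
                gene_values=gene_values,
                standardized=standardize_genes(gene_values),
                groups=st.groups,
                species=st.species,
            )
        )
    return out, genes
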