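"""Per-study two-group differential expression and cross-study consensus.

Each study is tested gene-by-gene with a two-sample t-test (Welch by default
— group sizes of 3 to 24 arrays make the equal-variance assumption fragile),
p-values are Benjamini-Hochberg adjusted, and a gene is called up- or
down-regulated when it clears both a p threshold and an absolute log2
fold-change threshold (default |log2FC| >= 1.5, i.e. about 2.8-fold).  Genes
called in at least ``min_support`` of the studies of a species form the
consensus DEG set; direction conflicts between studies are kept but flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import AbstractSet, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .manifest_io import MCAO, SHAM, StudyExpression, ValidationError
from .preprocess import PreprocessedStudy

_VARIANCE_FLOOR = 1e-12


def _split_groups(values: pd.DataFrame, groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    groups = groups.loc[values.columns]
    a = values.loc[:, groups == MCAO].to_numpy(dtype=float)
    b = values.loc[:, groups == SHAM].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("each group needs >= 2 samples for a t-test")
    return a, b


def group_stats(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-gene group means, SDs (ddof=1) and sizes for MCAO and sham."""
    a, b = _split_groups(values, groups)
    return pd.DataFrame(
        {
            "mean_mcao": a.mean(axis=1),
            "sd_mcao": a.std(axis=1, ddof=1),
            "n_mcao": a.shape[1],
            "mean_sham": b.mean(axis=1),
            "sd_sham": b.std(axis=1, ddof=1),
            "n_sham": b.shape[1],
        },
        index=values.index,
    )


def gene_t_test(
    x: StudyExpression | PreprocessedStudy | pd.DataFrame,
    groups: pd.Series | None = None,
    variant: str = "welch",
) -> pd.DataFrame:
    """Two-sample t-test per gene (MCAO vs sham), two-sided.

    ``variant`` is ``"student"`` (pooled variance, df = n1+n2-2) or
    ``"welch"`` (Satterthwaite df).  Genes with zero variance in both groups
    get p = 1 when the means are equal, otherwise the variance is floored at
    1e-12 with a warning.
    """
    if isinstance(x, (StudyExpression, PreprocessedStudy)):
        values = x.values if isinstance(x, StudyExpression) else x.standardized
        groups = x.groups
    else:
        values = x
        if groups is None:
            raise ValidationError("groups required when passing a bare matrix")
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    a, b = _split_groups(values, groups)
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)

    if variant == "student":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se2, float(n1 + n2 - 2))
    else:
        t1, t2 = v1 / n1, v2 / n2
        se2 = t1 + t2
        with np.errstate(invalid="ignore", divide="ignore"):
            df = se2**2 / (t1**2 / (n1 - 1) + t2**2 / (n2 - 1))

    diff = m1 - m2
    zero = se2 <= 0
    if zero.any():
        degenerate = zero & (diff != 0)
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} gene(s) with zero variance but unequal "
                "means; variance floored",
                stacklevel=2,
            )
        se2 = np.where(zero, _VARIANCE_FLOOR, se2)
        df = np.where(np.isfinite(df), df, float(n1 + n2 - 2))
    t = diff / np.sqrt(se2)
    t = np.where(zero & (diff == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero & (diff == 0), 1.0, p)
    return pd.DataFrame({"t": t, "df": df, "p": p}, index=values.index)


def log2_fold_change(
    values: pd.DataFrame | StudyExpression | PreprocessedStudy,
    groups: pd.Series | None = None,
) -> pd.Series:
    """Mean(MCAO) - mean(sham) per gene on the log2 scale (pre-standardization)."""
    if isinstance(values, StudyExpression):
        values, groups = values.values, values.groups
    elif isinstance(values, PreprocessedStudy):
        values, groups = values.gene_values, values.groups
    if groups is None:
        raise ValidationError("groups required when passing a bare matrix")
    a, b = _split_groups(values, groups)
    return pd.Series(a.mean(axis=1) - b.mean(axis=1), index=values.index, name="log2fc")


def bh_adjust(p: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return p if isinstance(p, pd.Series) else arr
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    adjusted = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(adjusted, index=p.index, name="p_fdr")
    return adjusted


@dataclass
class DEResult:
    """Differential-expression table for one study.

    ``table`` columns: log2fc, t, df, p_raw, p_fdr, call (up/down/none).
    """

    study_id: str
    table: pd.DataFrame
    p_threshold: float
    lfc_threshold: float
    use_fdr: bool

    @property
    def up(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "up"])

    @property
    def down(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "down"])

    @property
    def degs(self) -> set[str]:
        return self.up | self.down

    def directions(self) -> dict[str, str]:
        called = self.table[self.table["call"] != "none"]
        return dict(zip(called.index, called["call"]))

    @property
    def counts(self) -> dict[str, int]:
        """Count / up / down summary, one row of the per-study summary table."""
        n_up, n_down = len(self.up), len(self.down)
        return {"count": n_up + n_down, "n_up": n_up, "n_down": n_down}


def call_degs(
    table: pd.DataFrame,
    study_id: str = "",
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.5,
    use_fdr: bool = True,
) -> DEResult:
    """Call each gene up / down / none from its p-value and log2 fold change.

    ``up`` requires log2fc >= +lfc_threshold and the chosen p (FDR-adjusted
    when ``use_fdr``) below ``p_threshold``; ``down`` is symmetric.
    """
    table = table.copy()
    p = table["p_fdr"] if use_fdr else table["p_raw"]
    sig = p < p_threshold
    call = np.where(
        sig & (table["log2fc"] >= lfc_threshold), "up",
        np.where(sig & (table["log2fc"] <= -lfc_threshold), "down", "none"),
    )
    table["call"] = call
    return DEResult(study_id, table, p_threshold, lfc_threshold, use_fdr)


def de_analysis(
    study: PreprocessedStudy,
    variant: str = "welch",
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.5,
    use_fdr: bool = True,
) -> DEResult:
    """Full per-study analysis: t-test, fold change, BH adjustment, calls."""
    tt = gene_t_test(study.standardized, study.groups, variant=variant)
    fc = log2_fold_change(study.gene_values, study.groups)
    table = pd.DataFrame(
        {
            "log2fc": fc,
            "t": tt["t"],
            "df": tt["df"],
            "p_raw": tt["p"],
            "p_fdr": bh_adjust(tt["p"]),
        },
        index=study.standardized.index,
    )
    return call_degs(table, study.study_id, p_threshold, lfc_threshold, use_fdr)


def _direction_maps(
    calls: Sequence[DEResult] | Mapping[str, AbstractSet[str]] | Mapping[str, Mapping[str, str]],
) -> dict[str, dict[str, str]]:
    if isinstance(calls, Mapping):
        out: dict[str, dict[str, str]] = {}
        for study, entry in calls.items():
            if isinstance(entry, Mapping):
                out[study] = dict(entry)
            else:
                out[study] = {g: "na" for g in entry}
        return out
    return {r.study_id: r.directions() for r in calls}


def consensus_table(
    calls: Sequence[DEResult] | Mapping[str, AbstractSet[str]],
    min_support: int,
) -> pd.DataFrame:
    """Support table for genes called in at least ``min_support`` studies.

    Columns: support (number of studies calling the gene), n_up, n_down and
    a ``conflict`` flag marking genes called up in one study and down in
    another.  Direction conflicts are retained, not dropped: consensus is on
    presence.
    """
    direction = _direction_maps(calls)
    n_studies = len(direction)
    if not 1 <= min_support <= n_studies:
        raise ValidationError(
            f"min_support must lie in [1, {n_studies}], got {min_support}"
        )
    support: dict[str, list[str]] = {}
    for study in sorted(direction):
        for gene, call in direction[study].items():
            support.setdefault(gene, []).append(call)
    rows = []
    for gene in sorted(support):
        calls_g = support[gene]
        if len(calls_g) < min_support:
            continue
        n_up = calls_g.count("up")
        n_down = calls_g.count("down")
        rows.append(
            {
                "gene": gene,
                "support": len(calls_g),
                "n_up": n_up,
                "n_down": n_down,
                "conflict": n_up > 0 and n_down > 0,
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "support", "n_up", "n_down", "conflict"])
    return df.set_index("gene")


def consensus_degs(
    calls: Sequence[DEResult] | Mapping[str, AbstractSet[str]],
    min_support: int,
) -> set[str]:
    """Genes called (up or down) in at least ``min_support`` studies."""
    return set(consensus_table(calls, min_support).index)
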