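"""Five-method cross-study meta-analysis with vote counting.

Per gene, five statistics are combined across the k studies of a species:

1. Fisher's sum of logs over per-study two-sided t-test p-values
   (S = -2 sum ln p, chi-square with 2k df).
2. Random-effects (DerSimonian-Laird) pooling of Hedges' g, the within-study
   variance optionally moderated by empirical-Bayes shrinkage of the pooled
   sample variances (the "moderated t" flavor).
3. RankProduct: the geometric mean of a gene's fold-change ranks across
   studies, separately for the up and down direction, with permutation
   (rank-shuffle) significance.
4. A weighted Z (Stouffer) combination of one-sided p-values, weighted by
   inverse effect-size variance.
5. Fixed-effect (Hedges-Olkin) inverse-variance pooling of unmoderated g.

A gene is a meta-DEG when at least ``min_methods`` (default 4) of the five
p-values fall below ``alpha`` (default 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .manifest_io import ValidationError
from .per_study_de import group_stats, log2_fold_change
from .preprocess import PreprocessedStudy

P_FLOOR = 1e-300
_Z_CLAMP = 1e-15

METHODS = ("p_fisher", "p_rem", "p_rankprod", "p_stouffer", "p_fem")


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

def hedges_g(n1, mean1, sd1, n2, mean2, sd2):
    """Bias-corrected standardized mean difference (MCAO minus sham).

    g = J * (mean1 - mean2) / s_pooled with J = 1 - 3 / (4(n1+n2-2) - 1);
    var_g = (n1+n2)/(n1*n2) + g^2 / (2(n1+n2)).  Inputs may be scalars or
    aligned arrays (one entry per gene).  Returns ``(g, var_g)``.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    mean1 = np.asarray(mean1, dtype=float)
    mean2 = np.asarray(mean2, dtype=float)
    sd1 = np.asarray(sd1, dtype=float)
    sd2 = np.asarray(sd2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValidationError("hedges_g needs n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = mean1 - mean2
    zero = sp2 <= 0
    if np.any(zero & (diff != 0)):
        raise ValidationError("zero pooled SD with unequal means: g undefined")
    sp = np.sqrt(np.where(zero, 1.0, sp2))  # placeholder, diff is 0 there
    d = np.where(zero, 0.0, diff / sp)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    var_g = (n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2))
    if g.ndim == 0:
        return float(g), float(var_g)
    return g, var_g


def study_effect_sizes(study: PreprocessedStudy) -> pd.DataFrame:
    """Hedges' g and its variance per gene for one preprocessed study."""
    gs = group_stats(study.standardized, study.groups)
    g, var_g = hedges_g(
        gs["n_mcao"], gs["mean_mcao"], gs["sd_mcao"],
        gs["n_sham"], gs["mean_sham"], gs["sd_sham"],
    )
    return pd.DataFrame({"g": g, "var_g": var_g}, index=gs.index)


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation (scaled inverse-chi-square prior)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderated_variance(sample_variances, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene sample variances toward a common prior value.

    Under the hierarchical model s2_g ~ s0^2 * F(df, d0), the prior degrees
    of freedom d0 and prior variance s0^2 are estimated by the method of
    moments on log sample variances; the shrunken (posterior) variance is
    (d0*s0^2 + df*s2) / (d0 + df).  When the observed log-variance spread is
    no larger than the sampling spread, d0 = inf and every gene gets s0^2.

    Returns ``(shrunken_variances, d0, s0_squared)``.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    if s2.size < 10:
        raise ValidationError("moderated_variance needs >= 10 genes")
    if np.any(s2 <= 0) or np.any(~np.isfinite(s2)):
        raise ValidationError("sample variances must be positive and finite")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    if evar < 1e-15:
        # exactly identical variances: no ensemble spread at all, so treat the
        # common value itself as the prior rather than debiasing it
        s0sq = float(np.exp(z.mean()))
        return np.full_like(s2, s0sq), math.inf, s0sq
    resid = evar - float(special.polygamma(1, df / 2.0))
    if resid > 0:
        d0 = 2.0 * _trigamma_inverse(resid)
        s0sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
        shrunken = (d0 * s0sq + df * s2) / (d0 + df)
    else:
        d0 = math.inf
        s0sq = math.exp(emean)
        shrunken = np.full_like(s2, s0sq)
    return shrunken, d0, s0sq


# ---------------------------------------------------------------------------
# p-value combination
# ---------------------------------------------------------------------------

def _clamped(p: np.ndarray) -> np.ndarray:
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to 1e-300", stacklevel=3)
        p = np.maximum(p, P_FLOOR)
    return p


def fisher_combine(p) -> tuple[np.ndarray, np.ndarray]:
    """Fisher's sum-of-logs: S = -2 sum ln p, combined p from chi2(2k).

    ``p``: (..., k) array of per-study p-values.  A single study (k = 1) is
    returned unchanged (identity convention).  Returns ``(S, p_combined)``.
    """
    arr = _clamped(np.atleast_2d(np.asarray(p, dtype=float)))
    k = arr.shape[-1]
    s = -2.0 * np.log(arr).sum(axis=-1)
    combined = arr[..., 0] if k == 1 else stats.chi2.sf(s, df=2 * k)
    if np.ndim(p) == 1:
        return float(s[0]), float(combined[0])
    return s, combined


def stouffer_combine(p_one_sided, weights) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted Z combination of one-sided p-values.

    z_i = Phi^-1(1 - p_i);  Z = sum(w_i z_i) / sqrt(sum w_i^2).  Returns
    ``(Z, p_one_sided, p_two_sided)`` where the two-sided p doubles the
    smaller tail and is capped at 1.  ``weights`` may be per-study (length
    k) or per-gene-per-study (same shape as ``p_one_sided``).
    """
    arr = np.atleast_2d(np.asarray(p_one_sided, dtype=float))
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    arr = np.clip(arr, _Z_CLAMP, 1.0 - _Z_CLAMP)
    w = np.asarray(weights, dtype=float)
    w = np.broadcast_to(w, arr.shape)
    if np.any(w < 0):
        raise ValidationError("weights must be >= 0")
    denom = np.sqrt((w**2).sum(axis=-1))
    if np.any(denom == 0):
        raise ValidationError("weights must not all be zero")
    z = stats.norm.isf(arr)
    big_z = (w * z).sum(axis=-1) / denom
    p_one = stats.norm.sf(big_z)
    p_two = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(big_z)))
    if np.ndim(p_one_sided) == 1:
        return float(big_z[0]), float(p_one[0]), float(p_two[0])
    return big_z, p_one, p_two


# ---------------------------------------------------------------------------
# Effect-size pooling
# ---------------------------------------------------------------------------

def fixed_effect_combine(g, var_g) -> dict[str, np.ndarray]:
    """Inverse-variance (Hedges-Olkin) fixed-effect pooling.

    ``g`` and ``var_g``: (..., k) arrays.  Returns dict with ``pooled``,
    ``se``, ``z`` and two-sided ``p``.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    v = np.atleast_2d(np.asarray(var_g, dtype=float))
    if np.any(v <= 0):
        raise ValidationError("effect-size variances must be positive")
    w = 1.0 / v
    sw = w.sum(axis=-1)
    pooled = (w * g).sum(axis=-1) / sw
    se = 1.0 / np.sqrt(sw)
    z = pooled / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return {"pooled": pooled, "se": se, "z": z, "p": p}


def random_effect_combine(g, var_g) -> dict[str, np.ndarray]:
    """DerSimonian-Laird random-effects pooling.

    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights w = 1/var; the pooled estimate then re-weights by
    1 / (var + tau2).  Returns dict with ``pooled``, ``se``, ``z``, ``p``,
    ``tau2`` and ``Q``; reduces to the fixed-effect answer when Q <= k-1.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    v = np.atleast_2d(np.asarray(var_g, dtype=float))
    if np.any(v <= 0):
        raise ValidationError("effect-size variances must be positive")
    k = g.shape[-1]
    if k < 2:
        raise ValidationError("random_effect_combine needs k >= 2 studies")
    w = 1.0 / v
    sw = w.sum(axis=-1)
    fe_pooled = (w * g).sum(axis=-1) / sw
    q = (w * (g - fe_pooled[..., None]) ** 2).sum(axis=-1)
    c = sw - (w**2).sum(axis=-1) / sw
    tau2 = np.maximum(0.0, (q - (k - 1)) / c)
    w_star = 1.0 / (v + tau2[..., None])
    sw_star = w_star.sum(axis=-1)
    pooled = (w_star * g).sum(axis=-1) / sw_star
    se = 1.0 / np.sqrt(sw_star)
    z = pooled / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return {"pooled": pooled, "se": se, "z": z, "p": p, "tau2": tau2, "Q": q}


# ---------------------------------------------------------------------------
# RankProduct
# ---------------------------------------------------------------------------

def rank_product(
    fold_changes: pd.DataFrame | np.ndarray,
    direction: str = "up",
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """RankProduct statistic with rank-shuffle permutation significance.

    Genes are ranked per study by log2 fold change (rank 1 = most up for
    ``direction="up"``, most down for ``"down"``); RP is the geometric mean
    of a gene's ranks.  The null is built from ``B`` independent shuffles of
    each study's rank vector: p(g) = (1 + #{null RP <= RP_g}) / (B*n + 1).
    ``pfp`` is the Benjamini-style percentage-of-false-positives estimate
    p * n / rank(RP).
    """
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    if B < 1:
        raise ValidationError("B must be >= 1")
    is_df = isinstance(fold_changes, pd.DataFrame)
    fc = fold_changes.to_numpy(dtype=float) if is_df else np.asarray(fold_changes, float)
    if fc.ndim != 2 or fc.shape[1] < 2:
        raise ValidationError("need a genes x studies matrix with k >= 2")
    n, k = fc.shape
    oriented = -fc if direction == "up" else fc
    ranks = np.apply_along_axis(stats.rankdata, 0, oriented)  # average ties
    log_ranks = np.log(ranks)
    rp = np.exp(log_ranks.mean(axis=1))

    rng = np.random.default_rng(seed)
    null = np.empty((B, n))
    for b in range(B):
        acc = np.zeros(n)
        for j in range(k):
            acc += rng.permutation(log_ranks[:, j])
        null[b] = acc / k
    null_rp = np.sort(np.exp(null).ravel())
    count = np.searchsorted(null_rp, rp, side="right")
    p_perm = (1.0 + count) / (B * n + 1.0)
    rp_rank = stats.rankdata(rp, method="average")
    pfp = p_perm * n / rp_rank
    index = fold_changes.index if is_df else pd.RangeIndex(n)
    return pd.DataFrame({"rp": rp, "p_perm": p_perm, "pfp": pfp}, index=index)


# ---------------------------------------------------------------------------
# Vote counting
# ---------------------------------------------------------------------------

def vote_count(
    p_values: pd.DataFrame,
    alpha: float = 0.05,
    min_methods: int = 4,
) -> pd.DataFrame:
    """Count, per gene, how many methods reach significance.

    ``p_values``: genes x methods.  Adds ``votes`` (number of method
    p-values < alpha) and ``is_meta_deg`` (votes >= min_methods).
    """
    n_methods = p_values.shape[1]
    if not 1 <= min_methods <= n_methods:
        raise ValidationError(
            f"min_methods must lie in [1, {n_methods}], got {min_methods}"
        )
    out = p_values.copy()
    out["votes"] = (p_values < alpha).sum(axis=1).astype(int)
    out["is_meta_deg"] = out["votes"] >= min_methods
    return out


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

@dataclass
class MetaAnalysisResult:
    """Per-gene meta-analysis table plus forest-plot-ready per-study effects."""

    table: pd.DataFrame
    per_study_g: pd.DataFrame
    per_study_var: pd.DataFrame
    alpha: float
    min_methods: int

    @property
    def meta_degs(self) -> set[str]:
        return set(self.table.index[self.table["is_meta_deg"]])


def run_meta(
    studies: Sequence[PreprocessedStudy],
    alpha: float = 0.05,
    min_methods: int = 4,
    B: int = 1000,
    seed: int = 0,
    t_variant: str = "student",
    moderated: bool = False,
    stouffer_weighting: str = "sqrt_n",
) -> MetaAnalysisResult:
    """Run all five methods on a preprocessed collection and count votes.

    All studies must already be restricted to the common gene intersection
    (identical row index); partial gene coverage is rejected so k is the
    same for every gene.  ``stouffer_weighting`` is ``"sqrt_n"`` (fixed
    per-study weights sqrt(n_i); these keep the null distribution of Z
    exactly standard normal) or ``"invvar"`` (per-gene weights 1/var_g;
    data-dependent, slightly conservative under the null because the
    weights anti-correlate with the per-study evidence).  ``moderated``
    switches the REM to empirical-Bayes-shrunken within-study variances.
    """
    from .per_study_de import gene_t_test  # local import to avoid cycle noise

    if len(studies) < 2:
        raise ValidationError("meta-analysis needs >= 2 studies")
    index = studies[0].standardized.index
    for st in studies[1:]:
        if not st.standardized.index.equals(index):
            raise ValidationError(
                "studies must share one gene index (run preprocess_collection first)"
            )
    if stouffer_weighting not in ("invvar", "sqrt_n"):
        raise ValidationError(f"unknown stouffer_weighting {stouffer_weighting!r}")

    k = len(studies)
    n = len(index)
    p_two = np.empty((n, k))
    p_one = np.empty((n, k))
    g_cls = np.empty((n, k))
    v_cls = np.empty((n, k))
    g_mod = np.empty((n, k))
    v_mod = np.empty((n, k))
    fc = np.empty((n, k))
    sqrt_n = np.empty(k)

    for j, st in enumerate(studies):
        gs = group_stats(st.standardized, st.groups)
        n1 = int(gs["n_mcao"].iloc[0])
        n2 = int(gs["n_sham"].iloc[0])
        df = n1 + n2 - 2
        sqrt_n[j] = math.sqrt(n1 + n2)

        tt = gene_t_test(st.standardized, st.groups, variant=t_variant)
        p_two[:, j] = tt["p"].to_numpy()
        p_one[:, j] = stats.t.sf(tt["t"].to_numpy(), tt["df"].to_numpy())

        g, v = hedges_g(
            gs["n_mcao"], gs["mean_mcao"], gs["sd_mcao"],
            gs["n_sham"], gs["mean_sham"], gs["sd_sham"],
        )
        g_cls[:, j] = g
        v_cls[:, j] = v

        if moderated:
            sp2 = (
                (n1 - 1) * gs["sd_mcao"] ** 2 + (n2 - 1) * gs["sd_sham"] ** 2
            ).to_numpy() / df
            sp2_shrunk, _, _ = moderated_variance(sp2, df)
            jf = 1.0 - 3.0 / (4.0 * df - 1.0)
            diff = (gs["mean_mcao"] - gs["mean_sham"]).to_numpy()
            gm = jf * diff / np.sqrt(sp2_shrunk)
            g_mod[:, j] = gm
            v_mod[:, j] = (n1 + n2) / (n1 * n2) + gm**2 / (2.0 * (n1 + n2))
        else:
            g_mod[:, j] = g
            v_mod[:, j] = v

        fc[:, j] = log2_fold_change(st.gene_values, st.groups).to_numpy()

    _, p_fisher = fisher_combine(p_two)

    weights = 1.0 / v_cls if stouffer_weighting == "invvar" else sqrt_n
    _, _, p_stouffer = stouffer_combine(p_one, weights)

    fem = fixed_effect_combine(g_cls, v_cls)
    rem = random_effect_combine(g_mod, v_mod)

    up_seed, down_seed = np.random.SeedSequence(seed).spawn(2)
    fc_df = pd.DataFrame(fc, index=index, columns=[st.study_id for st in studies])
    rp_up = rank_product(fc_df, "up", B=B, seed=up_seed)
    rp_down = rank_product(fc_df, "down", B=B, seed=down_seed)
    p_rankprod = np.minimum(
        1.0, 2.0 * np.minimum(rp_up["p_perm"].to_numpy(), rp_down["p_perm"].to_numpy())
    )

    table = pd.DataFrame(
        {
            "p_fisher": p_fisher,
            "p_rem": rem["p"],
            "p_rankprod": p_rankprod,
            "p_stouffer": p_stouffer,
            "p_fem": fem["p"],
            "pooled_g": rem["pooled"],
            "tau2": rem["tau2"],
            "rp_pfp_up": rp_up["pfp"].to_numpy(),
            "rp_pfp_down": rp_down["pfp"].to_numpy(),
        },
        index=index,
    )
    voted = vote_count(table[list(METHODS)], alpha=alpha, min_methods=min_methods)
    table["votes"] = voted["votes"]
    table["is_meta_deg"] = voted["is_meta_deg"]

    study_ids = [st.study_id for st in studies]
    return MetaAnalysisResult(
        table=table,
        per_study_g=pd.DataFrame(g_cls, index=index, columns=study_ids),
        per_study_var=pd.DataFrame(v_cls, index=index, columns=study_ids),
        alpha=alpha,
        min_methods=min_methods,
    )
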