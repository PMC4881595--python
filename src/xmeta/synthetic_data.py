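"""Simulated multi-study MCAO/sham expression collections with known truth.

The generator emulates the statistical structure the meta-analysis assumes:
``k`` independent two-group studies per species measuring a shared set of
genes on the log2 scale, a fraction of genes truly differentially expressed
with a common standardized effect size and between-study heterogeneity,
platform-specific gene dropout, probe-level measurement (several probes per
gene with small probe noise), and missing cells.  Ground truth (which genes
are up/down and each study's realized effect) is returned alongside the data
so every downstream stage can be scored offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .manifest_io import (
    MCAO,
    SHAM,
    GeneSet,
    GeneSetCollection,
    ManifestEntry,
    StudyExpression,
    StudyManifest,
    ValidationError,
    write_expression_matrix,
    write_gmt,
    write_manifest,
)

import networkx as nx

#: SD of probe-level noise around the gene value, small relative to the
#: within-group SD of 1 so the mean-collapse step is near-lossless.
PROBE_NOISE_SD = 0.1

#: Gene baseline log2 intensities are drawn from Normal(8, 2): typical
#: mid-range intensities on log2-scale single-channel arrays.
BASELINE_MEAN = 8.0
BASELINE_SD = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated species collection.

    ``delta`` is the true standardized mean difference (MCAO minus sham, in
    units of the within-study SD of 1); ``tau2`` the between-study variance
    of each gene's realized effect.  Defaults describe four small rodent
    studies of 5 MCAO + 5 sham arrays each with 5% true DEGs of effect 2.
    """

    n_genes: int = 2000
    k_studies: int = 4
    species_label: str = "mouse"
    n_mcao: int | Sequence[int] = 5
    n_sham: int | Sequence[int] = 5
    frac_deg: float = 0.05
    delta: float = 2.0
    tau2: float = 0.1
    missing_rate: float = 0.02
    platform_dropout: float = 0.05
    probes_per_gene: int = 2
    emit_log_scale: bool = True
    seed: int = 0

    def per_study_sizes(self) -> list[tuple[int, int]]:
        def expand(x) -> list[int]:
            if isinstance(x, (int, np.integer)):
                return [int(x)] * self.k_studies
            xs = [int(v) for v in x]
            if len(xs) != self.k_studies:
                raise ValidationError(
                    f"per-study sample sizes must have length k_studies={self.k_studies}"
                )
            return xs

        return list(zip(expand(self.n_mcao), expand(self.n_sham)))

    def validate(self) -> None:
        if self.n_genes < 1 or self.k_studies < 1:
            raise ValidationError("n_genes and k_studies must be positive")
        if not 0.0 <= self.frac_deg <= 1.0:
            raise ValidationError("frac_deg must lie in [0, 1]")
        if self.frac_deg > 0 and self.frac_deg * self.n_genes < 1:
            raise ValidationError("frac_deg * n_genes must be >= 1 when frac_deg > 0")
        if not 0.0 <= self.platform_dropout < 1.0:
            raise ValidationError("platform_dropout must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.probes_per_gene < 1:
            raise ValidationError("probes_per_gene must be >= 1")
        if self.tau2 < 0:
            raise ValidationError("tau2 must be >= 0")
        for n1, n2 in self.per_study_sizes():
            if n1 < 2 or n2 < 2:
                raise ValidationError(
                    "each group needs >= 2 samples (variance undefined otherwise)"
                )


@dataclass(frozen=True)
class SimulatedTruth:
    """Ground truth for one simulated collection."""

    genes: tuple[str, ...]
    deg_up: frozenset[str]
    deg_down: frozenset[str]
    #: genes x studies matrix of realized per-study effects (0 for null genes)
    realized_effects: pd.DataFrame
    probe_map: dict[str, str]
    config: SimulationConfig

    def __post_init__(self) -> None:
        if self.deg_up & self.deg_down:
            raise ValidationError("deg_up and deg_down must be disjoint")

    @property
    def deg_all(self) -> frozenset[str]:
        return self.deg_up | self.deg_down


def gene_symbols(n_genes: int) -> tuple[str, ...]:
    width = max(4, len(str(n_genes)))
    return tuple(f"G{i:0{width}d}" for i in range(1, n_genes + 1))


def draw_truth(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[frozenset, frozenset]:
    """Pick which genes are true DEGs and their directions."""
    genes = gene_symbols(cfg.n_genes)
    n_deg = round(cfg.frac_deg * cfg.n_genes)
    chosen = rng.choice(cfg.n_genes, size=n_deg, replace=False)
    signs = rng.random(n_deg) < 0.5
    up = frozenset(genes[i] for i, s in zip(chosen, signs) if s)
    down = frozenset(genes[i] for i, s in zip(chosen, signs) if not s)
    return up, down


def simulate_collection(
    cfg: SimulationConfig,
    truth: SimulatedTruth | None = None,
) -> tuple[list[StudyExpression], SimulatedTruth]:
    """Simulate ``k`` two-group studies and the matching ground truth.

    Null genes are Normal(baseline, 1) on the log2 scale in both groups; for
    a true DEG, study ``s`` shifts its MCAO mean by a realized effect drawn
    from Normal(+/-delta, tau2).  Each study then independently loses a
    ``platform_dropout`` fraction of genes, expands genes to probes (probe
    value = gene value + Normal(0, 0.1)), and blanks ``missing_rate`` of
    cells.  Passing ``truth`` reuses its DEG identities (for shared truth
    across species) while drawing fresh realized effects and noise.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = gene_symbols(cfg.n_genes)

    if truth is None:
        deg_up, deg_down = draw_truth(cfg, rng)
    else:
        if len(truth.genes) != cfg.n_genes:
            raise ValidationError("shared truth must match n_genes")
        deg_up, deg_down = truth.deg_up, truth.deg_down

    sign = np.zeros(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in deg_up:
        sign[gene_pos[g]] = 1.0
    for g in deg_down:
        sign[gene_pos[g]] = -1.0

    study_ids = [f"SIM-{cfg.species_label.upper()}-{s + 1}" for s in range(cfg.k_studies)]
    tau = math.sqrt(cfg.tau2)
    baselines = rng.normal(BASELINE_MEAN, BASELINE_SD, size=cfg.n_genes)

    # realized per-study effects: 0 for null genes
    effects = np.zeros((cfg.n_genes, cfg.k_studies))
    is_deg = sign != 0
    effects[is_deg] = (
        sign[is_deg, None] * cfg.delta
        + rng.normal(0.0, tau, size=(is_deg.sum(), cfg.k_studies))
    )

    probe_map: dict[str, str] = {}
    studies: list[StudyExpression] = []
    sizes = cfg.per_study_sizes()
    for s, (study_id, (n1, n2)) in enumerate(zip(study_ids, sizes)):
        kept = rng.random(cfg.n_genes) >= cfg.platform_dropout
        kept_idx = np.flatnonzero(kept)
        n_kept = kept_idx.size
        n_samples = n1 + n2
        group = np.array([MCAO] * n1 + [SHAM] * n2)

        values = baselines[kept_idx, None] + rng.normal(0.0, 1.0, size=(n_kept, n_samples))
        values[:, :n1] += effects[kept_idx, s][:, None]

        # expand genes to probes
        p = cfg.probes_per_gene
        if p == 1:
            probe_ids = [genes[i] for i in kept_idx]
            probe_values = values
        else:
            probe_ids = [f"{genes[i]}_p{j + 1}" for i in kept_idx for j in range(p)]
            probe_values = np.repeat(values, p, axis=0) + rng.normal(
                0.0, PROBE_NOISE_SD, size=(n_kept * p, n_samples)
            )
        for pid in probe_ids:
            probe_map[pid] = pid.split("_p")[0]

        if cfg.missing_rate > 0:
            mask = rng.random(probe_values.shape) < cfg.missing_rate
            probe_values = probe_values.copy()
            probe_values[mask] = np.nan

        if not cfg.emit_log_scale:
            probe_values = np.exp2(probe_values)

        sample_ids = [f"{study_id}_{g[0]}{j + 1}" for j, g in zip(range(n_samples), group)]
        # sample ids must be unique per group, rebuild with per-group counters
        sample_ids = (
            [f"{study_id}_M{j + 1}" for j in range(n1)]
            + [f"{study_id}_S{j + 1}" for j in range(n2)]
        )
        df = pd.DataFrame(probe_values, index=probe_ids, columns=sample_ids)
        studies.append(
            StudyExpression(
                study_id=study_id,
                values=df,
                groups=pd.Series(group, index=sample_ids),
                level="probe",
                is_log2=cfg.emit_log_scale,
                species=cfg.species_label,
            )
        )

    truth_out = SimulatedTruth(
        genes=genes,
        deg_up=deg_up,
        deg_down=deg_down,
        realized_effects=pd.DataFrame(effects, index=list(genes), columns=study_ids),
        probe_map=probe_map,
        config=cfg,
    )
    return studies, truth_out


def collection_manifest(studies: Sequence[StudyExpression]) -> StudyManifest:
    """Manifest entries describing a simulated collection."""
    entries = []
    for st in studies:
        entries.append(
            ManifestEntry(
                series_id=st.study_id,
                species=st.species or "mouse",
                n_mcao=len(st.samples_in_group(MCAO)),
                n_sham=len(st.samples_in_group(SHAM)),
                platform="simulated",
                path=f"{st.study_id}.tsv",
            )
        )
    return StudyManifest(tuple(entries))


def simulate_gene_sets(
    truth: SimulatedTruth,
    n_sets: int = 20,
    enriched_fraction: float = 0.3,
    set_size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
    deg_member_fraction: float = 0.6,
) -> GeneSetCollection:
    """Gene sets matched to a simulated truth for enrichment testing.

    Enriched sets draw ``deg_member_fraction`` (>= 50%) of their members from
    the true DEGs, the rest uniformly; background sets draw uniformly from
    all genes.  Which sets are enriched is recorded in the description.
    """
    if not truth.genes:
        raise ValidationError("truth has no genes")
    lo, hi = set_size_range
    if hi > len(truth.genes):
        raise ValidationError("set size exceeds number of genes")
    if lo < 1 or lo > hi:
        raise ValidationError("invalid set_size_range")
    if deg_member_fraction < 0.5:
        raise ValidationError("enriched sets must draw >= 50% of members from DEGs")
    rng = np.random.default_rng(seed)
    genes = np.array(truth.genes)
    degs = np.array(sorted(truth.deg_all))
    n_enriched = round(n_sets * enriched_fraction)
    sets: dict[str, GeneSet] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        enriched = i < n_enriched and degs.size > 0
        if enriched:
            n_from_deg = min(int(math.ceil(deg_member_fraction * size)), degs.size)
            picked = set(rng.choice(degs, size=n_from_deg, replace=False))
            pool = np.array([g for g in genes if g not in picked])
            picked |= set(rng.choice(pool, size=size - n_from_deg, replace=False))
        else:
            picked = set(rng.choice(genes, size=size, replace=False))
        set_id = f"SET{i + 1:03d}"
        desc = "enriched" if enriched else "background"
        sets[set_id] = GeneSet(set_id, desc, frozenset(g.upper() for g in picked))
    return GeneSetCollection(sets)


def simulate_edge_list(
    truth: SimulatedTruth,
    n_background_genes: int = 200,
    p_edge_deg: float = 0.3,
    p_edge_background: float = 0.02,
    seed: int = 0,
) -> nx.Graph:
    """A synthetic interaction network where true DEGs are densely connected.

    Emulates the shape of a confidence-scored protein-interaction edge list:
    DEG-DEG pairs connect with probability ``p_edge_deg`` and carry higher
    confidence scores than background pairs.
    """
    rng = np.random.default_rng(seed)
    degs = sorted(g.upper() for g in truth.deg_all)
    non_deg = [g.upper() for g in truth.genes if g not in truth.deg_all]
    n_bg = min(n_background_genes, len(non_deg))
    background = sorted(rng.choice(np.array(non_deg), size=n_bg, replace=False)) if n_bg else []
    nodes = degs + list(background)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    deg_set = set(degs)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            both_deg = a in deg_set and b in deg_set
            p = p_edge_deg if both_deg else p_edge_background
            if rng.random() < p:
                score = rng.uniform(0.5, 1.0) if both_deg else rng.uniform(0.15, 0.7)
                graph.add_edge(a, b, score=round(float(score), 3))
    return graph


def write_collection(
    studies: Sequence[StudyExpression],
    truth: SimulatedTruth,
    outdir: str | Path,
    gene_sets: GeneSetCollection | None = None,
) -> None:
    """Write per-study TSVs, group labels, a manifest, probe map and truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for st in studies:
        write_expression_matrix(st, outdir / f"{st.study_id}.tsv")
        with (outdir / f"{st.study_id}.groups.tsv").open("w", encoding="utf-8") as fh:
            fh.write("sample_id\tgroup\n")
            for sid, grp in st.groups.items():
                fh.write(f"{sid}\t{grp}\n")
    write_manifest(collection_manifest(studies), outdir / "manifest.tsv")
    with (outdir / "probe_map.tsv").open("w", encoding="utf-8") as fh:
        fh.write("probe_id\tgene_symbol\n")
        for pid in sorted(truth.probe_map):
            fh.write(f"{pid}\t{truth.probe_map[pid]}\n")
    truth_df = pd.DataFrame(
        {
            "gene": list(truth.genes),
            "direction": [
                "up" if g in truth.deg_up else "down" if g in truth.deg_down else "none"
                for g in truth.genes
            ],
        }
    ).set_index("gene")
    truth_df = truth_df.join(truth.realized_effects)
    truth_df.to_csv(outdir / "truth.tsv", sep="\t", float_format="%.6g", lineterminator="\n")
    if gene_sets is not None:
        write_gmt(gene_sets, outdir / "gene_sets.gmt")
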