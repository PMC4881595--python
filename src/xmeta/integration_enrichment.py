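"""Meta x per-study integration, cross-species intersection, enrichment, network.

The integration step raises specificity: meta-analysis DEGs are kept only
when they were also called in at least ``min_support`` of the individual
studies.  The per-species integrated sets are then intersected across
species by upper-cased gene symbol, integrated/meta sets are tested for
gene-set over-representation with the hypergeometric distribution against
the per-species common-gene universe, and a confidence-scored interaction
network restricted to the DEGs is summarized by node degree (the maximum-
degree node is reported as the hub).

:func:`run_pipeline` drives the whole analysis end to end on simulated
two-species collections with shared ground truth, writing deterministic
result tables and a machine-readable run log.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import AbstractSet, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .manifest_io import (
    GeneSetCollection,
    StudyExpression,
    ValidationError,
    write_result_table,
)
from .meta_analysis import MetaAnalysisResult, run_meta
from .per_study_de import DEResult, bh_adjust, consensus_table, de_analysis
from .preprocess import PreprocessedStudy, preprocess_collection
from .synthetic_data import (
    SimulationConfig,
    SimulatedTruth,
    simulate_collection,
    simulate_edge_list,
    simulate_gene_sets,
)

logger = logging.getLogger("xmeta")


def _support_counts(
    per_study_calls: Sequence[DEResult] | Mapping[str, AbstractSet[str]],
) -> dict[str, int]:
    if isinstance(per_study_calls, Mapping):
        sets = list(per_study_calls.values())
    else:
        sets = [r.degs for r in per_study_calls]
    counts: dict[str, int] = {}
    for s in sets:
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    return counts


def integrate_sets(
    meta_degs: AbstractSet[str],
    per_study_calls: Sequence[DEResult] | Mapping[str, AbstractSet[str]],
    min_support: int,
) -> set[str]:
    """Meta-DEGs also called in at least ``min_support`` individual studies."""
    n_studies = (len(per_study_calls) if not isinstance(per_study_calls, Mapping)
                 else len(per_study_calls))
    if min_support > n_studies:
        raise ValidationError(
            f"min_support={min_support} exceeds the {n_studies} studies supplied"
        )
    if not meta_degs:
        warnings.warn("empty meta-DEG set: integration returns the empty set",
                      stacklevel=2)
        return set()
    if min_support <= 0:
        return set(meta_degs)
    counts = _support_counts(per_study_calls)
    return {g for g in meta_degs if counts.get(g, 0) >= min_support}


def cross_species_common(
    set_a: AbstractSet[str], set_b: AbstractSet[str]
) -> dict[str, tuple[str, str]]:
    """Case-insensitive symbol intersection of two species' DEG sets.

    Returns canonical upper-case symbol -> (spelling in set_a, spelling in
    set_b); ``set(result)`` is the canonical intersection.
    """
    upper_a = {g.upper(): g for g in sorted(set_a)}
    upper_b = {g.upper(): g for g in sorted(set_b)}
    return {
        sym: (upper_a[sym], upper_b[sym])
        for sym in sorted(upper_a.keys() & upper_b.keys())
    }


def hypergeom_enrich(
    query: AbstractSet[str],
    collection: GeneSetCollection,
    universe: AbstractSet[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the query.

    Every set is first intersected with the universe; with N = |universe|,
    K = |set & universe|, n = |query| and x = |query & set|, the p-value is
    P(X >= x) for X ~ Hypergeometric(N, K, n).  Rows are sorted by p
    ascending (ties by set id); ``percent`` = 100 * x / n.  A BH-adjusted
    column is included for reference; the conventional gate is raw p < 0.05.
    """
    universe_u = {g.upper() for g in universe}
    query_u = {g.upper() for g in query}
    if not universe_u or not query_u:
        raise ValidationError("query and universe must be non-empty")
    if not query_u <= universe_u:
        extra = sorted(query_u - universe_u)[:5]
        raise ValidationError(f"query genes outside the universe, e.g. {extra}")
    big_n = len(universe_u)
    n = len(query_u)
    rows = []
    for gs in collection:
        members = gs.members & universe_u
        x = len(query_u & members)
        big_k = len(members)
        # P(X >= x); survival function at x-1
        p = float(stats.hypergeom.sf(x - 1, big_n, big_k, n))
        rows.append(
            {
                "set_id": gs.set_id,
                "description": gs.description,
                "n_set": big_k,
                "n_hits": x,
                "percent": 100.0 * x / n,
                "p_hyper": min(p, 1.0),
            }
        )
    df = pd.DataFrame(
        rows, columns=["set_id", "description", "n_set", "n_hits", "percent", "p_hyper"]
    )
    if len(df):
        df["p_fdr"] = bh_adjust(df["p_hyper"].to_numpy())
        df = df.sort_values(["p_hyper", "set_id"], kind="stable").reset_index(drop=True)
    return df


@dataclass
class SubnetworkResult:
    graph: nx.Graph
    degrees: pd.Series
    hub: str | None


def extract_subnetwork(
    graph: nx.Graph,
    genes: AbstractSet[str],
    min_score: float = 0.4,
) -> SubnetworkResult:
    """Induced subgraph on the DEGs, keeping edges with score >= min_score.

    The hub is the maximum-degree node (ties broken alphabetically); None
    for an empty or edgeless subgraph.
    """
    nodes = {g.upper() for g in genes} & set(graph.nodes)
    sub = nx.Graph()
    sub.add_nodes_from(sorted(nodes))
    for a, b, data in graph.subgraph(nodes).edges(data=True):
        if data.get("score", 1.0) >= min_score:
            sub.add_edge(a, b, **data)
    if sub.number_of_nodes() == 0:
        return SubnetworkResult(sub, pd.Series(dtype=int), None)
    degrees = pd.Series(dict(sub.degree())).sort_index()
    hub = None
    if degrees.max() > 0:
        top = degrees[degrees == degrees.max()]
        hub = sorted(top.index)[0]
    return SubnetworkResult(sub, degrees.sort_values(ascending=False, kind="stable"), hub)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the end-to-end analysis needs, seeds included."""

    seed: int = 0
    species: tuple[str, ...] = ("mouse", "rat")
    shared_truth: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # per-study differential expression
    de_p_threshold: float = 0.05
    de_lfc_threshold: float = 1.5
    de_use_fdr: bool = False
    de_variant: str = "welch"
    consensus_min_support: int = 3
    # meta-analysis
    alpha: float = 0.05
    min_methods: int = 4
    rank_product_B: int = 1000
    meta_t_variant: str = "student"
    moderated: bool = False
    stouffer_weighting: str = "sqrt_n"
    # integration / enrichment / network
    integration_min_support: int = 3
    n_gene_sets: int = 20
    enriched_fraction: float = 0.3
    set_size_range: tuple[int, int] = (10, 50)
    min_score: float = 0.4
    k_impute: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        if "species" in raw:
            raw["species"] = tuple(raw["species"])
        if "set_size_range" in raw:
            raw["set_size_range"] = tuple(raw["set_size_range"])
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "simulation"}
        d["species"] = list(self.species)
        d["set_size_range"] = list(self.set_size_range)
        d["simulation"] = dict(self.simulation.__dict__)
        return d


@dataclass
class SpeciesResult:
    species: str
    truth: SimulatedTruth
    preprocessed: list[PreprocessedStudy]
    common_genes: list[str]
    de_results: list[DEResult]
    de_summary: pd.DataFrame
    consensus: set[str]
    consensus_tbl: pd.DataFrame
    meta: MetaAnalysisResult
    integrated: set[str]
    enrichment: pd.DataFrame | None
    subnetwork: SubnetworkResult | None


@dataclass
class PipelineResult:
    config: PipelineConfig
    species: dict[str, SpeciesResult]
    cross_species: dict[str, tuple[str, str]]
    run_log: dict


def analyze_species(
    studies: Sequence[StudyExpression],
    cfg: PipelineConfig,
    probe_map: Mapping[str, str] | None,
    truth: SimulatedTruth,
    gene_sets: GeneSetCollection | None,
    network: nx.Graph | None,
    species: str,
) -> SpeciesResult:
    """Preprocess -> per-study DE -> meta-analysis -> integration for one species."""
    preprocessed, genes = preprocess_collection(
        studies, probe_map=probe_map, k_impute=cfg.k_impute
    )
    de_results = [
        de_analysis(
            ps,
            variant=cfg.de_variant,
            p_threshold=cfg.de_p_threshold,
            lfc_threshold=cfg.de_lfc_threshold,
            use_fdr=cfg.de_use_fdr,
        )
        for ps in preprocessed
    ]
    de_summary = pd.DataFrame(
        [{"study": r.study_id, **r.counts} for r in de_results]
    ).set_index("study")
    cons_tbl = consensus_table(de_results, cfg.consensus_min_support)
    consensus = set(cons_tbl.index)

    meta = run_meta(
        preprocessed,
        alpha=cfg.alpha,
        min_methods=cfg.min_methods,
        B=cfg.rank_product_B,
        seed=cfg.seed,
        t_variant=cfg.meta_t_variant,
        moderated=cfg.moderated,
        stouffer_weighting=cfg.stouffer_weighting,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty meta set is reported in the log
        integrated = integrate_sets(
            meta.meta_degs, de_results, cfg.integration_min_support
        )

    enrichment = None
    if gene_sets is not None and meta.meta_degs:
        enrichment = hypergeom_enrich(meta.meta_degs, gene_sets, set(genes))
    subnetwork = None
    if network is not None:
        target = integrated if integrated else meta.meta_degs
        subnetwork = extract_subnetwork(network, target, min_score=cfg.min_score)

    return SpeciesResult(
        species=species,
        truth=truth,
        preprocessed=preprocessed,
        common_genes=genes,
        de_results=de_results,
        de_summary=de_summary,
        consensus=consensus,
        consensus_tbl=cons_tbl,
        meta=meta,
        integrated=integrated,
        enrichment=enrichment,
        subnetwork=subnetwork,
    )


def _child_seed(root: np.random.SeedSequence) -> int:
    return int(root.spawn(1)[0].generate_state(1)[0] % (2**31))


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Simulate every species' collection and run the full analysis.

    With ``shared_truth`` (default) all species share the same true DEG
    identities (independent realized effects and noise), so the cross-species
    intersection has a well-defined ground truth.  Same config + seed gives
    byte-identical output tables.
    """
    root = np.random.SeedSequence(cfg.seed)
    species_results: dict[str, SpeciesResult] = {}
    shared: SimulatedTruth | None = None
    for label in cfg.species:
        sim_cfg = replace(cfg.simulation, species_label=label, seed=_child_seed(root))
        studies, truth = simulate_collection(
            sim_cfg, truth=shared if cfg.shared_truth else None
        )
        if cfg.shared_truth and shared is None:
            shared = truth
        gene_sets = simulate_gene_sets(
            truth,
            n_sets=cfg.n_gene_sets,
            enriched_fraction=cfg.enriched_fraction,
            set_size_range=cfg.set_size_range,
            seed=_child_seed(root),
        )
        network = simulate_edge_list(truth, seed=_child_seed(root))
        species_results[label] = analyze_species(
            studies, cfg, truth.probe_map, truth, gene_sets, network, label
        )

    labels = list(cfg.species)
    if len(labels) >= 2:
        cross = cross_species_common(
            species_results[labels[0]].integrated, species_results[labels[1]].integrated
        )
    else:
        cross = {}

    run_log = {
        "parameters": cfg.to_dict(),
        "stages": {
            label: {
                "n_common_genes": len(res.common_genes),
                "de_counts": {
                    sid: {k: int(v) for k, v in row.items()}
                    for sid, row in res.de_summary.iterrows()
                },
                "n_consensus_degs": len(res.consensus),
                "n_meta_degs": len(res.meta.meta_degs),
                "n_integrated_degs": len(res.integrated),
                "hub": res.subnetwork.hub if res.subnetwork else None,
            }
            for label, res in species_results.items()
        },
        "n_cross_species_common": len(cross),
        "cross_species_common": sorted(cross),
    }
    result = PipelineResult(cfg, species_results, cross, run_log)
    if outdir is not None:
        write_pipeline_outputs(result, outdir)
    return result


def write_pipeline_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"seed": result.config.seed}
    for label, res in result.species.items():
        for de in res.de_results:
            write_result_table(
                de.table, outdir / f"de_{de.study_id}.tsv",
                provenance={"stage": "per_study_de", **prov},
            )
        write_result_table(
            res.de_summary, outdir / f"de_summary_{label}.tsv",
            provenance={"stage": "per_study_de", **prov},
        )
        write_result_table(
            res.consensus_tbl, outdir / f"consensus_{label}.tsv",
            provenance={"stage": "consensus", **prov},
        )
        meta_out = res.meta.table.join(res.meta.per_study_g.add_prefix("g_"))
        meta_out = meta_out.join(res.meta.per_study_var.add_prefix("var_g_"))
        write_result_table(
            meta_out, outdir / f"meta_{label}.tsv",
            provenance={"stage": "meta_analysis", **prov},
        )
        (outdir / f"integrated_{label}.txt").write_text(
            "".join(f"{g}\n" for g in sorted(res.integrated)), encoding="utf-8"
        )
        if res.enrichment is not None:
            write_result_table(
                res.enrichment.set_index("set_id"),
                outdir / f"enrichment_{label}.tsv",
                provenance={"stage": "enrichment", **prov},
            )
    with (outdir / "cross_species.tsv").open("w", encoding="utf-8") as fh:
        labels = list(result.species)
        fh.write("symbol\t" + "\t".join(f"spelling_{s}" for s in labels[:2]) + "\n")
        for sym in sorted(result.cross_species):
            a, b = result.cross_species[sym]
            fh.write(f"{sym}\t{a}\t{b}\n")
    with (outdir / "run_log.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(result.run_log, fh, sort_keys=True)
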