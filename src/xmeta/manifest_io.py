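"""On-disk artifacts: study manifests, expression matrices, GMT gene sets, edge lists, result tables.

Everything the pipeline reads or writes is tab-separated UTF-8 with a header
row; ``NA`` (or an empty cell) is the missing-value token.  Gene symbols are
upper-cased at read time so that mouse/rat symbol spellings (``Timp1``) match
gene-set collections that use the human convention (``TIMP1``).
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

MCAO = "MCAO"
SHAM = "sham"
SPECIES = ("mouse", "rat")

NA_TOKEN = "NA"


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Contents parsed fine but violate a domain invariant."""


# ---------------------------------------------------------------------------
# Published study characteristics (MCAO vs sham rodent microarray series).
#
# These eight public GEO/ArrayExpress series are the inputs of the original
# cross-study analysis; sample counts are used only for manifest bookkeeping
# (the pipeline itself runs on user-supplied or simulated matrices).
# Columns: series_id, species, ischemic period (min), reperfusion periods (h),
# n MCAO arrays, n sham arrays, platform.
# ---------------------------------------------------------------------------
STUDY_CHARACTERISTICS: tuple[tuple, ...] = (
    ("E-MEXP-2547", "mouse", 30.0, (24.0, 240.0), 5, 5,
     "Affymetrix GeneChip Mouse Gene 1.0 ST Array"),
    ("GSE23160", "mouse", 120.0, (2.0, 8.0, 24.0), 24, 8,
     "Illumina MouseRef-8 v2.0 expression beadchip"),
    ("GSE30655", "mouse", 60.0, (24.0,), 7, 3,
     "Affymetrix Mouse Genome 430 2.0 Array"),
    ("GSE58720", "mouse", 90.0, (24.0,), 3, 3,
     "Agilent-028005 SurePrint G3 Mouse GE 8x60K Microarray"),
    ("E-MEXP-2222", "rat", 90.0, (6.0, 24.0), 12, 3,
     "Affymetrix Rat Genome 230 2.0 Array"),
    ("GSE33725", "rat", None, (2.0, 6.0), 6, 6,
     "Agilent-014879 Whole Rat Genome Microarray 4x44K G4131F"),
    ("GSE52001", "rat", 120.0, (144.0,), 3, 3,
     "Agilent-028282 Whole Rat Genome Microarray 4x44K v3"),
    ("GSE61616", "rat", 120.0, (168.0,), 5, 5,
     "Affymetrix Rat Genome 230 2.0 Array"),
)

# Published per-study differential-expression summaries for the same series:
# series_id -> (total DEG count, up-regulated, down-regulated).
PUBLISHED_DE_COUNTS: dict[str, tuple[int, int, int]] = {
    "E-MEXP-2547": (179, 179, 0),
    "GSE23160": (22, 22, 0),
    "GSE30655": (341, 128, 213),
    "GSE58720": (1162, 841, 321),
    "E-MEXP-2222": (83, 81, 2),
    "GSE33725": (38, 38, 0),
    "GSE52001": (94, 66, 28),
    "GSE61616": (827, 695, 132),
}


@dataclass(frozen=True)
class ManifestEntry:
    series_id: str
    species: str
    n_mcao: int
    n_sham: int
    platform: str = ""
    ischemic_period_min: float | None = None
    reperfusion_period_h: tuple[float, ...] | None = None
    path: str | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(
                f"{self.series_id}: species must be one of {SPECIES}, got {self.species!r}"
            )
        if self.n_mcao < 1 or self.n_sham < 1:
            raise ValidationError(
                f"{self.series_id}: sample counts must be positive "
                f"(n_mcao={self.n_mcao}, n_sham={self.n_sham})"
            )


@dataclass(frozen=True)
class StudyManifest:
    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.series_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate series ids: {dup}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def subset(self, species: str) -> "StudyManifest":
        return StudyManifest(tuple(e for e in self.entries if e.species == species))


def reference_manifest() -> StudyManifest:
    """Manifest of the eight published MCAO/sham microarray series."""
    return StudyManifest(tuple(
        ManifestEntry(sid, sp, n_mcao=nm, n_sham=ns, platform=plat,
                      ischemic_period_min=isch, reperfusion_period_h=rep)
        for sid, sp, isch, rep, nm, ns, plat in STUDY_CHARACTERISTICS
    ))


_MANIFEST_COLUMNS = (
    "series_id", "species", "ischemic_period_min", "reperfusion_period_h",
    "n_mcao", "n_sham", "platform", "path",
)


def _parse_optional_float(tok: str) -> float | None:
    return None if tok in ("", NA_TOKEN) else float(tok)


def read_manifest(path: str | Path) -> StudyManifest:
    """Read a tab-separated study manifest.

    Required columns: series_id, species, n_mcao, n_sham.  Optional columns
    (``NA`` allowed): ischemic_period_min, reperfusion_period_h (comma-joined
    hours), platform, path.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in ("series_id", "species", "n_mcao", "n_sham"):
            if col not in header:
                raise FormatError(f"{path}: missing required manifest column {col!r}")
        entries = []
        for row in reader:
            try:
                n_mcao = int(row["n_mcao"])
                n_sham = int(row["n_sham"])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-integer sample count in row {row['series_id']!r}"
                ) from exc
            rep_tok = (row.get("reperfusion_period_h") or "").strip()
            rep = (None if rep_tok in ("", NA_TOKEN)
                   else tuple(float(t) for t in rep_tok.split(",")))
            entries.append(ManifestEntry(
                series_id=row["series_id"],
                species=row["species"],
                n_mcao=n_mcao,
                n_sham=n_sham,
                platform=row.get("platform") or "",
                ischemic_period_min=_parse_optional_float(
                    (row.get("ischemic_period_min") or "").strip()),
                reperfusion_period_h=rep,
                path=(row.get("path") or None) or None,
            ))
    return StudyManifest(tuple(entries))


def write_manifest(manifest: StudyManifest, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MANIFEST_COLUMNS)
        for e in manifest:
            writer.writerow([
                e.series_id,
                e.species,
                NA_TOKEN if e.ischemic_period_min is None else f"{e.ischemic_period_min:g}",
                NA_TOKEN if e.reperfusion_period_h is None
                else ",".join(f"{h:g}" for h in e.reperfusion_period_h),
                e.n_mcao,
                e.n_sham,
                e.platform,
                e.path or NA_TOKEN,
            ])


def summarize_manifest(manifest: StudyManifest) -> dict:
    """Per-species and total study/array counts.

    Returns a dict with keys ``total`` and one per species, each mapping to
    ``{"n_studies": ..., "n_mcao": ..., "n_sham": ...}``.
    """
    summary: dict[str, dict[str, int]] = {
        "total": {"n_studies": 0, "n_mcao": 0, "n_sham": 0}
    }
    for e in manifest:
        for key in ("total", e.species):
            bucket = summary.setdefault(key, {"n_studies": 0, "n_mcao": 0, "n_sham": 0})
            bucket["n_studies"] += 1
            bucket["n_mcao"] += e.n_mcao
            bucket["n_sham"] += e.n_sham
    return summary


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class StudyExpression:
    """One study's features-by-samples expression matrix with group labels.

    ``values`` is a pandas DataFrame (rows = probes or gene symbols, columns =
    sample ids, NaN = missing).  ``groups`` maps each sample id to ``MCAO`` or
    ``sham``.  ``level`` says whether rows are probes (duplicates of a gene
    allowed via a probe-to-gene map) or collapsed gene symbols (unique).
    ``is_log2`` flags whether values are already on the log2 scale.
    """

    study_id: str
    values: pd.DataFrame
    groups: pd.Series
    level: str = "probe"
    is_log2: bool = True
    species: str | None = None

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise ValidationError(f"level must be 'probe' or 'gene', got {self.level!r}")
        self.groups = pd.Series(self.groups)
        if list(self.groups.index) != list(self.values.columns):
            # allow dict-like input ordered differently from the columns
            try:
                self.groups = self.groups.loc[self.values.columns]
            except KeyError as exc:
                raise ValidationError(
                    f"{self.study_id}: sample(s) without a group label"
                ) from exc
        bad = set(self.groups.unique()) - {MCAO, SHAM}
        if bad:
            raise ValidationError(f"{self.study_id}: unknown group labels {sorted(bad)}")
        if not {MCAO, SHAM} <= set(self.groups.unique()):
            raise ValidationError(f"{self.study_id}: both {MCAO} and {SHAM} required")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValidationError(f"{self.study_id}: duplicate feature ids, e.g. {dup}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def with_values(self, values: pd.DataFrame, level: str | None = None,
                    is_log2: bool | None = None) -> "StudyExpression":
        return StudyExpression(
            study_id=self.study_id,
            values=values,
            groups=self.groups.loc[values.columns],
            level=self.level if level is None else level,
            is_log2=self.is_log2 if is_log2 is None else is_log2,
            species=self.species,
        )


def read_expression_matrix(
    path: str | Path,
    group_map: Mapping[str, str],
    *,
    study_id: str | None = None,
    level: str = "probe",
    is_log2: bool = True,
    species: str | None = None,
) -> StudyExpression:
    """Read a TSV expression matrix (first column = feature id, rest = samples)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN, ""],
                     keep_default_na=False)
    df = df.astype(float)
    df.index = df.index.astype(str)
    missing = [s for s in df.columns if s not in group_map]
    if missing:
        raise ValidationError(f"{path}: samples without group label: {missing}")
    if level == "probe" and not df.index.is_unique:
        # duplicate probe ids are a file defect even at probe level: rows would
        # be indistinguishable downstream
        raise FormatError(f"{path}: duplicate feature ids in matrix")
    groups = pd.Series({s: group_map[s] for s in df.columns}).loc[df.columns]
    return StudyExpression(
        study_id=study_id or path.stem,
        values=df,
        groups=groups,
        level=level,
        is_log2=is_log2,
        species=species,
    )


def write_expression_matrix(study: StudyExpression, path: str | Path,
                            feature_col: str = "feature_id") -> None:
    path = Path(path)
    out = study.values.copy()
    out.index.name = feature_col
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.10g",
               lineterminator="\n")


# ---------------------------------------------------------------------------
# Gene-set collections (GMT) and interaction edge lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]


@dataclass(frozen=True)
class GeneSetCollection:
    sets: Mapping[str, GeneSet]

    def __post_init__(self) -> None:
        for sid, gs in self.sets.items():
            if not gs.members:
                raise ValidationError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: set_id, description, member genes..."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs set_id, description and "
                    f"at least one member ({len(fields)} fields found)"
                )
            set_id, desc = fields[0], fields[1]
            members = frozenset(g.upper() for g in fields[2:] if g)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {set_id!r} has no members")
            if set_id in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            sets[set_id] = GeneSet(set_id, desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.members)]) + "\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a TSV protein-interaction edge list: geneA, geneB, score in [0, 1].

    Self-loops are dropped; a pair listed more than once (in either order)
    keeps the maximum score.  Node names are upper-cased symbols.
    """
    path = Path(path)
    graph = nx.Graph()
    with path.open(encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return graph
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 3:
                raise FormatError(f"{path}:{lineno}: expected geneA, geneB, score")
            a, b = row[0].upper(), row[1].upper()
            score = float(row[2])
            if not 0.0 <= score <= 1.0:
                raise ValidationError(
                    f"{path}:{lineno}: confidence score {score} outside [0, 1]"
                )
            if a == b:
                continue
            if graph.has_edge(a, b):
                graph[a][b]["score"] = max(graph[a][b]["score"], score)
            else:
                graph.add_edge(a, b, score=score)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('score', 1.0):.3f}\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_result_table(table: pd.DataFrame, path: str | Path,
                       provenance: Mapping[str, object] | None = None) -> None:
    """Write a per-gene result table as TSV, NaN serialized as ``NA``.

    Provenance (stage name, parameters, seed) is written as ``# key: value``
    comment lines before the header; numeric values keep 10 significant
    digits so a round trip through :func:`read_result_table` is lossless at
    that precision.
    """
    if not table.columns.is_unique:
        raise ValidationError("result table column names must be unique")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, sep="\t", na_rep=NA_TOKEN, float_format="%.10g",
                     lineterminator="\n")


def read_result_table(path: str | Path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", comment="#", index_col=index_col,
                       na_values=[NA_TOKEN], keep_default_na=False)
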