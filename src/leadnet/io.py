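"""Readers and writers for every tabular input and output.

Formats
-------
* Edge table: TSV ``gene1<TAB>gene2<TAB>combined_score`` with optional
  header.  Two score dialects are supported: STRING-style integers on a
  0-1000 scale (``string_integer``) and unit-interval floats
  (``unit_float``); ``auto`` detects integers when every score exceeds 1.
* Gene list: plain text, one symbol per line, ``#`` comments.
* Annotations: TSV ``gene<TAB>term_id[<TAB>term_name]``.
* Ontology: TSV ``child_term<TAB>parent_term``.
* Assay tables: CSV with a header row (schemas in :mod:`leadnet.assays`).
* Run configuration: YAML mirroring :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .enrichment import AnnotationTable, OntologyEdges
from .errors import ParseError, ValidationError
from .network import InteractionNetwork, normalize_symbol

logger = logging.getLogger("leadnet")


# ---------------------------------------------------------------------------
# gene lists

class GeneList:
    """Ordered list of unique, case-normalised gene symbols."""

    def __init__(self, symbols):
        seen: dict[str, None] = {}
        for s in symbols:
            seen.setdefault(normalize_symbol(s), None)
        self.symbols: list[str] = list(seen)

    def __iter__(self):
        return iter(self.symbols)

    def __len__(self):
        return len(self.symbols)

    def __contains__(self, item):
        return normalize_symbol(item) in self.symbols

    def __eq__(self, other):
        other_syms = getattr(other, "symbols", other)
        return self.symbols == list(other_syms)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"GeneList({self.symbols!r})"


def read_gene_list(path) -> GeneList:
    """One symbol per non-empty line; ``#`` comments skipped; order kept."""
    symbols = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        symbols.append(line)
    if not symbols:
        raise ValidationError(f"gene list {path} is empty")
    return GeneList(symbols)


def write_gene_list(genes, path) -> None:
    syms = getattr(genes, "symbols", genes)
    Path(path).write_text("".join(f"{s}\n" for s in syms))


def illustrative_seed_list() -> GeneList:
    """A bundled 20-gene demonstration seed list (illustrative only)."""
    from importlib.resources import files

    path = files("leadnet").joinpath("data/illustrative_seeds.txt")
    symbols = [ln.strip() for ln in path.read_text().splitlines()
               if ln.strip() and not ln.startswith("#")]
    return GeneList(symbols)


# ---------------------------------------------------------------------------
# edge tables

def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_edge_table(path, dialect: str = "auto") -> InteractionNetwork:
    """Load a STRING-dialect TSV edge table into an :class:`InteractionNetwork`.

    ``string_integer`` divides scores by 1000; ``auto`` falls back to the
    integer dialect when every score exceeds 1.  The first row is treated as
    a header iff its third column does not parse as a number.  Duplicate
    unordered pairs collapse to the maximum score; self-loops are dropped
    with a logged warning.
    """
    if dialect not in ("auto", "string_integer", "unit_float"):
        raise ValidationError(f"unknown edge-table dialect {dialect!r}")
    rows: list[tuple[int, str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"expected >= 3 tab-separated columns, got {len(parts)}",
                    line=lineno,
                )
            a, b, score_tok = parts[0].strip(), parts[1].strip(), parts[2].strip()
            if lineno == 1 and not _looks_numeric(score_tok):
                continue  # header row
            if not _looks_numeric(score_tok):
                raise ParseError(f"score {score_tok!r} is not numeric", line=lineno)
            rows.append((lineno, a, b, float(score_tok)))

    if dialect == "auto":
        dialect = "string_integer" if rows and all(s > 1 for _, _, _, s in rows) else "unit_float"
        logger.debug("edge table %s: auto-detected dialect %s", path, dialect)

    net = InteractionNetwork()
    for lineno, a, b, score in rows:
        if dialect == "string_integer":
            score = score / 1000.0
        if not (0.0 < score <= 1.0):
            raise ValidationError(
                f"line {lineno}: score {score} outside (0, 1] after dialect conversion"
            )
        a_n, b_n = normalize_symbol(a), normalize_symbol(b)
        if a_n == b_n:
            logger.warning("edge table %s line %d: dropping self-loop on %s",
                           path, lineno, a_n)
            net.add_node(a_n)
            continue
        net.add_edge(a_n, b_n, score)
    return net


def write_edge_table(net: InteractionNetwork, path, header: bool = True) -> None:
    """Write a unit-float TSV edge table (isolated nodes appended as comments)."""
    lines = []
    if header:
        lines.append("gene1\tgene2\tcombined_score")
    connected = set()
    for a, b, s in net.edges():
        connected.update((a, b))
        lines.append(f"{a}\t{b}\t{s!r}")
    for n in sorted(net.nodes - connected):
        lines.append(f"# isolated\t{n}")
    Path(path).write_text("".join(f"{ln}\n" for ln in lines))


def read_edge_table_isolated_aware(path, dialect: str = "auto") -> InteractionNetwork:
    """Like :func:`read_edge_table` but restores ``# isolated`` node comments."""
    net = read_edge_table(path, dialect=dialect)
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("# isolated\t"):
            net.add_node(raw.split("\t", 1)[1])
    return net


# ---------------------------------------------------------------------------
# annotations / ontology

def read_annotation_table(path) -> AnnotationTable:
    """TSV ``gene<TAB>term_id[<TAB>term_name]``; duplicates collapse."""
    annot = AnnotationTable()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("expected gene<TAB>term_id", line=lineno)
            name = parts[2].strip() if len(parts) > 2 else None
            annot.add(parts[0], parts[1], name or None)
    return annot


def write_annotation_table(annot: AnnotationTable, path) -> None:
    lines = []
    for gene, term in sorted(annot.pairs):
        name = annot.term_names.get(term, "")
        lines.append(f"{gene}\t{term}\t{name}" if name else f"{gene}\t{term}")
    Path(path).write_text("".join(f"{ln}\n" for ln in lines))


def read_ontology_edges(path) -> OntologyEdges:
    """TSV ``child_term<TAB>parent_term``; DAG-ness checked at propagation."""
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("expected child_term<TAB>parent_term", line=lineno)
            edges.append((parts[0], parts[1]))
    return OntologyEdges(edges)


# ---------------------------------------------------------------------------
# assay CSVs

_ASSAY_SCHEMAS = {
    "ct": ["sample", "group", "gene", "ct"],
    "wound": ["well", "group", "initial_area_px", "final_area_px"],
    "aoeb": ["field", "group", "live", "apoptotic", "necrotic"],
    "lanes": ["lane", "group", "intact_band", "total_lane"],
}


def read_assay_csv(path, kind: str) -> pd.DataFrame:
    """Read an assay CSV (kind in {"ct", "wound", "aoeb", "lanes"}).

    The header row is required; extra columns are preserved.
    """
    if kind not in _ASSAY_SCHEMAS:
        raise ValidationError(f"unknown assay kind {kind!r}")
    df = pd.read_csv(path)
    missing = [c for c in _ASSAY_SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ParseError(f"assay CSV {path} missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# run configuration

@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration.

    Defaults mirror the published analysis: a confidence band of
    0.9-0.99 on the combined score, one shell of seed expansion,
    silhouette-selected class count, and alpha = 0.001 for the
    class-separation test (assay statistics use 0.05).
    """

    min_score: float = 0.9
    max_score: float = 0.99
    expansion_steps: int = 1
    n_classes: int | str = "auto"
    rng_seed: int = 0
    alpha: float = 0.001
    fit_method: str = "loglog_ols"

    def __post_init__(self):
        if not (0.0 < self.min_score <= self.max_score <= 1.0):
            raise ValidationError(
                f"confidence band [{self.min_score}, {self.max_score}] must satisfy "
                "0 < min <= max <= 1"
            )
        if int(self.expansion_steps) < 0:
            raise ValidationError("expansion_steps must be >= 0")
        self.expansion_steps = int(self.expansion_steps)
        if self.n_classes != "auto":
            if int(self.n_classes) < 1:
                raise ValidationError("n_classes must be >= 1 or 'auto'")
            self.n_classes = int(self.n_classes)
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.fit_method not in ("loglog_ols", "mle"):
            raise ValidationError(f"unknown fit_method {self.fit_method!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config {path} must be a YAML mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# result reports

def write_report(results: dict, out_dir) -> dict[str, str]:
    """Write pipeline outputs to ``out_dir``; returns a name -> path manifest.

    Recognised keys in ``results`` (all optional): ``gene_scores`` and
    ``class_stats`` and ``anova_tukey`` and ``enrichment`` (DataFrames),
    ``power_law`` (mapping), ``leaders`` (iterable of symbols).  Numeric
    values are written at full precision and survive a write -> read round
    trip to at least 12 significant digits.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _csv(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest[name] = str(path)

    for name in ("gene_scores", "class_stats", "anova_tukey", "enrichment"):
        if results.get(name) is not None:
            _csv(name, results[name])
    if results.get("power_law") is not None:
        path = out / "power_law.json"
        path.write_text(json.dumps(results["power_law"], indent=2, sort_keys=True) + "\n")
        manifest["power_law"] = str(path)
    if results.get("leaders") is not None:
        path = out / "leaders.txt"
        write_gene_list(results["leaders"], path)
        manifest["leaders"] = str(path)
    return manifest
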