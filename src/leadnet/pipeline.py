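"""End-to-end orchestration of the leader-gene run.

Stage order is fixed: read -> confidence filter -> seed expansion -> WNL/TIS
scoring -> class clustering -> ANOVA/Tukey -> leader identification ->
power-law topology fit -> (optional) ontology enrichment -> report writing.
A machine-readable :class:`RunManifest` records the configuration, input
digests, per-stage outputs and wall-clock, and every warning raised along
the way; enrichment failures degrade gracefully to a warning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

from . import __version__
from .enrichment import run_enrichment
from .errors import LeadnetError, ValidationError
from .io import (RunConfig, read_annotation_table, read_gene_list,
                 read_ontology_edges, write_report)
from .leader import LeaderGeneModel

logger = logging.getLogger("leadnet")


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict
    inputs: dict[str, str]              # path -> sha256
    outputs: dict[str, str]             # artefact name -> path
    stage_seconds: dict[str, float]
    warnings: list[str]
    leaders: list[str]
    version: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def run_leader_gene_pipeline(edges, seeds, annot=None, ontology=None,
                             cfg: RunConfig | None = None,
                             out_dir="results") -> RunManifest:
    """Run the full leader-gene analysis from input files to a report directory.

    Parameters
    ----------
    edges : path
        STRING-dialect TSV edge table.
    seeds : path
        Seed gene list (one symbol per line).
    annot, ontology : path, optional
        Gene-term annotation TSV and child-parent ontology TSV; when
        ``annot`` is omitted the enrichment stage is skipped with a warning.
    cfg : RunConfig, optional
    out_dir : path
        Report directory (created if absent).

    Returns
    -------
    RunManifest
        Also written to ``out_dir/manifest.json``.
    """
    cfg = cfg or RunConfig()
    collector = _WarningCollector()
    logger.addHandler(collector)
    stage_seconds: dict[str, float] = {}
    inputs: dict[str, str] = {}

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                stage_seconds[name] = round(time.perf_counter() - self.t0, 6)
                return False
        return _T()

    try:
        with timed("read"):
            inputs[str(edges)] = _sha256(edges)
            inputs[str(seeds)] = _sha256(seeds)
            model = LeaderGeneModel.from_files(edges, seeds, config=cfg)
            seed_list = model.seeds
        logger.info("read %d nodes / %d edges, %d seeds",
                    model.network.n_nodes, model.network.n_edges, len(seed_list))

        with timed("leader_gene_fit"):
            results = model.fit()
        logger.info("analysed %d genes in %d classes; %d leader(s)",
                    results.network.n_nodes, results.partition.n_classes,
                    len(results.leaders.leaders))

        enrichment_df = None
        if annot is not None:
            with timed("enrichment"):
                try:
                    inputs[str(annot)] = _sha256(annot)
                    annot_table = read_annotation_table(annot)
                    ont = None
                    if ontology is not None:
                        inputs[str(ontology)] = _sha256(ontology)
                        ont = read_ontology_edges(ontology)
                    enrichment_df = run_enrichment(
                        sorted(results.leaders.leaders), annot_table, ontology=ont)
                except LeadnetError as exc:
                    logger.warning("enrichment stage skipped: %s", exc)
        else:
            logger.warning("no annotation table given; enrichment stage skipped")

        with timed("write_report"):
            outputs = results.save(out_dir)
            if enrichment_df is not None:
                extra = write_report({"enrichment": enrichment_df}, out_dir)
                outputs.update(extra)

        manifest = RunManifest(
            config=cfg.to_dict(), inputs=inputs, outputs=outputs,
            stage_seconds=stage_seconds,
            warnings=list(dict.fromkeys(collector.messages + results.warnings)),
            leaders=sorted(results.leaders.leaders), version=__version__,
        )
        (Path(out_dir) / "manifest.json").write_text(manifest.to_json() + "\n")
        return manifest
    except LeadnetError:
        raise
    except FileNotFoundError as exc:
        raise ValidationError(str(exc)) from exc
    finally:
        logger.removeHandler(collector)
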