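"""Seeded synthetic-data generators with planted ground truth.

Every pipeline input can be generated deterministically from a config plus an
RNG seed, with a recoverable target planted in each: a high-confidence
near-clique module whose members should be identified as leader genes, an
over-represented annotation term, and assay tables whose effect sizes are
known exactly.  The generators exercise the analysis contracts; they do not
attempt to imitate the human interactome or GO.

Network backbone
----------------
Preferential attachment seeded with an initial clique of ``attachment_m + 1``
nodes; each subsequent node attaches ``attachment_m`` edges to distinct
existing nodes with probability proportional to current degree.  Without a
planted module this yields exactly ``m(m+1)/2 + (n - m - 1) m`` edges and an
approximately power-law degree distribution.  Edge confidence scores are
drawn from a Beta(a, b) rescaled to (0.5, 1] so that a realistic share of the
background survives a 0.9-0.99 confidence band; the planted module is wired
among the earliest (hub) nodes at a distinct high score so the band isolates
it, the way high-confidence interactions dominate a curated network.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationTable
from .errors import ValidationError
from .network import InteractionNetwork

logger = logging.getLogger("leadnet")

FOUR_ARMS = ("control", "metformin", "cocl2", "cocl2_metformin")


@dataclasses.dataclass
class NetworkSimConfig:
    """Scale-free backbone + planted high-WNL module."""

    n_nodes: int = 100
    attachment_m: int = 1
    score_beta_a: float = 2.0
    score_beta_b: float = 3.0
    planted_size: int = 5
    planted_score: float = 0.99
    planted_density: float = 1.0
    boundary_score_max: float = 0.9
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 5:
            raise ValidationError("n_nodes must be >= 5")
        if not (1 <= self.attachment_m < self.n_nodes):
            raise ValidationError("attachment_m must satisfy 1 <= m < n_nodes")
        if not (0 <= self.planted_size < self.n_nodes):
            raise ValidationError("planted_size must satisfy 0 <= size < n_nodes")
        if not (0.0 < self.planted_score <= 1.0):
            raise ValidationError("planted_score must lie in (0, 1]")
        if not (0.0 <= self.planted_density <= 1.0):
            raise ValidationError("planted_density must lie in [0, 1]")
        if self.score_beta_a <= 0 or self.score_beta_b <= 0:
            raise ValidationError("Beta parameters must be positive")
        if not (0.5 < self.boundary_score_max <= 1.0):
            raise ValidationError("boundary_score_max must lie in (0.5, 1]")


def _gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def gen_network(cfg: NetworkSimConfig) -> tuple[InteractionNetwork, set[str]]:
    """Generate the backbone plus planted module; returns (network, planted genes).

    Deterministic: the same config (including ``rng_seed``) reproduces a
    byte-identical edge table.  Planted-module edges overwrite any backbone
    edge between the same pair, so every planted edge carries exactly
    ``planted_score``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n, m = cfg.n_nodes, cfg.attachment_m
    edges: list[tuple[int, int]] = []
    degree = np.zeros(n, dtype=float)

    # initial clique of m + 1 nodes
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            edges.append((i, j))
            degree[i] += 1
            degree[j] += 1

    for new in range(m + 1, n):
        probs = degree[:new] / degree[:new].sum()
        targets = rng.choice(new, size=m, replace=False, p=probs)
        for t in sorted(int(t) for t in targets):
            edges.append((t, new))
            degree[t] += 1
            degree[new] += 1

    scores = 0.5 + 0.5 * rng.beta(cfg.score_beta_a, cfg.score_beta_b, size=len(edges))

    # Module-boundary edges (backbone edges touching a planted node) are
    # rescaled into (0.5, boundary_score_max) so the planted ground truth is
    # unambiguous: the module's internal wiring is the only high-confidence
    # structure its members carry, and a confidence filter at or above the
    # boundary score isolates it.  Background-background edges keep the full
    # (0.5, 1] support, so some background edges still survive a 0.9-0.99 band.
    planted_idx = set(range(cfg.planted_size))
    squeeze = (cfg.boundary_score_max - 0.5) / 0.5
    for e, (i, j) in enumerate(edges):
        if i in planted_idx or j in planted_idx:
            scores[e] = 0.5 + (scores[e] - 0.5) * squeeze

    net = InteractionNetwork(nodes=(_gene_name(i) for i in range(n)))
    for (i, j), s in zip(edges, scores):
        net.add_edge(_gene_name(i), _gene_name(j), float(s))

    planted = {_gene_name(i) for i in range(cfg.planted_size)}
    planted_sorted = sorted(planted)
    for ia in range(len(planted_sorted)):
        for ib in range(ia + 1, len(planted_sorted)):
            if cfg.planted_density >= 1.0 or rng.random() < cfg.planted_density:
                a, b = planted_sorted[ia], planted_sorted[ib]
                if net.has_edge(a, b):
                    net.graph[a][b]["score"] = cfg.planted_score
                else:
                    net.add_edge(a, b, cfg.planted_score)
    return net, planted


def planted_leader_inputs(rng_seed: int, n_background_seeds: int = 15,
                          cfg: NetworkSimConfig | None = None,
                          ) -> tuple[InteractionNetwork, set[str], list[str]]:
    """Canonical planted-leader study inputs: network, planted set, seed list.

    The seed list emulates a literature-derived starting list of about 20
    genes: the planted module members plus ``n_background_seeds`` background
    genes sampled uniformly.  Returns (network, planted, seeds).
    """
    cfg = cfg or NetworkSimConfig(rng_seed=rng_seed)
    if cfg.rng_seed != rng_seed:
        cfg = dataclasses.replace(cfg, rng_seed=rng_seed)
    net, planted = gen_network(cfg)
    rng = np.random.default_rng(rng_seed + 2**20)
    background = sorted(net.nodes - planted)
    extra = rng.choice(background, size=min(n_background_seeds, len(background)),
                       replace=False)
    seeds = sorted(planted) + [str(g) for g in extra]
    return net, planted, seeds


def gen_annotations(genes, n_terms: int, enriched_term: str, enriched_genes,
                    base_prob: float, rng_seed: int = 0) -> AnnotationTable:
    """Random gene-term annotations with one planted over-represented term.

    Every (gene, term) pair is present independently with ``base_prob``;
    ``enriched_term`` additionally annotates all of ``enriched_genes``.
    """
    symbols = list(getattr(genes, "symbols", genes))
    if not symbols:
        raise ValidationError("empty gene list")
    enriched = set(getattr(enriched_genes, "symbols", enriched_genes))
    if not enriched <= set(symbols):
        raise ValidationError("enriched_genes must be a subset of genes")
    if not (0.0 <= base_prob <= 1.0):
        raise ValidationError("base_prob must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    terms = [f"T{i + 1:04d}" for i in range(n_terms)]
    if enriched_term not in terms:
        terms.append(enriched_term)
    annot = AnnotationTable()
    draws = rng.random((len(symbols), len(terms)))
    for gi, gene in enumerate(symbols):
        for ti, term in enumerate(terms):
            if draws[gi, ti] < base_prob:
                annot.add(gene, term)
    for gene in sorted(enriched):
        annot.add(gene, enriched_term)
    return annot


@dataclasses.dataclass
class AssaySimConfig:
    """Four-arm assay design (control / metformin / CoCl2 / CoCl2+metformin).

    Defaults model a metformin-under-hypoxia experiment: the combined arm
    carries the largest apoptotic response (target-gene induction, impaired
    wound closure, raised apoptotic fraction), CoCl2-mimicked hypoxia alone a
    mild one.  ``ct_baseline`` is a typical endogenous-control Ct;
    ``target_offset`` the calibrator-group dCt (target minus reference).
    """

    groups: Sequence[str] = FOUR_ARMS
    n_samples_per_group: int = 6
    fold_changes: Mapping = dataclasses.field(default_factory=lambda: {
        "control": 1.0, "metformin": 1.5, "cocl2": 0.7, "cocl2_metformin": 2.5})
    ct_baseline: float = 20.0
    ct_sigma: float = 0.2
    target_offset: float = 2.0
    wound_effect: Mapping[str, float] = dataclasses.field(default_factory=lambda: {
        "control": 0.35, "metformin": 0.55, "cocl2": 0.45, "cocl2_metformin": 0.75})
    wound_sigma: float = 0.10
    wound_initial_area: float = 1.0e5
    count_totals: int = 300
    apoptotic_prob: Mapping[str, float] = dataclasses.field(default_factory=lambda: {
        "control": 0.05, "metformin": 0.12, "cocl2": 0.08, "cocl2_metformin": 0.40})
    necrotic_share: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_samples_per_group < 3:
            raise ValidationError("n_samples_per_group must be >= 3")
        if self.ct_sigma < 0 or self.wound_sigma < 0:
            raise ValidationError("noise sigmas must be >= 0")
        for g, p in self.apoptotic_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"apoptotic_prob[{g!r}] outside [0, 1]")
        if not (0.0 <= self.necrotic_share < 1.0):
            raise ValidationError("necrotic_share must lie in [0, 1)")

    def fold_for(self, group: str, gene: str) -> float:
        fc = self.fold_changes
        key = (group, gene) if (group, gene) in fc else group
        if key not in fc:
            raise ValidationError(f"no fold change configured for group {group!r}")
        val = float(fc[key])
        if val <= 0:
            raise ValidationError("fold changes must be positive")
        return val


def gen_ct_table(cfg: AssaySimConfig, target: str, reference: str,
                 calibrator_group: str = "control") -> pd.DataFrame:
    """Synthetic qPCR Ct table (triplicate technical replicates per reaction).

    Reference-gene Ct replicates are Normal(ct_baseline, ct_sigma); target
    replicates are ct_baseline + target_offset - log2(fold(group)) + noise.
    With ``ct_sigma = 0`` the Livak inversion recovers the configured fold
    changes exactly (provided the calibrator fold is 1; otherwise folds are
    recovered relative to it).
    """
    if calibrator_group not in cfg.groups:
        raise ValidationError(f"calibrator group {calibrator_group!r} not in design")
    rng = np.random.default_rng(cfg.rng_seed)
    rows = []
    for group in cfg.groups:
        fold = cfg.fold_for(group, target)
        for s in range(cfg.n_samples_per_group):
            sample = f"{group}_s{s + 1}"
            for _ in range(3):
                rows.append({"sample": sample, "group": group, "gene": reference,
                             "ct": cfg.ct_baseline + rng.normal(0, cfg.ct_sigma)})
            mu = cfg.ct_baseline + cfg.target_offset - np.log2(fold)
            for _ in range(3):
                rows.append({"sample": sample, "group": group, "gene": target,
                             "ct": mu + rng.normal(0, cfg.ct_sigma)})
    return pd.DataFrame(rows)


def gen_wound_and_aoeb(cfg: AssaySimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic wound-area and AO/EB count tables for the four-arm design.

    Wound: final area = initial x wound_effect(group) x lognormal(0, sigma).
    AO/EB: per field, multinomial(count_totals) over (live, apoptotic,
    necrotic) with the configured apoptotic probability and a fixed necrotic
    share.
    """
    for g, e in cfg.wound_effect.items():
        if e <= 0:
            raise ValidationError(f"wound_effect[{g!r}] must be positive")
    rng = np.random.default_rng(cfg.rng_seed)
    wound_rows, aoeb_rows = [], []
    for group in cfg.groups:
        effect = float(cfg.wound_effect[group])
        p_apo = float(cfg.apoptotic_prob[group])
        p_nec = cfg.necrotic_share * p_apo  # necrosis scales with death burden
        p_live = 1.0 - p_apo - p_nec
        for s in range(cfg.n_samples_per_group):
            initial = cfg.wound_initial_area
            noise = np.exp(rng.normal(0.0, cfg.wound_sigma)) if cfg.wound_sigma else 1.0
            wound_rows.append({"well": f"{group}_w{s + 1}", "group": group,
                               "initial_area_px": initial,
                               "final_area_px": initial * effect * noise})
            live, apo, nec = rng.multinomial(cfg.count_totals,
                                             [p_live, p_apo, p_nec])
            aoeb_rows.append({"field": f"{group}_f{s + 1}", "group": group,
                              "live": int(live), "apoptotic": int(apo),
                              "necrotic": int(nec)})
    return pd.DataFrame(wound_rows), pd.DataFrame(aoeb_rows)
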