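"""Leader-gene identification on a confidence-filtered interaction network.

The leader-gene approach ranks every gene in a protein-protein interaction
network by its weighted connectivity and designates the top-scoring class as
the "leader genes".  Two concordant scores are computed per gene:

* **WNL** (weighted number of links): the sum of the combined confidence
  scores (unit scale) of the gene's incident interactions — a score-weighted
  degree.
* **TIS** (total interaction score): the same sum on STRING's integer
  (x1000) scale, with each edge rounded half-away-from-zero.

Genes are clustered on WNL with an exact 1-D k-means, classes are compared
with one-way ANOVA plus Tukey-Kramer post-hoc tests, and the class with the
highest mean WNL is reported as the leader class (a warning is attached if
that class does not also maximise mean TIS).

The stage sequence is exposed both as free functions and as a
:class:`LeaderGeneModel` / :class:`LeaderGeneResults` pair, where the model
holds the network plus analysis settings and ``fit()`` returns the scored,
clustered, tested result with a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import topology
from .cluster import kmeans_1d, select_k_silhouette
from .errors import ValidationError
from .network import InteractionNetwork, normalize_symbol
from .stats import AnovaResult, one_way_anova, tukey_hsd

logger = logging.getLogger("leadnet")


# ---------------------------------------------------------------------------
# stage functions

def filter_by_confidence(net: InteractionNetwork, min_score: float,
                         max_score: float) -> InteractionNetwork:
    """Keep exactly the edges with min_score <= score <= max_score (inclusive).

    The node set is unchanged: genes whose every interaction falls outside
    the band remain as isolated nodes.
    """
    if not (0.0 < min_score <= max_score <= 1.0):
        raise ValidationError(
            f"confidence band [{min_score}, {max_score}] must satisfy "
            "0 < min <= max <= 1"
        )
    out = InteractionNetwork(nodes=net.nodes)
    for a, b, s in net.edges():
        if min_score <= s <= max_score:
            out.add_edge(a, b, s)
    return out


def expand_seed(net: InteractionNetwork, seeds, steps: int) -> InteractionNetwork:
    """Subnetwork induced on the seeds plus nodes within ``steps`` edges.

    ``steps=0`` returns the seed-induced subnetwork.  Seeds absent from the
    network are retained as isolated nodes with a logged warning (literature
    symbols frequently miss the network namespace).
    """
    symbols = getattr(seeds, "symbols", seeds)
    seed_set = {normalize_symbol(s) for s in symbols}
    if not seed_set:
        raise ValidationError("seed list is empty")
    if steps < 0:
        raise ValidationError("expansion steps must be >= 0")
    missing = seed_set - net.nodes
    if missing:
        logger.warning("seeds absent from network kept as isolated nodes: %s",
                       ", ".join(sorted(missing)))
    frontier = seed_set & net.nodes
    reached = set(frontier)
    for _ in range(steps):
        nxt = set()
        for node in frontier:
            nxt.update(net.graph.neighbors(node))
        frontier = nxt - reached
        if not frontier:
            break
        reached |= frontier
    return net.subnetwork(reached | seed_set)


def compute_wnl(net: InteractionNetwork) -> dict[str, float]:
    """Weighted number of links: per gene, the sum of incident edge scores."""
    wnl = {n: 0.0 for n in net.nodes}
    for a, b, s in net.edges():
        wnl[a] += s
        wnl[b] += s
    return wnl


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def compute_tis(net: InteractionNetwork) -> dict[str, int]:
    """Total interaction score: incident sum of round(1000 x score).

    Rounding is half-away-from-zero, fixed and locale-independent.
    """
    tis = {n: 0 for n in net.nodes}
    for a, b, s in net.edges():
        t = _round_half_away(1000.0 * s)
        tis[a] += t
        tis[b] += t
    return tis


def score_table(net: InteractionNetwork) -> pd.DataFrame:
    """Per-gene degree, WNL and TIS as a DataFrame sorted by descending WNL."""
    wnl, tis = compute_wnl(net), compute_tis(net)
    df = pd.DataFrame(
        [{"gene": g, "degree": net.degree(g), "wnl": wnl[g], "tis": tis[g]}
         for g in sorted(net.nodes)]
    )
    return df.sort_values(["wnl", "gene"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)


@dataclasses.dataclass
class ClassPartition:
    """Genes partitioned into classes ordered by strictly decreasing mean WNL."""

    classes: list[list[str]]        # class 1 first (highest mean WNL)
    class_means: list[float]

    def label_of(self) -> dict[str, int]:
        """Gene -> 1-based class label."""
        return {g: i + 1 for i, cls in enumerate(self.classes) for g in cls}

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def cluster_scores(scores, n_classes="auto", rng_seed: int = 0) -> ClassPartition:
    """Partition genes into classes by exact 1-D k-means on WNL.

    ``n_classes="auto"`` selects k in 2..min(6, n_distinct) by maximum mean
    silhouette (ties favour the smaller k).  The result is deterministic and
    independent of ``rng_seed`` (kept in the signature for interface
    stability).  Classes are relabelled in descending mean-WNL order.
    """
    genes = sorted(scores)
    vals = np.asarray([float(scores[g]) for g in genes])
    if vals.size == 0:
        raise ValidationError("no genes to cluster")
    n_distinct = np.unique(vals).size
    if n_classes == "auto":
        k = select_k_silhouette(vals)
    else:
        k = int(n_classes)
        if k >= 2 and vals.size < 2:
            raise ValidationError("need >= 2 genes for >= 2 classes")
        if k > n_distinct:
            raise ValidationError(
                f"n_classes={k} exceeds the {n_distinct} distinct WNL value(s)"
            )
    labels, centers, _ = kmeans_1d(vals, k)
    # kmeans_1d orders clusters by ascending mean; reverse for descending
    classes: list[list[str]] = []
    means: list[float] = []
    for c in range(k - 1, -1, -1):
        members = [g for g, lab in zip(genes, labels) if lab == c]
        classes.append(sorted(members))
        means.append(float(centers[c]))
    return ClassPartition(classes=classes, class_means=means)


class ClassSeparation(NamedTuple):
    anova: AnovaResult
    tukey: pd.DataFrame
    excluded_classes: list[int]

    @property
    def anova_p(self) -> float:
        return self.anova.p_value


def class_separation_test(partition: ClassPartition, scores) -> ClassSeparation:
    """One-way ANOVA + Tukey HSD of gene-level WNL across classes.

    Classes with fewer than two members cannot contribute a within-class
    variance and are excluded with a logged warning.
    """
    by_class: dict[str, list[float]] = {}
    excluded: list[int] = []
    for i, cls in enumerate(partition.classes, start=1):
        if len(cls) < 2:
            excluded.append(i)
            logger.warning("class %d has < 2 members; excluded from the F test", i)
            continue
        by_class[f"class{i}"] = [float(scores[g]) for g in cls]
    if len(by_class) < 2:
        raise ValidationError("fewer than 2 classes with >= 2 members")
    anova = one_way_anova(by_class)
    tukey = tukey_hsd(by_class)
    return ClassSeparation(anova=anova, tukey=tukey, excluded_classes=excluded)


@dataclasses.dataclass
class LeaderResult:
    """The leader class and the statistics supporting its separation."""

    leaders: set[str]
    leader_class: int
    anova_p: float | None
    tukey_table: pd.DataFrame | None
    warnings: list[str] = dataclasses.field(default_factory=list)


def identify_leaders(partition: ClassPartition, wnl, tis,
                     separation: ClassSeparation | None = None) -> LeaderResult:
    """Leaders = the class with maximal mean WNL (class 1 by construction).

    Consistency check: the same class must also maximise mean TIS; a
    discordance is attached as a warning, not an error.
    """
    if not partition.classes or not partition.classes[0]:
        raise ValidationError("empty partition")
    warnings: list[str] = []
    tis_means = [float(np.mean([tis[g] for g in cls])) if cls else -np.inf
                 for cls in partition.classes]
    if int(np.argmax(tis_means)) != 0:
        msg = ("WNL/TIS discordance: class 1 maximises mean WNL but class "
               f"{int(np.argmax(tis_means)) + 1} maximises mean TIS")
        logger.warning(msg)
        warnings.append(msg)
    return LeaderResult(
        leaders=set(partition.classes[0]),
        leader_class=1,
        anova_p=separation.anova_p if separation is not None else None,
        tukey_table=separation.tukey if separation is not None else None,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Model / Results API

class LeaderGeneModel:
    """Leader-gene analysis of an interaction network.

    Parameters
    ----------
    network : InteractionNetwork
        The full weighted network (before confidence filtering).
    seeds : GeneList or iterable of str, optional
        Seed genes; when given the network is restricted to the seeds plus
        their ``expansion_steps``-neighbourhood after filtering.
    min_score, max_score : float
        Inclusive confidence band on the combined score (default 0.9-0.99).
    expansion_steps : int
        Breadth-first shells to add around the seeds (default 1).
    n_classes : int or "auto"
        Number of WNL classes, or silhouette-based selection.
    class_alpha : float
        Significance level quoted for the class-separation test (default
        0.001).
    fit_method : {"loglog_ols", "mle"}
        Degree-distribution fit method.

    Examples
    --------
    >>> model = LeaderGeneModel(net, seeds=["TP53", "CASP3"])
    >>> res = model.fit()
    >>> sorted(res.leaders.leaders)   # doctest: +SKIP
    ['TP53']
    """

    def __init__(self, network: InteractionNetwork, seeds=None, *,
                 min_score: float = 0.9, max_score: float = 0.99,
                 expansion_steps: int = 1, n_classes="auto",
                 class_alpha: float = 0.001, fit_method: str = "loglog_ols",
                 rng_seed: int = 0):
        self.network = network
        self.seeds = seeds
        self.min_score = min_score
        self.max_score = max_score
        self.expansion_steps = expansion_steps
        self.n_classes = n_classes
        self.class_alpha = class_alpha
        self.fit_method = fit_method
        self.rng_seed = rng_seed

    @classmethod
    def from_files(cls, edges_path, seeds_path=None, config=None,
                   dialect: str = "auto") -> "LeaderGeneModel":
        """Build the model from an edge-table TSV and optional seed list."""
        from .io import RunConfig, read_edge_table, read_gene_list

        cfg = config or RunConfig()
        net = read_edge_table(edges_path, dialect=dialect)
        seeds = read_gene_list(seeds_path) if seeds_path else None
        return cls(net, seeds=seeds, min_score=cfg.min_score,
                   max_score=cfg.max_score, expansion_steps=cfg.expansion_steps,
                   n_classes=cfg.n_classes, class_alpha=cfg.alpha,
                   fit_method=cfg.fit_method, rng_seed=cfg.rng_seed)

    def fit(self) -> "LeaderGeneResults":
        """Run filter -> expand -> score -> cluster -> test -> leaders -> topology."""
        warnings: list[str] = []
        filtered = filter_by_confidence(self.network, self.min_score, self.max_score)
        if self.seeds is not None:
            analysed = expand_seed(filtered, self.seeds, self.expansion_steps)
        else:
            analysed = filtered
        if analysed.n_nodes == 0:
            raise ValidationError("no genes remain after filtering/expansion")

        scores = score_table(analysed)
        wnl = dict(zip(scores["gene"], scores["wnl"]))
        tis = dict(zip(scores["gene"], scores["tis"]))

        partition = cluster_scores(wnl, n_classes=self.n_classes,
                                   rng_seed=self.rng_seed)
        try:
            separation = class_separation_test(partition, wnl)
        except ValidationError as exc:
            separation = None
            warnings.append(f"class-separation test unavailable: {exc}")
            logger.warning("class-separation test unavailable: %s", exc)
        leaders = identify_leaders(partition, wnl, tis, separation)
        warnings.extend(leaders.warnings)

        labels = partition.label_of()
        scores = scores.assign(class_label=[labels[g] for g in scores["gene"]])

        try:
            dist = topology.degree_distribution(analysed)
            power_law = topology.fit_power_law(dist, method=self.fit_method)
        except ValidationError as exc:
            dist, power_law = None, None
            warnings.append(f"power-law fit unavailable: {exc}")
            logger.warning("power-law fit unavailable: %s", exc)

        return LeaderGeneResults(model=self, network=analysed, scores=scores,
                                 partition=partition, separation=separation,
                                 leaders=leaders, degree_dist=dist,
                                 power_law=power_law, warnings=warnings)


@dataclasses.dataclass
class LeaderGeneResults:
    """Fitted leader-gene analysis: scores, classes, tests, topology."""

    model: LeaderGeneModel
    network: InteractionNetwork
    scores: pd.DataFrame            # gene, degree, wnl, tis, class_label
    partition: ClassPartition
    separation: ClassSeparation | None
    leaders: LeaderResult
    degree_dist: "topology.DegreeDistribution | None"
    power_law: "topology.PowerLawFit | None"
    warnings: list[str]

    def class_stats(self) -> pd.DataFrame:
        """Per-class size, mean WNL and mean TIS."""
        rows = []
        tis = dict(zip(self.scores["gene"], self.scores["tis"]))
        for i, (cls, mean_wnl) in enumerate(
                zip(self.partition.classes, self.partition.class_means), start=1):
            rows.append({"class_label": i, "n_genes": len(cls),
                         "mean_wnl": mean_wnl,
                         "mean_tis": float(np.mean([tis[g] for g in cls]))})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary table of the fitted analysis."""
        lines = ["Leader-gene analysis", "=" * 44]
        lines.append(f"Genes analysed:      {self.network.n_nodes}")
        lines.append(f"Edges in band:       {self.network.n_edges} "
                     f"[{self.model.min_score}, {self.model.max_score}]")
        lines.append(f"Classes (WNL):       {self.partition.n_classes}")
        if self.separation is not None:
            a = self.separation.anova
            lines.append(f"Class separation:    F({a.df_between},{a.df_within}) = "
                         f"{a.f_statistic:.4g}, p = {a.p_value:.3g}")
        if self.power_law is not None:
            pl = self.power_law
            r2 = "n/a" if pl.r_squared is None else f"{pl.r_squared:.3f}"
            lines.append(f"Power-law fit:       exponent {pl.exponent:.3f}, "
                         f"R^2 {r2} ({pl.method})")
        lines.append(f"Leader class:        {self.leaders.leader_class} "
                     f"({len(self.leaders.leaders)} gene(s))")
        lines.append("Leaders:             " + ", ".join(sorted(self.leaders.leaders)))
        for w in self.warnings:
            lines.append(f"warning: {w}")
        lines.append("")
        lines.append(self.class_stats().to_string(index=False))
        return "\n".join(lines)

    def plot_degree_distribution(self, ax=None):
        """Log-log degree-count scatter with the fitted power law overlaid."""
        import matplotlib.pyplot as plt

        if self.degree_dist is None:
            raise ValidationError("no degree distribution available")
        if ax is None:
            _, ax = plt.subplots()
        ks = [k for k, _ in self.degree_dist.points]
        ns = [c for _, c in self.degree_dist.points]
        ax.scatter(ks, ns, label="observed")
        if self.power_law is not None and self.power_law.method == "loglog_ols":
            kk = np.linspace(min(ks), max(ks), 100)
            ax.plot(kk, self.power_law.prefactor * kk ** (-self.power_law.exponent),
                    label=f"N(k) ~ k^-{self.power_law.exponent:.2f}")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("degree k")
        ax.set_ylabel("node count N(k)")
        ax.legend()
        return ax

    def save(self, out_dir) -> dict[str, str]:
        """Write the standard report files; returns the file manifest."""
        from .io import write_report

        results = {"gene_scores": self.scores, "class_stats": self.class_stats(),
                   "leaders": sorted(self.leaders.leaders)}
        if self.separation is not None:
            results["anova_tukey"] = self.separation.tukey.assign(
                anova_f=self.separation.anova.f_statistic,
                anova_p=self.separation.anova.p_value,
            )
        if self.power_law is not None:
            pl = self.power_law
            results["power_law"] = {
                "exponent": pl.exponent, "prefactor": pl.prefactor,
                "r_squared": pl.r_squared, "n_points": pl.n_points,
                "isolated_nodes": (self.degree_dist.isolated
                                   if self.degree_dist else 0),
                "method": pl.method,
            }
        return write_report(results, out_dir)
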