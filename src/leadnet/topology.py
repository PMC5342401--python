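"""Degree-distribution extraction and power-law fitting.

The degree distribution N(k) of a scale-free network follows N(k) ~ c k^-b.
Following the NetworkAnalyzer convention, the default fit regresses
log10 N(k) on log10 k by ordinary least squares over all observed degrees
k >= 1 (no binning, no k_min search) and reports the exponent as the
positive slope magnitude together with the R^2 on the logged points.  A
discrete maximum-likelihood exponent (zeta-normalised, k_min = 1) is
available as an independent cross-check; it yields no R^2.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .errors import ValidationError
from .network import InteractionNetwork

logger = logging.getLogger("leadnet")


@dataclasses.dataclass
class DegreeDistribution:
    """Degree-count pairs (k >= 1), plus the isolated-node count."""

    points: list[tuple[int, int]]   # (degree, count), degrees unique ascending
    isolated: int = 0

    def __post_init__(self):
        self.points = sorted((int(k), int(c)) for k, c in self.points)
        degrees = [k for k, _ in self.points]
        if len(set(degrees)) != len(degrees):
            raise ValidationError("duplicate degrees in distribution")
        if any(k < 1 or c < 1 for k, c in self.points):
            raise ValidationError("degrees and counts must be >= 1")

    @property
    def n_nodes(self) -> int:
        return sum(c for _, c in self.points)


def degree_distribution(net: InteractionNetwork) -> DegreeDistribution:
    """Count nodes per degree; isolated (degree-0) nodes reported separately."""
    counts: dict[int, int] = {}
    isolated = 0
    for node in net.nodes:
        k = net.degree(node)
        if k == 0:
            isolated += 1
        else:
            counts[k] = counts.get(k, 0) + 1
    return DegreeDistribution(points=sorted(counts.items()), isolated=isolated)


@dataclasses.dataclass
class PowerLawFit:
    """Fitted N(k) = prefactor * k^(-exponent); exponent is the positive magnitude."""

    exponent: float
    prefactor: float
    r_squared: float | None
    n_points: int
    method: str


def _fit_loglog_ols(points: list[tuple[int, int]]) -> PowerLawFit:
    ks = np.array([k for k, _ in points], dtype=float)
    ns = np.array([c for _, c in points], dtype=float)
    x, y = np.log10(ks), np.log10(ns)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-20 else 0.0  # flat-line convention
    else:
        r2 = 1.0 - ss_res / ss_tot
    return PowerLawFit(exponent=float(-slope), prefactor=float(10.0 ** intercept),
                       r_squared=float(min(max(r2, 0.0), 1.0)),
                       n_points=len(points), method="loglog_ols")


def _fit_mle(points: list[tuple[int, int]]) -> PowerLawFit:
    ks = np.array([k for k, _ in points], dtype=float)
    cs = np.array([c for _, c in points], dtype=float)
    n = cs.sum()
    if n < 10:
        logger.warning("MLE power-law fit on %d nodes; >= 10 recommended", int(n))
    sum_log_k = float(np.sum(cs * np.log(ks)))

    def neg_loglik(b: float) -> float:
        return n * np.log(zeta(b, 1)) + b * sum_log_k

    res = minimize_scalar(neg_loglik, bounds=(1.0001, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    b = float(res.x)
    # prefactor for the implied expected counts: n / zeta(b)
    return PowerLawFit(exponent=b, prefactor=float(n / zeta(b, 1)),
                       r_squared=None, n_points=len(points), method="mle")


def fit_power_law(dist: DegreeDistribution, method: str = "loglog_ols") -> PowerLawFit:
    """Fit N(k) ~ c k^-b to a degree distribution.

    ``loglog_ols`` (default) gives the exponent magnitude and R^2 of the
    log10-log10 least-squares line; ``mle`` gives the discrete zeta-normalised
    maximum-likelihood exponent (k_min = 1, no R^2), intended as a
    cross-check.  Requires at least two distinct degrees.
    """
    if len(dist.points) < 2:
        raise ValidationError(
            "power-law fit requires >= 2 distinct degrees "
            f"(got {len(dist.points)})"
        )
    if method == "loglog_ols":
        return _fit_loglog_ols(dist.points)
    if method == "mle":
        return _fit_mle(dist.points)
    raise ValidationError(f"unknown fit method {method!r}")
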