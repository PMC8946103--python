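"""Power-law fitting and topology classification.

Two fitting routes, matching what each quantity statistically is:

* :func:`fit_powerlaw_mle` — discrete maximum-likelihood power-law fit of
  a degree *sample* (per-node degrees), with the lower cutoff ``x_min``
  chosen to minimise the Kolmogorov-Smirnov distance and a
  semi-parametric bootstrap p-value, following the standard procedure of
  Clauset, Shalizi and Newman for heavy-tailed data.
* :func:`fit_loglog_slope` — ordinary least squares of log(value) on
  log(k) for the degree-binned *profiles* (c(k), C_N(k) and the binned
  centralities), where a KS bootstrap is not defined.

Sign convention, fixed once for the whole package: the reported
``exponent`` is the positive gamma of ``y ~ k**(-gamma)``; a *negative*
exponent therefore means the profile increases with degree (e.g. an
assortative neighbourhood-connectivity profile).

:func:`classify_topology` turns six fits into a topology class.  The
hierarchical signature in the field is a clustering profile decaying like
c(k) ~ k**-1; finite scale-free networks with no modular hierarchy (e.g.
preferential attachment) still show a mild residual c(k) decay, so the
hierarchical call requires the clustering exponent to reach
``c_hier_min`` (default 0.5) rather than merely exceed the flatness
band used for the assortativity sign test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import optimize, special

from hubtrace.netio import Network
from hubtrace.topology import (
    DegreeProfile,
    bin_measure_by_degree,
    betweenness_centrality,
    closeness_centrality,
    clustering_by_degree,
    degree_distribution,
    eigenvector_centrality,
    neighborhood_connectivity,
)

_ALPHA_MIN, _ALPHA_MAX = 1.01, 8.0


@dataclass(frozen=True)
class PowerLawFit:
    """A fitted power-law relation y ~ k**(-exponent).

    ``exponent > 0`` means the relation decays with k.  ``ks_stat`` is the
    KS distance for MLE fits and the maximum absolute log-space residual
    for OLS slope fits; ``stderr`` is the OLS slope standard error (absent
    for MLE fits).
    """

    measure: str
    exponent: float
    method: Literal["mle_ks", "loglog_ols"]
    ks_stat: float
    n_points: int
    intercept: float | None = None
    p_value: float | None = None
    x_min: int | None = None
    stderr: float | None = None

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError(f"{self.measure}: fit needs >= 3 points")
        if self.ks_stat < 0:
            raise ValueError("ks_stat must be >= 0")

    @property
    def decays(self) -> bool:
        return self.exponent > 0


@dataclass(frozen=True)
class FitThresholds:
    """Thresholds steering topology classification.

    gof_max / p_min gate the *quality flags* of MLE fits; flat_band is the
    absolute exponent band treated as "no trend" for sign tests;
    c_hier_min is the minimum c(k) decay exponent accepted as the
    hierarchical k**-1-type signature.
    """

    gof_max: float = 0.33
    p_min: float = 0.1
    flat_band: float = 0.05
    c_hier_min: float = 0.5


@dataclass(frozen=True)
class TopologySummary:
    """Six power-law fits plus the derived topology class.

    ``fits`` is keyed by ``{p, c, cn, cb, cc, ce}``.  The class is a pure
    function of the fits and thresholds (see :func:`classify_topology`),
    so it can always be re-derived from the stored record.
    """

    fits: Mapping[str, PowerLawFit | None]
    topology_class: Literal["hierarchical_scale_free", "scale_free", "unclassified"]
    assortative: bool
    assortativity: Literal["assortative", "disassortative", "neutral"]
    thresholds: FitThresholds = field(default_factory=FitThresholds)
    warnings: tuple[str, ...] = ()

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "topology_class": self.topology_class,
            "assortative": self.assortative,
            "assortativity": self.assortativity,
            "thresholds": asdict(self.thresholds),
            "warnings": list(self.warnings),
            "fits": {
                key: (asdict(f) if f is not None else None)
                for key, f in sorted(self.fits.items())
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# Discrete power-law machinery


def _zeta(alpha: float, q: float | np.ndarray) -> float | np.ndarray:
    return special.zeta(alpha, q)


def _mle_alpha(tail: np.ndarray, xmin: int) -> float:
    """Exact discrete MLE of alpha for the tail x >= xmin."""
    n = tail.size
    slog = float(np.sum(np.log(tail)))

    def nll(alpha: float) -> float:
        return n * math.log(_zeta(alpha, xmin)) + alpha * slog

    res = optimize.minimize_scalar(nll, bounds=(_ALPHA_MIN, _ALPHA_MAX),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    return float(res.x)


def _ks_distance(tail: np.ndarray, alpha: float, xmin: int) -> float:
    """KS distance between the empirical tail CDF and the fitted model."""
    xs, counts = np.unique(tail, return_counts=True)
    ecdf = np.cumsum(counts) / tail.size
    z = _zeta(alpha, xmin)
    # model CDF at x: P(X <= x) = 1 - zeta(alpha, x+1)/zeta(alpha, xmin)
    mcdf = 1.0 - _zeta(alpha, xs + 1.0) / z
    # compare at both sides of each step
    ecdf_lo = np.concatenate([[0.0], ecdf[:-1]])
    mcdf_lo = 1.0 - _zeta(alpha, xs.astype(float)) / z
    return float(max(np.max(np.abs(ecdf - mcdf)), np.max(np.abs(mcdf_lo - ecdf_lo))))


def _fit_tail_scan(samples: np.ndarray, xmin_cap: float) -> tuple[float, int, float]:
    """Scan candidate x_min values, return (alpha, xmin, ks) minimising KS."""
    xs = np.sort(samples)
    candidates = np.unique(xs)
    candidates = candidates[candidates <= xmin_cap]
    if candidates.size == 0:
        candidates = np.unique(xs)[:1]
    best = None
    for xmin in candidates:
        tail = xs[xs >= xmin]
        if tail.size < 3 or np.unique(tail).size < 2:
            continue
        alpha = _mle_alpha(tail, int(xmin))
        ks = _ks_distance(tail, alpha, int(xmin))
        if best is None or ks < best[2]:
            best = (alpha, int(xmin), ks)
    if best is None:
        raise ValueError("degenerate support: no usable x_min candidate")
    return best


def sample_discrete_powerlaw(
    alpha: float, xmin: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact i.i.d. draws from the discrete power law p(x) ~ x**-alpha,
    x >= xmin, via inverse transform on the Hurwitz-zeta normalised CDF.

    A cumulative table covers the bulk; the (rare) deep-tail draws beyond
    the table fall back to a doubling + bisection search on the
    complementary CDF, so sampling is exact at every quantile.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    if xmin < 1:
        raise ValueError("xmin must be >= 1")
    z = _zeta(alpha, xmin)
    u = rng.random(n)
    # cumulative table covers all but ~1/10 of an expected draw; the rest
    # (and any freak deep-tail quantile) goes through exact bisection
    hi = max(2 * xmin, 1024)
    while _zeta(alpha, hi) / z > 1.0 / (10.0 * n) and (hi - xmin) < 2**23:
        hi *= 2
    xs = np.arange(xmin, hi + 1, dtype=float)
    pmf = xs ** (-alpha) / z
    cdf = np.cumsum(pmf)
    idx = np.searchsorted(cdf, u, side="left")
    out = xmin + idx
    over = idx >= xs.size  # beyond table: solve individually
    for i in np.flatnonzero(over):
        # smallest x with P(X >= x+1) <= 1-u, via doubling then bisection
        target = 1.0 - u[i]
        lo_x, hi_x = xmin, hi
        while _zeta(alpha, hi_x + 1) / z > target:
            lo_x, hi_x = hi_x, hi_x * 2
        while hi_x - lo_x > 1:
            mid = (lo_x + hi_x) // 2
            if _zeta(alpha, mid + 1) / z > target:
                lo_x = mid
            else:
                hi_x = mid
        out[i] = hi_x
    return out.astype(np.int64)


def fit_powerlaw_mle(
    samples: Sequence[int],
    n_boot: int = 2500,
    rng_seed: int = 0,
    measure: str = "p",
    xmin_percentile: float = 80.0,
) -> PowerLawFit:
    """Discrete power-law MLE with KS-minimising x_min and bootstrap p.

    The p-value is the fraction of ``n_boot`` synthetic datasets — drawn
    semi-parametrically: fitted model above x_min, empirical body below —
    whose refit KS distance is at least the observed one.  ``n_boot = 0``
    skips the bootstrap (p_value absent).  Candidate x_min values are
    capped at the ``xmin_percentile`` of the sample so the fitted tail
    keeps statistical support.
    """
    x = np.asarray(samples, dtype=np.int64)
    if x.size < 50:
        raise ValueError(f"need >= 50 samples, got {x.size}")
    if np.any(x < 1):
        raise ValueError("samples must be integers >= 1")
    if np.unique(x).size < 2:
        raise ValueError("degenerate support: all samples identical")
    if n_boot < 0:
        raise ValueError("n_boot must be >= 0")
    cap = float(np.percentile(x, xmin_percentile))
    alpha, xmin, ks = _fit_tail_scan(x, cap)

    p_value = None
    if n_boot > 0:
        rng = np.random.default_rng(rng_seed)
        body = x[x < xmin]
        p_tail = 1.0 - body.size / x.size
        exceed = 0
        for _ in range(n_boot):
            take_tail = rng.random(x.size) < p_tail
            n_tail = int(np.sum(take_tail))
            synth = np.empty(x.size, dtype=np.int64)
            if n_tail:
                synth[:n_tail] = sample_discrete_powerlaw(alpha, xmin, n_tail, rng)
            if x.size - n_tail:
                synth[n_tail:] = rng.choice(body, size=x.size - n_tail)
            _, _, ks_b = _fit_tail_scan(synth, float(np.percentile(synth, xmin_percentile)))
            if ks_b >= ks:
                exceed += 1
        p_value = exceed / n_boot

    n_points = int(np.sum(x >= xmin))
    return PowerLawFit(
        measure=measure, exponent=alpha, method="mle_ks", ks_stat=ks,
        n_points=n_points, p_value=p_value, x_min=xmin,
    )


# ---------------------------------------------------------------------------
# Log-log slope fits for degree profiles


def fit_loglog_slope(
    profile: DegreeProfile, min_points: int = 3
) -> PowerLawFit:
    """OLS of log(value) on log(k); exponent = -slope.

    Bins with k < 1 or value <= 0 are dropped (the log is undefined
    there).  ``ks_stat`` is the maximum absolute residual in natural-log
    space — zero for an exact power law.
    """
    mask = (profile.ks >= 1) & (profile.vals > 0)
    ks = profile.ks[mask].astype(float)
    vs = profile.vals[mask]
    if ks.size < min_points:
        raise ValueError(
            f"insufficient support: {ks.size} usable bins < {min_points}"
        )
    lx, ly = np.log(ks), np.log(vs)
    A = np.vstack([lx, np.ones_like(lx)]).T
    coef, *_ = np.linalg.lstsq(A, ly, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = ly - (slope * lx + intercept)
    max_resid = float(np.max(np.abs(resid)))
    dof = ks.size - 2
    if dof > 0 and np.ptp(lx) > 0:
        s2 = float(np.sum(resid**2)) / dof
        sxx = float(np.sum((lx - lx.mean()) ** 2))
        stderr = math.sqrt(s2 / sxx) if sxx > 0 else float("inf")
    else:
        stderr = 0.0
    return PowerLawFit(
        measure=profile.name, exponent=-slope, method="loglog_ols",
        ks_stat=max_resid, n_points=int(ks.size), intercept=intercept,
        stderr=stderr,
    )


# ---------------------------------------------------------------------------
# Classification


def classify_topology(
    fits: Mapping[str, PowerLawFit | None],
    thresholds: FitThresholds = FitThresholds(),
) -> TopologySummary:
    """Derive the topology class and assortativity from six fits.

    Rules (deterministic and threshold-monotone):

    * ``hierarchical_scale_free`` — p(k) decays (exponent above
      ``flat_band``) and the c(k) exponent reaches ``c_hier_min`` (the
      c(k) ~ k**-1-type modular-hierarchy signature).
    * ``scale_free`` — p(k) decays but c(k) stays below ``c_hier_min``
      (flat or mildly decaying clustering).
    * ``unclassified`` — anything else, including missing fits.

    Assortativity is read from the sign of the C_N(k) slope: an
    *increasing* profile (exponent < -flat_band) is assortative.  MLE
    fits failing ``p_min`` / ``gof_max`` contribute warnings, not class
    changes: the class is a statement about exponent signs, fit quality
    is reported alongside.
    """
    required = {"p", "c", "cn", "cb", "cc", "ce"}
    missing = required - set(fits)
    if missing:
        raise ValueError(f"missing fits for {sorted(missing)}")

    warnings: list[str] = []
    for key, f in fits.items():
        if f is None:
            warnings.append(f"{key}: fit absent")
            continue
        if f.method == "mle_ks":
            if f.p_value is not None and f.p_value < thresholds.p_min:
                warnings.append(
                    f"{key}: bootstrap p={f.p_value:.3f} < {thresholds.p_min}"
                )
            if f.ks_stat > thresholds.gof_max:
                warnings.append(
                    f"{key}: KS gof {f.ks_stat:.3f} > {thresholds.gof_max}"
                )

    p_fit, c_fit, cn_fit = fits["p"], fits["c"], fits["cn"]
    if p_fit is None or c_fit is None:
        topo = "unclassified"
    elif p_fit.exponent > thresholds.flat_band:
        if c_fit.exponent >= thresholds.c_hier_min:
            topo = "hierarchical_scale_free"
        else:
            topo = "scale_free"
    else:
        topo = "unclassified"

    if cn_fit is None or abs(cn_fit.exponent) <= thresholds.flat_band:
        assort = "neutral"
    elif cn_fit.exponent < -thresholds.flat_band:
        assort = "assortative"
    else:
        assort = "disassortative"

    return TopologySummary(
        fits=dict(fits), topology_class=topo,
        assortative=(assort == "assortative"), assortativity=assort,
        thresholds=thresholds, warnings=tuple(warnings),
    )


def summarize_topology(
    net: Network,
    n_boot: int = 0,
    rng_seed: int = 0,
    thresholds: FitThresholds = FitThresholds(),
    min_points: int = 3,
    degree_fit: Literal["mle_ks", "loglog_ols"] = "mle_ks",
    measures: frozenset[str] | set[str] | None = None,
) -> TopologySummary:
    """Compute the six profiles/centralities of a network and fit each.

    The degree distribution is fitted by discrete MLE on the raw per-node
    degree sample (falling back to an OLS fit of the binned p(k) profile
    when the sample is too small); the five measure-vs-degree profiles
    are fitted by log-log OLS on exact degree bins.  Fits that lose
    support (too few usable bins) are recorded as absent.  ``measures``
    restricts the computation to a subset of {p, c, cn, cb, cc, ce}
    (the classification needs only p, c and cn; the centrality fits cost
    all-pairs shortest paths, noticeable above a few thousand nodes).
    """
    wanted = set(measures) if measures is not None else {
        "p", "c", "cn", "cb", "cc", "ce"}
    degs = [d for _, d in net.graph.degree() if d >= 1]

    def _try(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (ValueError, RuntimeError):
            return None

    fits: dict[str, PowerLawFit | None] = dict.fromkeys(
        ("p", "c", "cn", "cb", "cc", "ce"))
    if "p" in wanted:
        if degree_fit == "mle_ks" and len(degs) >= 50:
            fits["p"] = _try(fit_powerlaw_mle, degs, n_boot=n_boot,
                             rng_seed=rng_seed, measure="p(k)")
        if fits["p"] is None:
            fits["p"] = _try(fit_loglog_slope, degree_distribution(net),
                             min_points)
    if "c" in wanted:
        fits["c"] = _try(
            lambda: fit_loglog_slope(clustering_by_degree(net), min_points))
    if "cn" in wanted:
        fits["cn"] = _try(
            lambda: fit_loglog_slope(neighborhood_connectivity(net), min_points))
    if "cb" in wanted:
        fits["cb"] = _try(lambda: fit_loglog_slope(
            bin_measure_by_degree(net, betweenness_centrality(net)), min_points))
    if "cc" in wanted:
        fits["cc"] = _try(lambda: fit_loglog_slope(
            bin_measure_by_degree(net, closeness_centrality(net)), min_points))
    if "ce" in wanted:
        fits["ce"] = _try(lambda: fit_loglog_slope(
            bin_measure_by_degree(net, eigenvector_centrality(net)), min_points))
    return classify_topology(fits, thresholds)
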