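"""Bayes factors for stratigraphic age ranges and per-fossil summaries.

The Bayes factor for the hypothesis H1 that a fossil's true age lies
inside its palaeontological age range [l, u] (against H2, outside) is
the ratio of posterior to prior odds,

    BF = [p(H1|D,M) / p(H2|D,M)] / [p(H1|M) / p(H2|M)],

with the posterior probability read off the MCMC output and the prior
probability computed from the analytic FBD sampling-time density
averaged over the parameter priors.  log BF is natural-log throughout;
|log BF| > 3 is read as strong evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from fossildater.fbd import (
    PriorSpec,
    implicit_prior_draw,
    normalized_age_probability,
)
from fossildater.simulate import AgeConstraint

__all__ = [
    "FossilAgeReport",
    "posterior_prob_age_range",
    "prior_prob_age_range",
    "bayes_factor",
    "classify_support",
    "hpd_interval",
    "ess",
    "error_metrics",
    "rsd",
    "precision",
    "dataset_summary",
    "leave_one_out_report",
]


def posterior_prob_age_range(trace, l: float, u: float) -> float:
    """Fraction of post-burn-in focal-age samples inside [l, u]."""
    ages = trace.samples("focal_age") if hasattr(trace, "samples") else np.asarray(trace)
    if len(ages) == 0:
        raise ValueError("empty trace")
    return float(np.mean((ages >= l) & (ages <= u)))


def prior_prob_age_range(
    l: float,
    u: float,
    priors: PriorSpec,
    n_draws: int = 5000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Prior probability that a fossil's sampling time falls in [l, u].

    Monte-Carlo average, over FBD parameter draws from the prior, of the
    normalized sampling-time probability of [l, u]; draws whose origin
    T < l contribute 0 (the process is too young to admit such fossils).
    """
    if n_draws < 1000:
        raise ValueError("use at least 1000 draws")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    total = 0.0
    for _ in range(n_draws):
        params = implicit_prior_draw(priors, rng)
        if params.origin_T < l or params.s == 0.0:
            continue
        try:
            total += normalized_age_probability(l, u, params)
        except (ArithmeticError, OverflowError):
            continue  # pathological tail draw contributes ~0 mass in [l, u]
    return total / n_draws


@dataclass(frozen=True)
class BayesFactor:
    bf: float
    log_bf: float
    clamped: bool = False


def bayes_factor(
    post_p: float, prior_p: float, n_samples: int | None = None
) -> BayesFactor:
    """Posterior-to-prior odds ratio for an age-range hypothesis.

    Degenerate posterior probabilities 0 or 1 are clamped to the
    finite-sample resolution 1/(2 n_samples) and flagged.
    """
    clamped = False
    if post_p in (0.0, 1.0):
        if n_samples is None:
            raise ValueError(
                "post_p of 0 or 1 needs n_samples for the finite-sample clamp"
            )
        eps = 1.0 / (2.0 * n_samples)
        post_p = eps if post_p == 0.0 else 1.0 - eps
        clamped = True
    if not 0.0 < post_p < 1.0 or not 0.0 < prior_p < 1.0:
        raise ValueError("probabilities must be in (0, 1)")
    bf = (post_p / (1.0 - post_p)) / (prior_p / (1.0 - prior_p))
    return BayesFactor(bf=bf, log_bf=math.log(bf), clamped=clamped)


def classify_support(log_bf: float) -> str:
    """Support category at the +-3 natural-log thresholds."""
    if not np.isfinite(log_bf):
        raise ValueError("log BF must be finite")
    if log_bf < -3.0:
        return "strong_against"
    if log_bf < 0.0:
        return "negative"
    if log_bf > 3.0:
        return "strong_for"
    return "positive"


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 samples for an HPD interval")
    m = int(math.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def ess(samples: np.ndarray) -> float:
    """Effective sample size by the initial-positive-sequence rule.

    ESS = n / (1 + 2 * sum_k rho_k), summing autocorrelations until the
    first non-positive pair (rho_{2t} + rho_{2t+1} <= 0).  A constant
    series is defined as ESS = n.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 samples")
    v = np.var(x)
    if v == 0:
        return float(n)  # degenerate series
    xc = x - x.mean()
    from scipy import signal

    acf = signal.fftconvolve(xc, xc[::-1], mode="full")[n - 1:] / (v * n)
    tau = 0.0
    t = 1
    while t + 1 < n:
        pair = acf[t] + acf[t + 1]
        if pair <= 0:
            break
        tau += pair
        t += 2
    return float(n / (1.0 + 2.0 * tau))


def error_metrics(
    phylo_median: float, geo_range: AgeConstraint
) -> tuple[float, float | None]:
    """(error, relative error) of a phylogenetic age vs. the geological range.

    The error is |phylogenetic median - geological mid-point| in Myr;
    the relative error divides by the geological mid-point (None when
    the mid-point is 0).
    """
    geo_median = geo_range.midpoint
    err = abs(phylo_median - geo_median)
    rel = err / geo_median if geo_median > 0 else None
    return err, rel


def rsd(samples: np.ndarray) -> float:
    """Relative standard deviation: posterior sd / posterior median."""
    x = np.asarray(samples, dtype=float)
    med = np.median(x)
    if med == 0:
        raise ValueError("RSD undefined for zero median")
    return float(np.std(x, ddof=1) / med)


def precision(samples: np.ndarray) -> float:
    """Precision 1/variance of the marginal posterior."""
    x = np.asarray(samples, dtype=float)
    v = np.var(x, ddof=1)
    if v == 0:
        return math.inf  # constant samples: infinite precision
    return float(1.0 / v)


@dataclass
class FossilAgeReport:
    """One row of the per-fossil report table."""

    taxon: str
    post: float
    bf: float
    log_bf: float
    phylo_age: float
    lower: float
    upper: float
    sd: float
    error: float
    relative_error: float | None
    rsd: float
    precision: float
    ess: float
    geo_lower: float
    geo_upper: float


def dataset_summary(
    reports: list[FossilAgeReport],
) -> dict:
    """Dataset-level summary over per-fossil estimates.

    R^2 is the squared Pearson correlation between phylogenetic medians
    and geological mid-points; medians of error, relative error and RSD
    follow the per-fossil definitions; ``outside_hpd`` lists fossils
    whose geological mid-point escapes the phylogenetic 95% HPD.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 fossils")
    phylo = np.array([r.phylo_age for r in reports])
    geo = np.array([(r.geo_lower + r.geo_upper) / 2.0 for r in reports])
    r2 = float(np.corrcoef(phylo, geo)[0, 1] ** 2)
    outside = [
        r.taxon
        for r in reports
        if not (r.lower <= (r.geo_lower + r.geo_upper) / 2.0 <= r.upper)
    ]
    rels = [r.relative_error for r in reports if r.relative_error is not None]
    return {
        "r_squared": r2,
        "median_error": float(np.median([r.error for r in reports])),
        "median_relative_error": float(np.median(rels)) if rels else math.nan,
        "median_rsd": float(np.median([r.rsd for r in reports])),
        "n_outside_hpd": len(outside),
        "outside_hpd": outside,
    }


def leave_one_out_report(
    tree,
    data,
    constraints: list[AgeConstraint],
    priors: PriorSpec,
    config,
    seed: int,
    prior_prob_draws: int = 3000,
    taxa: list[str] | None = None,
) -> list[FossilAgeReport]:
    """Focal-fossil analysis of each fossil in turn.

    For every fossil (or the subset ``taxa``) the stratigraphic
    constraint is replaced by the FBD prior, the chain is run, and a
    report row with posterior range probability, Bayes factor and error
    metrics is emitted.  Per-fossil failures are recorded as None rows
    rather than aborting the run.
    """
    from fossildater.mcmc import estimate_focal_fossil_age

    by_taxon = {c.taxon: c for c in constraints}
    todo = taxa if taxa is not None else [c.taxon for c in constraints]
    rng = np.random.default_rng(seed)
    rows: list[FossilAgeReport] = []
    for taxon in todo:
        geo = by_taxon[taxon]
        sub_seed = int(rng.integers(2**31 - 1))
        try:
            est = estimate_focal_fossil_age(
                tree, data, constraints, priors, taxon, config, sub_seed
            )
        except Exception:
            continue
        ages = est.trace.samples("focal_age")
        post = posterior_prob_age_range(est.trace, geo.lower, geo.upper)
        prior_p = prior_prob_age_range(
            geo.lower, geo.upper, priors, n_draws=prior_prob_draws,
            seed=int(rng.integers(2**31 - 1)),
        )
        prior_p = min(max(prior_p, 1e-12), 1 - 1e-12)
        b = bayes_factor(post, prior_p, n_samples=len(ages))
        err, rel = error_metrics(est.median, geo)
        rows.append(
            FossilAgeReport(
                taxon=taxon,
                post=post,
                bf=b.bf,
                log_bf=b.log_bf,
                phylo_age=est.median,
                lower=est.hpd_lower,
                upper=est.hpd_upper,
                sd=est.sd,
                error=err,
                relative_error=rel,
                rsd=rsd(ages),
                precision=precision(ages),
                ess=est.ess,
                geo_lower=geo.lower,
                geo_upper=geo.upper,
            )
        )
    return rows
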