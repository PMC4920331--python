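"""MCMC over fossil ages, divergence times, clock and FBD parameters.

The sampler works on a fixed reference topology (a sampled-ancestor
time-tree); node ages, fossil ages, the attachment configuration of each
fossil (tip on a branch vs. sampled ancestor), the FBD parameters
(d, r, s-or-psi, origin T), the morphological clock and the gamma shape
are all updated by Metropolis-Hastings moves.  Fossil ages carry an
indicator prior that is 1 inside the stratigraphic range [l_i, u_i] and
0 outside; estimating the *focal* fossil's age phylogenetically amounts
to widening its range to [0, T].

The FBD tree density is evaluated with extant-sampling probability
rho = 1 and fossil-removal probability 0, conditioned on survival of the
process; constants that depend only on the fixed sampled configuration
(labelling, orientation) are dropped, as they cancel in MCMC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from fossildater.fbd import FBDParams, Prior, PriorSpec
from fossildater.morph import (
    CharacterMatrix,
    ClockModel,
    MkModelConfig,
    ucln_branch_rates,
)
from fossildater._pruning import prune_loglik
from fossildater.simulate import AgeConstraint
from fossildater.trees import SampledTree

__all__ = [
    "ChainConfig",
    "ModelState",
    "TraceLog",
    "fbd_tree_log_density",
    "log_posterior",
    "run_mcmc",
    "estimate_focal_fossil_age",
]

_LOG4 = math.log(4.0)


def _bd_constants(lam: float, mu: float, psi: float) -> tuple[float, float]:
    c1 = math.sqrt((lam - mu - psi) ** 2 + 4.0 * lam * psi)
    c2 = (lam + mu + psi) / c1  # rho = 1
    return c1, c2


def _logq_p0(t: np.ndarray, lam: float, mu: float, psi: float):
    """log q(t) and p0(t) of the FBD process with rho = 1.

    q is the probability-density factor of an edge spanning [0, t] and
    p0 the probability a lineage at time t leaves no sampled extant
    descendant.  With psi = 0 these reduce to the linear birth-death
    p1 and p0 of Kendall.
    """
    c1, c2 = _bd_constants(lam, mu, psi)
    ex = np.exp(-c1 * np.asarray(t, dtype=float))
    denom = ex * (1.0 - c2) + (1.0 + c2)
    logq = _LOG4 - c1 * np.asarray(t, dtype=float) - 2.0 * np.log(denom)
    p0 = (lam + mu + psi + c1 * (ex * (1.0 - c2) - (1.0 + c2)) / denom) / (
        2.0 * lam
    )
    return logq, p0


def fbd_tree_log_density(tree: SampledTree, params: FBDParams) -> float:
    """Log FBD density of a sampled-ancestor tree, conditioned on survival.

    Returns -inf for states outside the support (origin below the root,
    fossils above the origin, or fossils present with psi = 0).
    """
    arr = tree.to_arrays()
    fossil = np.array(
        [n.kind == "fossil" and n.is_tip for n in arr.nodes], dtype=bool
    )
    return _fbd_log_density_arrays(
        arr.ages,
        arr.parent,
        arr.left,
        fossil,
        params.origin_T,
        params.speciation,
        params.extinction,
        params.fossil_sampling,
    )


def _fbd_log_density_arrays(
    ages: np.ndarray,
    parent: np.ndarray,
    left: np.ndarray,
    fossil_tip: np.ndarray,
    T: float,
    lam: float,
    mu: float,
    psi: float,
) -> float:
    root = len(ages) - 1
    if T < ages[root]:
        return -np.inf
    ft = np.nonzero(fossil_tip)[0]
    if len(ft) > 0 and psi == 0.0:
        return -np.inf
    # branch durations must be nonnegative
    tops = np.where(parent >= 0, ages[np.maximum(parent, 0)], T)
    if (tops - ages < 0).any():
        return -np.inf
    is_sa = ages[parent[ft]] == ages[ft] if len(ft) else np.zeros(0, bool)
    sa_attach = np.zeros(len(ages), dtype=bool)
    sa_attach[parent[ft[is_sa]]] = True
    internal = left >= 0
    bif = internal & ~sa_attach
    logq_T, p0_T = _logq_p0(np.array([T]), lam, mu, psi)
    out = float(logq_T[0]) - math.log1p(-float(p0_T[0]))
    # labelled-tree convention: each bifurcation carries 2*lambda*q (two
    # orientations collapse onto one labelled topology); sampled-ancestor
    # attachments carry no such factor, so the 2 matters when a fossil
    # switches between tip and ancestor configurations
    bif_ages = ages[bif]
    if len(bif_ages):
        logq_b, _ = _logq_p0(bif_ages, lam, mu, psi)
        out += len(bif_ages) * math.log(2.0 * lam) + float(logq_b.sum())
    n_sa = int(is_sa.sum())
    if n_sa:
        out += n_sa * math.log(psi)
    tip_f = ft[~is_sa]
    if len(tip_f):
        logq_f, p0_f = _logq_p0(ages[tip_f], lam, mu, psi)
        if (p0_f <= 0).any():
            return -np.inf
        out += len(tip_f) * math.log(psi) + float(
            np.log(p0_f).sum() - logq_f.sum()
        )
    return out


# -- priors ------------------------------------------------------------------

_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)


def _logpdf(prior: Prior, x: float) -> float:
    fam = prior.family
    if fam == "fixed":
        return 0.0
    if fam == "uniform":
        a, b = prior.params
        return -math.log(b - a) if a <= x <= b else -np.inf
    if x <= 0:
        return -np.inf
    if fam == "lognormal":
        m, s_ = prior.params
        z = (math.log(x) - m) / s_
        return -math.log(x * s_) - _HALF_LOG_2PI - 0.5 * z * z
    if fam == "gamma":
        shape, rate = prior.params
        return (
            shape * math.log(rate)
            - math.lgamma(shape)
            + (shape - 1.0) * math.log(x)
            - rate * x
        )
    raise ValueError(f"unknown prior family {fam!r}")


# -- chain configuration ------------------------------------------------------


@dataclass
class ChainConfig:
    """MCMC chain settings."""

    n_iter: int = 20000
    thin: int = 20
    burnin_frac: float = 0.25
    tune: bool = True
    clock_kind: str = "strict"  # strict | ucln
    model: MkModelConfig = field(default_factory=MkModelConfig)
    prob_collapse: float = 0.5  # atom weight of the sampled-ancestor proposal

    def __post_init__(self) -> None:
        if self.n_iter < self.thin or self.thin < 1:
            raise ValueError("need n_iter >= thin >= 1")
        if not 0.0 <= self.burnin_frac <= 0.9:
            raise ValueError("burn-in fraction must be in [0, 0.9]")


@dataclass
class TraceLog:
    """Posterior samples indexed by iteration, plus acceptance counts."""

    columns: dict[str, np.ndarray]
    acceptance: dict[str, tuple[int, int]]
    burnin_frac: float = 0.25

    def __post_init__(self) -> None:
        it = self.columns["iteration"]
        if len(it) > 1 and not (np.diff(it) > 0).all():
            raise ValueError("iterations must be strictly increasing")

    def __len__(self) -> int:
        return len(self.columns["iteration"])

    def samples(self, name: str, burnin: bool = True) -> np.ndarray:
        x = self.columns[name]
        if burnin:
            x = x[int(len(x) * self.burnin_frac):]
        return x

    def acceptance_rate(self, move: str) -> float:
        acc, tries = self.acceptance[move]
        return acc / tries if tries else math.nan

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.columns)


@dataclass
class ModelState:
    """A full model state: tree, FBD parameters, clock, site model."""

    tree: SampledTree
    params: FBDParams
    clock: ClockModel
    gamma_shape: float | None = None
    focal: str | None = None


def log_posterior(
    state: ModelState,
    data: CharacterMatrix | None,
    constraints: list[AgeConstraint],
    priors: PriorSpec,
    model: MkModelConfig | None = None,
) -> float:
    """Log posterior density of ``state`` (up to a constant).

    Sum of the morphological log-likelihood, the FBD tree log-density,
    the parameter log-priors and the stratigraphic-range indicator
    (-inf when a non-focal fossil age leaves its range).
    """
    from fossildater.morph import tree_log_likelihood

    p = state.params
    by_taxon = {c.taxon: c for c in constraints}
    for node in state.tree.fossil_tips():
        if node.label == state.focal:
            if not 0.0 <= node.age <= p.origin_T:
                return -np.inf
            continue
        c = by_taxon.get(node.label)
        if c is not None and not c.contains(node.age):
            return -np.inf
    lp = _logpdf(priors.d, p.d) + _logpdf(priors.r, p.r)
    if priors.implicit_s:
        lp += _logpdf(priors.s_or_psi, p.fossil_sampling)
    else:
        lp += _logpdf(priors.s_or_psi, p.s)
    if priors.implicit_T:
        lp += _implicit_T_logpdf(priors.T_or_N, p.origin_T, p.d)
    else:
        lp += _logpdf(priors.T_or_N, p.origin_T)
    lp += _logpdf(priors.clock_mean, state.clock.mean)
    if state.clock.kind == "ucln":
        lp += _logpdf(priors.clock_log_sd, state.clock.log_sd)
    if state.gamma_shape is not None:
        lp += _logpdf(priors.gamma_shape, state.gamma_shape)
    if not np.isfinite(lp):
        return -np.inf
    ld = fbd_tree_log_density(state.tree, p)
    if not np.isfinite(ld):
        return -np.inf
    ll = 0.0
    if data is not None and data.n_chars > 0:
        cfg = model or MkModelConfig(
            gamma_shape=state.gamma_shape,
            gamma_ncat=4 if state.gamma_shape is not None else 1,
        )
        ll = tree_log_likelihood(state.tree, data, cfg, state.clock)
    return lp + ld + ll


def _implicit_T_logpdf(n_prior: Prior, T: float, d: float) -> float:
    # T = ln(N)/d with N ~ prior on the number of present-day species:
    # p(T | d) = p_N(e^{dT}) * d * e^{dT}
    n = math.exp(min(d * T, 700.0))
    base = _logpdf(n_prior, n)
    if not np.isfinite(base):
        return -np.inf
    return base + math.log(d) + d * T


# -- the sampler --------------------------------------------------------------


class _Engine:
    """Flat-array MCMC engine over a fixed topology."""

    def __init__(
        self,
        tree: SampledTree,
        data: CharacterMatrix | None,
        constraints: list[AgeConstraint],
        priors: PriorSpec,
        config: ChainConfig,
        focal: str | None,
        rng: np.random.Generator,
    ) -> None:
        self.rng = rng
        self.priors = priors
        self.config = config
        self.focal = focal
        self.tree = tree.copy()
        arr = self.tree.to_arrays()
        self.arr = arr
        self.ages = arr.ages  # mutable
        self.parent = arr.parent
        self.left = arr.left
        self.right = arr.right
        self.n_nodes = len(self.ages)
        self.root = self.n_nodes - 1
        self.fossil_tip = np.array(
            [n.kind == "fossil" and n.is_tip for n in arr.nodes], dtype=bool
        )
        self.fossil_idx = np.nonzero(self.fossil_tip)[0]
        self.internal_idx = np.nonzero(arr.left >= 0)[0]
        # stratigraphic bounds per node (fossils only; others unbounded)
        self.lo = np.zeros(self.n_nodes)
        self.hi = np.full(self.n_nodes, np.inf)
        by_taxon = {c.taxon: c for c in constraints}
        for i in self.fossil_idx:
            label = arr.labels[i]
            if label == focal:
                continue  # focal: [0, T] via tree support
            c = by_taxon.get(label)
            if c is not None:
                self.lo[i], self.hi[i] = c.lower, c.upper
        self.focal_idx = (
            int(arr.labels.index(focal)) if focal is not None else -1
        )
        # data, grouped by resolved state count
        self.groups: list[tuple[int, np.ndarray]] = []
        if data is not None and data.n_chars > 0:
            from fossildater.morph import _tip_masks

            kres = data.observed_state_counts()
            masks = _tip_masks(data, arr.labels, kres)
            for k in np.unique(kres):
                cols = np.nonzero(kres == k)[0]
                self.groups.append(
                    (int(k), np.ascontiguousarray(masks[:, cols]))
                )
        # sampled scalars
        self.d = priors.d.median()
        self.r = priors.r.median()
        self.s_or_psi = priors.s_or_psi.median()
        self.clock_mean = priors.clock_mean.median()
        self.clock_sd = (
            priors.clock_log_sd.median() if config.clock_kind == "ucln" else 0.0
        )
        self.gamma_shape = (
            priors.gamma_shape.median()
            if config.model.gamma_shape is not None
            else None
        )
        self.quantiles = (
            np.full(self.n_nodes, 0.5)
            if config.clock_kind == "ucln"
            else None
        )
        self.T = self._initial_origin()
        self._init_ages(by_taxon)
        # move bookkeeping
        self.scales: dict[str, float] = {
            "d": 0.5,
            "s_or_psi": 0.7,
            "r": 0.2,
            "T": 0.1,
            "clock_mean": 0.8,
            "clock_sd": 0.5,
            "gamma_shape": 0.5,
        }
        self.acc: dict[str, list[int]] = {}
        self._lik = self.log_likelihood()
        self.cur = self.log_posterior()
        if not np.isfinite(self.cur):
            raise RuntimeError(
                "zero-probability initial state: check that the reference "
                "tree is consistent with the age ranges and priors"
            )

    # -- initialization ---------------------------------------------------

    def _initial_origin(self) -> float:
        root_age = float(self.ages[self.root])
        T = max(self.arr.origin_T, root_age * 1.05)
        if self.priors.implicit_T:
            upper = math.log(self.priors.T_or_N.params[1]) / self.d
            if root_age >= upper:
                # lower d until the implicit support admits the root
                self.d = 0.9 * math.log(self.priors.T_or_N.params[1]) / root_age
                upper = math.log(self.priors.T_or_N.params[1]) / self.d
            T = min(max(T, root_age * 1.02), upper * 0.999)
        elif self.priors.T_or_N.family == "uniform":
            T = min(T, self.priors.T_or_N.params[1] * 0.999)
        elif self.priors.T_or_N.family == "fixed":
            T = self.priors.T_or_N.params[0]
        return T

    def _init_ages(self, by_taxon: dict[str, AgeConstraint]) -> None:
        """Move fossil ages toward their range mid-points where the tree
        permits; the reference ages are kept otherwise."""
        for i in self.fossil_idx:
            label = self.arr.labels[i]
            if label == self.focal or label not in by_taxon:
                continue
            c = by_taxon[label]
            v = self.parent[i]
            if self.ages[v] == self.ages[i]:
                continue  # sampled ancestor: keep the joint configuration
            hi = min(c.upper, self.ages[v])
            lo = c.lower
            if lo <= hi:
                target = min(max(c.midpoint, lo), hi * 0.999 + lo * 0.001)
                self.ages[i] = target

    # -- posterior ---------------------------------------------------------

    def _rates(self) -> tuple[float, float, float]:
        lam = self.d / (1.0 - self.r)
        mu = self.r * self.d / (1.0 - self.r)
        if self.priors.implicit_s:
            psi = self.s_or_psi
        else:
            s = self.s_or_psi
            psi = s * mu / (1.0 - s) if s < 1.0 else np.inf
        return lam, mu, psi

    def log_prior(self) -> float:
        pr = self.priors
        lp = _logpdf(pr.d, self.d) + _logpdf(pr.r, self.r)
        lp += _logpdf(pr.s_or_psi, self.s_or_psi)
        if pr.implicit_T:
            lp += _implicit_T_logpdf(pr.T_or_N, self.T, self.d)
        else:
            lp += _logpdf(pr.T_or_N, self.T)
        lp += _logpdf(pr.clock_mean, self.clock_mean)
        if self.config.clock_kind == "ucln":
            lp += _logpdf(pr.clock_log_sd, self.clock_sd)
        if self.gamma_shape is not None:
            lp += _logpdf(pr.gamma_shape, self.gamma_shape)
        return lp

    def log_indicator(self) -> float:
        ok = (self.ages[self.fossil_idx] >= self.lo[self.fossil_idx] - 1e-12) & (
            self.ages[self.fossil_idx] <= self.hi[self.fossil_idx] + 1e-12
        )
        return 0.0 if ok.all() else -np.inf

    def log_tree_density(self) -> float:
        lam, mu, psi = self._rates()
        if not (lam > 0 and mu >= 0 and np.isfinite(psi)):
            return -np.inf
        return _fbd_log_density_arrays(
            self.ages, self.parent, self.left, self.fossil_tip,
            self.T, lam, mu, psi,
        )

    def log_likelihood(self) -> float:
        if not self.groups:
            return 0.0
        tops = np.where(self.parent >= 0, self.ages[np.maximum(self.parent, 0)], self.T)
        dur = tops - self.ages
        if (dur < 0).any():
            return -np.inf
        if self.quantiles is not None and self.clock_sd > 0.0:
            rates = ucln_branch_rates(self.clock_mean, self.clock_sd, self.quantiles)
        else:
            rates = np.full(self.n_nodes, self.clock_mean)
        blen = dur * rates
        gamma_rates = (
            np.array([1.0])
            if self.gamma_shape is None
            else MkModelConfig(
                gamma_shape=self.gamma_shape,
                gamma_ncat=self.config.model.gamma_ncat,
            ).rates()
        )
        total = 0.0
        for k, masks in self.groups:
            if len(gamma_rates) == 1:
                logl = prune_loglik(self.left, self.right, masks, blen, k)
                total += float(logl.sum())
            else:
                per = np.stack(
                    [
                        prune_loglik(self.left, self.right, masks, blen * g, k)
                        for g in gamma_rates
                    ]
                )
                m = per.max(axis=0)
                total += float(
                    (m + np.log(np.mean(np.exp(per - m), axis=0))).sum()
                )
        return total

    def log_posterior(self) -> float:
        lp = self.log_prior()
        if not np.isfinite(lp):
            return -np.inf
        li = self.log_indicator()
        if not np.isfinite(li):
            return -np.inf
        ld = self.log_tree_density()
        if not np.isfinite(ld):
            return -np.inf
        return lp + li + ld + self.log_likelihood()

    def _propose_posterior(self, lik_changed: bool) -> tuple[float, float]:
        """Posterior of the proposed state, reusing the cached likelihood
        for moves that cannot change it (FBD scalars; the origin branch
        carries no characters)."""
        lp = self.log_prior()
        if not np.isfinite(lp):
            return -np.inf, self._lik
        li = self.log_indicator()
        if not np.isfinite(li):
            return -np.inf, self._lik
        ld = self.log_tree_density()
        if not np.isfinite(ld):
            return -np.inf, self._lik
        lik = self.log_likelihood() if lik_changed else self._lik
        return lp + li + ld + lik, lik

    # -- moves -------------------------------------------------------------

    _LIK_INVARIANT_MOVES = frozenset({"d", "r", "s_or_psi", "T"})

    def _accept(self, move: str, log_ratio: float) -> bool:
        a = self.acc.setdefault(move, [0, 0])
        a[1] += 1
        if np.isfinite(log_ratio) and (
            log_ratio >= 0.0 or self.rng.random() < math.exp(log_ratio)
        ):
            a[0] += 1
            return True
        return False

    def _scale_move(self, move: str, attr: str) -> None:
        old = getattr(self, attr)
        factor = math.exp(self.scales[move] * (self.rng.random() - 0.5))
        setattr(self, attr, old * factor)
        lik_changed = move not in self._LIK_INVARIANT_MOVES
        new, lik = self._propose_posterior(lik_changed)
        if self._accept(move, new - self.cur + math.log(factor)):
            self.cur, self._lik = new, lik
        else:
            setattr(self, attr, old)

    def _window01_move(self, move: str, attr: str) -> None:
        old = getattr(self, attr)
        x = old + self.scales[move] * (self.rng.random() - 0.5)
        # reflect into (0, 1)
        for _ in range(100):
            if x < 0.0:
                x = -x
            elif x > 1.0:
                x = 2.0 - x
            else:
                break
        setattr(self, attr, x)
        lik_changed = move not in self._LIK_INVARIANT_MOVES
        new, lik = self._propose_posterior(lik_changed)
        if self._accept(move, new - self.cur):
            self.cur, self._lik = new, lik
        else:
            setattr(self, attr, old)

    def _origin_move(self) -> None:
        old = self.T
        factor = math.exp(self.scales["T"] * (self.rng.random() - 0.5))
        self.T = old * factor
        new, lik = self._propose_posterior(False)
        if self._accept("T", new - self.cur + math.log(factor)):
            self.cur, self._lik = new, lik
        else:
            self.T = old

    def _node_age_move(self) -> None:
        i = int(self.rng.choice(self.internal_idx))
        l_, r_ = self.left[i], self.right[i]
        # skip sampled-ancestor attachment nodes (their age is tied)
        for c in (l_, r_):
            if self.fossil_tip[c] and self.ages[c] == self.ages[i]:
                return
        lo = max(self.ages[l_], self.ages[r_])
        hi = self.T if i == self.root else self.ages[self.parent[i]]
        if hi <= lo:
            return
        old = self.ages[i]
        self.ages[i] = self.rng.uniform(lo, hi)
        new, lik = self._propose_posterior(True)
        if self._accept("node_age", new - self.cur):
            self.cur, self._lik = new, lik
        else:
            self.ages[i] = old

    def _fossil_age_move(self, f: int | None = None) -> None:
        if f is None:
            f = int(self.rng.choice(self.fossil_idx))
        v = self.parent[f]
        if self.ages[v] == self.ages[f]:
            # sampled ancestor: move fossil and attachment jointly
            sib = self.left[v] if self.right[v] == f else self.right[v]
            lo = max(self.lo[f], self.ages[sib])
            hi = min(
                self.hi[f],
                self.T if v == self.root else self.ages[self.parent[v]],
            )
            if hi <= lo:
                return
            old = self.ages[f]
            y = self.rng.uniform(lo, hi)
            self.ages[f] = y
            self.ages[v] = y
            new, lik = self._propose_posterior(True)
            if self._accept("fossil_age", new - self.cur):
                self.cur, self._lik = new, lik
            else:
                self.ages[f] = old
                self.ages[v] = old
        else:
            lo = self.lo[f]
            hi = min(self.hi[f], self.ages[v])
            if hi <= lo:
                return
            old = self.ages[f]
            self.ages[f] = self.rng.uniform(lo, hi)
            new, lik = self._propose_posterior(True)
            if self._accept("fossil_age", new - self.cur):
                self.cur, self._lik = new, lik
            else:
                self.ages[f] = old

    def _attachment_move(self, f: int | None = None) -> None:
        """Move a fossil's attachment age; the zero-length boundary (the
        sampled-ancestor configuration) is proposed as a discrete atom,
        with the interval length entering the acceptance ratio to account
        for the lost continuous dimension."""
        if f is None:
            f = int(self.rng.choice(self.fossil_idx))
        v = self.parent[f]
        sib = self.left[v] if self.right[v] == f else self.right[v]
        y = self.ages[f]
        lo = max(y, self.ages[sib])
        hi = self.T if v == self.root else self.ages[self.parent[v]]
        if hi <= lo:
            return
        pc = self.config.prob_collapse if y > self.ages[sib] else 0.0
        is_sa = self.ages[v] == y
        old = self.ages[v]
        if is_sa:
            # expand: propose a continuous attachment age
            self.ages[v] = self.rng.uniform(lo, hi)
            new, lik = self._propose_posterior(True)
            log_ratio = new - self.cur + math.log(pc) + math.log(hi - lo)
            if self._accept("attachment", log_ratio):
                self.cur, self._lik = new, lik
            else:
                self.ages[v] = old
        elif pc > 0.0 and self.rng.random() < pc:
            # collapse to sampled ancestor
            self.ages[v] = y
            new, lik = self._propose_posterior(True)
            log_ratio = new - self.cur - math.log(pc) - math.log(hi - lo)
            if self._accept("attachment", log_ratio):
                self.cur, self._lik = new, lik
            else:
                self.ages[v] = old
        else:
            self.ages[v] = self.rng.uniform(lo, hi)
            new, lik = self._propose_posterior(True)
            if self._accept("attachment", new - self.cur):
                self.cur, self._lik = new, lik
            else:
                self.ages[v] = old

    def _quantile_move(self) -> None:
        i = int(self.rng.integers(self.n_nodes))
        old = self.quantiles[i]
        x = old + 0.2 * (self.rng.random() - 0.5)
        x = x - math.floor(x)  # wrap into (0, 1)
        x = min(max(x, 1e-9), 1 - 1e-9)
        self.quantiles[i] = x
        new, lik = self._propose_posterior(True)
        if self._accept("quantile", new - self.cur):
            self.cur, self._lik = new, lik
        else:
            self.quantiles[i] = old

    # -- the chain ---------------------------------------------------------

    def _move_menu(self) -> list[tuple[str, float]]:
        pr = self.priors
        menu: list[tuple[str, float]] = []
        if pr.d.family != "fixed":
            menu.append(("d", 1.0))
        if pr.r.family != "fixed":
            menu.append(("r", 1.0))
        if pr.s_or_psi.family != "fixed":
            menu.append(("s_or_psi", 1.0))
        if pr.T_or_N.family != "fixed" or pr.implicit_T:
            menu.append(("T", 1.0))
        if pr.clock_mean.family != "fixed":
            menu.append(("clock_mean", 1.5))
        if self.config.clock_kind == "ucln":
            menu.append(("clock_sd", 1.0))
            menu.append(("quantile", 0.2 * self.n_nodes))
        if self.gamma_shape is not None:
            menu.append(("gamma_shape", 1.0))
        menu.append(("node_age", 0.6 * len(self.internal_idx)))
        if len(self.fossil_idx):
            menu.append(("fossil_age", 1.0 * len(self.fossil_idx)))
            menu.append(("attachment", 0.6 * len(self.fossil_idx)))
        if self.focal_idx >= 0:
            # extra attention for the focal fossil, whose marginal is the target
            menu.append(("focal_age", 4.0))
            menu.append(("focal_attachment", 3.0))
        return menu

    def _dispatch(self, move: str) -> None:
        if move in ("d", "s_or_psi", "clock_mean", "clock_sd", "gamma_shape"):
            if move == "s_or_psi" and not self.priors.implicit_s:
                self._window01_move(move, "s_or_psi")
            else:
                self._scale_move(move, move)
        elif move == "r":
            self._window01_move("r", "r")
        elif move == "T":
            self._origin_move()
        elif move == "node_age":
            self._node_age_move()
        elif move == "fossil_age":
            self._fossil_age_move()
        elif move == "attachment":
            self._attachment_move()
        elif move == "focal_age":
            self._fossil_age_move(self.focal_idx)
        elif move == "focal_attachment":
            self._attachment_move(self.focal_idx)
        elif move == "quantile":
            self._quantile_move()

    def _tune(self) -> None:
        for move, scale_key in (
            ("d", "d"),
            ("r", "r"),
            ("s_or_psi", "s_or_psi"),
            ("T", "T"),
            ("clock_mean", "clock_mean"),
            ("clock_sd", "clock_sd"),
            ("gamma_shape", "gamma_shape"),
        ):
            a = self.acc.get(move)
            if a and a[1] >= 20:
                rate = a[0] / a[1]
                self.scales[scale_key] *= math.exp(0.7 * (rate - 0.25))
                self.scales[scale_key] = min(max(self.scales[scale_key], 1e-3), 20.0)
                a[0] = a[1] = 0

    def run(self) -> TraceLog:
        cfg = self.config
        menu = self._move_menu()
        names = [m for m, _ in menu]
        weights = np.array([w for _, w in menu])
        weights = weights / weights.sum()
        cum = np.cumsum(weights)
        burnin_end = int(cfg.n_iter * cfg.burnin_frac)
        rows: dict[str, list[float]] = {
            c: []
            for c in (
                "iteration", "posterior", "likelihood", "prior",
                "d", "r", "s", "psi", "origin_T", "clock_mean",
                "clock_sd", "gamma_shape", "focal_age", "focal_sa", "root_age",
            )
        }
        tuned_acc_reset = False
        for it in range(1, cfg.n_iter + 1):
            move = names[int(np.searchsorted(cum, self.rng.random()))]
            self._dispatch(move)
            if cfg.tune and it <= burnin_end and it % 200 == 0:
                self._tune()
            if it == burnin_end and not tuned_acc_reset:
                # freeze tuning; restart acceptance bookkeeping
                self.acc = {}
                tuned_acc_reset = True
            if it % cfg.thin == 0:
                lam, mu, psi = self._rates()
                s = psi / (mu + psi) if (mu + psi) > 0 else 0.0
                lik = self._lik
                pri = self.log_prior() + self.log_tree_density() + self.log_indicator()
                rows["iteration"].append(it)
                rows["posterior"].append(self.cur)
                rows["likelihood"].append(lik)
                rows["prior"].append(pri)
                rows["d"].append(self.d)
                rows["r"].append(self.r)
                rows["s"].append(s if self.priors.implicit_s else self.s_or_psi)
                rows["psi"].append(psi)
                rows["origin_T"].append(self.T)
                rows["clock_mean"].append(self.clock_mean)
                rows["clock_sd"].append(self.clock_sd)
                rows["gamma_shape"].append(
                    self.gamma_shape if self.gamma_shape is not None else math.nan
                )
                rows["focal_age"].append(
                    self.ages[self.focal_idx] if self.focal_idx >= 0 else math.nan
                )
                rows["focal_sa"].append(
                    float(
                        self.ages[self.parent[self.focal_idx]]
                        == self.ages[self.focal_idx]
                    )
                    if self.focal_idx >= 0
                    else math.nan
                )
                rows["root_age"].append(self.ages[self.root])
            if it % 5000 == 0:
                # guard against numerical drift of the cached posterior
                self._lik = self.log_likelihood()
                self.cur = self.log_posterior()
        return TraceLog(
            columns={k: np.asarray(v) for k, v in rows.items()},
            acceptance={m: (a[0], a[1]) for m, a in self.acc.items()},
            burnin_frac=cfg.burnin_frac,
        )


def run_mcmc(
    tree: SampledTree,
    data: CharacterMatrix | None,
    constraints: list[AgeConstraint],
    priors: PriorSpec,
    config: ChainConfig,
    seed: int | np.random.Generator,
    focal: str | None = None,
) -> TraceLog:
    """Run the Metropolis-Hastings chain; deterministic given ``seed``.

    ``tree`` supplies the fixed reference topology and initial node ages.
    ``data`` may be None (or empty) for a prior-only chain.  When
    ``focal`` names a fossil, its stratigraphic constraint is replaced by
    the FBD prior on [0, T].
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if focal is not None:
        labels = {n.label for n in tree.fossil_tips()}
        if focal not in labels:
            raise ValueError(f"focal taxon {focal!r} is not a fossil on the tree")
    engine = _Engine(tree, data, constraints, priors, config, focal, rng)
    return engine.run()


@dataclass(frozen=True)
class FossilAgeEstimate:
    """Posterior summary of one fossil's phylogenetically estimated age."""

    taxon: str
    median: float
    hpd_lower: float
    hpd_upper: float
    sd: float
    ess: float
    trace: TraceLog


def estimate_focal_fossil_age(
    tree: SampledTree,
    data: CharacterMatrix | None,
    constraints: list[AgeConstraint],
    priors: PriorSpec,
    focal: str,
    config: ChainConfig,
    seed: int | np.random.Generator,
) -> FossilAgeEstimate:
    """Phylogenetic estimate of one fossil's age.

    Runs the chain with the focal fossil's stratigraphic range widened to
    [0, T] and summarizes its marginal posterior age.
    """
    from fossildater.summaries import ess as _ess
    from fossildater.summaries import hpd_interval

    trace = run_mcmc(tree, data, constraints, priors, config, seed, focal=focal)
    ages = trace.samples("focal_age")
    lower, upper = hpd_interval(ages, 0.95)
    return FossilAgeEstimate(
        taxon=focal,
        median=float(np.median(ages)),
        hpd_lower=lower,
        hpd_upper=upper,
        sd=float(np.std(ages, ddof=1)),
        ess=_ess(ages),
        trace=trace,
    )
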