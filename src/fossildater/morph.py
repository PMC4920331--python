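"""Lewis-Mk likelihood of discrete morphological characters on a time-tree.

The Mk model is a k-state continuous-time Markov chain with equal rates
between all states.  The generator is normalized so that the clock rate
is the expected number of state changes per Myr at stationarity
(off-diagonal entries rate/(k-1)).  Supports strict or uncorrelated
lognormal (UCLN) relaxed morphological clocks, state-count partitioning,
discrete-gamma rate variation across characters, and an optional
variable-characters-only (Mkv) ascertainment correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from fossildater._pruning import prune_loglik
from fossildater.trees import SampledTree

__all__ = [
    "CharacterMatrix",
    "ClockModel",
    "MkModelConfig",
    "partition_by_state_count",
    "mk_transition_matrix",
    "discrete_gamma_rates",
    "ucln_branch_rates",
    "tree_log_likelihood",
]

MISSING = -1


@dataclass
class CharacterMatrix:
    """Taxa-by-characters matrix of discrete state codes.

    ``data[i, j]`` is the state (0..k_j-1) of taxon i for character j, or
    -1 for missing ("?").  ``state_counts`` holds the declared number of
    states per character; ``ambiguities`` optionally maps (taxon_index,
    char_index) to the tuple of states of a polymorphic cell.
    """

    taxa: list[str]
    data: np.ndarray
    state_counts: np.ndarray
    ambiguities: dict[tuple[int, int], tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        self.state_counts = np.asarray(self.state_counts, dtype=np.int64)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")
        if self.data.shape != (len(self.taxa), len(self.state_counts)):
            raise ValueError("data shape does not match taxa/state_counts")
        if (self.state_counts < 2).any():
            raise ValueError("every character needs k >= 2 states")
        for j in range(self.n_chars):
            col = self.data[:, j]
            if (col >= self.state_counts[j]).any():
                raise ValueError(f"character {j} has codes >= declared k")
        if (self.data < MISSING).any():
            raise ValueError("invalid negative state codes")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return self.data.shape[1]

    def observed_state_counts(self) -> np.ndarray:
        """Number of distinct observed states per character.

        Characters that are constant or entirely missing resolve to 2,
        the minimal valid Mk state space.
        """
        out = np.empty(self.n_chars, dtype=np.int64)
        for j in range(self.n_chars):
            observed = set(self.data[:, j][self.data[:, j] >= 0].tolist())
            for (i, jj), states in self.ambiguities.items():
                if jj == j:
                    observed.update(states)
            out[j] = max(len(observed), 2)
        return out

    def subset_chars(self, indices: np.ndarray) -> "CharacterMatrix":
        indices = np.asarray(indices)
        remap = {int(j): pos for pos, j in enumerate(indices)}
        amb = {
            (i, remap[j]): st
            for (i, j), st in self.ambiguities.items()
            if j in remap
        }
        return CharacterMatrix(
            taxa=list(self.taxa),
            data=self.data[:, indices].copy(),
            state_counts=self.state_counts[indices].copy(),
            ambiguities=amb,
        )

    def non_missing_count(self, taxon: str) -> int:
        i = self.taxa.index(taxon)
        return int((self.data[i] >= 0).sum())


@dataclass
class ClockModel:
    """Morphological clock: strict, or UCLN relaxed.

    ``mean`` is the real-space mean branch rate in expected changes per
    Myr.  For the UCLN clock each branch's rate is an independent
    lognormal draw with real-space mean ``mean`` and log standard
    deviation ``log_sd``, realized here through per-branch quantiles.
    """

    kind: str = "strict"  # strict | ucln
    mean: float = 0.02
    log_sd: float = 0.0
    branch_quantiles: np.ndarray | None = None

    def branch_rates(self, n_branches: int) -> np.ndarray:
        if not self.mean > 0:
            raise ValueError("clock mean rate must be positive")
        if self.kind == "strict" or self.log_sd == 0.0:
            return np.full(n_branches, self.mean)
        if self.kind != "ucln":
            raise ValueError(f"unknown clock kind {self.kind!r}")
        q = self.branch_quantiles
        if q is None or len(q) != n_branches:
            raise ValueError("ucln clock needs one quantile per branch")
        return ucln_branch_rates(self.mean, self.log_sd, np.asarray(q))


@dataclass
class MkModelConfig:
    """Mk model configuration: partitioning, rate variation, ascertainment."""

    partition: str = "single"  # single | by_state_count
    gamma_shape: float | None = None
    gamma_ncat: int = 4
    ascertainment: str = "none"  # none | variable

    def __post_init__(self) -> None:
        if self.gamma_ncat < 1:
            raise ValueError("gamma category count must be >= 1")
        if self.gamma_shape is not None and not self.gamma_shape > 0:
            raise ValueError("gamma shape must be positive")

    def rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.array([1.0])
        return discrete_gamma_rates(self.gamma_shape, self.gamma_ncat)


def partition_by_state_count(
    matrix: CharacterMatrix,
) -> list[CharacterMatrix]:
    """Split characters into partitions by observed distinct-state count.

    Partitions are returned in increasing order of k, each holding all
    characters with that many observed states and preserving character
    order.  Constant or all-missing characters resolve to k = 2.
    """
    if matrix.n_chars == 0:
        raise ValueError("empty character matrix")
    observed = matrix.observed_state_counts()
    return [
        matrix.subset_chars(np.nonzero(observed == k)[0])
        for k in np.unique(observed)
    ]


def mk_transition_matrix(k: int, rate: float, t: float) -> np.ndarray:
    """Mk transition-probability matrix over duration ``t``.

    P_ii = 1/k + (k-1)/k * exp(-k/(k-1) * rate * t); off-diagonals equal.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if rate < 0 or t < 0:
        raise ValueError("rate and t must be nonnegative")
    e = np.exp(-k / (k - 1.0) * rate * t)
    pii = 1.0 / k + (k - 1.0) / k * e
    pij = (1.0 - e) / k
    return np.full((k, k), pij) + np.eye(k) * (pii - pij)


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean-one rate multipliers from equal-probability gamma categories.

    Category representative rates are the conditional means of a
    Gamma(alpha, mean 1) distribution between its i/ncat quantiles.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return np.array([1.0])
    edges = stats.gamma.ppf(np.linspace(0, 1, ncat + 1), a=alpha, scale=1.0 / alpha)
    # E[X; a<X<b] for Gamma(alpha, scale) = mean * (F_{alpha+1}(b)-F_{alpha+1}(a))
    upper_cdf = stats.gamma.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = ncat * np.diff(upper_cdf)
    return rates / rates.mean()  # exact unit mean despite ppf round-off


def ucln_branch_rates(
    mu: float, S: float, quantile_assignments: np.ndarray
) -> np.ndarray:
    """Per-branch rates of the UCLN clock from branch quantiles.

    Rates are lognormal with real-space mean ``mu`` and log-sd ``S``
    (log-mean ln(mu) - S^2/2); S = 0 collapses to the strict clock.
    """
    q = np.asarray(quantile_assignments, dtype=float)
    if ((q <= 0) | (q >= 1)).any():
        raise ValueError("quantiles must lie in (0, 1)")
    if S == 0.0:
        return np.full(q.shape, mu)
    return np.exp(np.log(mu) - S**2 / 2.0 + S * stats.norm.ppf(q))


# -- likelihood -------------------------------------------------------------


def _state_maps(matrix: CharacterMatrix) -> list[dict[int, int]]:
    """Per-character map from observed state codes to consecutive ranks.

    The Mk state space of each character is its set of observed states,
    so codes are recoded to 0..k-1 (gaps in the coding collapse).
    """
    maps: list[dict[int, int]] = []
    for j in range(matrix.n_chars):
        observed = set(matrix.data[:, j][matrix.data[:, j] >= 0].tolist())
        for (i, jj), states in matrix.ambiguities.items():
            if jj == j:
                observed.update(states)
        maps.append({int(s): rank for rank, s in enumerate(sorted(observed))})
    return maps


def _tip_masks(
    matrix: CharacterMatrix, labels: list[str | None], k_resolved: np.ndarray
) -> np.ndarray:
    """Bitmask of compatible states per (node, character); tips only."""
    n_nodes = len(labels)
    masks = np.zeros((n_nodes, matrix.n_chars), dtype=np.int32)
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    maps = _state_maps(matrix)
    for node_i, label in enumerate(labels):
        if label is None or label not in row_of:
            continue
        row = row_of[label]
        for j in range(matrix.n_chars):
            code = matrix.data[row, j]
            if code == MISSING:
                amb = matrix.ambiguities.get((row, j))
                if amb:
                    m = 0
                    for s_ in amb:
                        m |= 1 << maps[j][s_]
                    masks[node_i, j] = m
                else:
                    masks[node_i, j] = (1 << int(k_resolved[j])) - 1
            else:
                masks[node_i, j] = 1 << maps[j][int(code)]
    return masks


def tree_log_likelihood(
    tree: SampledTree,
    matrix: CharacterMatrix,
    model: MkModelConfig | None = None,
    clock: ClockModel | None = None,
) -> float:
    """Log-likelihood of ``matrix`` on ``tree`` by Felsenstein pruning.

    Characters are grouped by their resolved (observed) state count and
    pruned with uniform root frequencies 1/k; missing cells marginalize
    over all states; sampled ancestors contribute their observed state
    through a zero-length terminal branch.  Gamma rate categories are
    averaged with equal weight; the optional Mkv correction conditions
    each character on being variable.
    """
    model = model or MkModelConfig()
    clock = clock or ClockModel()
    arrays = tree.to_arrays()
    tip_labels = {lab for lab, t in zip(arrays.labels, arrays.is_tip) if t}
    missing_taxa = set(matrix.taxa) - tip_labels
    if missing_taxa:
        raise ValueError(f"taxa not on tree: {sorted(missing_taxa)}")
    durations = arrays.durations()
    rates = clock.branch_rates(len(durations))
    blen = durations * rates
    k_resolved = matrix.observed_state_counts()
    masks = _tip_masks(matrix, arrays.labels, k_resolved)
    gamma_rates = model.rates()
    total = 0.0
    for k in np.unique(k_resolved):
        cols = np.nonzero(k_resolved == k)[0]
        sub_masks = np.ascontiguousarray(masks[:, cols])
        per_cat = np.empty((len(gamma_rates), len(cols)))
        for ci, g in enumerate(gamma_rates):
            per_cat[ci] = prune_loglik(
                arrays.left, arrays.right, sub_masks, blen * g, int(k)
            )
        m = per_cat.max(axis=0)
        char_logl = m + np.log(
            np.mean(np.exp(per_cat - m), axis=0)
        )
        if model.ascertainment == "variable":
            char_logl = char_logl - _log_prob_variable(
                arrays, blen, gamma_rates, int(k)
            )
        bad = ~np.isfinite(char_logl)
        if bad.any():
            raise ArithmeticError(
                f"non-finite log-likelihood for character(s) "
                f"{cols[np.nonzero(bad)[0]].tolist()}"
            )
        total += float(char_logl.sum())
    return total


def _log_prob_variable(arrays, blen, gamma_rates, k: int) -> float:
    """log(1 - P(character constant)) for the Mkv correction."""
    n_nodes = len(arrays.left)
    masks = np.zeros((n_nodes, k), dtype=np.int32)
    for i in range(n_nodes):
        if arrays.is_tip[i]:
            for s in range(k):
                masks[i, s] = 1 << s
    per_cat = np.empty((len(gamma_rates), k))
    for ci, g in enumerate(gamma_rates):
        per_cat[ci] = prune_loglik(arrays.left, arrays.right, masks, blen * g, k)
    p_const = float(np.exp(per_cat).mean(axis=0).sum())
    if p_const >= 1.0:
        raise ArithmeticError("constant-pattern probability reached 1")
    return float(np.log1p(-p_const))
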