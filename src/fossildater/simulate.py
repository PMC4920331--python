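"""Forward simulation of FBD trees and Lewis-Mk character matrices.

The simulator runs the fossilized birth-death process forward in time
from the origin at age ``T`` to the present: lineages speciate at rate
lambda, go extinct at rate mu, and leave fossil samples as a Poisson
process with rate psi; every lineage alive at the present is sampled.
The complete tree is then pruned to the sampled taxa, with fossils that
have sampled descendants becoming sampled ancestors.

Synthetic datasets emulating the two empirical study systems (a
penguin-like matrix of ~55 taxa x 202 characters and a canid-like
matrix of ~125 taxa x 122 characters) are produced by
:func:`fixture_preset`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fossildater.fbd import FBDParams
from fossildater.morph import CharacterMatrix, ClockModel
from fossildater.trees import ExplosionError, Node, SampledTree

__all__ = [
    "AgeConstraint",
    "simulate_fbd_tree",
    "simulate_characters",
    "make_age_ranges",
    "fixture_preset",
]


@dataclass(frozen=True)
class AgeConstraint:
    """Stratigraphic age range [lower, upper] for one taxon, Myr."""

    taxon: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper:
            raise ValueError(
                f"invalid age range [{self.lower}, {self.upper}] for {self.taxon}"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def contains(self, age: float) -> bool:
        return self.lower <= age <= self.upper


# -- tree simulation --------------------------------------------------------


class _Lineage:
    __slots__ = ("parent", "fossil_ages")

    def __init__(self, parent: Node | None) -> None:
        self.parent = parent
        self.fossil_ages: list[float] = []


def _close_lineage(lin: _Lineage, terminal: Node) -> Node:
    """Insert fossil marker nodes between the lineage's parent and terminal.

    Returns the topmost node of the chain (to be attached to the parent).
    """
    top = terminal
    for age in sorted(lin.fossil_ages):  # youngest first, build upward
        marker = Node(age, kind="fossil_marker")
        marker.add_child(top)
        top = marker
    if lin.parent is not None:
        lin.parent.add_child(top)
    return top


def _prune(node: Node) -> Node | None:
    """Prune a complete-tree subtree to its sampled taxa (recursive)."""
    if node.kind == "extant":
        return node
    if node.kind == "dead":
        return None
    if node.kind == "fossil_marker":
        child = _prune(node.children[0]) if node.children else None
        fossil = Node(node.age, kind="fossil")
        if child is None:
            return fossil  # youngest sample on this path: a fossil tip
        # sampled ancestor: binarized attachment point with zero branch
        attach = Node(node.age, kind="internal")
        attach.add_child(fossil)
        attach.add_child(child)
        return attach
    kept = [c for c in (_prune(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    new = Node(node.age, kind="internal")
    for c in kept:
        new.add_child(c)
    return new


def _label(tree: SampledTree) -> None:
    ne = nf = 0
    for node in tree.postorder():
        if node.kind == "extant":
            ne += 1
            node.label = f"extant_{ne}"
        elif node.kind == "fossil" and node.is_tip:
            nf += 1
            node.label = f"fossil_{nf}"


def simulate_fbd_tree(
    params: FBDParams,
    rng: np.random.Generator,
    condition_on_survival: bool = True,
    lineage_cap: int = 10**5,
    max_tries: int = 10**6,
) -> SampledTree:
    """Simulate one sampled tree under the FBD process.

    With ``condition_on_survival`` the simulation is rejection-sampled
    until at least one extant lineage survives to the present.  Raises
    :class:`ExplosionError` if the number of concurrent lineages exceeds
    ``lineage_cap``.
    """
    lam, mu, psi = params.speciation, params.extinction, params.fossil_sampling
    total_rate = lam + mu + psi
    for _ in range(max_tries):
        # active lineages, each extending downward from `age` toward 0
        active: list[tuple[float, _Lineage]] = [(params.origin_T, _Lineage(None))]
        done: list[Node] = []
        root_top: Node | None = None

        def close(age: float, lin: _Lineage, kind: str) -> Node:
            terminal = Node(age, kind=kind)
            return _close_lineage(lin, terminal)

        while active:
            if len(active) > lineage_cap:
                raise ExplosionError(
                    f"simulation exceeded lineage cap {lineage_cap}"
                )
            age, lin = active.pop()
            t = age - rng.exponential(1.0 / total_rate)
            while t > 0 and rng.random() < psi / total_rate:
                lin.fossil_ages.append(t)
                t -= rng.exponential(1.0 / total_rate)
            if t <= 0:
                top = close(0.0, lin, "extant")
            elif rng.random() < lam / (lam + mu):
                birth = Node(t, kind="birth")
                top = _close_lineage(lin, birth)
                active.append((t, _Lineage(birth)))
                active.append((t, _Lineage(birth)))
            else:
                top = close(t, lin, "dead")
            if lin.parent is None:
                root_top = top
        assert root_top is not None
        pruned = _prune(root_top)
        tree = SampledTree(pruned, params.origin_T)
        if condition_on_survival and tree.n_extant < 1:
            continue
        _label(tree)
        return tree
    raise RuntimeError("no surviving simulation within max_tries")


# -- character simulation ---------------------------------------------------


def simulate_characters(
    tree: SampledTree,
    n_chars: int,
    state_counts: np.ndarray | int,
    clock: ClockModel,
    rng: np.random.Generator,
    gamma_alpha: float | None = None,
    missing_rate: float = 0.0,
) -> CharacterMatrix:
    """Evolve discrete characters along ``tree`` under the Lewis-Mk model.

    Each character has ``k`` states (scalar or per-character array), its
    root state drawn uniformly; branch lengths in expected changes are
    duration x branch rate x per-character site rate (a continuous
    Gamma(``gamma_alpha``, mean 1) multiplier when requested).  An
    optional ``missing_rate`` converts cells to "?" independently.
    """
    if np.isscalar(state_counts):
        ks = np.full(n_chars, int(state_counts))
    else:
        ks = np.asarray(state_counts, dtype=np.int64)
        if len(ks) != n_chars:
            raise ValueError("state_counts length must equal n_chars")
    if (ks < 2).any():
        raise ValueError("all state counts must be >= 2")
    nodes = list(tree.postorder())
    rates = clock.branch_rates(len(nodes))
    site_rates = (
        rng.gamma(gamma_alpha, 1.0 / gamma_alpha, size=n_chars)
        if gamma_alpha is not None
        else np.ones(n_chars)
    )
    states: dict[int, np.ndarray] = {}
    root = nodes[-1]
    states[id(root)] = rng.integers(0, ks, size=n_chars).astype(np.int8)
    # preorder walk: parents before children
    for idx in range(len(nodes) - 1, -1, -1):
        node = nodes[idx]
        parent_states = states[id(node)]
        for child in node.children:
            child_idx = nodes.index(child)
            dur = max(node.age - child.age, 0.0)
            b = dur * rates[child_idx] * site_rates
            child_states = parent_states.copy()
            for k in np.unique(ks):
                sel = ks == k
                p_change = (1.0 - np.exp(-k / (k - 1.0) * b[sel])) * (k - 1.0) / k
                flip = rng.random(sel.sum()) < p_change
                if flip.any():
                    idxs = np.nonzero(sel)[0][flip]
                    shift = rng.integers(1, k, size=len(idxs))
                    child_states[idxs] = (child_states[idxs] + shift) % k
            states[id(child)] = child_states
    tips = tree.tips()
    data = np.stack([states[id(t)] for t in tips])
    if missing_rate > 0.0:
        mask = rng.random(data.shape) < missing_rate
        data[mask] = -1
    return CharacterMatrix(
        taxa=[t.label for t in tips], data=data, state_counts=ks
    )


# -- age ranges -------------------------------------------------------------


def make_age_ranges(
    tree: SampledTree,
    half_width: float,
    rng: np.random.Generator | None = None,
    fractional: bool = False,
    jitter: bool = False,
) -> list[AgeConstraint]:
    """Stratigraphic-style intervals containing each fossil's true age.

    ``half_width`` is in Myr, or a fraction of the true age when
    ``fractional``.  With ``jitter`` the interval mid-point is offset
    uniformly (the interval still contains the true age); intervals are
    clipped at 0.
    """
    if half_width < 0:
        raise ValueError("half_width must be nonnegative")
    out = []
    for node in tree.fossil_tips():
        age = node.age
        h = half_width * age if fractional else half_width
        if jitter and h > 0:
            if rng is None:
                raise ValueError("jitter requires an rng")
            shift = rng.uniform(-h, h)
        else:
            shift = 0.0
        lower = max(age + shift - h, 0.0)
        upper = max(age + shift + h, age)
        lower = min(lower, age)
        out.append(AgeConstraint(node.label, lower, upper))
    return out


# -- dataset presets --------------------------------------------------------

#: FBD and clock settings emulating the two empirical study systems.
#: penguin_like: ~19 extant + ~36 fossil taxa over ~65 Myr, 202 characters
#: from binary to k=7 with >95% below 4 states.  canid_like: 9 extant +
#: ~116 fossil taxa over ~37 Myr, 122 characters from binary to k=5.
_PRESETS = {
    "penguin_like": dict(
        params=FBDParams(origin_T=65.0, d=0.045, r=0.5, s=0.65),
        n_chars=202,
        # state-count distribution: >95% of characters with k < 4
        k_values=(2, 3, 4, 5, 6, 7),
        k_weights=(0.70, 0.26, 0.013, 0.012, 0.008, 0.007),
        clock_rate=0.0179,  # per-Myr morphological clock
        extant_target=19,
        fossil_target=36,
    ),
    "canid_like": dict(
        params=FBDParams(origin_T=37.0, d=0.0594, r=0.5, s=0.93),
        n_chars=122,
        k_values=(2, 3, 4, 5),
        k_weights=(0.72, 0.24, 0.025, 0.015),
        clock_rate=0.0283,
        extant_target=9,
        fossil_target=116,
    ),
}


def _apportion_state_counts(
    k_values: tuple[int, ...],
    k_weights: tuple[float, ...],
    n_chars: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Deterministic per-k character counts (largest remainder), shuffled."""
    exact = np.asarray(k_weights) * n_chars
    counts = np.floor(exact).astype(int)
    order = np.argsort(-(exact - counts))
    for i in order[: n_chars - counts.sum()]:
        counts[i] += 1
    ks = np.repeat(np.asarray(k_values), counts)
    rng.shuffle(ks)
    return ks


def fixture_preset(
    name: str,
    rng: np.random.Generator,
    scale: float = 1.0,
    half_width: float = 2.5,
) -> tuple[SampledTree, CharacterMatrix, list[AgeConstraint]]:
    """Simulate a dataset emulating one of the two study systems.

    ``name`` is ``penguin_like`` or ``canid_like``.  Trees are
    rejection-sampled until taxon counts fall within +-20% of the target
    (the canid preset requires the extant count exactly).  ``scale``
    shrinks taxon and character targets proportionally for reduced test
    fixtures.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}")
    cfg = _PRESETS[name]
    params: FBDParams = cfg["params"]
    extant_target = max(int(round(cfg["extant_target"] * scale)), 2)
    fossil_target = max(int(round(cfg["fossil_target"] * scale)), 2)
    n_chars = max(int(round(cfg["n_chars"] * scale)), 10)
    exact_extant = name == "canid_like" and scale == 1.0
    for _ in range(20000):
        tree = simulate_fbd_tree(params, rng)
        ok_extant = (
            tree.n_extant == extant_target
            if exact_extant
            else abs(tree.n_extant - extant_target) <= 0.2 * extant_target
        )
        ok_fossil = abs(tree.n_fossils - fossil_target) <= 0.2 * fossil_target
        if ok_extant and ok_fossil:
            break
    else:
        raise RuntimeError(f"could not hit taxon targets for preset {name}")
    ks = _apportion_state_counts(
        cfg["k_values"], cfg["k_weights"], n_chars, rng
    )
    clock = ClockModel(kind="strict", mean=cfg["clock_rate"])
    matrix = simulate_characters(tree, n_chars, ks, clock, rng)
    ranges = make_age_ranges(tree, half_width=half_width)
    return tree, matrix, ranges
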