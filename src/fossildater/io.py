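"""Readers and writers for the formats the tool touches.

NEXUS (datatype standard, symbols "0123456789", missing "?", polymorphic
"{...}" as ambiguity), Newick time-trees with sampled ancestors as
zero-length terminal branches, tab-separated age-range tables (taxon,
lower, upper), BEAST-style tab-separated trace logs, 2-column density
curves, and the TOML run configuration.  Every output embeds the seed
and a configuration hash in comment headers.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from fossildater.fbd import (
    BROAD_2014_PRIOR,
    IMPLICIT_2016_PRIOR,
    Prior,
    PriorSpec,
)
from fossildater.mcmc import ChainConfig, TraceLog
from fossildater.morph import CharacterMatrix, MkModelConfig
from fossildater.simulate import AgeConstraint
from fossildater.trees import SampledTree

__all__ = [
    "RunConfig",
    "read_nexus_standard",
    "write_nexus_standard",
    "read_age_ranges",
    "write_age_ranges",
    "read_trace",
    "write_trace",
    "write_newick",
    "read_newick",
    "write_density_curve",
    "read_config",
]

_SYMBOLS = "0123456789"

PRIOR_PRESETS = {
    "implicit_2016": IMPLICIT_2016_PRIOR,
    "gavryushkina_2014": BROAD_2014_PRIOR,
}


@dataclass
class RunConfig:
    """Run configuration: model and prior presets plus chain settings."""

    model_preset: str = "mk1_strict"  # mk1_strict | mk_partitioned_ucln
    prior_preset: str = "implicit_2016"
    chain_length: int = 20000
    thinning: int = 20
    burnin_frac: float = 0.25
    seed: int = 1
    topology: str = "fixed"
    custom_priors: PriorSpec | None = None

    def __post_init__(self) -> None:
        if not self.chain_length >= self.thinning > 0:
            raise ValueError("need chain_length >= thinning > 0")
        if not 0.0 <= self.burnin_frac <= 0.9:
            raise ValueError("burnin_frac must be in [0, 0.9]")
        if self.model_preset not in ("mk1_strict", "mk_partitioned_ucln"):
            raise ValueError(f"unknown model preset {self.model_preset!r}")
        if self.topology != "fixed":
            raise ValueError("only fixed-topology runs are supported")

    def priors(self) -> PriorSpec:
        if self.prior_preset == "custom":
            if self.custom_priors is None:
                raise ValueError("custom prior preset needs [priors] tables")
            return self.custom_priors
        try:
            return PRIOR_PRESETS[self.prior_preset]
        except KeyError:
            raise ValueError(f"unknown prior preset {self.prior_preset!r}")

    def chain_config(self) -> ChainConfig:
        if self.model_preset == "mk_partitioned_ucln":
            return ChainConfig(
                n_iter=self.chain_length,
                thin=self.thinning,
                burnin_frac=self.burnin_frac,
                clock_kind="ucln",
                model=MkModelConfig(
                    partition="by_state_count", gamma_shape=0.5, gamma_ncat=4
                ),
            )
        return ChainConfig(
            n_iter=self.chain_length,
            thin=self.thinning,
            burnin_frac=self.burnin_frac,
            clock_kind="strict",
        )

    def hash(self) -> str:
        text = repr(sorted(self.__dict__.items(), key=lambda kv: kv[0]))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _provenance(seed: int | None, config: RunConfig | None) -> list[str]:
    lines = []
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config.hash()}")
    return lines


# -- NEXUS ------------------------------------------------------------------


def read_nexus_standard(path: str | Path) -> CharacterMatrix:
    """Read a NEXUS standard-datatype matrix into a CharacterMatrix.

    "?" cells become missing; polymorphic "{...}" cells are stored as
    ambiguity over the listed states.  The declared state count of each
    character is max(observed states, 2).
    """
    try:
        dm = dendropy.StandardCharacterMatrix.get(
            path=str(path), schema="nexus", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises various parse errors
        raise ValueError(f"malformed NEXUS file {path}: {exc}") from exc
    taxa = [t.label for t in dm]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxa in NEXUS file")
    n_chars = max(len(dm[t]) for t in dm)
    data = np.full((len(taxa), n_chars), -1, dtype=np.int8)
    ambiguities: dict[tuple[int, int], tuple[int, ...]] = {}
    for i, tax in enumerate(dm):
        for j, state in enumerate(dm[tax]):
            if state.state_denomination == 0:  # fundamental
                data[i, j] = int(state.symbol)
            elif state.symbol in ("?", "-") or state.member_states is None:
                continue
            else:
                members = tuple(
                    sorted(
                        int(s.symbol)
                        for s in state.member_states
                        if s.symbol in _SYMBOLS
                    )
                )
                if 0 < len(members) < 10:
                    ambiguities[(i, j)] = members
    ks = np.empty(n_chars, dtype=np.int64)
    for j in range(n_chars):
        observed = set(int(x) for x in data[:, j] if x >= 0)
        for (i, jj), mem in ambiguities.items():
            if jj == j:
                observed.update(mem)
        ks[j] = max(max(observed) + 1 if observed else 2, 2)
    return CharacterMatrix(
        taxa=taxa, data=data, state_counts=ks, ambiguities=ambiguities
    )


def write_nexus_standard(
    matrix: CharacterMatrix,
    path: str | Path,
    seed: int | None = None,
    config: RunConfig | None = None,
) -> None:
    """Write a CharacterMatrix as a NEXUS standard-datatype file."""
    lines = ["#NEXUS"]
    for p in _provenance(seed, config):
        lines.append(f"[{p[2:]}]")
    lines += [
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};",
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{_SYMBOLS}" MISSING=? GAP=-;',
        "MATRIX",
    ]
    for i, taxon in enumerate(matrix.taxa):
        cells = []
        for j in range(matrix.n_chars):
            code = matrix.data[i, j]
            if code >= 0:
                cells.append(str(int(code)))
            elif (i, j) in matrix.ambiguities:
                cells.append("{" + "".join(map(str, matrix.ambiguities[(i, j)])) + "}")
            else:
                cells.append("?")
        name = f"'{taxon}'" if " " in taxon else taxon
        lines.append(f"{name} {''.join(cells)}")
    lines += [";", "END;", ""]
    Path(path).write_text("\n".join(lines))


# -- age ranges -------------------------------------------------------------


def read_age_ranges(path: str | Path) -> list[AgeConstraint]:
    """Read a TSV of stratigraphic age ranges (taxon, lower, upper)."""
    out: list[AgeConstraint] = []
    seen: set[str] = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "taxon":
            continue
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 tab-separated columns")
        taxon, lo, hi = parts[0], float(parts[1]), float(parts[2])
        if taxon in seen:
            raise ValueError(f"{path}:{ln}: duplicate taxon {taxon!r}")
        seen.add(taxon)
        if lo > hi:
            raise ValueError(
                f"{path}:{ln}: lower {lo} exceeds upper {hi} for {taxon!r}"
            )
        out.append(AgeConstraint(taxon, lo, hi))
    return out


def write_age_ranges(
    constraints: list[AgeConstraint],
    path: str | Path,
    seed: int | None = None,
    config: RunConfig | None = None,
) -> None:
    lines = _provenance(seed, config)
    lines.append("taxon\tlower\tupper")
    for c in constraints:
        lines.append(f"{c.taxon}\t{c.lower:.17g}\t{c.upper:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- traces -----------------------------------------------------------------


def write_trace(
    trace: TraceLog,
    path: str | Path,
    seed: int | None = None,
    config: RunConfig | None = None,
) -> None:
    """Write a trace as a BEAST-style TSV log (17 significant digits)."""
    cols = list(trace.columns)
    lines = _provenance(seed, config)
    lines.append("\t".join(cols))
    n = len(trace)
    for i in range(n):
        lines.append(
            "\t".join(f"{trace.columns[c][i]:.17g}" for c in cols)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path, burnin_frac: float = 0.25) -> TraceLog:
    header: list[str] | None = None
    rows: list[list[float]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        if header is None:
            header = line.split("\t")
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ValueError(f"{path}:{ln}: ragged row")
        rows.append([float(x) for x in parts])
    if header is None:
        raise ValueError(f"{path}: no header row")
    arr = np.array(rows) if rows else np.empty((0, len(header)))
    return TraceLog(
        columns={c: arr[:, i] for i, c in enumerate(header)},
        acceptance={},
        burnin_frac=burnin_frac,
    )


# -- trees ------------------------------------------------------------------


def write_newick(tree: SampledTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def read_newick(path: str | Path, origin_T: float | None = None) -> SampledTree:
    """Read a Newick time-tree (branch lengths in Myr) as a SampledTree.

    Tip kinds are inferred from the resulting ages: age ~0 means extant,
    positive means fossil.  ``origin_T`` defaults to 1.05x the root age.
    """
    from fossildater.trees import Node

    dt = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    # depth from root, then convert to ages
    depth: dict = {}
    maxdepth = 0.0
    for nd in dt.preorder_node_iter():
        d = 0.0 if nd.parent_node is None else depth[nd.parent_node] + (
            nd.edge.length or 0.0
        )
        depth[nd] = d
        maxdepth = max(maxdepth, d)

    def convert(nd) -> Node:
        age = max(maxdepth - depth[nd], 0.0)
        if nd.is_leaf():
            kind = "extant" if age < 1e-9 else "fossil"
            node = Node(age, kind=kind, label=nd.taxon.label if nd.taxon else None)
        else:
            node = Node(age, kind="internal")
            for c in nd.child_nodes():
                node.add_child(convert(c))
        return node

    root = convert(dt.seed_node)
    T = origin_T if origin_T is not None else maxdepth * 1.05
    return SampledTree(root, T)


# -- density curves ----------------------------------------------------------


def write_density_curve(
    ages: np.ndarray,
    density: np.ndarray,
    path: str | Path,
    seed: int | None = None,
    config: RunConfig | None = None,
) -> None:
    lines = _provenance(seed, config)
    lines.append("age_Myr\tdensity")
    for a, d in zip(ages, density):
        lines.append(f"{a:.17g}\t{d:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- config ------------------------------------------------------------------


def _prior_from_table(tab: dict) -> Prior:
    return Prior(tab["family"], tuple(float(x) for x in tab["params"]))


def read_config(path: str | Path) -> RunConfig:
    """Read a TOML run configuration.

    Recognized keys: model_preset, prior_preset, chain_length, thinning,
    burnin_frac, seed, topology, and an optional [priors] section with
    per-parameter family/params tables plus implicit_T/implicit_s flags.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    priors_tab = raw.pop("priors", None)
    custom = None
    if priors_tab is not None:
        kwargs = {}
        for key in ("d", "r", "s_or_psi", "T_or_N", "clock_mean",
                    "clock_log_sd", "gamma_shape"):
            if key in priors_tab:
                kwargs[key] = _prior_from_table(priors_tab[key])
        for key in ("implicit_T", "implicit_s"):
            if key in priors_tab:
                kwargs[key] = bool(priors_tab[key])
        custom = PriorSpec(**kwargs)
    allowed = {
        "model_preset", "prior_preset", "chain_length", "thinning",
        "burnin_frac", "seed", "topology",
    }
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(custom_priors=custom, **raw)
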