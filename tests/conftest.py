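"""Shared fixtures: hand-built trees and reduced simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from fossildater.fbd import FBDParams
from fossildater.simulate import fixture_preset, simulate_fbd_tree
from fossildater.trees import Node, SampledTree


@pytest.fixture
def rng():
    return np.random.default_rng(20160719)


@pytest.fixture
def std_params():
    """The reference parameter set used throughout the density checks."""
    return FBDParams(origin_T=40.0, d=0.05, r=0.5, s=0.2)


def build_three_taxon_tree() -> SampledTree:
    """((fossil_1:2, extant_1:6)v:4, extant_2:10)root, origin 12.

    One fossil tip at age 2 attached at age 6; root at age 10.
    """
    root = Node(10.0, "internal")
    v = Node(6.0, "internal")
    f = Node(2.0, "fossil", "fossil_1")
    a = Node(0.0, "extant", "extant_1")
    b = Node(0.0, "extant", "extant_2")
    v.add_child(f)
    v.add_child(a)
    root.add_child(v)
    root.add_child(b)
    return SampledTree(root, 12.0)


def build_sampled_ancestor_tree() -> SampledTree:
    """Same shape but the fossil is a sampled ancestor (age = attachment)."""
    tree = build_three_taxon_tree()
    f = tree.find("fossil_1")
    f.age = f.parent.age
    return tree


@pytest.fixture
def three_taxon_tree():
    return build_three_taxon_tree()


@pytest.fixture
def sa_tree():
    return build_sampled_ancestor_tree()


@pytest.fixture(scope="session")
def penguin_small():
    """Reduced penguin-like dataset shared across read-only tests."""
    rng = np.random.default_rng(7)
    return fixture_preset("penguin_like", rng, scale=0.4)


def random_fossil_tree(
    params: FBDParams, rng, min_fossils=1, min_extant=1, max_tips=None
):
    """A surviving FBD simulation with at least the requested samples."""
    while True:
        tree = simulate_fbd_tree(params, rng)
        if tree.n_fossils >= min_fossils and tree.n_extant >= min_extant:
            if max_tips is None or tree.n_fossils + tree.n_extant <= max_tips:
                return tree
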