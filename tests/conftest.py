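"""Shared fixtures: synthetic complexes and brute-force helpers."""

from __future__ import annotations

import numpy as np
import pytest

from gnmiface import (
    CalphaTrace,
    Node,
    build_kirchhoff,
    correlation_map,
    decompose,
    generate_fixture,
    partition_subunits,
)


def random_walk_trace(
    rng: np.random.Generator,
    n_per_chain: tuple[int, ...] = (20,),
    step: float = 3.8,
    chain_offset: float = 5.0,
) -> CalphaTrace:
    """Random C-alpha walk(s): consecutive residues exactly ``step`` apart.

    Consecutive residues of a chain are always in contact at the 7 A
    cutoff, so each chain's contact graph is connected by construction;
    whether different chains connect depends on the random geometry.
    """
    nodes = []
    origin = np.zeros(3)
    for ci, n in enumerate(n_per_chain):
        chain = chr(ord("A") + ci)
        pos = origin.copy()
        for i in range(n):
            nodes.append(Node(chain, i + 1, " ", "GLY", tuple(pos)))
            direction = rng.normal(size=3)
            pos = pos + step * direction / np.linalg.norm(direction)
        origin = origin + np.array([chain_offset, 0.0, 0.0])
    return CalphaTrace.from_nodes(nodes, source_id="random_walk")


def brute_force_contacts(coords: np.ndarray, cutoff: float = 7.0) -> np.ndarray:
    """O(N^2) loop-based contact matrix, independent of the library path."""
    n = len(coords)
    contact = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.sqrt(sum((coords[i][k] - coords[j][k]) ** 2 for k in range(3)))
            contact[i, j] = d <= cutoff
    return contact


@pytest.fixture(scope="session")
def dumbbell():
    return generate_fixture("dumbbell_dimer", seed=1)


@pytest.fixture(scope="session")
def intertwined():
    return generate_fixture("intertwined_dimer", seed=1)


@pytest.fixture(scope="session")
def anchor_toy():
    return generate_fixture("anchor_toy", seed=1)


@pytest.fixture(scope="session")
def anchor_toy_pipeline(anchor_toy):
    """Trace, partition, spectrum and normalized all/slow maps of the toy."""
    part = partition_subunits(anchor_toy)
    spectrum = decompose(build_kirchhoff(anchor_toy))
    return {
        "trace": anchor_toy,
        "partition": part,
        "spectrum": spectrum,
        "all": correlation_map(spectrum, "all"),
        "slow10": correlation_map(spectrum, "slowest_10"),
    }


@pytest.fixture(scope="session")
def dumbbell_pipeline(dumbbell):
    part = partition_subunits(dumbbell)
    spectrum = decompose(build_kirchhoff(dumbbell))
    return {
        "trace": dumbbell,
        "partition": part,
        "spectrum": spectrum,
        "all": correlation_map(spectrum, "all"),
    }
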