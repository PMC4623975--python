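"""Coarse-grained structure model: C-alpha traces, subunit partitions, fixtures.

A complex is reduced to one node per residue at its C-alpha position, which is
all the elastic-network machinery downstream needs.  Residue identity keeps the
author's numbering plus insertion code, because hinge and anchor reports are
keyed that way (e.g. ``A:HIS328``); nothing is ever renumbered.

Sequence adjacency means *consecutive observed residues within a chain*, even
across numbering gaps left by unresolved residues: the model only ever sees the
modeled trace.
"""

from __future__ import annotations

import io
import math
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptyStructure,
    FetchError,
    FixtureError,
    ParseError,
    PartitionError,
)

__all__ = [
    "Node",
    "CalphaTrace",
    "SubunitPartition",
    "read_structure",
    "write_pdb",
    "fetch_structure",
    "partition_subunits",
    "concat_traces",
    "generate_fixture",
    "FIXTURE_KINDS",
]

#: Distance between consecutive residues in synthetic chains (virtual
#: C-alpha--C-alpha bond length), in Angstrom.
CA_SPACING = 3.8


class Node(NamedTuple):
    """One residue of a coarse-grained trace."""

    chain_id: str
    res_seq: int
    icode: str  # one character, " " when absent
    res_name: str
    coord: tuple[float, float, float]

    @property
    def label(self) -> str:
        """Human-readable residue key, e.g. ``A:HIS328`` or ``B:GLY52A``."""
        ic = self.icode.strip()
        return f"{self.chain_id}:{self.res_name}{self.res_seq}{ic}"


@dataclass(frozen=True)
class CalphaTrace:
    """Ordered C-alpha trace of a (possibly multi-chain) structure.

    Nodes appear in file order and are chain-contiguous.  The
    ``(chain_id, res_seq, icode)`` triples are unique and all coordinates
    are finite; both are enforced at construction.
    """

    chain_ids: tuple[str, ...]
    res_seqs: tuple[int, ...]
    icodes: tuple[str, ...]
    res_names: tuple[str, ...]
    coords: np.ndarray  # (N, 3) float64
    source_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.chain_ids)
        if not (n == len(self.res_seqs) == len(self.icodes) == len(self.res_names)):
            raise ValueError("field lengths disagree")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (n, 3):
            raise ValueError(f"coords shape {coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "coords", coords)
        keys = set(zip(self.chain_ids, self.res_seqs, self.icodes))
        if len(keys) != n:
            raise ValueError("duplicate (chain, res_seq, icode) residue keys")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_nodes(cls, nodes: Iterable[Node], source_id: str = "") -> "CalphaTrace":
        nodes = list(nodes)
        return cls(
            chain_ids=tuple(n.chain_id for n in nodes),
            res_seqs=tuple(n.res_seq for n in nodes),
            icodes=tuple(n.icode for n in nodes),
            res_names=tuple(n.res_name for n in nodes),
            coords=np.array([n.coord for n in nodes], dtype=float).reshape(-1, 3),
            source_id=source_id,
        )

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.chain_ids)

    def __iter__(self) -> Iterator[Node]:
        return iter(self.nodes)

    @property
    def nodes(self) -> list[Node]:
        return [
            Node(c, s, i, r, (x, y, z))
            for c, s, i, r, (x, y, z) in zip(
                self.chain_ids, self.res_seqs, self.icodes, self.res_names, self.coords
            )
        ]

    @property
    def chains(self) -> tuple[str, ...]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return tuple(seen)

    def chain_indices(self, chain_id: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.chain_ids) == chain_id)

    def chain_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for c in self.chain_ids:
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def label(self, i: int) -> str:
        return self.nodes[i].label


@dataclass(frozen=True)
class SubunitPartition:
    """Assignment of every chain to one of the two interacting subunits.

    A subunit is an interacting partner unit: a single chain or several
    chains acting as one side of the interface.
    """

    subunit_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.subunit_of.values()) != {1, 2}:
            raise PartitionError("both subunits must contain at least one chain")

    def chains_of(self, subunit: int) -> tuple[str, ...]:
        return tuple(c for c, s in self.subunit_of.items() if s == subunit)

    def indices(self, trace: CalphaTrace) -> tuple[np.ndarray, np.ndarray]:
        """Node indices of subunit 1 and subunit 2 in trace order."""
        labels = np.array([self.subunit_of.get(c, 0) for c in trace.chain_ids])
        return np.flatnonzero(labels == 1), np.flatnonzero(labels == 2)

    def subunit_sizes(self, trace: CalphaTrace) -> tuple[int, int]:
        i1, i2 = self.indices(trace)
        return len(i1), len(i2)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def _validate_coordinate_fields(pdb_text: str) -> None:
    """Reject ATOM/HETATM records whose x/y/z columns are not numeric.

    The underlying reader is lenient and would silently zero-fill bad
    fields; a malformed coordinate must surface as a hard error instead.
    """
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line.rstrip()) < 54:
            raise ParseError(f"line {lineno}: truncated coordinate record")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            field_ = line[lo:hi]
            try:
                float(field_)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: malformed {what} coordinate {field_!r}"
                ) from None


def read_structure(
    pdb_text: str,
    model_index: int = 0,
    altloc_policy: str = "occupancy",
) -> CalphaTrace:
    """Parse PDB-format text into a :class:`CalphaTrace`.

    One node is produced per residue that has a C-alpha atom (atom name
    ``CA`` and element carbon, so calcium ions are never picked up).
    Waters and residues without a C-alpha are skipped; non-standard
    residues with a C-alpha are retained, since the elastic network is
    chemistry-agnostic.

    Parameters
    ----------
    pdb_text:
        Content of a PDB-format file.
    model_index:
        Which model of a multi-model (e.g. NMR) file to use; default the
        first.
    altloc_policy:
        ``"occupancy"`` (default) resolves alternate locations to the
        highest-occupancy C-alpha, ties broken by file order;
        ``"first"`` always takes the first C-alpha encountered.
    """
    if altloc_policy not in ("occupancy", "first"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    _validate_coordinate_fields(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse PDB text: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructure("no models in input")
    if not 0 <= model_index < len(st):
        raise ParseError(
            f"model_index {model_index} out of range (file has {len(st)} models)"
        )
    model = st[model_index]

    nodes: list[Node] = []
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES or res.is_water():
                continue
            cas = [
                a
                for a in res
                if a.name == "CA" and (a.element.name in ("C", "X") or not a.element.name)
            ]
            if not cas:
                continue
            if altloc_policy == "occupancy":
                best = max(cas, key=lambda a: a.occ)  # max() keeps first on ties
            else:
                best = cas[0]
            icode = res.seqid.icode if res.seqid.icode.strip() else " "
            nodes.append(
                Node(
                    chain_id=chain.name,
                    res_seq=res.seqid.num,
                    icode=icode,
                    res_name=res.name,
                    coord=(best.pos.x, best.pos.y, best.pos.z),
                )
            )
    if not nodes:
        raise EmptyStructure("no C-alpha atoms in the requested model")
    name = st.name if st.name and st.name != "string" else ""
    try:
        return CalphaTrace.from_nodes(nodes, source_id=name)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def write_pdb(trace: CalphaTrace, bfactors: Sequence[float] | None = None) -> str:
    """Render a trace as PDB-format text (one ``ATOM`` C-alpha per residue).

    ``bfactors`` optionally fills the B-factor column, e.g. with a dynamic
    domain label or an anchor flag for visualization in any molecular
    viewer.
    """
    if bfactors is not None and len(bfactors) != len(trace):
        raise ValueError("bfactors length must match trace length")
    out = io.StringIO()
    serial = 0
    prev_chain: str | None = None
    for i, node in enumerate(trace.nodes):
        if prev_chain is not None and node.chain_id != prev_chain:
            out.write("TER\n")
        prev_chain = node.chain_id
        serial += 1
        b = 0.0 if bfactors is None else float(bfactors[i])
        x, y, z = node.coord
        out.write(
            f"ATOM  {serial:5d}  CA  {node.res_name:>3s} {node.chain_id:1s}"
            f"{node.res_seq:4d}{node.icode:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}"
            f"           C  \n"
        )
    out.write("TER\nEND\n")
    return out.getvalue()


_RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def fetch_structure(
    pdb_id: str,
    cache_dir: str | Path | None = None,
    timeout: float = 20.0,
    **read_kwargs,
) -> CalphaTrace:
    """Load a structure by 4-character PDB identifier.

    A local cache directory, when given, is consulted first and populated
    after a successful download; with a warm cache no network access
    happens at all.
    """
    pdb_id = pdb_id.strip().lower()
    if len(pdb_id) != 4:
        raise ValueError(f"not a 4-character PDB id: {pdb_id!r}")
    text: str | None = None
    cache_file: Path | None = None
    if cache_dir is not None:
        cache_file = Path(cache_dir) / f"{pdb_id}.pdb"
        if cache_file.is_file():
            text = cache_file.read_text()
    if text is None:
        url = _RCSB_URL.format(pdb_id=pdb_id.upper())
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                text = resp.read().decode("utf-8", errors="replace")
        except (urllib.error.URLError, OSError, TimeoutError) as exc:
            raise FetchError(f"could not fetch {pdb_id!r} from {url}: {exc}") from exc
        if cache_file is not None:
            cache_file.parent.mkdir(parents=True, exist_ok=True)
            cache_file.write_text(text)
    trace = read_structure(text, **read_kwargs)
    return CalphaTrace(
        trace.chain_ids,
        trace.res_seqs,
        trace.icodes,
        trace.res_names,
        trace.coords,
        source_id=pdb_id,
    )


# ---------------------------------------------------------------------------
# Subunit partition
# ---------------------------------------------------------------------------


def partition_subunits(trace: CalphaTrace, spec: str = "") -> SubunitPartition:
    """Build the two-subunit partition from a chain spec like ``"A:B"``.

    ``"AB:C"`` puts chains A and B into subunit 1 and C into subunit 2.
    An empty spec is allowed only for a two-chain trace, where each chain
    becomes its own subunit.
    """
    present = set(trace.chains)
    spec = spec.strip()
    if not spec:
        if len(present) != 2:
            raise PartitionError(
                f"trace has {len(present)} chains; an explicit partition "
                "spec like 'AB:C' is required unless there are exactly two"
            )
        c1, c2 = trace.chains
        return SubunitPartition({c1: 1, c2: 2})
    parts = spec.split(":")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise PartitionError(f"partition spec must be '<chains>:<chains>', got {spec!r}")
    mapping: dict[str, int] = {}
    for side, chains in zip((1, 2), parts):
        for ch in chains.replace(",", ""):
            if ch.isspace():
                continue
            if ch not in present:
                raise PartitionError(f"chain {ch!r} not present in trace")
            if ch in mapping and mapping[ch] != side:
                raise PartitionError(f"chain {ch!r} assigned to both subunits")
            mapping[ch] = side
    missing = present - set(mapping)
    if missing:
        raise PartitionError(f"chains {sorted(missing)} not assigned to a subunit")
    return SubunitPartition(mapping)


def concat_traces(traces: Sequence[CalphaTrace], source_id: str = "") -> CalphaTrace:
    """Concatenate traces with disjoint chain identifiers into one complex."""
    nodes: list[Node] = []
    for t in traces:
        nodes.extend(t.nodes)
    return CalphaTrace.from_nodes(nodes, source_id=source_id)


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("linear_chain", "dumbbell_dimer", "intertwined_dimer", "anchor_toy")

_MIN_SEPARATION = 0.5  # Angstrom; coordinates closer than this are "coincident"

_AA20 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split()
)


def _res_names(n: int) -> list[str]:
    return [_AA20[i % len(_AA20)] for i in range(n)]


def _make_trace(chains: dict[str, np.ndarray], source_id: str) -> CalphaTrace:
    nodes: list[Node] = []
    for chain_id, coords in chains.items():
        names = _res_names(len(coords))
        for i, (xyz, name) in enumerate(zip(coords, names)):
            nodes.append(Node(chain_id, i + 1, " ", name, tuple(float(v) for v in xyz)))
    trace = CalphaTrace.from_nodes(nodes, source_id=source_id)
    # reject geometries with (near-)coincident nodes
    d = trace.coords[:, None, :] - trace.coords[None, :, :]
    dist = np.sqrt((d**2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    if dist.min() < _MIN_SEPARATION:
        raise FixtureError(
            f"fixture has coincident coordinates (min pair distance {dist.min():.2f} A)"
        )
    return trace


def _snake_ball(n: int, spacing: float) -> np.ndarray:
    """n grid points filling a ball, ordered so consecutive points are close."""
    r = 1
    while (2 * r + 1) ** 3 < 4 * n:
        r += 1
    pts = []
    for iz in range(-r, r + 1):
        ys = range(-r, r + 1) if iz % 2 == 0 else range(r, -r - 1, -1)
        for iy in ys:
            xs = range(-r, r + 1) if iy % 2 == 0 else range(r, -r - 1, -1)
            for ix in xs:
                pts.append((ix, iy, iz))
    pts = np.array(pts, dtype=float)
    # keep the n points closest to the center, preserving snake order
    norms = (pts**2).sum(1)
    cutoff = np.sort(norms)[n - 1]
    kept = pts[norms <= cutoff][:n]
    return kept * spacing


def _linear_chain(n: int, spacing: float) -> dict[str, np.ndarray]:
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    return {"A": coords}


def _chain_dumbbell(
    n_cluster: int, n_linker: int, spacing: float, rng: np.random.Generator, jitter: float
) -> np.ndarray:
    """One chain: dense cluster -- thin linker -- dense cluster, along x."""
    ball = _snake_ball(n_cluster, spacing)
    ball = ball + rng.normal(0.0, jitter, ball.shape)
    half_span = (n_linker + 1) * spacing / 2.0 + abs(ball[:, 0]).max()
    left = ball + np.array([-half_span, 0.0, 0.0])
    right = ball[::-1] + np.array([half_span, 0.0, 0.0])
    xs = (np.arange(n_linker) - (n_linker - 1) / 2.0) * spacing
    linker = np.column_stack([xs, np.zeros(n_linker), np.zeros(n_linker)])
    return np.vstack([left, linker, right])


def _dumbbell_dimer(
    n_cluster: int,
    n_linker: int,
    spacing: float,
    chain_gap: float,
    rng: np.random.Generator,
    jitter: float,
) -> dict[str, np.ndarray]:
    a = _chain_dumbbell(n_cluster, n_linker, spacing, rng, jitter)
    # B is the image of A under the involution (x, y, z) -> (-x, gap - y, z),
    # so swapping the chains maps the complex exactly onto itself.
    b = a.copy()
    b[:, 0] *= -1.0
    b[:, 1] = chain_gap - a[:, 1]
    return {"A": a, "B": b}


def _intertwined_dimer(
    n_cluster: int,
    n_linker: int,
    spacing: float,
    chain_gap: float,
    rng: np.random.Generator,
    jitter: float,
) -> dict[str, np.ndarray]:
    a = _chain_dumbbell(n_cluster, n_linker, spacing, rng, jitter)
    b = a + np.array([0.0, chain_gap, 0.0])  # parallel copy: both lobes mix chains
    return {"A": a, "B": b}


def _anchor_toy(
    n_body_a: int,
    n_body_b: int,
    anchor_len: int,
    spacing: float,
    rng: np.random.Generator,
    jitter: float,
) -> dict[str, np.ndarray]:
    """Globular chain A with chain B's protruding N-terminal segment buried in it.

    Chain B is built tip-first: residues ``1..anchor_len`` are the protruding
    anchor segment (deepest first), followed by a thin stalk and B's own body,
    which sits well clear of A.
    """
    ball_a = _snake_ball(n_body_a, spacing) + rng.normal(0.0, jitter, (n_body_a, 3))
    r_a = np.sqrt((ball_a**2).sum(1)).max()
    # anchor line along +x, starting inside the A ball and emerging from it
    tip_x = max(r_a - (anchor_len - 1) * spacing, 0.4)
    anchor = np.column_stack(
        [tip_x + spacing * np.arange(anchor_len), np.zeros(anchor_len), np.zeros(anchor_len)]
    )
    # carve a channel in A so the anchor is surrounded, not overlapped
    keep = np.ones(len(ball_a), dtype=bool)
    for p in anchor:
        keep &= np.sqrt(((ball_a - p) ** 2).sum(1)) > 2.6
    ball_a = ball_a[keep]
    stalk_n = 3
    stalk = anchor[-1] + np.column_stack(
        [spacing * np.arange(1, stalk_n + 1), np.zeros(stalk_n), np.zeros(stalk_n)]
    )
    ball_b = _snake_ball(n_body_b, spacing) + rng.normal(0.0, jitter, (n_body_b, 3))
    # keep the body within one grid step of the stalk end so the chain-B
    # subgraph stays connected regardless of jitter
    ball_b = ball_b + np.array(
        [stalk[-1, 0] + spacing - ball_b[:, 0].min(), 0.0, 0.0]
    )
    return {"A": ball_a, "B": np.vstack([anchor, stalk, ball_b])}


def generate_fixture(kind: str, params: dict | None = None, seed: int = 0) -> CalphaTrace:
    """Deterministically generate a synthetic C-alpha trace.

    These toys stand in for downloaded structures in tests: a single
    ``linear_chain``; a ``dumbbell_dimer`` whose chains each consist of two
    dense clusters joined by a thin linker, mirror-symmetric across the
    dimer axis so the slowest mode separates the two spatial lobes; an
    ``intertwined_dimer`` whose contact graph mixes the chains inside each
    lobe (the obligatory-like topology); and an ``anchor_toy`` in which a
    protruding segment of chain B is buried in chain A contacts (the
    non-obligatory-like anchor-and-groove topology).

    Output is bit-reproducible given ``(kind, params, seed)``.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    spacing = float(p.pop("spacing", CA_SPACING))
    jitter = float(p.pop("jitter", 0.25))
    if kind == "linear_chain":
        n = int(p.pop("n", 10))
        if n < 2:
            raise FixtureError("linear_chain needs n >= 2")
        chains = _linear_chain(n, spacing)
    elif kind in ("dumbbell_dimer", "intertwined_dimer"):
        n_cluster = int(p.pop("n_cluster", 12))
        n_linker = int(p.pop("n_linker", 4))
        chain_gap = float(p.pop("chain_gap", 5.7))
        if n_cluster < 2 or n_linker < 1:
            raise FixtureError("dumbbell needs n_cluster >= 2 and n_linker >= 1")
        builder = _dumbbell_dimer if kind == "dumbbell_dimer" else _intertwined_dimer
        chains = builder(n_cluster, n_linker, spacing, chain_gap, rng, jitter)
    elif kind == "anchor_toy":
        n_body_a = int(p.pop("n_body_a", 48))
        n_body_b = int(p.pop("n_body_b", 20))
        anchor_len = int(p.pop("anchor_len", 4))
        if anchor_len < 2 or n_body_a < 8 or n_body_b < 2:
            raise FixtureError("anchor_toy sizes too small")
        chains = _anchor_toy(n_body_a, n_body_b, anchor_len, spacing, rng, jitter)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    if p:
        raise ValueError(f"unknown fixture params {sorted(p)}")
    return _make_trace(chains, source_id=f"{kind}(seed={seed})")
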