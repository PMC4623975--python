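"""Dynamic domains, hinges, anchors and anchoring grooves.

A single mode's eigenvector splits the structure into *dynamic domains*:
clusters of residues that move collectively in one direction (uniform
eigenvector sign).  A *hinge* sits where the sign changes between
sequence-adjacent residues of a chain; the hinges mark the interfaces
between dynamic domains.  In obligatory complexes the dynamic domains
typically mix segments of both chains and the hinges avoid the subunit
interface; in non-obligatory complexes each subunit tends to be its own
dynamic domain, coupled through a few *anchor* residues that correlate more
strongly with the partner subunit than with their own, each facing an
*anchoring groove* -- the partner residues most correlated with the anchor
in the all-modes map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ModeSetError
from .gnm import CorrelationMap, ModeSpectrum
from .structure import CalphaTrace, SubunitPartition

__all__ = [
    "DomainAssignment",
    "HingeSite",
    "AnchorSet",
    "assign_domains",
    "detect_hinges",
    "find_anchors",
    "groove_of",
]

logger = logging.getLogger(__name__)

PLUS, MINUS, NEAR_ZERO = "plus", "minus", "near_zero"


@dataclass(frozen=True)
class DomainAssignment:
    """Per-residue motion labels for one internal mode.

    ``labels[i]`` is ``"plus"``/``"minus"`` by the sign of the mode
    eigenvector component at residue ``i``, or ``"near_zero"`` when the
    component's magnitude is below ``sign_tol``.
    """

    labels: tuple[str, ...]
    mode_index: int  # 1-based over nonzero modes
    sign_tol: float

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class HingeSite:
    """A sign change between consecutive observed residues of one chain.

    ``res_a``/``res_b`` are (res_seq, icode, res_name) of the two signed
    residues flanking the change; they are sequence-adjacent unless
    near-zero residues intervene (those are transparent).
    """

    chain_id: str
    res_a: tuple[int, str, str]
    res_b: tuple[int, str, str]

    @property
    def label(self) -> str:
        (sa, ia, na), (sb, ib, nb) = self.res_a, self.res_b
        return f"{self.chain_id}:{na}{sa}{ia.strip()}/{nb}{sb}{ib.strip()}"


@dataclass(frozen=True)
class AnchorSet:
    """Anchors, their grooves, and the associating-regions ratio AR.

    ``anchors`` holds node indices (into the trace) of residues that
    correlate more strongly with the juxtaposed subunit than with their
    own; ``grooves[i]`` lists, for anchor ``anchors[i]``, up to three
    partner-subunit node indices with the highest all-modes correlations,
    descending.  ``ar`` is the number of anchors from both subunits over
    the total residue count of the complex.
    """

    anchors: tuple[int, ...]
    subunit_of_anchor: tuple[int, ...]
    grooves: tuple[tuple[int, ...], ...]
    ar: float

    def __len__(self) -> int:
        return len(self.anchors)


# ---------------------------------------------------------------------------


def assign_domains(
    spectrum: ModeSpectrum,
    mode_index: int,
    sign_tol: float | None = None,
) -> DomainAssignment:
    """Label residues plus/minus/near-zero by one mode's eigenvector signs.

    ``mode_index`` is 1-based over internal modes (1 = slowest nonzero).
    ``sign_tol`` defaults to ``1e-6 * max|u|``, scale-aware so that clean
    synthetic eigenvectors are labeled exactly.
    """
    u = spectrum.mode(mode_index)  # raises ModeSetError when out of range
    if sign_tol is None:
        sign_tol = 1e-6 * float(np.abs(u).max())
    if sign_tol < 0:
        raise ValueError("sign_tol must be non-negative")
    labels = np.full(len(u), NEAR_ZERO, dtype=object)
    labels[u > sign_tol] = PLUS
    labels[u < -sign_tol] = MINUS
    return DomainAssignment(
        labels=tuple(labels), mode_index=mode_index, sign_tol=float(sign_tol)
    )


def detect_hinges(assignment: DomainAssignment, trace: CalphaTrace) -> list[HingeSite]:
    """Hinges: opposite-sign consecutive residues within each chain.

    Consecutive means consecutive *observed* residues (numbering gaps from
    unresolved residues are crossed silently).  Near-zero residues are
    transparent: a run of them between opposite signs yields exactly one
    hinge, reported between the two flanking signed residues.
    """
    if len(assignment) != len(trace):
        raise ValueError("assignment and trace lengths disagree")
    hinges: list[HingeSite] = []
    last_signed: int | None = None  # node index of last signed residue in chain
    prev_chain: str | None = None
    for i, lab in enumerate(assignment.labels):
        chain = trace.chain_ids[i]
        if chain != prev_chain:
            prev_chain = chain
            last_signed = None
        if lab == NEAR_ZERO:
            continue
        if last_signed is not None and assignment.labels[last_signed] != lab:
            a, b = trace.nodes[last_signed], trace.nodes[i]
            hinges.append(
                HingeSite(
                    chain_id=chain,
                    res_a=(a.res_seq, a.icode, a.res_name),
                    res_b=(b.res_seq, b.icode, b.res_name),
                )
            )
        last_signed = i
    return hinges


def _anchor_mask(
    c: np.ndarray, idx1: np.ndarray, idx2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean anchor masks for subunit-1 and subunit-2 residues.

    Residue i of one subunit is an anchor iff its mean correlation with the
    other subunit exceeds its mean correlation with the rest of its own
    subunit (self excluded).  A single-residue subunit has no own-subunit
    partners; its own mean is defined as 0, so the criterion degenerates to
    "positively correlated with the partner on average".
    """
    masks = []
    for own, other in ((idx1, idx2), (idx2, idx1)):
        other_mean = c[np.ix_(own, other)].mean(axis=1)
        if len(own) > 1:
            own_mean = (c[np.ix_(own, own)].sum(axis=1) - 1.0) / (len(own) - 1)
        else:
            logger.warning(
                "single-residue subunit: own-subunit mean defined as 0 for its residue"
            )
            own_mean = np.zeros(1)
        masks.append(other_mean > own_mean)
    return masks[0], masks[1]


def find_anchors(
    all_modes_map: CorrelationMap,
    partition: SubunitPartition,
    trace: CalphaTrace,
) -> AnchorSet:
    """Anchors, grooves and AR from the normalized all-modes map.

    The anchor statistic is the arithmetic mean of normalized correlations:
    own-subunit mean (self excluded) versus juxtaposed-subunit mean.  AR is
    the count of anchors from both subunits divided by the residue count of
    the whole complex, in [0, 1].
    """
    if all_modes_map.normalized is None:
        raise ValueError("normalized all-modes map required; call normalize() first")
    c = all_modes_map.normalized
    if c.shape[0] != len(trace):
        raise ValueError("map and trace sizes disagree")
    idx1, idx2 = partition.indices(trace)
    m1, m2 = _anchor_mask(c, idx1, idx2)
    anchors: list[int] = []
    subunits: list[int] = []
    for own_idx, mask, su in ((idx1, m1, 1), (idx2, m2, 2)):
        for i in own_idx[mask]:
            anchors.append(int(i))
            subunits.append(su)
    order = np.argsort(anchors, kind="stable")  # trace order
    anchors = [anchors[k] for k in order]
    subunits = [subunits[k] for k in order]
    grooves = tuple(
        tuple(groove_of(i, all_modes_map, partition, trace)) for i in anchors
    )
    return AnchorSet(
        anchors=tuple(anchors),
        subunit_of_anchor=tuple(subunits),
        grooves=grooves,
        ar=len(anchors) / len(trace),
    )


def groove_of(
    anchor_index: int,
    all_modes_map: CorrelationMap,
    partition: SubunitPartition,
    trace: CalphaTrace,
    top: int = 3,
) -> list[int]:
    """Partner-subunit residues most correlated with an anchor (all modes).

    Returns up to ``top`` node indices sorted by descending normalized
    correlation; ties are broken by trace order.
    """
    if all_modes_map.normalized is None:
        raise ValueError("normalized all-modes map required")
    c = all_modes_map.normalized
    idx1, idx2 = partition.indices(trace)
    if anchor_index in set(idx1.tolist()):
        partner = idx2
    elif anchor_index in set(idx2.tolist()):
        partner = idx1
    else:
        raise ValueError(f"node {anchor_index} belongs to neither subunit")
    vals = c[anchor_index, partner]
    order = np.argsort(-vals, kind="stable")[: min(top, len(partner))]
    return [int(partner[k]) for k in order]
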