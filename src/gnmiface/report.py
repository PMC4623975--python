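"""End-to-end pipeline and report/matrix writers.

``run_single`` wires the whole method together for one complex:

    read -> Kirchhoff -> modes -> maps (all / ten-slowest / two-slowest)
         -> hinges, anchors, AR -> attributes -> size regime -> decision

``run_batch`` applies it to a labeled manifest and aggregates success
rates, listing singular-connectivity failures separately.  All writers
emit plain tab-delimited text or PDB-format files; the per-residue
mode-1 domain label (+1 / -1 / 0) and the anchor flag are written into the
B-factor column of a C-alpha PDB copy so any molecular viewer can color
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import classify, dynamics, gnm, structure
from .classify import (
    AttributeVector,
    Decision,
    EvaluationResult,
    ThresholdSet,
)
from .dynamics import AnchorSet, HingeSite
from .errors import GnmifaceError, SingularNetworkError
from .gnm import CorrelationMap, GNMParams
from .structure import CalphaTrace, SubunitPartition

__all__ = ["RunReport", "BatchResult", "run_single", "run_batch", "write_outputs",
           "load_default_thresholds", "read_manifest"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunReport:
    """Complete, reproducible record of one classification run."""

    source_id: str
    trace: CalphaTrace
    partition: SubunitPartition
    params: GNMParams
    regime: str
    attributes: AttributeVector
    thresholds: ThresholdSet
    decision: Decision
    reduced_decisions: dict[str, Decision]
    hinges_mode1: list[HingeSite]
    hinges_mode2: list[HingeSite]
    anchor_set: AnchorSet
    maps: dict[str, CorrelationMap]
    mode1_labels: tuple[str, ...]


@dataclass(frozen=True)
class BatchResult:
    """Aggregate of a labeled-manifest run."""

    reports: list[tuple[str, RunReport, str]]  # (identifier, report, true label)
    failures: list[tuple[str, str]]  # (identifier, error message)
    evaluation: EvaluationResult


def load_default_thresholds() -> dict[str, ThresholdSet]:
    """Thresholds shipped with the package (see ``data/default_thresholds.cfg``).

    These defaults are calibrated on the synthetic two-class attribute
    generator, not on curated complexes; for real work calibrate on a
    labeled dataset with ``gnmiface calibrate`` and pass the file
    explicitly.
    """
    path = Path(__file__).parent / "data" / "default_thresholds.cfg"
    return classify.read_thresholds(path.read_text())


def run_single(
    trace: CalphaTrace,
    partition: SubunitPartition,
    thresholds: dict[str, ThresholdSet] | None = None,
    params: GNMParams = GNMParams(),
    with_reduced: bool = True,
) -> RunReport:
    """Classify one complex and collect every intermediate of interest."""
    kirch = gnm.build_kirchhoff(trace, params)
    try:
        spectrum = gnm.decompose(kirch, params)
    except SingularNetworkError as exc:
        dmin = gnm.min_intersubunit_distance(trace, partition)
        raise SingularNetworkError(
            f"{exc} Minimum inter-subunit C-alpha distance here: {dmin:.2f} A."
        ) from exc

    maps = {
        sel: gnm.correlation_map(spectrum, sel, params)
        for sel in ("all", "slowest_10", "slowest_2")
    }
    anchor_set = dynamics.find_anchors(maps["all"], partition, trace)
    attrs = classify.compute_attributes(
        maps["all"], maps["slowest_10"], partition, anchor_set, trace
    )
    sizes = partition.subunit_sizes(trace)
    if thresholds is None:
        thresholds = load_default_thresholds()
    regime = classify.select_regime(
        sizes, next(iter(thresholds.values())).small_subunit_cutoff
    )
    ts = thresholds.get(regime) or next(iter(thresholds.values()))
    if ts.regime != regime:
        logger.warning(
            "no %r threshold set provided; falling back to %r", regime, ts.regime
        )
    decision = classify.decide(attrs, ts)

    reduced: dict[str, Decision] = {}
    if with_reduced:
        # The slow-map (A_s, N_s, P_s) thresholds serve both reduced trials;
        # no separate threshold sets are defined for them.
        anp_thresholds = (ts.a_slow, ts.n_slow, ts.p_slow)
        for sel in ("slowest_2", "slowest_10"):
            anp = classify.interface_anp(maps[sel], partition, trace)
            reduced[sel] = classify.decide_reduced(anp, anp_thresholds, mode_config=sel)

    assignment1 = dynamics.assign_domains(spectrum, 1)
    hinges1 = dynamics.detect_hinges(assignment1, trace)
    hinges2: list[HingeSite] = []
    if spectrum.n_nonzero >= 2:
        hinges2 = dynamics.detect_hinges(dynamics.assign_domains(spectrum, 2), trace)

    return RunReport(
        source_id=trace.source_id,
        trace=trace,
        partition=partition,
        params=params,
        regime=regime,
        attributes=attrs,
        thresholds=ts,
        decision=decision,
        reduced_decisions=reduced,
        hinges_mode1=hinges1,
        hinges_mode2=hinges2,
        anchor_set=anchor_set,
        maps=maps,
        mode1_labels=assignment1.labels,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _hinge_table(hinges_by_mode: dict[int, list[HingeSite]]) -> str:
    lines = ["mode\tchain\tres_a\tres_b"]
    for mode, hinges in hinges_by_mode.items():
        for h in hinges:
            (sa, ia, na), (sb, ib, nb) = h.res_a, h.res_b
            lines.append(
                f"{mode}\t{h.chain_id}\t{na}{sa}{ia.strip()}\t{nb}{sb}{ib.strip()}"
            )
    return "\n".join(lines) + "\n"


def _anchor_table(report: RunReport) -> str:
    lines = ["subunit\tanchor\tgroove_1\tgroove_2\tgroove_3"]
    t = report.trace
    for idx, su, groove in zip(
        report.anchor_set.anchors,
        report.anchor_set.subunit_of_anchor,
        report.anchor_set.grooves,
    ):
        cells = [str(su), t.label(idx)] + [t.label(g) for g in groove]
        cells += [""] * (5 - len(cells))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def summary_text(report: RunReport) -> str:
    """Human-readable run summary (stable given identical inputs)."""
    lines = [
        f"complex\t{report.source_id}",
        "partition\t"
        + "".join(report.partition.chains_of(1))
        + ":"
        + "".join(report.partition.chains_of(2)),
        f"subunit_sizes\t{report.partition.subunit_sizes(report.trace)}",
        f"regime\t{report.regime}",
    ]
    for name, value in report.attributes.as_dict().items():
        direction = classify.ATTRIBUTE_DIRECTIONS[name]
        thr = getattr(report.thresholds, name)
        verdict = "obligatory-side" if report.decision.verdicts[name] else "non-obligatory-side"
        lines.append(f"attr:{name}\t{value:.6f}\t{direction}\t{thr:.6f}\t{verdict}")
    lines.append(f"D\t{report.decision.d}")
    lines.append(f"label\t{report.decision.label}")
    for sel, dec in report.reduced_decisions.items():
        lines.append(f"reduced:{sel}\tD={dec.d}\t{dec.label}")
    lines.append(f"hinges_mode1\t{'; '.join(h.label for h in report.hinges_mode1) or '-'}")
    lines.append(f"hinges_mode2\t{'; '.join(h.label for h in report.hinges_mode2) or '-'}")
    lines.append(f"n_anchors\t{len(report.anchor_set)}")
    lines.append(f"AR\t{report.anchor_set.ar:.6f}")
    return "\n".join(lines) + "\n"


def write_outputs(report: RunReport, out_dir: str | Path) -> list[Path]:
    """Write matrices, tables and annotated PDB files for one run.

    Emits, per mode set, raw and normalized correlation matrices as
    labeled TSV; hinge and anchor/groove tables; a run summary; and two
    B-factor-annotated C-alpha PDB files (mode-1 domain label, anchor
    flag).  Returns the written paths.  Output is a pure function of the
    report, so repeated runs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        written.append(p)

    for sel, cmap in report.maps.items():
        emit(f"correlation_{sel}_normalized.tsv", gnm.write_map_tsv(cmap, report.trace, "normalized"))
        emit(f"correlation_{sel}_raw.tsv", gnm.write_map_tsv(cmap, report.trace, "raw"))
    emit("hinges.tsv", _hinge_table({1: report.hinges_mode1, 2: report.hinges_mode2}))
    emit("anchors.tsv", _anchor_table(report))
    emit("summary.txt", summary_text(report))

    domain_b = [
        {"plus": 1.0, "minus": -1.0, "near_zero": 0.0}[lab]
        for lab in report.mode1_labels
    ]
    emit("domains_mode1.pdb", structure.write_pdb(report.trace, bfactors=domain_b))
    anchor_b = np.zeros(len(report.trace))
    anchor_b[list(report.anchor_set.anchors)] = 1.0
    emit("anchors.pdb", structure.write_pdb(report.trace, bfactors=anchor_b))
    return written


# ---------------------------------------------------------------------------
# Batch
# ---------------------------------------------------------------------------


def read_manifest(text: str) -> list[tuple[str, str, str]]:
    """Parse a tab-delimited manifest: structure<TAB>partition<TAB>label.

    ``structure`` is a file path or a 4-character PDB id; lines starting
    with ``#`` and blank lines are skipped.
    """
    rows: list[tuple[str, str, str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"manifest line needs 3 tab-separated fields: {line!r}")
        rows.append((parts[0], parts[1], parts[2]))
    return rows


def run_batch(
    manifest: Sequence[tuple[str, str, str]],
    thresholds: dict[str, ThresholdSet] | None = None,
    params: GNMParams = GNMParams(),
    cache_dir: str | Path | None = None,
) -> BatchResult:
    """Classify every complex of a labeled manifest and aggregate results.

    Complexes whose contact network is disconnected (singular connectivity
    matrix) are counted and listed as failures rather than aborting the
    batch, mirroring how such cases are excluded from dataset statistics.
    """
    reports: list[tuple[str, RunReport, str]] = []
    failures: list[tuple[str, str]] = []
    for ident, part_spec, label in manifest:
        try:
            path = Path(ident)
            if path.is_file():
                trace = structure.read_structure(path.read_text())
                trace = CalphaTrace(
                    trace.chain_ids, trace.res_seqs, trace.icodes,
                    trace.res_names, trace.coords, source_id=str(ident),
                )
            else:
                trace = structure.fetch_structure(ident, cache_dir=cache_dir)
            partition = structure.partition_subunits(trace, part_spec)
            report = run_single(trace, partition, thresholds, params)
            reports.append((ident, report, label))
        except GnmifaceError as exc:
            logger.warning("failed on %s: %s", ident, exc)
            failures.append((ident, str(exc)))
    evaluation = classify.evaluate(
        (rep.decision, label) for _, rep, label in reports
    )
    return BatchResult(reports=reports, failures=failures, evaluation=evaluation)
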