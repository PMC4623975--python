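"""Seven-attribute decision rule for obligatory vs non-obligatory interfaces.

Attributes, all computed over inter-subunit residue pairs of normalized
cross-correlation maps:

=========  =============================================================
``a_all``  mean of all correlations, all-modes map            (A_a)
``n_all``  mean of the strictly negative correlations, all    (N_a)
``p_all``  mean of the strictly positive correlations, all    (P_a)
``a_slow`` mean of all correlations, ten-slowest map          (A_s)
``n_slow`` mean of negative correlations, ten-slowest map     (N_s)
``p_slow`` mean of positive correlations, ten-slowest map     (P_s)
``ar``     associating-regions ratio: anchors / total residues (AR)
=========  =============================================================

The decision counts how many attributes fall on the obligatory side of
their thresholds (hatted values):

    D = (A_a > ^A_a) + (N_a > ^N_a) + (P_a < ^P_a)
      + (A_s > ^A_s) + (N_s > ^N_s) + (P_s < ^P_s) + (AR > ^AR)

and the label is *obligatory* iff D >= 4 (majority of seven).  Note the
direction: obligatory interfaces show many weak-to-moderate correlated
pairs across the interface -- higher A and N (less negative), *lower* P --
and more anchors, hence P compares with ``<`` while all others use ``>``.

Reduced trials that use a single mode set (two slowest or ten slowest)
have only A, N, P and call the complex obligatory iff at least 2 of 3
attributes are on the obligatory side.

Two threshold regimes exist because small binding partners change the
correlation statistics: one set applies when both subunits have more than
65 residues (``large``), another when any subunit is smaller (``small``).
A subunit of exactly 65 residues falls in the ``large`` regime here (the
boundary case is a documented convention).
"""

from __future__ import annotations

import configparser
import io
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .dynamics import AnchorSet
from .errors import CalibrationError, PartitionError
from .gnm import CorrelationMap
from .structure import CalphaTrace, SubunitPartition

__all__ = [
    "OBLIGATORY",
    "NON_OBLIGATORY",
    "ATTRIBUTE_NAMES",
    "ATTRIBUTE_DIRECTIONS",
    "AttributeVector",
    "ThresholdSet",
    "Decision",
    "EvaluationResult",
    "write_thresholds",
    "read_thresholds",
    "compute_attributes",
    "interface_anp",
    "decide",
    "decide_reduced",
    "select_regime",
    "calibrate_thresholds",
    "evaluate",
    "sample_attribute_vectors",
    "subset_stability",
]

OBLIGATORY = "obligatory"
NON_OBLIGATORY = "non_obligatory"

ATTRIBUTE_NAMES = ("a_all", "n_all", "p_all", "a_slow", "n_slow", "p_slow", "ar")

#: Comparison direction per attribute: ">" means larger values vote
#: obligatory, "<" means smaller values do.
ATTRIBUTE_DIRECTIONS = {
    "a_all": ">",
    "n_all": ">",
    "p_all": "<",
    "a_slow": ">",
    "n_slow": ">",
    "p_slow": "<",
    "ar": ">",
}

@dataclass(frozen=True)
class AttributeVector:
    """The seven decision attributes of one complex (dimensionless)."""

    a_all: float
    n_all: float
    p_all: float
    a_slow: float
    n_slow: float
    p_slow: float
    ar: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ATTRIBUTE_NAMES}


@dataclass(frozen=True)
class ThresholdSet:
    """Per-attribute decision thresholds for one size regime."""

    a_all: float
    n_all: float
    p_all: float
    a_slow: float
    n_slow: float
    p_slow: float
    ar: float
    regime: str = "large"
    small_subunit_cutoff: int = 65

    def __post_init__(self) -> None:
        if self.regime not in ("large", "small"):
            raise ValueError("regime must be 'large' or 'small'")
        for name in ATTRIBUTE_NAMES:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} is not finite")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ATTRIBUTE_NAMES}


def write_thresholds(threshold_sets: Sequence[ThresholdSet]) -> str:
    """Serialize threshold sets as a small key=value config (one block per regime)."""
    cp = configparser.ConfigParser()
    for ts in threshold_sets:
        cp[ts.regime] = {name: repr(getattr(ts, name)) for name in ATTRIBUTE_NAMES}
        cp[ts.regime]["small_subunit_cutoff"] = str(ts.small_subunit_cutoff)
    buf = io.StringIO()
    cp.write(buf)
    return buf.getvalue()


def read_thresholds(text: str) -> dict[str, ThresholdSet]:
    """Parse a thresholds config; returns a mapping regime -> ThresholdSet."""
    cp = configparser.ConfigParser()
    cp.read_string(text)
    out: dict[str, ThresholdSet] = {}
    for regime in cp.sections():
        sec = cp[regime]
        out[regime] = ThresholdSet(
            **{name: float(sec[name]) for name in ATTRIBUTE_NAMES},
            regime=regime,
            small_subunit_cutoff=int(sec.get("small_subunit_cutoff", "65")),
        )
    return out


@dataclass(frozen=True)
class Decision:
    """Outcome of the majority rule for one complex."""

    d: int
    label: str
    verdicts: dict[str, bool]
    rule: str  # "full_7" or "reduced_3"
    mode_config: str

    def __post_init__(self) -> None:
        if self.d != sum(self.verdicts.values()):
            raise ValueError("D must equal the number of true verdicts")


# ---------------------------------------------------------------------------
# Attribute computation
# ---------------------------------------------------------------------------


def _block_stats(c: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> tuple[float, float, float]:
    """(A, N, P) over the inter-subunit block of a normalized map.

    N (P) is the mean over strictly negative (positive) entries, 0 when no
    entry of that sign exists, keeping the decision comparisons
    well-defined on degenerate maps.
    """
    block = c[np.ix_(idx1, idx2)].ravel()
    if block.size == 0:
        raise PartitionError("no inter-subunit residue pairs (empty subunit)")
    a = float(block.mean())
    neg = block[block < 0]
    pos = block[block > 0]
    n = float(neg.mean()) if neg.size else 0.0
    p = float(pos.mean()) if pos.size else 0.0
    return a, n, p


def compute_attributes(
    all_map: CorrelationMap,
    slow10_map: CorrelationMap,
    partition: SubunitPartition,
    anchor_set: AnchorSet,
    trace: CalphaTrace,
) -> AttributeVector:
    """Build the seven-attribute vector from the two normalized maps.

    The all-modes map contributes A_a, N_a, P_a (and, upstream, the anchor
    set whose AR is copied here); the ten-slowest map contributes A_s, N_s,
    P_s.
    """
    for m, name in ((all_map, "all-modes"), (slow10_map, "ten-slowest")):
        if m.normalized is None:
            raise ValueError(f"{name} map is not normalized")
    idx1, idx2 = partition.indices(trace)
    a_a, n_a, p_a = _block_stats(all_map.normalized, idx1, idx2)
    a_s, n_s, p_s = _block_stats(slow10_map.normalized, idx1, idx2)
    return AttributeVector(
        a_all=a_a, n_all=n_a, p_all=p_a,
        a_slow=a_s, n_slow=n_s, p_slow=p_s,
        ar=anchor_set.ar,
    )


def interface_anp(
    cmap: CorrelationMap, partition: SubunitPartition, trace: CalphaTrace
) -> tuple[float, float, float]:
    """(A, N, P) of one normalized map's inter-subunit block (reduced trials)."""
    if cmap.normalized is None:
        raise ValueError("map is not normalized")
    idx1, idx2 = partition.indices(trace)
    return _block_stats(cmap.normalized, idx1, idx2)


# ---------------------------------------------------------------------------
# Decision rules
# ---------------------------------------------------------------------------


def _passes(value: float, threshold: float, direction: str) -> bool:
    return value > threshold if direction == ">" else value < threshold


def decide(attrs: AttributeVector, thresholds: ThresholdSet) -> Decision:
    """Full seven-attribute majority rule: obligatory iff D >= 4."""
    verdicts = {
        name: _passes(getattr(attrs, name), getattr(thresholds, name),
                      ATTRIBUTE_DIRECTIONS[name])
        for name in ATTRIBUTE_NAMES
    }
    d = sum(verdicts.values())
    return Decision(
        d=d,
        label=OBLIGATORY if d >= 4 else NON_OBLIGATORY,
        verdicts=verdicts,
        rule="full_7",
        mode_config="slowest_10+all",
    )


def decide_reduced(
    anp: tuple[float, float, float],
    anp_thresholds: tuple[float, float, float],
    mode_config: str = "slowest_10",
) -> Decision:
    """Reduced single-mode-set rule: obligatory iff >= 2 of (A, N, P) pass."""
    names = ("a", "n", "p")
    directions = (">", ">", "<")
    verdicts = {
        name: _passes(v, t, direction)
        for name, v, t, direction in zip(names, anp, anp_thresholds, directions)
    }
    d = sum(verdicts.values())
    return Decision(
        d=d,
        label=OBLIGATORY if d >= 2 else NON_OBLIGATORY,
        verdicts=verdicts,
        rule="reduced_3",
        mode_config=mode_config,
    )


def select_regime(
    subunit_sizes: tuple[int, int], small_subunit_cutoff: int = 65
) -> str:
    """``"small"`` iff any subunit has fewer residues than the cutoff.

    A subunit of exactly ``small_subunit_cutoff`` residues counts as large.
    """
    if min(subunit_sizes) < 1:
        raise PartitionError("both subunits need at least one residue")
    return "small" if min(subunit_sizes) < small_subunit_cutoff else "large"


# ---------------------------------------------------------------------------
# Calibration and evaluation
# ---------------------------------------------------------------------------


def _balanced_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    tpr = pred[truth].mean() if truth.any() else 0.0
    tnr = (~pred[~truth]).mean() if (~truth).any() else 0.0
    return 0.5 * (tpr + tnr)


def _best_cut(values: np.ndarray, is_obl: np.ndarray, direction: str) -> float:
    """Candidate-midpoint threshold maximizing single-attribute balanced accuracy.

    Candidates are midpoints between consecutive sorted distinct values;
    ties go to the smallest midpoint.  Deterministic by construction.
    """
    uniq = np.unique(values)
    if len(uniq) == 1:
        candidates = np.array([uniq[0]])
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t = candidates[0]
    best_score = -1.0
    for t in candidates:
        pred = values > t if direction == ">" else values < t
        score = _balanced_accuracy(pred, is_obl)
        if score > best_score + 1e-12:  # strict improvement; ties keep smallest
            best_score = score
            best_t = t
    return float(best_t)


def calibrate_thresholds(
    labeled: Sequence[tuple[AttributeVector, str]],
    regime: str = "large",
    small_subunit_cutoff: int = 65,
) -> ThresholdSet:
    """Fit per-attribute thresholds from labeled attribute vectors.

    Each attribute's threshold independently maximizes the balanced
    accuracy of its single-attribute rule in the decision direction,
    scanning midpoints between consecutive sorted values.  Balanced
    accuracy is used because the training data of interest are class
    imbalanced; the procedure is deterministic.
    """
    if not labeled:
        raise CalibrationError("no labeled examples")
    labels = np.array([lab for _, lab in labeled])
    is_obl = labels == OBLIGATORY
    if is_obl.all() or not is_obl.any():
        raise CalibrationError("need at least one example of each label")
    cuts = {}
    for name in ATTRIBUTE_NAMES:
        values = np.array([getattr(av, name) for av, _ in labeled], dtype=float)
        cuts[name] = _best_cut(values, is_obl, ATTRIBUTE_DIRECTIONS[name])
    return ThresholdSet(
        **cuts, regime=regime, small_subunit_cutoff=small_subunit_cutoff
    )


@dataclass(frozen=True)
class EvaluationResult:
    """Per-class and overall success rates plus the D histogram."""

    n_obligatory: int
    n_non_obligatory: int
    correct_obligatory: int
    correct_non_obligatory: int
    d_histogram: dict[int, int]

    @property
    def rate_obligatory(self) -> float:
        return self.correct_obligatory / self.n_obligatory if self.n_obligatory else float("nan")

    @property
    def rate_non_obligatory(self) -> float:
        return (
            self.correct_non_obligatory / self.n_non_obligatory
            if self.n_non_obligatory
            else float("nan")
        )

    @property
    def rate_overall(self) -> float:
        total = self.n_obligatory + self.n_non_obligatory
        return (self.correct_obligatory + self.correct_non_obligatory) / total if total else float("nan")


def evaluate(labeled_decisions: Iterable[tuple[Decision, str]]) -> EvaluationResult:
    """Success-rate bookkeeping over (decision, true label) pairs."""
    n_o = n_n = c_o = c_n = 0
    hist: Counter[int] = Counter()
    for dec, truth in labeled_decisions:
        hist[dec.d] += 1
        if truth == OBLIGATORY:
            n_o += 1
            c_o += dec.label == OBLIGATORY
        elif truth == NON_OBLIGATORY:
            n_n += 1
            c_n += dec.label == NON_OBLIGATORY
        else:
            raise ValueError(f"unknown label {truth!r}")
    return EvaluationResult(
        n_obligatory=n_o,
        n_non_obligatory=n_n,
        correct_obligatory=c_o,
        correct_non_obligatory=c_n,
        d_histogram=dict(sorted(hist.items())),
    )


# ---------------------------------------------------------------------------
# Synthetic attribute vectors (for calibration experiments)
# ---------------------------------------------------------------------------

#: Class-conditional Gaussian centers for non-obligatory complexes; the
#: obligatory class is shifted by one standard deviation per attribute in
#: its decision direction.  Centers are placed where normalized
#: inter-subunit correlation summaries plausibly live: A near zero, N and P
#: moderate and of opposite sign, AR a small fraction.
_SYNTH_CENTER = {
    "a_all": 0.00, "n_all": -0.30, "p_all": 0.30,
    "a_slow": 0.00, "n_slow": -0.35, "p_slow": 0.35,
    "ar": 0.05,
}
_SYNTH_SIGMA = {name: 0.10 for name in ATTRIBUTE_NAMES} | {"ar": 0.04}


def sample_attribute_vectors(
    n_per_class: int,
    rng: np.random.Generator | int,
    separation: float = 1.0,
) -> list[tuple[AttributeVector, str]]:
    """Draw synthetic labeled attribute vectors from two Gaussians.

    Per attribute, the obligatory class mean is offset from the
    non-obligatory one by ``separation`` standard deviations in the
    attribute's decision direction.  N is clipped to <= 0, P to >= 0 and AR
    to [0, 1] so the vectors respect the attribute sign conventions.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    out: list[tuple[AttributeVector, str]] = []
    for label in (OBLIGATORY, NON_OBLIGATORY):
        for _ in range(n_per_class):
            vals = {}
            for name in ATTRIBUTE_NAMES:
                mu = _SYNTH_CENTER[name]
                sigma = _SYNTH_SIGMA[name]
                if label == OBLIGATORY:
                    shift = separation * sigma
                    mu = mu + shift if ATTRIBUTE_DIRECTIONS[name] == ">" else mu - shift
                vals[name] = rng.normal(mu, sigma)
            vals["n_all"] = min(vals["n_all"], 0.0)
            vals["n_slow"] = min(vals["n_slow"], 0.0)
            vals["p_all"] = max(vals["p_all"], 0.0)
            vals["p_slow"] = max(vals["p_slow"], 0.0)
            vals["ar"] = float(np.clip(vals["ar"], 0.0, 1.0))
            out.append((AttributeVector(**vals), label))
    return out


def subset_stability(
    labeled: Sequence[tuple[AttributeVector, str]],
    n_folds: int = 5,
    rng: np.random.Generator | int = 0,
) -> tuple[float, float, list[float]]:
    """Random-subset replication of calibration + evaluation.

    The labeled set is shuffled and split into ``n_folds`` groups; for each
    group, thresholds are calibrated on the other groups and the full
    seven-attribute rule is scored on the held-out group.  Returns
    ``(mean, standard deviation, per-fold overall accuracies)``.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    order = rng.permutation(len(labeled))
    folds = np.array_split(order, n_folds)
    accs: list[float] = []
    for k in range(n_folds):
        test_idx = set(folds[k].tolist())
        train = [labeled[i] for i in range(len(labeled)) if i not in test_idx]
        test = [labeled[i] for i in sorted(test_idx)]
        ts = calibrate_thresholds(train)
        res = evaluate((decide(av, ts), lab) for av, lab in test)
        accs.append(res.rate_overall)
    return float(np.mean(accs)), float(np.std(accs)), accs
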