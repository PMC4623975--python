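# Methods

## Coarse-grained structure model

A complex is reduced to one node per residue at its Cα position.  Residue
identity is the author's chain, residue number and insertion code — nothing
is renumbered, so hinge and anchor reports read like `A:HIS328/LEU329`.
Sequence adjacency means consecutive *observed* residues within a chain;
numbering gaps left by unresolved residues are crossed silently, because the
elastic network only ever sees the modeled trace.  Non-standard residues
with a Cα are kept (the network is chemistry-agnostic); waters, Cα-less
residues and calcium ions (atom name CA, element Ca) are dropped.  For
multi-model (NMR) files the first model is used unless another index is
requested, matching the single-conformation premise of the method.
Alternate locations resolve to the highest-occupancy Cα, ties to the first
in file.  The underlying PDB reader is lenient, so ATOM/HETATM coordinate
columns are validated separately and malformed fields raise a parse error
rather than being zero-filled.

The *subunit partition* maps every chain to side 1 or 2 of the interface
(`"AB:C"` syntax).  It is always explicit user input for complexes with
more than two chains; only a two-chain complex defaults to one chain per
subunit.

## Elastic network and correlation maps

The Gaussian network model connects residue pairs within a cutoff
*r*<sub>c</sub> by identical springs.  Parameters:

| parameter | default | units | role |
|---|---|---|---|
| `cutoff_rc` | 7.0 | Å | contact cutoff defining the Kirchhoff matrix |
| `gamma` | 1.0 | arbitrary | spring constant; scales raw covariance only |
| `kbt` | 1.0 | arbitrary | thermal energy; scales raw covariance only |
| `zero_eig_tol` | 100·N·ε (relative) | — | zero-eigenvalue detection |

Normalized correlations are invariant to `gamma` and `kbt`, so their values
matter only if raw covariances are compared across runs.  The cutoff
comparison is inclusive (≤ 7 Å); the convention at exactly the boundary is
not load-bearing, and the synthetic fixtures deliberately avoid pair
distances at exactly 7 Å.

Mode bookkeeping: eigenvalues are sorted ascending with a stable order
under degeneracy; "two slowest" / "ten slowest" always means the
smallest-eigenvalue *nonzero* modes, and `slowest_k` truncates to the number
of internal modes available.  Multi-mode maps are the λ⁻¹-weighted
covariance sum restricted to the mode set, normalized afterwards — not an
average of per-mode normalized maps.  Quantities consumed downstream
(covariance sums, their normalized maps) are invariant within a degenerate
eigenvalue subspace, so eigenvector non-uniqueness under degeneracy is
harmless.

Numerical choices.  Zero modes are counted as eigenvalues below
`100·N·ε·λ_max`; the factor 100 absorbs symmetric-eigensolver roundoff
(which can leave the numerical zero near 10⁻¹⁴ on small dense contact
graphs) while remaining orders of magnitude below any genuine slow-mode
eigenvalue.  One zero mode is the connected case; two or more raise
`SingularNetworkError`, which for a two-subunit complex occurs exactly when
the minimum inter-subunit Cα distance exceeds the cutoff — the error message
reports that distance.  Normalization divides by √(raw_ii·raw_jj) and sets
the diagonal to exactly 1; a residue with numerically zero mean-square
fluctuation under the chosen mode set raises `DegenerateFluctuationError`
instead of producing NaNs.

## Hinges, anchors, grooves

A mode's eigenvector labels each residue `plus`, `minus`, or `near_zero`
(|component| below `sign_tol`, default `1e-6·max|u|`, scale-aware so clean
synthetic eigenvectors are labeled exactly).  A hinge is a sign change
between consecutive observed residues of one chain.  Near-zero residues are
transparent: a run of them between opposite signs yields exactly one hinge,
reported between the two flanking signed residues — this avoids double
counting at soft nodes and keeps both reported residues strictly signed.
Hinge positions are invariant to the eigenvector's arbitrary global sign
and to rigid-body transformation of the input coordinates.

Anchors use the normalized all-modes map.  The statistic for "correlates
more strongly with the juxtaposed subunit" is the arithmetic mean: residue
*i* is an anchor iff its mean correlation with the partner subunit exceeds
its mean correlation with the rest of its own subunit (self excluded).  The
mean is the simplest faithful reading of the criterion; slow-mode-only
anchor maps can be computed through the same functions by passing a
different map, but the all-modes map is the default and is what the AR
attribute uses.  For a degenerate single-residue subunit the own-subunit
mean is defined as 0 (the criterion reduces to "positively correlated with
the partner") and a warning is logged.  Each anchor's groove is the up-to-3
partner-subunit residues with the highest all-modes correlation to it,
descending, ties broken by trace order.  AR is the anchor count from both
subunits divided by the total residue count, so AR ∈ [0, 1] and AR·N is an
integer.

## Decision rule and calibration

The seven attributes (A, N, P over the all-modes and ten-slowest maps; AR)
are means over inter-subunit pairs of normalized correlations; N and P are
defined as 0 when no pair of that sign exists, keeping the comparisons
well-defined on degenerate maps.  The full rule counts obligatory-side
attributes (P compares with <, the rest with >) and labels obligatory iff
D ≥ 4; the reduced single-mode-set rule uses (A, N, P) with a 2-of-3
majority, sharing the slow-map thresholds (no separate reduced threshold
sets are defined).  The size regime is `small` iff any subunit has fewer
than 65 residues; a subunit of exactly 65 counts as `large` — the boundary
case is a convention of this implementation, documented rather than claimed.

Calibration fits each attribute's threshold independently: candidate cuts
are midpoints between consecutive sorted distinct values, the objective is
balanced accuracy of the single-attribute rule in its decision direction,
and ties keep the smallest midpoint, making the procedure deterministic.
Balanced accuracy is chosen because realistic labeled sets are
class-imbalanced.  The shipped default thresholds were produced by this
procedure on the synthetic attribute generator below (seed 20150) and are
placeholders for real calibration: they let the CLI run out of the box and
are clearly marked in the config header.  The five-random-subset stability
utility shuffles the labeled set into five folds, calibrates on each
complement, scores the held-out fold, and reports mean, standard deviation
and per-fold accuracies.

## Synthetic data

Two generators make all computation testable without downloads.

*Structure fixtures* (`generate_fixture`) build deterministic Cα traces at
3.8 Å virtual bond length with small Gaussian coordinate jitter (σ = 0.25 Å):
a `linear_chain`; a `dumbbell_dimer` whose chains are each two dense
clusters (12 residues on a 3.8 Å grid ball) joined by a thin 4-residue
linker, chain B being the exact involutive mirror of chain A so that the
chain swap is a symmetry of the complex and the slowest mode separates the
two spatial lobes with one linker hinge per chain; an `intertwined_dimer`
(parallel rather than mirrored copy) whose contact graph mixes the chains
inside each lobe, the obligatory-like topology; and an `anchor_toy` whose
chain B starts with a 4-residue segment buried in a carved channel of the
chain-A globule, so each protruding residue has more inter- than intra-chain
contacts — the non-obligatory-like anchor topology.  These toys reproduce
the *topological* signatures the method reads (lobe separation, chain
mixing, buried anchors) but not the secondary-structure contact statistics,
size distribution, or packing heterogeneity of real proteins; passing tests
on them validates the machinery and its invariants, not classification
accuracy on real complexes.

*Attribute vectors* (`sample_attribute_vectors`) draw the seven attributes
from class-conditional Gaussians: non-obligatory centers at A = 0,
N = −0.30/−0.35, P = 0.30/0.35 (all/slow), AR = 0.05, with σ = 0.10
(0.04 for AR), and the obligatory class offset by one σ per attribute in its
decision direction; N/P/AR are clipped to their sign domains.  One σ of
separation makes each single attribute a weak classifier (≈ 69% balanced
accuracy at the optimum) while the 7-attribute majority reaches the high
80s — the sort of regime a realistically imperfect attribute set operates
in.  These vectors exercise calibration and evaluation only; they say
nothing about how real complexes populate attribute space.

## Problem sizes and limitations

Tests and the acceptance script use fixtures of ≈ 10–200 residues and
calibration sets of 200 vectors per class, sizes at which the dense
eigendecomposition is instantaneous and the pseudoinverse cross-check is
exact to ≈ 10⁻¹³.  Known limitations: mmCIF input, biological-unit
reconstruction, anisotropic network models and B-factor fitting of γ are
out of scope; thresholds shipped by default are synthetic-calibrated, so
real-data classification requires calibrating on a curated labeled set; the
two acceptance tests that assert published hinge/anchor values on PDB
entries 1QU7 and 2SIC require those coordinate files (fetched once and
cached) and fail without them; and the obligatory/non-obligatory boundary
is itself continuous, so even calibrated thresholds misclassify borderline
complexes.
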