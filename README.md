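# gnmiface

Classify a protein–protein complex as **obligatory** (the subunits stay bound
throughout their functional lifetime, often because they are unstable alone)
or **non-obligatory** (stable subunits that associate and dissociate, as in
enzyme–inhibitor or signaling complexes) from nothing but the equilibrium
fluctuation dynamics of a single structure.

The intuition: interfaces are wired for transduction.  In obligatory
complexes the *dynamic domains* — groups of residues moving collectively in
one direction — typically mix segments of both chains, and the hinges between
domains avoid the interface.  In non-obligatory complexes each subunit tends
to be an autonomous dynamic domain, coupled across the interface through a
few *anchor* residues facing an *anchoring groove* on the partner.

The package is for structural bioinformaticians who have a complex in PDB
format (file or fetched by 4-character identifier), a partition of its chains
into the two interacting subunits, and optionally a labeled set of complexes
to calibrate decision thresholds on.

## Model

Fluctuations come from the Gaussian network model (GNM).  Every residue is a
node at its Cα position; residue pairs with Cα–Cα distance ≤ *r*<sub>c</sub>
(7 Å) are joined by identical springs γ, giving the Kirchhoff (connectivity)
matrix **Γ** — the graph Laplacian of the contact network.  With eigenmodes
**Γ** = **U Λ U**ᵀ, the cross-correlation of residue fluctuations restricted
to a mode set *S* is

⟨Δ**R**ᵢ·Δ**R**ⱼ⟩ = (3k<sub>B</sub>T/γ) Σ<sub>k∈S</sub> λₖ⁻¹ (**u**ₖ**u**ₖᵀ)ᵢⱼ ,

normalized to *C*ᵢⱼ ∈ [−1, +1].  The trivial zero mode is always excluded;
a disconnected contact network (two or more zero modes — which happens
exactly when the minimum inter-subunit Cα distance exceeds 7 Å) is rejected
as a singular connectivity matrix.

From the normalized maps over the **ten slowest** modes (subscript *s*) and
over **all** modes (subscript *a*), seven attributes are computed on the
inter-subunit residue pairs: the mean of all (*A*), of the negative (*N*) and
of the positive (*P*) correlations for each map, plus *AR*, the fraction of
residues that are *anchors* — residues correlating more strongly with the
juxtaposed subunit than with their own.  The decision counts obligatory-side
attributes

D = (A_a > Â_a) + (N_a > N̂_a) + (P_a < P̂_a) + (A_s > Â_s) + (N_s > N̂_s) + (P_s < P̂_s) + (AR > ÂR)

and the complex is labeled obligatory iff **D ≥ 4**.  Hatted values are
thresholds calibrated on labeled data, with separate sets for the regime
where both subunits exceed 65 residues and the regime with a smaller
subunit.  Reduced 2-of-3 variants over a single mode set (two slowest or
ten slowest) are available for comparison.

## Worked example

Synthetic structures stand in for downloads; the `anchor_toy` fixture is a
globular chain A with a protruding segment of chain B buried in it — the
anchor-and-groove topology typical of non-obligatory interfaces:

```sh
$ gnmiface fixture --kind anchor_toy --seed 1 -o toy.pdb
$ gnmiface run --structure toy.pdb --partition A:B
complex	toy.pdb
partition	A:B
subunit_sizes	(45, 27)
regime	small
attr:a_all	-0.578597	>	0.040595	non-obligatory-side
attr:n_all	-0.810714	>	-0.234977	non-obligatory-side
attr:p_all	0.756078	<	0.255164	non-obligatory-side
attr:a_slow	-0.640909	>	0.037473	non-obligatory-side
attr:n_slow	-0.909085	>	-0.310000	non-obligatory-side
attr:p_slow	0.901099	<	0.285002	non-obligatory-side
attr:ar	0.055556	>	0.081383	non-obligatory-side
D	0
label	non_obligatory
...
n_anchors	4
AR	0.055556
```

Each `attr:` line shows the attribute value, the comparison direction, the
threshold, and which side the value falls on.  Here every attribute is on
the non-obligatory side (D = 0): inter-subunit correlations are strongly
polarized (mean −0.58) rather than mixed, and only the four buried
protruding residues of chain B are anchors (AR = 4/72 ≈ 0.056).  Adding
`--out DIR` writes the raw and normalized correlation matrices (TSV), hinge
and anchor/groove tables, and Cα PDB files with the mode-1 dynamic-domain
label or the anchor flag in the B-factor column for viewing.

Thresholds ship as a plain-text config calibrated on the synthetic attribute
generator; calibrate on your own labeled manifest with

```sh
gnmiface calibrate --manifest labeled.tsv --out thresholds.cfg
gnmiface batch --manifest labeled.tsv --thresholds thresholds.cfg
```

where the manifest rows are `structure-or-id <TAB> partition <TAB> label`.

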