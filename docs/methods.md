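# Methods

This note documents the models, numerical choices and limitations behind
each module. It states nothing the test suite or `scripts/acceptance.py` do
not themselves compute.

## Synthetic data (`syndata`)

The generators produce the *stated world* the analyses are tested in; their
defaults are fixed once and not tuned against test outcomes.

**Families.** One random ancestor of length L (default fixtures use 200–300
residues); each member mutates every site independently with probability m,
replacing the residue uniformly among the 19 alternatives. Two descendants
then agree at a site with probability (1−m)² + m²/19, and m is solved from
the target mean pairwise identity by inverting this quadratic. Identities
below the ≈5% random floor are rejected. Realised identity is within ±5
points of target for L ≥ 200 (checked with the exact aligner). The default
fixture — 20 members at 80% identity — stands in for a retrieved family; it
has no phylogenetic correlation structure, so a green test establishes
identity control and separability, not realism of tree shape.

**Decoys** are Fisher–Yates shuffles of real member sequences: identical
length and composition, no positional signal — the null model both for the
AS separation fixtures and for E-value calibration.

**Genomes.** Feature tables use 1-based inclusive coordinates with explicit
strand (GenBank convention), non-overlapping ORFs (lengths 300–1497 bp,
intergenic gaps 20–199 bp) on one contig. A pathway genome receives one gene
per required signature group, placed uniformly at random within ±10 ORFs of
the central seed SQase gene, so it satisfies its own rule set by
construction; background genes draw decoy domain tags disjoint from every
signature tag. What a green round-trip establishes is rule/window logic, not
robustness to annotation noise — tags are exact, never missing or wrong.

**Kinetic data** are exact hyperbola evaluations plus i.i.d. Gaussian noise;
`noise_sd = 0` gives the exact curve used for recovery tests.

**Toy structures** have closed-form geometry: an atom pair at a set
separation; a residue pair whose χ₁ differs by a set angle (the Cα–Cβ bond
is placed on the z axis so the rotation maps to the dihedral exactly); and a
CA-only two-helix "dimer" whose buried area is checked against an
independent Monte-Carlo sampler.

## Pairwise alignment and AS (`pairalign`)

Alignment is optimal affine-gap dynamic programming (Biopython's
`PairwiseAligner`) under BLOSUM62 with the BLAST gap convention: a gap of
length k costs 11 + k (open 11, extend 1). The ambiguity code X is rescored
to 0 against everything. Percent identity is identities over non-gap aligned
columns — stated explicitly because identity conventions differ.

The alignment score is made self-contained rather than delegated to a search
engine: bits = (λ·raw − ln K)/ln 2 with the standard gapped BLOSUM62-11-1
constants λ = 0.267, K = 0.041 (exposed as module constants), an
E-value-like quantity E = m·n·2^(−bits) over the pairwise m·n search space,
and AS = −log₁₀ E (E floored at 1e−300 to keep AS finite). Published
SSN-tool scores use a database-scale search space, so absolute AS values
here are not comparable to any particular published threshold (e.g. an
AS-133 cut); within one dataset the ordering is the same, which is all
thresholding needs.

## Similarity networks (`ssn`)

Graphs are `networkx` graphs; clusters are connected components numbered by
(size descending, lexicographic minimum id) for reproducible output.
Betweenness is unnormalised internally (pair counts) to avoid normalisation
convention bugs; exports carry whatever attributes the nodes hold.

Threshold selection is a concrete criterion standing in for the
centrality-guided approach that network practitioners apply by eye: pick the
smallest grid AS at which (a) the cluster count is unchanged over at least
two consecutive grid steps and (b) mean betweenness has fallen below a
configurable fraction (default 0.1) of its value at the grid minimum. When
the baseline betweenness is already zero (e.g. a single clique), (b)
degenerates to requiring zero betweenness on a graph that still has edges —
so an edgeless sweep selects nothing rather than trivially everything. The
full sweep table is always returned so a human can re-select. The strategy
is a design choice of this package, not a claim about any published
computation.

XGMML (Cytoscape dialect) is written and read here with typed `att`
elements so round-trips are lossless; GraphML goes through networkx.

## Profile search (`profsearch`)

A full profile HMM is deliberately replaced by a PSSM: per-column log-odds
in half-bits, 2·log₂(p̃/q), where p̃ blends Henikoff position-based weighted
frequencies with α = 0.5 background pseudo-observations,
p̃ = (n_c·p + α·q)/(n_c + α), against BLOSUM62 background frequencies q.
Columns with >50% gaps are masked. This preserves the procedure that matters
— iterative model rebuilding to a stable retrieved set — at a fraction of
the engineering, and is stated openly as a simplification.

Scoring is local affine-gap DP (same 11/1 gap costs). The row recurrence is
fully vectorised: the horizontal affine-gap term is a running cumulative
maximum, valid because chaining two adjacent gaps is never better than one
longer gap; the implementation is checked against a plain-Python Gotoh
reference. E-values come from a Gumbel fit (`scipy.stats.gumbel_r`) to the
scores of ≥200 shuffled decoys, scaled by database size; the floor of
1e−300 makes an E-cutoff of 0 return nothing. Convergence is exact set
equality of retrieved ids with the previous round (the seed MSA counts as
round zero); a non-consecutively recurring set is flagged `oscillating`.
Realignment threads each hit onto the profile columns via the DP trace,
dropping insertions — adequate for family bookkeeping, not for producing a
publication MSA.

## Genome neighbourhoods (`neighborhood`)

The window is the seed gene ±k ORFs (default 10) in genomic order on the
seed's contig — positional, strand-independent, never crossing contigs.
Rules are data (`data/pathway_rules.yaml`): per pathway, groups of accepted
domain tags and a minimum number of satisfied groups — all groups for the
multi-enzyme sulfo-EMP (isomerase/kinase/aldolase/SLA-dehydrogenase) and
sulfo-ED (dehydrogenase/lactonase/dehydratase/aldolase) pathways, one for
the single-signature SFT/SMO/SDO pathways, plus an optional
transporter-or-regulator co-occurrence requirement (off by default) that
keeps single-gene signatures honest. Tags are symbolic enzyme-role labels;
swap in PFAM accessions if your annotations carry them. Domain tags are
consumed, never computed — running a domain scanner is out of scope.

Conflict resolution (not specified anywhere authoritative): all rule sets
are evaluated; the pathway with the most matched groups wins; an exact tie
returns `ambiguous` with all candidates listed rather than an arbitrary
pick. GH31/GH188 presence flags are reported independently of the pathway
call.

## Kinetics (`kinetics`)

Primary estimator: nonlinear least squares (Levenberg–Marquardt via
`scipy.optimize.curve_fit`, xtol/ftol 1e−12) on the untransformed
hyperbola. The double-reciprocal (Lineweaver–Burk) line is used only for
initial guesses and plotting — as an estimator it is biased by the
reciprocal's error weighting. If the unconstrained path yields non-positive
parameters the fit is redone in log-parameter space (positivity by
construction), with standard errors mapped back by the delta method. SEs
are Jacobian-based at the optimum. A warning (not an error) is raised for
fewer than four distinct concentrations or a grid that does not span
[K_M/2, 2·K_M]. Mn²⁺/DTT effects on enzyme stability are out of scope: the
model is the rate law only.

## Fragment masses and label inference (`msfrag`)

Formulas count D separately from H; nominal mass uses integer mass numbers,
monoisotopic uses IUPAC isotope masses with the electron mass included for
ions. The printed instrument values for SQ species (243.00, 317.08) are
treated as nominal-scale settings; inference uses nominal masses and the
monoisotopic values (which differ in the second decimal) are computed but
not "corrected" against them.

Carbon-coverage sets for the diagnostic 123/153/183 fragment series are
figure-derived fixture data, declared in `SQ_FRAGMENT_TABLE`, not computed
from fragmentation chemistry — the inference engine consumes declared
coverage so the chemical assumptions stay visible and editable. What the
experiment actually uses is that the three unchanged ions jointly cover
C3–C6. Exchangeable positions (OH, SO₃H protons) are outside the model: the
label is assumed carbon-bound and non-exchangeable. Inference is the
intersection of per-observation feasible sets under the single-label model;
it provably equals brute-force enumeration over the six hypotheses (the
test suite asserts this equality on random observation sets).

## Structure geometry (`structgeo`)

I/O through biotite (PDB and mmCIF); alternate locations resolve to the
highest-occupancy conformer; waters are dropped on read unless retained.
Superposition is Kabsch (SVD with determinant correction, so reflections
are never returned), over N/CA/C/O of residues paired by (chain, residue
number) with an explicit chain map for differently-labelled protomers; the
residue count is reported alongside the RMSD so any claim is checkable
under a stated pairing. χ₁ is the N–CA–CB–Xγ dihedral with the γ atom
chosen by priority (CG, CG1, OG, OG1, SG, CG2); rotation between structures
is the minimal circular difference in [0°, 180°].

SASA is Shrake–Rupley with a deterministic golden-section lattice (default
960 points, probe 1.4 Å) — no RNG, so results are bit-reproducible; the
cost is that rotation invariance holds only to lattice discretisation
(≤1%, tested). Radii are fixed (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80,
H 1.20 Å) and printed here so offsets against other tools' unstated radii
are explainable. Interface area is reported as total buried over both
protomers, SASA(A)+SASA(B)−SASA(AB) — the convention consistent with
pairing a total buried area with a percent-of-monomer-surface figure — with
the per-side value (÷2) alongside. Ligands, waters and ions are excluded by
default. Published interface and distance figures for the deposited SqgA
complexes require those coordinate files; this repository ships no
coordinates, so the structural tests run on constructed toys with known
answers, and `examples/structure_geometry.py` shows how to point the same
operations at local copies of real deposits.

## Pipeline (`pipeline`)

A directory-of-files run with a JSON manifest (package version, config,
stage wall times, SHA-256 of every output): identical configs give
identical checksums, which the tests assert. Stage order: syndata →
profsearch → pairalign → ssn → neighborhood → report. Stage failure raises
after earlier outputs are on disk.

## Known limitations

- Database-scale behaviour (≈1600-member families, absolute AS thresholds,
  taxonomy surveys) is out of reach at desk scale; the suite covers the
  properties those analyses rest on (DP optimality, centrality correctness,
  separation, convergence, classifier round-trips) on controlled fixtures.
- The PSSM search has no insert-state emission model; very gappy families
  would be served poorly.
- The pathway classifier is only as good as its tag vocabulary; it performs
  no sequence analysis of its own.
- SASA treats all atoms as spheres with fixed radii and ignores hydrogens
  absent from the coordinates.
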