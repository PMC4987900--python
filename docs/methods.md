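# Methods

## Scope and model

`confstats` treats an ensemble of protein structures as repeated
observations of corresponding residues. The unit of analysis is the
**alignment position**: a column of a multiple sequence alignment that
identifies the "same" residue across structures, with gaps marking
absence. All statistics — Cartesian fluctuations, circular torsion
summaries, conformer distances — are indexed by position, so ensembles of
similar-but-different sequences can be compared directly.

## Input policies

PDB files are read under a deliberately narrow, reproducible policy: only
`ATOM` records (no `HETATM`), only the first `MODEL` of multi-model
files, and for alternate locations the first record *in file order* —
literal and reproducible, rather than the highest-occupancy choice some
parsers make. Chain selection accepts an explicit chain id, `first`
(chain of the first ATOM record), `*` (all chains) or `_` (blank chain
id). Records are parsed at the fixed columns of PDB format 3.3; lines too
short to carry a B-factor get 0 with a warning. Hydrogens are kept if
present but excluded from the statistics groups: X-ray ensembles rarely
include them and mixing would bias fluctuations. A chain id repeated
after an intervening chain is treated as one chain (records are grouped
by id, not by contiguity).

## Alignment

Two routes build the residue↔position map. **Numbering**: columns are
the sorted union of (residue number, insertion code) keys — or (chain,
number, icode) when any structure uses several chains, so numbers cannot
collide across chains. This assumes consistent author numbering and is
exact when that holds. **File**: a user-supplied aligned FASTA or CLUSTAL
alignment, matched to structures by row label (basename, plus `:chain`
when an explicit chain was requested — label matching avoids the silent
misbinding an order-based rule would allow). Each row's gap-stripped
sequence must equal the structure's extracted sequence; mismatches are
errors naming the structure and offset. Position numbering starts at 1
and can be shifted.

## Superposition

Single-pass Kabsch: the closed-form SVD solution of the least-squares
rotation with the reflection branch corrected to det(R) = +1, translation
from the centroids. No iterative outlier trimming and no ML covariance
weighting — the least-squares optimum is the well-defined, easily
verified reference behaviour, and superposition is a pluggable stage.
Matched atoms are those with identical names within the chosen atom set
(default backbone N, CA, C, O; Cα-only available) at mutually non-gap
columns; missing atoms are skipped. The transform is applied to all atoms
of the structure. The reference defaults to the first structure.
Degenerate inputs (fewer than 3 pairs, collinear clouds) are errors.

## Torsions

φ(i) = C(i−1)–N(i)–CA(i)–C(i), ψ(i) = N–CA–C–N(i+1), ω(i) =
CA–C–N(i+1)–CA(i+1), IUPAC sign, values in (−180°, 180°]. ω belongs to
residue i (the bond towards i+1), so ψ and ω are undefined at the
C-terminal side of a contiguous run and φ at the N-terminal side.
**Contiguity** is operationalized as peptide C–N distance < 2.5 Å; the
bonded distance is 1.33 Å, so the cutoff tolerates distorted models while
catching engineered or real chain breaks. χ₁–χ₄ follow the standard
atom-quadruple table (χ₁ = N–CA–CB–γ with the γ atom per residue type;
Pro has χ₁/χ₂ only; Ala/Gly none). Missing atoms yield UNDEFINED with a
log entry, never an error or a zero. Two-fold-degenerate terminal
dihedrals (Phe/Tyr χ₂, Asp χ₂, Glu χ₃) are reported raw, without symmetry
folding — no folding rule is assumed, and the choice is isolated here so
statistics stay interpretable.

Note one geometric fact the tests rely on: the signed dihedral is
*invariant* under reading the quadruple from the other end (reversal is a
proper operation); it is the mirror reflection that flips the sign.

## Circular statistics

Angles are stored in degrees; trigonometry converts locally. With mean
resultant length R̄, the circular mean is atan2 of the mean sine and
cosine and the circular sd is √(−2 ln R̄) (Mardia's dispersion), chosen
over min-arc alternatives for its standard asymptotics and isolated
behind one function for easy swap. A sample with R̄ ≤ 1e−12 (e.g. an
antipodal pair) has no defined direction: the primitive raises, and the
aggregation layer reports the count with mean/sd as NA. For tightly
clustered samples (range < 10°) mean and sd agree with linear statistics
to < 0.01°, which the tests assert. Per-position summaries are produced
globally and, when the Structure list assigns families, per family.

## Cartesian statistics

For each atom name present in ≥ 2 structures at a position, the per-atom
fluctuation is the population RMS deviation about the mean position
(divide by N, the RMSF convention); the row value RMS-combines per-atom
fluctuations, i.e. averages the *squared* fluctuations before the root —
averaging after the root is the documented alternative and would differ
only when atoms fluctuate unequally. Backbone = {N, CA, C, O}; sidechain
= all other heavy atoms; OXT is excluded from both so the terminal
carboxylate does not inflate either group. Gly-only positions therefore
report sidechain fluctuation exactly 0 — the classic zero points in
sidechain profiles. Atoms seen in a single structure contribute to the
mean B-factor but not to the fluctuation.

## Clustering

The distance between two conformers is the **mean** circular distance
over the selected (position, angle) variables defined in both structures
at shared non-gap columns. The mean keeps the value in degrees and
directly comparable to the radius parameter; RMS and max aggregation are
provided as configurable alternatives since the aggregation is a genuine
design choice. Pairs are compared on the intersection of their defined
variables; a warning is logged when the count varies by more than 50%
across pairs. Complete (maximum) linkage is computed by a direct O(n³)
agglomeration with deterministic tie-breaking by smallest contained leaf
index; the test suite cross-checks merge heights against an independent
library implementation on tie-free random matrices. The flat cut
*refuses* every merge with height ≥ radius, so the radius is literally
the minimum complete-linkage distance allowed between surviving clusters;
a merge at exactly the radius is refused. Cluster ids are 1-based by
decreasing size (ties by smallest member index). The tree is written as
Newick with node heights equal to merge heights and branch length =
parent height − child height, making the tree ultrametric with leaves at
height 0.

## Synthetic ensembles

The builder grows chains atom-by-atom from internal coordinates
(NeRF-style placement) with idealized geometry: N–CA 1.458 Å, CA–C
1.525 Å, C–N 1.329 Å, backbone angles 111°/117°/121°, carbonyl O placed
anti to the next amide N, CB placed with the improper C–N–CA–CB = −122.6°
fixing the L-configuration. Sidechains are built along the χ-defining
atom chain only (branch and ring atoms are omitted); every targeted
torsion is placed exactly, so recomputing torsions reproduces the targets
to ~1e−13°. Ensembles draw per-structure torsions from a family center
plus wrapped-normal noise applied **in torsion space**, where the
clustering metric lives, so family separation is controlled exactly.
Defaults emulate the canonical two-state benchmark: two families, 10
structures each, centers 120° apart in φ/ψ over a 5-position stretch,
within-family sd 5°, clustered at the default 60° radius. What this does
*not* emulate: real sidechain rotamer correlations, anisotropic
B-factors, missing density, sequence heterogeneity across the ensemble,
and Cartesian-space noise — so passing tests demonstrate correctness of
the statistics, not robustness to crystallographic artifacts.

One consequence of torsion-space noise worth knowing when reading
Cartesian profiles: a local torsion perturbation moves everything
downstream of it (lever effect), so fluctuation peaks can sit at or
downstream of the perturbed stretch after global superposition, rather
than strictly inside it.

## Numerical choices and limitations

* Angles compare at 1e−9° for pure geometry, 1e−6° for build→measure
  round trips (PDB text carries only 3 decimals per coordinate, ~0.05°;
  in-memory round trips are exact).
* Kabsch collinearity is detected by rank with tolerance 1e−8; the
  orthonormality of returned rotations holds to 1e−9.
* Problem sizes in tests and the acceptance script (ensembles of 6–20
  structures of 20 residues, 8-leaf random linkage instances) were chosen
  as the smallest sizes at which every property is non-trivially
  exercised; all stages are linear or cubic in ensemble size and run in
  seconds.
* The pipeline writes all numeric tables at fixed 4-decimal precision,
  which is what makes repeated runs byte-identical.
* mmCIF input, gzip, automatic downloads, de-novo sequence alignment,
  ML/iterative superposition, symmetry folding of degenerate χ angles and
  distribution plots are out of scope; the tables contain everything the
  plots would show.
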