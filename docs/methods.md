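# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `dsbdesign`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Structures, numbering, alternate locations

Structures are read from PDB files (gemmi backend) into a plain
chains → residues → atoms hierarchy with author residue numbering
(1-based, insertion codes honoured); every engineered position (e.g. 63,
93, 104 in the motivating hexamer) is interpreted in this scheme. Alternate
locations are resolved to the highest-occupancy conformer, ties broken by
file order — deterministic and standard. HETATM groups are kept and
flagged; hydrogens are retained because the d2 catalytic distance is
defined to a carboxyl proton. Ensembles travel as multi-model PDB with an
identical atom roster per MODEL; a mismatch aborts with the first differing
atom named. Writing uses an in-package fixed-width record writer so that
ATOM/HETATM/MODEL records mirror the containers exactly.

## Global sequence identity

Needleman–Wunsch global alignment with BLOSUM62, gap open 10, gap extend
0.5 (Biopython `PairwiseAligner`); identity = identical aligned pairs /
gap-free aligned columns × 100. This is the convention under which
template–target identity is conventionally quoted for homology modelling;
the denominator choice matters only when gaps are present. Both SEQRES and
observed-residue template sequences are supported (SEQRES preferred when
present, since a deposited model's unresolved loops would otherwise deflate
the column count).

## Symmetry detection

* **Chain superposition.** Chains are matched residue-by-residue through a
  global sequence alignment of their extracted sequences (this tolerates
  the ~98%-identical template case), then superposed on aligned Cα pairs by
  the Kabsch algorithm; at least 20 aligned pairs are required. The
  rotation angle is θ = arccos((tr R − 1)/2).
* **Equivalence classes.** Chains with pairwise Cα RMSD < 2.0 Å (default,
  configurable) are equivalent; the relation is closed transitively
  (union–find), so "equivalence" is exactly an equivalence relation at the
  stated threshold. 2.0 Å is permissive enough for relaxed/heated models.
* **Cyclic order.** Within the largest class, each inter-chain rotation
  contributes (angle, axis). Axes are grouped by collinearity (10°
  tolerance); the cyclic order is inferred from the *dominant-axis group*
  as n = 360°/g, where g is the smallest non-trivial angle, verified
  against every angle in the group (all within 10° of a multiple of
  360°/n). Restricting to one axis matters: a trimer of C2 dimers shows
  angles {120°, 240°} about the principal axis plus 180° rotations about
  in-plane axes; the raw angle multiset would be consistent with C6, the
  dominant-axis reading gives the intended order 3.
* **Dimer partition.** "Tight dimer" is operationalised as the
  maximum-weight pairing of chains under inter-chain Cα–Cα contact counts
  (contact: < 8 Å). For ≤ 8 chains the matching is exact (enumeration);
  beyond that a greedy descent is used. Zero-contact pairs never pair; ties
  break lexicographically. The contact-count definition is this package's
  operationalisation — the source literature labels bridges
  inter-/intra-dimer without defining the dimer interface extent.

## Disulfide scanning

* **Window.** All unordered residue pairs with 3.0 Å ≤ d(Cα–Cα) ≤ 7.5 Å,
  excluding sequence-adjacent pairs (sterically impossible) and residues
  with incomplete backbones. Inter- and intra-chain pairs are both kept.
* **Side-chain model.** Backbones are held fixed (this is a screening
  stage, not refinement). Cβ is the observed atom when present, else an
  ideal Cβ (1.53 Å, N–Cα–Cβ = C–Cα–Cβ = 110.5°, L-configuration; the
  chirality sign is validated against reference amino-acid geometry in the
  tests). Sγ is placed at 1.81 Å, Cα–Cβ–Sγ = 114°, with χ1 swept over a
  10°-step grid (36 rotamers per residue, 1296 combinations per pair) —
  an exhaustive small grid rather than a rotamer library.
* **Score.** For each χ1 combination,
  `score = w_d·((d_SS−2.05)/0.05)² + w_a·Σ((θ−104.15)/5)² + w_x·((|χ_SS|−87)/10)²`,
  minimised over the grid. The ideal values (2.05 Å, 104.15°, ±87°) are the
  textbook disulfide geometry; the denominators are roughly the observed
  spreads of each coordinate in native disulfides, making the three terms
  commensurate. Weights default to (1, 1, 1); lower scores are better and
  0 is exactly textbook. The score is a transparent geometric screen — a
  deliberate design choice over a learned predictor: reproducible,
  dependency-free, and auditable term by term.
* **Ranking.** Candidates with score ≤ cutoff (default 50; `None` keeps
  all) sorted by (score, d\_Cα, residue ids) — deterministic output.
* **Locality and multiplicity.** Same chain → intra-subunit; dimer mates →
  intra-dimer; otherwise inter-dimer. Multiplicity counts the same-position
  images of a pair on equivalent chains that also satisfy the Cα window —
  3 for a C2-interface pair in a trimer-of-dimers hexamer, 6 for an
  intra-subunit pair replicated across six equivalent chains.

## Ensemble analytics

* **Kabsch.** Weighted least-squares rigid superposition via SVD with the
  determinant sign correction, so the rotation is always proper; degenerate
  (collinear, < 3 points) input raises.
* **RMSD series.** Each frame is superposed onto the reference (frame 0 by
  default) on the chosen selection (Cα default; backbone/all available) and
  the RMSD recorded. Distances for catalytic analysis are deliberately
  *not* superposed — they are frame-internal.
* **RMSF.** Frames are superposed onto the iterated mean structure (two
  passes: fit to first-pass mean, re-mean, re-fit) to remove reference
  bias; `rmsf_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩)`, RMS-aggregated within a residue
  for multi-atom selections. A single-frame ensemble has no defined
  fluctuation and raises. Mass weighting is off by default.
* **B-factor.** `B = (8π²/3)·rmsf²` (isotropic Debye–Waller), enforced as
  an exact invariant of the profile container. Averages are over the Cα
  selection by default.
* **Fold change.** Mean-B ratio high/low plus the per-residue ratio
  vector. On harmonic ensembles the ratio converges to the squared
  amplitude ratio, which is the quantitative content of "temperature
  inflates flexibility less in the rigidified variant".

## Catalytic geometry

Strict inequalities at the thresholds (d1 < 3.45 Å AND d2 < 2.5 Å; boundary
values are non-productive), matching the "less than" definition of the
productive complex. The productive fraction is monotone non-decreasing in
both thresholds by construction. The "#" (neighbouring-subunit) endpoint is
resolved explicitly by the caller; a helper picks the symmetry mate nearest
the partner atom in frame 1. If the C-terminal carboxyl proton is absent
from the topology the operation errors rather than silently substituting a
heavy atom. Histogram summaries use left-closed right-open bins aligned to
zero (width 0.1 Å default); the overlap coefficient is OVL = Σ min(p, q)
over the union bin range of the two normalised histograms.

## Synthetic generators: what they emulate, and what they don't

All fixtures are pure functions of their parameters and seed (byte-identical
reruns, asserted in tests).

* **Helix chains.** Ideal poly-ALA α-helices (φ = −57°, ψ = −47°, ω = 180°,
  standard bond geometry) chained by internal-coordinate placement; the
  exact screw axis of the residue-to-residue transform is aligned with z.
  This reproduces, rather than hard-codes, the canonical ~1.5 Å rise,
  ~100°/residue twist and 3.8 Å Cα–Cα step.
* **Oligomers.** Copies on a ring (default radius 16 Å) under exact Cn
  about z; with dimerisation each subunit gets a C2 mate (axis x, interface
  half-gap 5 Å), giving the trimer-of-dimers architecture for n = 3. The
  symmetry is exact by construction, so symmetry-detection round-trips are
  sharp tests.
* **Planted interface pairs.** The base chain is translated along the
  dimer-interface normal (or radially, for a pure ring) before
  symmetrisation so that one same-position cross-chain Cα pair lands on the
  requested separation exactly; the defaults used in tests (4.5, 5.6,
  6.5 Å) sit inside the scan window at the separations typical of
  engineered bridge sites. Translating *before* symmetrisation keeps the
  planted symmetry exact.
* **Harmonic ensembles.** Reference + i.i.d. per-axis Gaussian noise with
  per-residue amplitude σ_i (all atoms of a residue share σ_i); temperature
  is emulated purely as an amplitude multiplier. This is the minimal model
  for which RMSF and B-factor have closed forms (RMSF = σ√3, B-ratio = k²
  for amplitude ratio k), making parameter recovery an exact acceptance
  test. Optional per-frame random rigid motion (full SO(3) rotation,
  ±5 Å translation) verifies that superposition-based analytics are blind
  to it. What this model does **not** have: anisotropy, inter-residue
  correlation, anharmonic/multi-well dynamics, or solvent effects — so
  passing tests demonstrate estimator correctness, not force-field realism,
  and absolute B-values or fold changes from real MD are out of reach by
  design.
* **Distance series.** Gaussian with stated mean/SD, truncated at zero
  (negligible for the means/SDs used, ≥ 10σ from zero).

## Problem sizes and numerical choices in the checks

* RMSF convergence is checked at 10,000 frames on a 400-residue chain:
  superposition onto the sample mean absorbs ~6/(3N) of the noise variance
  (six rigid degrees of freedom), and 400 residues keep that bias an order
  of magnitude below the 2% per-residue band being verified.
* The productive-fraction check uses 100,000 frames (sampling SE ≈ 0.0008
  against a 0.005 band); histogram-overlap checks use 200,000 samples at
  bin width 0.1 Å, where binning broadens the empirical OVL by ≲ 0.015
  relative to the continuous min-density integral.
* Brute-force cross-checks (pair enumeration, exhaustive χ1 grids, exact
  dimer matching) run on fixtures up to ~1,000 residues / 8 chains.
* Kabsch agreement with an independent numerical minimiser is asserted at
  1e-6 RMSD — the level at which general-purpose rotation solvers
  themselves are reproducible at these coordinate magnitudes.

## Known limitations

* The scanner models cystine geometry on a fixed backbone; it does not
  repack neighbours, estimate ΔΔG, or filter by local flexibility.
* Symmetry classification covers cyclic order plus a dimer partition; no
  dihedral/helical point-group assignment and no crystallographic symmetry.
* Trajectory input is multi-model PDB only; binary MD formats are out of
  scope.
* The pipeline consumes or synthesises coordinate ensembles; it does not
  run molecular dynamics or QM/MM itself.
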