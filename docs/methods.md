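# Methods

## Model

A protein chain is represented by its Cα trace x₁…x_n (Å, residue
order). The comparison object is the pairwise distance matrix
D_ij = ‖x_i − x_j‖, rendered as an 8-bit image by

    img = int(255 · (D − min D) / (max D − min D)),

with `int` truncating toward zero. The minimum maps to 0 and — because
the ratio is computed before the multiply, so the maximum divides to
exactly 1.0 — the maximum maps to exactly 255. A zero-range (constant)
matrix, including the 1×1 case, maps to all zeros; this keeps the
pipeline total on degenerate inputs instead of raising on division by
zero.

Keypoints are difference-of-Gaussians scale-space extrema of the image;
each is described by the standard 128-bin gradient-orientation histogram
(4×4 spatial cells × 8 orientations). Detection and description are
delegated to scikit-image's SIFT implementation with its stock
hyperparameters (upsampling 2, 8 octaves, 3 scales per octave,
σ_min 1.6, σ_in 0.5, DoG contrast threshold 0.04/3, edge threshold 10);
all are exposed in `SiftParams` and recorded in every database so a
search always uses the parameters its database was built with. The
implementation's standard illumination handling (0.2-clamp and
renormalize) is kept, and descriptor rows are then L2-normalized to unit
length, which is what lets cosine similarity be read off a plain dot
product. Descriptor entries are non-negative before and after
normalization. Rows with zero norm (theoretically possible, never
observed) are dropped rather than normalized.

## Matching

For query and target feature matrices Q (n₁×128) and K (n₂×128) with
unit rows, M = Q·Kᵀ holds every pairwise cosine similarity. With
threshold t ∈ [0, 1): entries with M ≤ t are discarded; a query row with
any surviving entry contributes 1 to the match count m and its best
margin max(M_row) − t to the match score s. Consequently 0 ≤ m ≤ n₁,
s ≤ m·(1 − t), and m = 0 ⇔ s = 0. The literal "subtract t everywhere"
reading of thresholding would let a row count as matched with no single
similarity above t (or fail with one); the masked form used here is the
only semantics consistent with "at least one above-threshold match per
counted row", and an explicit scalar-loop reference implementation is
kept in the test suite and acceptance script to pin the equivalence.

The comparison is deliberately asymmetric (m counts query rows);
swapping query and target can change (m, s). Similarities are
accumulated in 64-bit floats regardless of storage precision so sums are
reproducible across platforms. The per-row best is the maximum value;
which target keypoint achieved it is not recorded, as the method returns
no residue-level correspondence.

**Default threshold t = 0.9.** Non-negative unit descriptors give random
pairs cosine similarities concentrated well below 0.9 (generic
helical-banding descriptors occasionally exceed it, which is why scores
are standardized rather than used raw). The default is validated by the
flexible-linker separation experiment passing at it, and is exposed on
every CLI command.

## Search and ranking

A database stores one feature matrix per structure, all built with one
`SiftParams`. A search computes (m, s) against every entry, standardizes
each of the two statistics over the full comparison population —
z = (x − mean)/σ with the population σ; a zero-variance population
(including size 1) standardizes to zeros — and ranks by z_sum = z_m +
z_s. The population is the current search (query versus every database
entry), not a precomputed background: this needs no global calibration
and directly matches "rank the results of one search". Ties on z_sum
break by m descending, then target id lexicographically, making output
order deterministic. Top-k truncation happens after z-scores are
computed, so it never changes them. Self-hits are kept by default
(self-retrieval is a core correctness check); `--exclude-self` removes
the entry matching the query id before the population is formed.

A query with zero features returns an empty hit list flagged
"no features" — low feature count is the method's characteristic
false-negative mechanism, and pretending to rank with no evidence would
be misleading. Queries with fewer than 5 features are flagged as
low-information but still ranked.

The database archive is a zip of `.npy` members written with fixed
timestamps, so rebuilding from identical inputs is byte-identical.
Descriptors are stored as float32 (unit norm survives the round trip
well within the 1e-6 tolerance the matcher enforces).

## Synthetic structures

The generator provides the desk-scale test surface; every fixture is a
deterministic function of its arguments.

* **Helix** — textbook α-helix parametrization: radius 2.3 Å, rise
  1.5 Å/residue, 100°/residue, plus Gaussian jitter σ = 0.05 Å (seeded).
  Consecutive Cα–Cα distances come out at 3.8 ± 0.2 Å.
* **Coil** — self-avoiding random walk, step 3.8 Å, exclusion radius
  3.0 Å. Only conformational variability is needed from it, not loop
  physics.
* **Helix bundle** — 2 helices below 60 residues, 3 from 60 up, with
  seed-driven segment split (Dirichlet), inter-helix spacing 8–12 Å,
  stagger, and ±20° axis tilts, packed antiparallel. The architecture —
  not merely the jitter — depends on the seed, so different seeds give
  genuinely different folds with distinct distance-image patterns.
  Early versions varied only the jitter; the resulting folds were
  indistinguishable to the detector, which is itself the expected
  behavior for near-identical structures.
* **Two-domain chain** — two bundles (fixed by their own domain seeds)
  joined by a self-avoiding linker; the chain seed randomizes only the
  linker walk and the rigid placement (random rotation + 3.8 Å offset)
  of the second domain, resampled up to 100× until no inter-domain Cα
  pair is closer than 2 Å. Diagonal distance-matrix blocks are invariant
  across chain seeds to rigid-motion round-off (< 1e-9 Å; the float
  rotation perturbs the last bits, so bit-identity is not claimed),
  while off-diagonal blocks change — the decomposition that makes the
  method linker-robust.

**Study conditions for the robustness experiments:** 80-residue domains
(typical natural domain size, and large enough that fixture images carry
feature counts in the tens — comparable to structures the method detects
reliably, whereas much smaller fixtures drift toward the few-feature
false-negative regime) with a 10-residue linker; a database of the
reference fold plus four unrelated folds; ten re-linkered queries. The
ten-structure self-retrieval database mixes six bundles and four
two-domain chains of 60–170 residues.

What the fixtures do **not** emulate: real side-chain packing, β-sheets,
sequence-dependent geometry, predicted-model error, and genuine IDR
ensembles. Passing the desk-scale experiments shows the pipeline's
mechanics — rigid-motion invariance, diagonal-block stability, ranking —
not proteome-scale retrieval accuracy on real structures.

## Structure parsing choices

First model of multi-model (NMR) files; first chain in file order unless
a chain is named; alternate locations resolve to the highest-occupancy
conformer (ties: first encountered); residues without a Cα (and CA-named
calcium ions, excluded by element) are skipped with a logged count.
Trace order follows Cα record order, not residue numbering — insertion
codes and negative residue numbers therefore need no special casing.
PDB, mmCIF, and their gzipped forms are read via gemmi.

## Numerical and degenerate-input choices

* Images below 8 px on a side are rejected as degenerate (too small for
  the scale space); flat images yield zero features, which is a valid
  result, not an error.
* The keypoint `response` field is carried in the schema but filled with
  0.0: the detector backend does not expose DoG responses, so the
  optional `max_features` cap keeps the first k keypoints in detection
  order instead of the k strongest.
* Unit-norm preconditions are enforced at 1e-6; distance-matrix
  rigid-motion invariance is asserted at 1e-9 Å.
* Database search reduces in manifest (build) order, so results are
  independent of any future parallelization across entries.

## Known limitations

Feature-poor structures (small, extended, or highly regular chains whose
distance image is a smooth ramp) produce few or no keypoints and cannot
be retrieved — the search flags them instead of guessing. Scores are
search-relative (z-scores over the current population), so they are not
comparable across databases and carry no E-value-style significance.
Cosine similarity at a fixed threshold is coarser than ratio-test
matching; the z-score standardization compensates at ranking level but
individual (m, s) pairs for unrelated structures of similar size can be
close.
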