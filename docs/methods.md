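# Methods

`ppiscreen` re-implements, as an open and testable pipeline, a screening
strategy for finding small-molecule blockers of a protein–protein
interaction: locate the interface *hot spots* of a receptor–partner complex,
triage docked poses by their interactions with those hot spots, label the
pose population into Best and Worst classes by three energy-related
properties, and train a ligand-based filter-ensemble classifier that
generalizes the split to arbitrarily large libraries. The motivating system
is the JUNO–IZUMO1 egg–sperm recognition complex, with JUNO as the receptor,
but nothing in the code is specific to it.

## Frozen virtual alanine scanning

Each interface residue of the receptor is virtually mutated to alanine by
deleting its side-chain atoms beyond the C-beta while keeping every
remaining atom exactly in place: no minimization, no hydrogen rebuilding,
and no rotation about the C-alpha/C-beta bond. The rationale for the frozen
convention is that the scan should interrogate the interactions present in
the deposited crystal structure, not a relaxed variant of it. Under frozen
coordinates the binding-affinity loss attributed to a residue ("delta
affinity", kcal/mol) is *exactly* the summed pairwise attraction between
the deleted atoms and the partner side — the additivity the test suite
verifies to 1e-9 kcal/mol. Glycine and alanine report 0 by convention
(nothing beyond C-beta to delete). Residues with delta affinity at or above
a threshold — default 4 kcal/mol — are called hot spots.

The pairwise potential is deliberately simple and fully declared, because
the original scan in this line of work was run with commercial scoring
functions whose forms are not public:

* Lennard-Jones 6-12 with the minimum at the sum of Bondi radii and
  geometric-mean per-element well depths (kcal/mol);
* Coulomb with distance-dependent dielectric eps(r) = 4r and coarse
  residue-template partial charges (hydrogen charge folded into the bonded
  heavy atom; unlisted atoms are neutral);
* interaction cutoff 6 Å (configurable in `EnergyParams`).

Absolute delta-affinity values from this potential are therefore *not*
comparable to any commercial package's numbers; the procedure (frozen scan,
additive loss, thresholded hot-spot call) is the reproducible object. The
hot-spot list a given structure yields is whatever the threshold produces —
the package does not hard-code an expected count.

Interface residues are defined geometrically — a receptor residue with any
heavy atom within 4.5 Å (configurable) of a partner heavy atom — replacing
the curated interface lists of external structure databases so the pipeline
has no network dependency.

## Pose interaction profiling

Three quantities summarize a docked pose, mirroring the triage properties
used with docking output (the docking score itself is always ingested,
never computed):

* **Hydrogen bonds.** Any receptor N/O/S paired with a ligand N/O/S at
  donor–acceptor distance ≤ 3.5 Å. When explicit hydrogens are present the
  best D–H···A angle must reach 120°; hydrogen-free structures are judged
  on distance alone. The criterion is geometric and configurable
  (`GeometryParams`); the upstream work used an interaction-typing engine
  whose exact geometry is unpublished.
* **Attractive van der Waals contacts.** Heavy-atom pairs whose separation
  over the sum of their van der Waals radii lies in [0.89, 1.30] — the
  common "good contact" window: closer is a clash, farther is not a
  contact. The per-residue partition of the count supports the
  required-interaction criteria below.
* **Buried surface area (BSA).** SASA(receptor) + SASA(ligand) −
  SASA(complex), clamped at zero, summed over both partners (the two-sided
  convention; the one-sided value is half this for near-symmetric burial).
  SASA is Shrake–Rupley with probe 1.4 Å and a 960-point golden-spiral
  lattice per atom. The lattice is deterministic, and each atom's lattice is
  anchored to a local frame built from its two nearest neighbors, which
  makes surface areas covariant under rigid motion: rotating the whole
  complex changes BSA only at floating-point level instead of lattice
  level. Isolated-atom SASA agrees with 4·pi·(r+probe)^2 to < 1%, and the
  two-sphere BSA agrees with the closed-form spherical-cap solution to
  ~0.9% at the default lattice.

## Criteria, labeling, and ranking

*Required-interaction criteria* demand an H-bond to ARG87 plus attractive
VDW contact with a named residue set. Three presets ship: the full site
(TYR44, GLU45, MET83, LEU81, TYR147), sub-site A (MET83, LEU81, TYR147),
and sub-site B (TYR44, GLU45, TRP62). TRP62 appears only in sub-site B
(demanding it across the full site rejects almost every pose) and LYS163 in
none (too distant from the rest of the site). `passes_criteria` is monotone:
adding interactions can never turn a pass into a fail.

*Best/Worst labeling* uses disjoint threshold regions in (docking score,
BSA, VDW count) space: Best requires score < −3 kcal/mol, BSA ≥ 750 Å², and
≥ 250 contacts; Worst requires score ≥ −1, BSA ≤ 600, and ≤ 150. The strict
inequality on the Best score bound is intentional and tested (a score of
exactly −3 is neither). Threshold membership — not a quantile rule — is the
class definition.

*Ranking* sums each record's rank on the three properties (score ascending,
contacts descending, BSA descending; ties share the better rank), ordering
by the rank sum with deterministic tie-breaks (docking score, then molecule
id). A rank-sum was chosen as the reproducible surrogate for the original
expert visual inspection, which admitted exceptions no algorithm should
silently reproduce; permutation-invariance of the output is tested.

## Descriptors

The classifier consumes any real-valued descriptor matrix. The shipped
descriptor set is RDKit's full 2D registry (~210 constitutional,
topological, and physicochemical descriptors), computed on canonicalized
structures so equivalent SMILES spellings produce identical rows. The
ordered name list is hashed into a manifest embedded in every trained
model, and scoring refuses tables missing a needed descriptor. The original
study computed 206 descriptors with a commercial package whose identities
are unpublished; equivalence with that set is neither possible nor claimed
— only the algorithmic surface (a molecules × descriptors matrix) matters
downstream. Pruning removes zero-variance columns and, from each pair with
|Pearson r| > 0.99, the later-ordered column; it is order-stable and
idempotent. An optional molecular-weight floor (350 g/mol) mirrors
screening restricted to molecules large enough to span a whole binding
site.

## The ISE filter-ensemble classifier

A *filter* is a conjunction of 1–4 descriptor-range clauses; a molecule
passes if every clause interval contains its value. Training searches the
space of filters stochastically with iterative elimination:

1. Every descriptor is split into up to 10 equal-frequency bins, fitted on
   the training split only. Clause intervals are unions of adjacent bins;
   intervals touching the outermost bins are open-ended, so test values
   beyond the training range still satisfy them.
2. Each iteration draws 2,000 random candidate filters from the pool of
   available (descriptor, bin) values and scores each by its training
   Matthews correlation coefficient (passing = predicted Best).
3. (descriptor, bin) values appearing in the bottom-scoring 25% of
   candidates at ≥ 2× their expected share (and ≥ 8 total appearances) are
   eliminated from the pool. In practice this prunes the bins
   anti-correlated with the Best class first, narrowing later sampling to
   the discriminating region of descriptor space.
4. The loop runs a fixed 50 iterations; elimination becomes a no-op once
   the pool is stable, and the remaining iterations keep sampling the
   narrowed space — which is where most surviving filters are found, so the
   search is not terminated at pool stability.
5. Candidates whose training MCC reaches the floor (default 0.7, matching
   the per-filter quality range reported for this kind of model) survive;
   survivors are greedily deduplicated, best first, dropping any filter
   whose clause-set Jaccard overlap with a kept one is ≥ 0.5.

All randomness flows from one integer seed; the same table and seed
reproduce a byte-identical serialized model. Training that yields no filter
at the floor returns an empty model with a warning rather than an error, so
callers can distinguish "nothing separable" from misuse.

The **molecular index** of a molecule is (n_pass − n_fail)/n_filters in
[−1, 1], unweighted by default. An MCC-weighted variant is available behind
`ISEParams(mcc_weighted_index=True)` but off by default: the unweighted form
matches the stated pass/fail semantics and bounds, and weighting adds a free
parameter without a principled calibration here.

**Cross-validation** is stratified k-fold (default 5): each fold's model is
trained on the remaining folds (binning included), every molecule is scored
exactly once as test data, and the final model is the deduplicated union of
the per-fold filter sets. The **enrichment curve** counts true positives
(Best) and false positives (Worst) at or above each observed index
threshold (plus −1); TP/FP with no false positives is reported as an
explicit infinity sentinel, never dropped. The screening **cutoff** is the
smallest threshold whose TP/FP reaches a requested enrichment (pipeline
default 3.0); an unattainable request raises an error reporting the maximum
achievable.

## Synthetic data

The generators define the conditions under which the pipeline is tested:

* **Toy complexes** place receptor residues as rigid five-atom clusters
  25 Å apart; planted H-bonds put a ligand nitrogen 2.6 Å below the
  residue's backbone oxygen (inside the H-bond cutoff, below the VDW ratio
  window, so the two detectors stay independent), and planted contacts fan
  up to 8 ligand carbons at exactly the mid-window carbon–carbon distance
  around the C-beta, angled so no other cluster atom falls in the window.
  Every generator returns a truth ledger; recovery tests assert against the
  ledger, not re-derived values. The geometry is intentionally unphysical —
  it exercises the detectors, not protein stereochemistry — so passing
  tests show detector correctness, not realism of real-structure output.
* **Pose tables** draw records inside the Best region, the Worst region,
  or strictly between them, so threshold labeling recovers the planted
  labels exactly. The default 137-record table splits 68/69, the learning
  set size used in this workflow.
* **Learning sets** are standard-normal noise per descriptor with the Best
  rows shifted by a stated effect size (default 2.0 pooled SDs, noise SD 1)
  on a stated number of informative descriptors (default 3 of 50). The
  normal noise model is a deliberate simplification — real descriptor
  marginals are heavy-tailed, discrete, and correlated — so recovery
  results bound what the algorithm can do on clean signal, not on real
  chemistry. Default sizes (68/69 molecules, 50 descriptors) keep the
  20-seed recovery and null studies at about a minute on one CPU.

Under these defaults the 20-seed study gives median pooled 5-fold test MCC
≈ 0.79 and median enrichment at the selected cutoff ≈ 3.4× the baseline
TP/FP (≈ 68/69 ≈ 0.99 at threshold −1); on pure-noise sets no seed of 20
produces a filter at the MCC floor that also attains pooled test MCC ≥ 0.3.
These numbers are recomputed, not asserted, by `scripts/acceptance.py`.

## Pipeline and provenance

`run_pipeline` executes enabled stages (simulate → hotspots → label → rank
→ train → screen) from one YAML config, validating every referenced path
before any stage runs. The single global seed is fanned out per stage by
hashing `"{seed}:{stage}"` (lower 31 bits of SHA-256), so toggling one
stage never perturbs another's randomness. The manifest records the config,
per-stage seeds, and a SHA-256 digest of every output; identical configs
reproduce identical digests, which the test suite checks byte-for-byte on
the serialized model.

## Numerical choices and degenerate inputs

* Bin edges at quantiles with duplicate edges merged; columns with fewer
  distinct values than bins get fewer bins, constants collapse to one bin
  with a warning and never enter the sampling pool.
* MCC returns 0 when any denominator factor is 0; an all-zero confusion
  matrix is an error.
* Clause intervals are lower-open/upper-closed, matching the bin
  assignment's `searchsorted` convention; equality cases are tested at the
  window edges and the strict Best-score bound.
* Ranking tie-breaks and filter ordering are fully specified (MCC, then
  clause tuples) so serialization is deterministic.
* Empty ligand atom sets, absent residues, missing chains, unknown
  elements, one-class label sets, and unattainable enrichment requests all
  raise typed errors rather than returning defaults.

## Known limitations

* The pairwise potential is a stand-in: hot-spot calls on real structures
  depend on its parameters and should be read as a ranking, not as
  free-energy-grade ΔΔG values. No protonation, repacking, or minimization.
* H-bond detection without explicit hydrogens cannot distinguish donors
  from acceptors and will accept donor–donor pairs at short range.
* BSA laterality conventions differ between tools; this package reports the
  two-sided sum.
* The ISE search is stochastic and the filter count varies with the seed;
  only statistics over seeds (medians, fractions) are stable quantities.
* The synthetic learning sets contain no descriptor correlation structure;
  performance on real, collinear descriptor matrices will differ (the
  pruning step exists precisely to blunt that difference).
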