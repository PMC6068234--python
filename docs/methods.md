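# Methods

This note documents the models, statistics, defaults and numerical choices
behind `tvp`, and what the synthetic data generator does and does not emulate.

## Scope and data model

The package profiles missense variants of a membrane transporter against two
kinds of structural evidence: static homology models of the transport cycle's
two endpoint conformations (inward-facing, IF; outward-facing, OF) and MD
trajectories started from those models.  Everything operates on Cα
coordinates in Å with author (1-based) residue numbering, matching
protein-change nomenclature such as R132W.  PDB input keeps ATOM records only
(first MODEL, altLoc blank/'A', insertion codes rejected — the intended
inputs are model-derived and have none).  Trajectories are multi-model PDB;
DCD is supported through MDAnalysis behind the same contract.  Superposition
is least-squares Kabsch over an explicit residue-equivalence selection:
equivalences are an input (fixed upstream by the family alignment), never
inferred by fragment alignment, which keeps the operation deterministic and
testable.

## Spatial clustering of variant sites

Variant Cα sites are joined when within a distance threshold (default 15 Å,
the conventional Cα contact radius at which neighboring helices and adjacent
turns are connected).  Clusters are the connected components of this graph.
Compactness is the geometric mean of component sizes — the member-count
reading, the only one that makes a geometric mean dimensionless — and density
is the number of within-cluster edges, which for a threshold graph equals the
total edge count.  Normalized density is their ratio.

Significance: site labels are re-drawn uniformly without replacement from all
residues with modeled Cα (not from sequence positions lacking coordinates),
and the add-one estimator p = (1 + #extreme)/(1 + n_perm) avoids p = 0.
Density statistics are tested in the upper tail (larger = more clustered) and
compactness in the lower tail, as documented in the API.  Default
n_perm = 9999 with a mandatory seed; an exhaustive mode enumerates all site
combinations for small problems.  Because the statistics are functions of a
finite graph they are discrete; ties are counted fully, which makes the
p-values valid but conservative when the distance spectrum is degenerate
(e.g. on perfectly symmetric synthetic bundles).  Calibration is therefore
checked on irregular geometry, where the add-one p-values are uniform to
within sampling error.

## Channel-lining electrostatic score

The channel lining is an input list of residue positions (derived upstream
from the 3D models).  A variant scores |pI(mut) − pI(wt)| if it lies on the
lining and 0 otherwise — off-lining variants are kept at zero rather than
dropped so every variant appears against the reference line.  pI values are
the Lehninger free-amino-acid table, shipped as package data and swappable;
the reference line is the maximum |pI(a) − pI(b)| over uncharged pairs
(1.41 pH units on this table, spanned by Cys 5.07 and Pro 6.48).  The score
is an absolute difference by design: the sign of a pI change is not
interpretable without knowing the local environment, while its magnitude
against the uncharged ceiling cleanly separates charge-involving
substitutions.  A geometric helper (`axis_lining`) can flag residues within a
radius of the inter-bundle axis; it is a labelled heuristic, not a
solvent-accessibility calculation.

## Stability calls

ΔΔG_fold values are consumed from per-conformation TSV tables (kcal/mol,
FoldX averaged-ΔΔG dialect); the energy function itself is out of scope.  A
variant's effective destabilization is ΔΔG_max over the available
conformations — destabilizing either endpoint can break transport — and the
call is ΔΔG_max ≥ m·k_B·T with m = 3 and T = 300 K by default
(3 × 0.0019872 × 300 ≈ 1.79 kcal/mol); both m and T are configurable.
Variants covered in only one conformation are flagged `partial`, not
rejected.  Class comparisons use Welch's unequal-variance t-test (robust to
the unequal spreads that ΔΔG distributions show), two-sided by default with
one-sided direction available; comparisons are emitted for ΔΔG_max and for
each conformation separately, since class separation can be
conformation-specific.

## Gate monitors and coupling classes

Four Cα anchors at the ends of the two bundle-threading helices define the
monitors: d₁ (A–B) tracks the intracellular opening, d₂ (C–D) the
extracellular opening, and six vertex angles among the anchors track the
relative helix orientation.  The six-angle enumeration is a shipped
convention — θ₁ is the angle at anchor A subtending C and D, then the
analogous vertices in a fixed order — and is fully overridable in
`MonitorDefinition`, since any triple convention is expressible there.
Angles are reported in degrees; coincident anchors raise a degenerate
geometry error rather than returning NaN.

In a functioning rocker-switch transporter the two gates move reciprocally,
so d₁ and θ₁ are strongly negatively correlated in the wild type.  Spearman
Cor(d₁, θ₁) classifies each variant's coupling with closed boundaries:
ρ ≤ −0.5 wild-type-like, −0.5 < ρ ≤ 0 diminished, ρ > 0 sign-altered
(decoupled).  The boundaries are part of the method definition and are tested
exactly.

Time-dependent series are autocorrelated, so naive t-tests overstate the
effective sample size.  Comparisons therefore subsample each series to 100
observations without replacement, compute Welch's t, and report the median
over 10 rounds; seeds are mandatory.  Monitor correlation matrices use
tie-corrected Spearman ρ with Benjamini–Hochberg adjustment across the upper
triangle as a single family; constant series yield NaN with a warning.

## Cartesian PCA and benign envelopes

PCA runs on flattened Cartesian Cα coordinates of pre-superposed frames
(sklearn-style estimator; full SVD, deterministic sign convention with the
largest-magnitude loading positive).  The reference set pools wild-type and
benign frames per starting conformation — this makes "the region defined by
benign variants" well-posed, and every variant is projected into that common
space.  The disordered-loop region is excluded from selections by supplying a
selection restricted to helices and their short connecting loops.

The 1D benign envelope is the shortest closed interval over order statistics
containing ⌈0.75·n⌉ reference scores (ties toward the lower interval); the 2D
envelope is the total-least-squares line through the reference cloud in a PC
plane with the narrowest closed residual band holding ⌈0.60·n⌉ points.  A
variant is *altered* on a component when its median score (1D) or median
signed residual (2D) falls strictly outside the envelope; envelopes are
closed sets, so a median exactly on the boundary is not altered.  Both masses
are configurable; 0.75/0.60 are the method's definition.

## Integration

The per-variant metric table (ΔΔG per conformation and maximum, channel
score, Kyte–Doolittle hydropathy change, per-PC altered flags per
conformation, coupling class) is discretized with strict thresholds: ΔΔG uses
the 3 k_BT cutoff, the channel score uses the uncharged reference line, the
hydropathy change uses a configurable cutoff (default 2.0, the scale of a
polar↔apolar swap on the Kyte–Doolittle scale); a value exactly at its
threshold is unaltered.  The wild type enters as a row of zeros/false flags.

Variant distances are Euclidean over standardized columns (sample std,
ddof = 1; constant columns contribute nothing; categorical columns one-hot
encoded; scattered missing values mean-imputed after rejecting all-missing
rows).  Embedding uses Kruskal's non-metric MDS: SMACOF majorization of
stress-1 from a deterministic classical-scaling start, so coordinates are
reproducible.  Grouping uses average-linkage agglomeration with scipy's
deterministic tie-breaking.  Genomics predictor scores are annotation only:
they are merged for side-by-side comparison but never enter the distances by
default.

## Synthetic data: what it does and does not emulate

The generator produces ideal α-helical Cα bundles (1.5 Å rise, 100°/residue
twist, 2.3 Å helix radius → consecutive Cα ≈ 3.83 Å) arranged antiparallel on
a ring, with a seeded pseudo-random sequence.  Trajectories add jointly
Gaussian amplitudes on two nearly independent geometric modes — one
translating anchor B along the gate axis (moves d₁), one moving anchor C
perpendicular to its arm (moves θ₁) — so the realized Cor(d₁, θ₁) approaches
a target; the realized value is always measured on the output and stored in
trajectory metadata, never assumed.  A constant shift along the distance mode
displaces a variant's PC median outside the benign envelope, emulating a
conformational-preference change.  ΔΔG tables draw from class-dependent
normals (defaults: benign 0, VUS 2, pathogenic 4 kcal/mol, σ = 1 — the
benign/pathogenic separation the method is designed to detect).  Variant
sites are sampled uniformly or within a ball (clustered pathogenic sites).

Not emulated: physically realistic force-field dynamics, side chains,
membrane environment, anharmonic transitions, or correlated noise along the
chain.  Passing tests on synthetic data therefore demonstrate the statistical
machinery (recovery of injected signal, calibration of nulls, monotone and
boundary behaviour), not that the biological signal in real trajectories is
of this magnitude or shape.

The bundled scenario simulates trajectories in duplicate (as replicate MD
runs would be) for the wild type and a per-class subset of variants, at a few
hundred frames each — sizes chosen so a complete scenario plus full pipeline
run finishes in about a minute on one CPU while leaving every statistic
comfortably estimable.

## Determinism and provenance

Every stochastic operation takes an explicit seed; the pipeline derives fixed
per-stage offsets from the configured seed.  Stage outputs carry provenance
headers (package version, stage, seed, key parameters) and contain no
timestamps, so reruns with identical configuration are byte-identical.

## Known limitations

* The permutation p-values are conservative under heavy statistic ties
  (degenerate geometries); no randomized tie-breaking is applied.
* The channel lining and the TM-helix ranges are inputs; the package supplies
  only labelled geometric heuristics for them.
* The pI score ignores local electrostatic context and protonation shifts.
* Non-metric MDS recovers configurations up to rotation/reflection; only
  distances and stress are comparable across runs, not raw coordinates.
* With few reference frames the benign envelopes are noisy; envelopes require
  at least 10 reference samples and the pipeline pools wild-type with benign
  runs to stabilize them.
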