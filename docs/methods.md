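# Methods

This note documents the models, conventions and numerical choices behind
each gipscape module, what the synthetic generators do and do not emulate,
and the problem sizes used by the test suite and `scripts/acceptance.py`.

## Degenerate-motif model

A signature is an ordered list of fixed-width position constraints compiled
from a PROSITE-style string: bracketed residue classes (`[MILVT]`), literal
residues, and single-position wildcards (`x`). Spaces, hyphens and commas
are treated as pure separators; this is the PROSITE convention and the only
reading under which the canonical GIP motif is well formed. There is no
variable-length syntax, so a match is a window of exactly 34 residues for
the canonical signature, whose sole literal is the invariant glycine at
element 24.

Matching semantics are deliberately conservative, as appropriate for
database screens where false positives are costly: the sequence alphabet is
the 20 standard residues plus X/B/Z/U; `X` satisfies only wildcard
positions, and B/Z/U never satisfy a class or literal. Matching is
case-insensitive; all overlapping matches are reported; classification
calls a sequence positive iff it has at least one match. Coordinates are
1-based inclusive everywhere (a match starting at residue 19 places the
glycine anchor at 19 + 24 − 1 = 42). The scanner is validated exactly
against a naïve per-window set-membership oracle (1,000 random
sequence/pattern pairs).

## Pairwise identity and neighbor joining

Only pairwise identities and a distance tree are consumed downstream, so
pairwise global alignment replaces multiple alignment. Scoring is BLOSUM62
with affine gap penalties, gap open 10 and extend 0.5 in the convention
where a gap of length L costs 10 + (L−1)·0.5; ties between co-optimal
alignments are broken by the aligner's deterministic enumeration order.
Scores are checked against an independent exhaustive-recursion oracle
(which is itself validated against literal enumeration of all alignments on
very short pairs).

Percent identity = identical columns / total alignment columns, gaps
included, terminal-gap columns excluded — a common tool convention,
documented here because no single standard exists. Distances are
d = 1 − id/100.

Neighbor joining follows Saitou–Nei with the Q criterion. Determinism
contracts: joins tie-break on the lowest index pair; a negative branch
length is clamped to 0 with the deficit added to its sister branch (the
standard practical fix; it never triggers on additive input). The final
three lineages are resolved around a trifurcating center, giving an
unrooted binary tree with 2n − 3 edges. On additive matrices the method is
consistent; the suite verifies exact topology (Robinson–Foulds 0) and path
lengths to 1e-9 on 100 random binary trees of 4–8 taxa, and cross-checks
topology against scikit-bio's independent NJ implementation. Newick output
quotes labels containing metacharacters or spaces (doubling embedded
quotes); round-trips preserve topology and lengths.

## CD unmixing

Raw ellipticity in millidegrees is converted to mean residue ellipticity by
the molar-residue convention MRE(λ) = θ_mdeg(λ)/(10·l·C·N_res), with l the
pathlength in cm, C the molar concentration and N_res the construct's
residue count (a required user input for truncated/tagged constructs). At
the reference instrument settings (0.1 mm cell, 28 μM, 70 residues), 10
mdeg ≈ 5.10e4 deg·cm²·dmol⁻¹.

Structure fractions solve

    min ‖θ − B f‖² + α‖f‖²   s.t.  f ≥ 0,  Σf = 1.

The sum constraint is hard so estimates are compositions; the ridge penalty
stabilizes ill-conditioned bases. This is the constrained
linear-combination idea of the classical CONTIN-style programs, with a
plain ridge over K aggregate classes instead of a smoothness operator over
dozens of reference proteins — adequate because only K = 3 aggregate
fractions are estimated. The solver enumerates supports of the active set
and solves each KKT system exactly: for small K this is the deterministic
global optimum of the convex QP (an earlier SLSQP-based solver was dropped
after converging to wrong active sets at the 1e-6 recovery tolerance).
`alpha="auto"` minimizes GCV, m‖r‖²/(m − edf)², over a log grid spanning
1e−4–1e10 on the sum-constrained reduced (nullspace) ridge problem,
ignoring the nonnegativity bound — standard practice; the bound is then
enforced at the chosen α. A rank-deficient basis with α = 0 raises an error
recommending regularization.

The packaged basis is synthetic: three smooth sums of Gaussians in λ
(182–260 nm grid) with the qualitative far-UV shapes of helix (positive
~192 nm band, negative 208/222 nm bands), sheet (positive ~196, negative
~217) and unordered structure (strong negative ~198). Its parameters live
in `data/cd_basis.json`, not in code. It is well conditioned and suitable
for validating the estimator; it is **not** a fitted reference set, so
fractions estimated for real spectra against it are illustrative, not
publishable estimates.

## Pore-pattern statistics

Inputs are pore-center coordinates (nm) in a rectangular window with area
reported in μm². Nearest-neighbor distances are plain Euclidean NN to any
other in-window point, with no edge correction by default (matching how
such measurements are typically read off micrographs). Two optional
corrections exist for sensitivity analysis: a border exclusion (points
within r of the edge are dropped as NN centers but kept as neighbors) and a
periodic ("torus") metric. Under the torus metric the Palm nearest-neighbor
law of the homogeneous Poisson process is exact, P(NN > r) = exp(−ρπr²), so
the pooled mean NN distance is an unbiased estimator of 1/(2√ρ); the law
check uses this metric with ρ = 100/μm² on a 2 μm² window, 500 replicates,
pooled over ~1e5 points, agreeing with 50 nm within 3 standard errors.

Bin fractions are computed over an explicit partition of [0, ∞) (first bin
closed, subsequent bins half-open), so they always form a probability
vector; overlapping or gapped partitions are rejected. "Distance between
adjacent pores" is read as center-to-center; an edge-to-edge reading can be
obtained by subtracting a pore diameter from the distances before binning.

The two-condition comparison is a seeded two-sided permutation test on the
difference of mean NN distance, p = (1 + #{|Δ_perm| ≥ |Δ_obs|})/(n_perm+1),
chosen because it needs no distributional assumptions and is exactly
calibrated for exchangeable samples (verified: empirical type-I error at
nominal 0.05 within [0.03, 0.07] over 1,000 null comparisons of iid draws
from the exact CSR NN law). **Caveat**: per-point NN distances taken
jointly from one pattern are not exchangeable — mutual-NN pairs share a
distance and neighbors are spatially correlated — which makes any pooled
permutation test anti-conservative on such input (measured ≈0.17 at
nominal 0.05 for CSR patterns of ~100 points). p-values computed on
per-point distances from single fields should therefore be read as
descriptive; calibrated inference requires replicate fields (permuting
field labels) or sparse subsampling.

Contour circularity is the isoperimetric ratio 4πA/P² via shapely (1 for a
circle, π/4 ≈ 0.785 for a square, lower for lobulated outlines);
self-intersecting polygons are rejected. No threshold for calling a nucleus
"irregular" is built in — any cutoff is a study-level choice, so the metric
is provided as plumbing only.

## Synthetic generators: what they emulate

All generators are pure functions of their spec including the seed.

* **Families.** The root is drawn uniformly within each constrained class
  and from a background composition (default uniform 1/20 — no composition
  statistics are available for the family being emulated) elsewhere;
  default flanks of 18/18 residues around the 34-residue core give
  70-residue proteins in the family's ~7–8 kDa range and place the match at
  residue 19, anchor at 42. Evolution along a tree (default: 10-leaf star,
  unit depth) applies Poisson(rate × branch length) substitutions per site
  with uniform replacement over the other 19 residues; no indels, no rate
  matrix, no codon structure — sufficient because only identity
  percentages are analyzed. With `preserve_signature`, constrained sites
  mutate only within their class, so descendant families classify positive
  at rate exactly 1.0. Rates of 0.2–0.5 yield reference-row identity
  ranges broadly comparable to the 41–78% divergence of the natural plant
  family; the generator is not calibrated beyond that.
* **Decoys.** Break-one decoys replace exactly one constrained position of
  a fresh conformant sequence with a residue outside its class and are
  scanner-verified non-matching; shuffles carry no such guarantee.
* **Spectra.** Noisy mixtures θ = Bf + N(0, σ²) per wavelength on the
  182–260 nm grid. Additive iid Gaussian noise only — no baseline drift,
  absorbance flattening or wavelength-dependent noise, so recovery results
  bound estimator error under a true model, not instrument pathology.
* **Point patterns.** CSR with Poisson counts; hard-core by dart throwing
  (rejection) capped at 1e6 attempts — adequate far from the packing limit,
  erroring with the attempted density otherwise; Thomas clusters with CSR
  parents (intensity defaulting to ρ/μ), Poisson(μ) offspring and isotropic
  Gaussian(σ_c) offsets, clipped to the window. Clipping loses offspring
  near the border, so a Thomas pattern's realized density falls a few
  percent below its nominal ρ. The simulated wild-type/mutant contrast in
  the acceptance script uses hard-core ρ = 50/μm², d_min = 60 nm (mean NN
  ≈ 93 nm, the regular regime) vs. Thomas at ρ = 87.5/μm² (1.75× denser),
  μ = 2, σ_c = 40 nm — mild clustering that drops the mean NN below 60 nm
  and inflates the 0–30 nm fraction, averaged over 20 fields of 2 μm².

## Pipeline and I/O

All residue coordinates are 1-based inclusive end to end; any half-open
arithmetic is internal and never serialized. FASTA I/O is Biopython-backed
(60-column wrapping, duplicate-ID and alphabet validation naming the
offending record). The JSON pipeline config is validated by a pydantic
schema and all referenced inputs are checked before any stage writes
(pre-flight), so a misconfigured run leaves no partial outputs. Stages
write to stage-scoped directories; the manifest records SHA-256 checksums
of every output, and identical config + seed reproduces identical
checksums, with timestamps confined to the log.

## Problem sizes and tolerances

Oracle and property checks run at: 1,000 scanner pairs (sequences ≤60 aa,
5–10 elements); 1,000 alignment pairs of length ≤8; 100 additive matrices
of 4–8 taxa (lengths to 1e-9); 20 noise-free + 200 noisy (σ = 2% of
spectrum max) CD recoveries (noise-free to 1e-6; noisy within 0.05 in
≥95%); 500 CSR fields for the NN law (3 SE); 1,000 permutation null tests
(n_perm = 199); 100 + 100 sequences for the classifier round trip. These
sizes make the full suite and the acceptance script each run in well under
a minute of CPU apiece while keeping every statistical band at its stated
width.

## Known limitations

* The signature screen is exact-match only; no PSSM/HMM scoring, no
  tolerance for single mismatches, no E-values.
* Identity percentages depend on the documented scoring and gap
  conventions; other tools' conventions will shift values by a few percent.
* The CD basis is synthetic; real-data fractions require a fitted
  reference basis and knowledge of N_res for the measured construct.
* Pore statistics assume already-extracted 2-D coordinates from tangential
  views; no image segmentation and no 3-D curvature correction.
* The permutation test's calibration caveat for within-field NN distances,
  above.
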