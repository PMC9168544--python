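# Methods

## Motif model and triad calling

Consensus motifs are compiled from a small grammar: `[ABC]` residue classes,
single-letter literals, `X` wildcards and one bounded gap `X(m-n)` per
pattern. Coordinates are 1-based with inclusive ends, matching how triad
residues are cited in the ferroxidase literature (E269 etc.).

Each motif's **anchor** — the element carrying the triad residue — is
identified structurally: the unique class that contains an acid (D or E) and
otherwise only the small substitutes A or G. In the three built-in motifs
this selects `[EA]`, `[DE]` and `[DEG]`. Compilation fails loudly when zero
or several candidates exist. A glycine at the `[DEG]` anchor of motif 3
counts toward completeness (the class is taken at face value) but each match
carries an `is_acidic` flag (D/E only) so downstream analyses can
distinguish the two.

Scanning reports *every* placement (overlaps allowed), sorted by start and
realized gap length. Non-standard letters (B, J, O, U, Z, X) satisfy only
wildcard and gap positions, never a residue class — the conservative
reading. Triad calling selects the maximum-cardinality set of matches with
anchors strictly increasing in M1 < M2 < M3 order (the triad is positional
in the MCO fold); ties are resolved toward the leftmost anchor tuple, so
calls are deterministic. The order constraint can be disabled. A sequence is
"considered" a candidate when completeness ≥ 2 (at least two of the three
motifs), the screening rule this classifier implements.

MCO hallmark detection (T1 Cu site, T2/T3 cluster) is configuration-driven;
the shipped defaults (`HCH`, `HXXHXH` His/Cys copper-ligand spacings) are a
documented extension — there is no canonical printed pattern for this
inspection step — and any grammar pattern may be substituted.

## Homology filters and the PSSM screen

Filter thresholds follow a literal reading of their sources: `>` thresholds
are strict (coverage > 60, identity > 30, alignment length > 175) and the
e-value *cutoff* is inclusive (≤ 1e-40). tblastn mode applies
coverage + e-value + identity; profile mode applies alignment length +
coverage (> 30%). Every rejection carries a reason string.

The profile screen is an ungapped log-odds PSSM rather than a profile HMM:
per-column scores are `log((count + pc·bg) / (n + pc) / bg)` with
pseudocount weight `pc` (default 1.0) and background `bg` (default uniform
1/20; an empirical composition may be supplied). Columns with > 50% gaps are
dropped before counting. This is a deliberate, testable stand-in: it
preserves the screen's structure (train on an alignment of LPR1-like
proteins, scan, apply the length rule) without insert/delete states, and no
score equivalence with any HMM tool is claimed. The score threshold is
exposed as configuration for the same reason. Window scoring is exhaustive
over all ungapped placements with leftmost tie-breaking; query coverage of a
profile hit is window length / profile length × 100.

## Phylogenetics

Maximum-likelihood inference is intentionally out of scope; the HGT claim
under test is *topological* and method-agnostic, so the pipeline uses the
simplest fully deterministic chain:

- **Distances**: p-distance over shared non-gap columns (pairwise deletion,
  which keeps small synthetic alignments usable), optionally
  Poisson-corrected, d = −ln(1 − p). Saturated pairs (p = 1) are clamped to
  p = 1 − 1/(2L) over L shared columns rather than erroring — an infinite
  distance would abort an otherwise informative matrix; zero shared columns
  do raise.
- **Neighbor joining**: classic agglomeration with two determinism
  guarantees: Q-criterion ties break on the lexicographically smallest pair
  of cluster representative labels (so the tree is invariant to input row
  order), and negative intermediate branch lengths are clamped to zero with
  the deficit shifted to the sister branch (total path lengths preserved).
  Additive matrices are recovered exactly; scikit-bio's NJ serves as an
  independent cross-check in the tests.
- **Midpoint rooting**: the root bisects the longest leaf-to-leaf path; ties
  break on the lexicographically smallest leaf pair. (Implemented directly —
  the bundled dendropy 5 `reroot_at_midpoint` returned a non-midpoint root
  on simple balanced trees, which the unit tests document.)
- **Bootstrap**: columns resampled with replacement, NJ rebuilt per
  replicate, bipartition frequencies reported. Bipartitions are keyed by the
  leaf set on the side away from the alphabetically first taxon; trivial
  splits have support 1 by definition.

**HGT consistency** on a rooted, labelled tree requires both: the ingroup
("plant") leaves are monophyletic, and the outgroup ("bacteria") leaves are
*not* — i.e. the plant clade is nested inside a paraphyletic bacterial
radiation rather than being its sister. A single transfer into the plant
stem predicts (true, true); two independent origins break monophyly;
vertical descent (or a root inside the plant clade) breaks nesting.

## Kinetics

A₅₆₀ converts to Fe²⁺ micromolar by Beer–Lambert with
ε₅₆₀ = 25,400 M⁻¹cm⁻¹ for the Fe²⁺–ferrozine complex; negative absorbances
clamp to zero with a warning. Oxidation rate is
(c_control − c_sample)/t in μM·min⁻¹; rates and background-subtracted
differences are clamped at zero and flagged rather than dropped, keeping the
substrate grid intact for fitting. Velocities are μM·min⁻¹ internally;
specific activities per mg protein are a presentation-layer scaling.

Michaelis–Menten fitting is unweighted nonlinear least squares
(`scipy.optimize.curve_fit`, positive-parameter bounds, xtol 1e-8) started
from a Hanes–Woolf regression of S/v on S (points with S ≤ 0 or v ≤ 0
excluded; a (median S, max v) fallback covers degenerate regressions).
Replicates are pooled into a single residual vector by default, matching
how multi-preparation assay sets are usually combined; per-replicate fits
are available by slicing the series. Standard errors come from the
Jacobian-based covariance. Noiseless data on any grid spanning K_M is
recovered to numerical tolerance; under 5% multiplicative noise with
triplicates on the 9-point 0.5–200 μM grid, K_M is recovered within 15% in
≥ 95/100 seeded replicates and the Monte-Carlo bias of the estimate is
below 5%.

The medium-conversion helper treats a w/v agar percentage as
(percent × 10) g dry agar per litre: μM = content(μg/g) × g/L ÷ molar mass.
Values are reported rounded to 2 significant figures alongside full
precision.

## Synthetic data

Generators are pure functions of (parameters, seed) — reruns are
byte-identical — and each emits a truth table sufficient to compute every
downstream expectation.

- **Triad sequences**: class proportions over {3/3, 2/3, 1/3, 0/3} are made
  exact by largest-remainder rounding; planted motifs are instantiated
  uniformly within classes, placed in order at random non-overlapping
  positions, and the background (default uniform 1/20) is resampled with
  bounded retries until the triad call equals the planted class — so truth
  labels for planted rows are exact by construction. Background-only rows
  are emitted raw, so spurious-match rates remain measurable against a
  brute-force oracle.
- **LPR1 stand-in**: `synthetic_lpr1_like()` is a 580-residue synthetic
  protein with the three motifs planted so the anchors fall at exactly
  269/370/462 — it exercises coordinate arithmetic at full protein scale and
  is *not* the real Arabidopsis sequence.
- **Hit tables**: each criterion passes independently with its stated
  probability; values are drawn uniformly from the passing or failing side
  of each threshold with a 0.5-unit guard band against float boundary
  artefacts.
- **HGT scenario** (defaults: 3 bacterial clades × 4 leaves, 4 plants,
  branch scale 0.1): random binary bacterial backbone with branches
  Uniform(0.5, 1.5) × scale; a compact plant clade (branches
  Uniform(0.2, 0.5) × scale — a recent radiation following a single
  transfer) grafted mid-edge onto a random internal, non-root bacterial
  edge. The construction guarantees (monophyletic, nested) on the true tree
  and keeps per-branch substitution probabilities ≤ 0.3, and the bacterial
  radiation deeper than the plant clade so midpoint rooting lands on a
  bacterial path.
- **Sequence evolution**: 20-state equal-rates model — on a branch of
  length t each site is replaced with probability 1 − exp(−t) by a uniform
  residue. The simplest process with closed-form divergence expectations; a
  deliberate simplification of empirical amino-acid exchangeability models.
  No indels, so evolved alignments are gap-free.
- **Kinetics**: v = Vmax·S/(K_M + S) × (1 + ε), ε ~ N(0, CV), clamped at
  zero; defaults (triplicates, CV 5%, 0–200 μM grid) mirror a typical
  ferrozine assay design.

### What the generators do not emulate

Real proteomes have compositional bias, domain repeats and homologous
non-ferroxidase MCOs, so real-data false-positive rates will exceed the
uniform-background rates measured here. Real alignments contain indels,
rate heterogeneity and long-branch effects that the equal-rates, gap-free
simulator omits; passing the HGT recovery property shows the
NJ/midpoint/monophyly chain is correct, not that distance methods suffice
for any real dataset. Assay noise in practice can be heteroscedastic beyond
the multiplicative model. Problem sizes in the test-suite simulations
(alignments of 500 columns, 16 leaves, 200 replicates; 10⁴-row hit tables)
were chosen as the smallest scales at which the binomial/recovery bounds are
sharp.

## Known limitations

- The PSSM screen is ungapped; a single long insertion in a real homolog
  splits its signal across windows.
- Bootstrap supports on distance trees are not comparable to ML bootstrap
  values and no numeric support level is claimed for any real clade.
- `fit_mm` pools replicates without weighting; strongly unbalanced replicate
  counts per substrate level will tilt the fit toward the denser levels.
- The e-value field of generated hit tables is synthetic and carries no
  statistical meaning beyond its position relative to the cutoff.
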