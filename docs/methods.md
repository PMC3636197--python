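# Methods

## Structure handling and descriptors

Libraries are read as SMILES (one `SMILES id` per line) or SDF v2000 via
RDKit; unparsable entries are logged with their position and skipped, and
an entirely unparsable file is a hard error. Salts and adducts are reduced
to their largest fragment (most heavy atoms; ties broken by molecular
weight, then by the lexicographically smallest canonical SMILES so the
choice is deterministic). Deduplication uses the stereo-aware InChIKey —
enantiomers carry different keys and both survive — keeping the first
occurrence in input order; the rare structures the InChI algorithm rejects
fall back to canonical isomeric SMILES keys.

Descriptor conventions (all 2D/topological):

| descriptor | convention | note |
|---|---|---|
| `alogp` | Crippen/Wildman additive atom contributions | vendor AlogP implementations differ by a few tenths; hand-checked fixtures assert sign and a ±1.0 window |
| `mw` | average atomic masses | |
| `hba`, `hbd` | Lipinski N+O and NH+OH counts | pharmacophore-style counts would differ; the Rule-of-Five context fixes the original convention |
| `n_rotatable` | RDKit default pattern | non-ring single bonds between non-terminal heavy atoms, amide C–N excluded |
| `n_rings` | SSSR count | |
| `fpsa` | Labute-ASA contribution of N and O atoms / total Labute ASA | a same-scale ratio guaranteed to lie in [0, 1]; Ertl TPSA divided by a surface area on a different scale can exceed 1, which is why it is not used |
| `n_chiral_c` | assigned carbon stereocenters only | library entries are assumed to carry explicit stereo; potential-but-unassigned centers are not counted |
| `f_chirality` | `n_chiral_c / n_carbon` | undefined (error) for carbon-free molecules |

Rule-of-Five comparisons are strict (`<`), so MW = 500.0 fails the MW
criterion. The library summary's `except_X` categories count molecules
satisfying the three criteria other than X irrespective of X, which makes
each a superset of the fully compliant set.

## Chemical-space PCA

The map is a mean-centered covariance-eigendecomposition PCA on the fixed
8-descriptor panel (AlogP, MW, HBD, HBA, rotatable bonds, rings, aromatic
rings, FPSA), deliberately **not** standardized: with raw units the
large-variance descriptors (MW above all) dominate PC1, which is the
convention under which such maps are read. A correlation-matrix variant is
available via `scale=True` (errors on constant columns). Component signs
are fixed by making each component's largest-magnitude loading positive,
so fits are reproducible across eigensolvers and row orderings.

Overlap between two libraries is the fraction of one cloud's points inside
the axis-aligned 1st–99th-percentile bounding box of the other, in score
space. A convex-hull membership test was considered and rejected: in 3-D
with the heavy outlier tails these libraries have, the hull is dominated
by a handful of extreme molecules and the estimate is unstable.

## Drug–target networks

Edge tables are aggregated to one row per (compound, target) pair by
maximum score before any filtering. Docking scores are positive,
higher-is-better (pKd-like); raw docking energies must be sign-flipped
upstream, since admissibility thresholds of the form "score > 9" are
meaningless on a negative energy scale. With a threshold, an edge is
admitted iff `score > threshold` **and** `score > ref_score[target]`
(both strict); a target missing from the reference table is an error that
names the target. Nodes enter the graph only through admitted edges, so
fully filtered compounds/targets drop out.

Topology statistics follow general-graph conventions so that summary rows
of heterogeneous published networks can be cross-checked with one set of
identities: density is 2E/(N(N−1)) over all nodes (equivalently
⟨k⟩/(N−1)), not the bipartite-specific E/(n_c·n_t); mean shortest path
averages over connected pairs only (finite on fragmented networks);
betweenness is Brandes on the full graph, normalized by (N−1)(N−2)/2,
endpoints excluded. Components are listed largest-first with equal sizes
ordered by smallest node id. Hubs rank by degree (ties: betweenness, then
id), bottlenecks symmetrically by betweenness.

The scale-free fit regresses log10(frequency) on log10(degree) over
degrees with nonzero frequency, returning `a = 10^intercept`, `gamma =
slope` (negative for decaying distributions) and the Pearson r of the
log–log points. This raw-histogram OLS is the convention used for the
published fits it is checked against; maximum-likelihood (Clauset-style)
estimators are out of scope. By default the fit can use all nodes or
either partition (`degree_sequence(net, partition="compound")`);
generator round-trip checks use the compound side, whose degrees are the
ones drawn from the power law.

## Indication prediction

The prediction coefficient is the sum of admissible docking scores over
the targets shared between a compound and a disease:

    coefficient(c, d) = Σ_{t ∈ targets(d), (c,t) admissible} score(c, t)

**This functional form is a reconstruction.** It is docking-score-weighted,
additive over disjoint target sets, monotone under added admissible edges,
and scales linearly with the score scale; on realistic scales (threshold
9, admissible scores ≈ 9–11) a compound hitting five or six disease
targets scores in the 50s, the magnitude published predictions exhibit.
No normalization by the disease's target count and no disease prior is
applied. Zero-coefficient pairs are omitted; ties order by compound id,
then disease.

## Synthetic data

The generators are pure functions of `GeneratorConfig` (each draws from
its own seeded stream, so changing one table's parameters does not perturb
another's). Defaults encode the study conditions:

* **Descriptors** — marginals of a large natural-product library:
  AlogP ~ Normal(2.788, 3.352); MW ~ log-normal parameterized to mean
  472.6 / sd 265.7 Da; FPSA ~ Normal(0.248, 0.128) truncated to [0, 1];
  count descriptors (HBA 7.5±6.7, HBD 3.4±4.1, rotatable 6.6±6.8, rings
  3.7±2.4, aromatic rings 0.9±1.3) ~ negative binomial matched by moments
  (their variances far exceed their means, ruling out Poisson; Poisson is
  the fallback when variance ≤ mean). Columns are independent — real
  descriptors correlate strongly (bigger molecules have more of
  everything), so synthetic Rule-of-Five rates and PCA spectra are *not*
  expected to match real-library values; tests assert marginal
  calibration (sample means within 3 standard errors), not joint
  structure.
* **Interaction networks** — compound degrees drawn from a power law with
  exponent 1.125 truncated at min(100, n_targets); each compound is wired
  to that many *distinct* targets drawn with popularity-skewed weights
  (rank^−0.8). Drawing distinct targets realizes every compound degree
  exactly and cannot produce parallel edges or an infeasible stub
  sequence, which a stub-matching configuration model with discarded
  multi-edges would not guarantee. Default 2000 compounds × 250 targets.
* **Docking scores** — each compound scored against a random panel of 5
  targets with background ~ Normal(5, 1.5) truncated at 0 (a sparse
  reported-score table, not the full all-by-all campaign); reference
  ligands ~ Normal(7.5, 1.0), capped 0.5 below the planted ceiling so a
  planted score above the reference always exists; 10% of compounds are
  planted binders with 2 extra pairs scored uniformly in [9, 11] and
  strictly above the target's reference — admissible by construction at
  the default threshold 9. Under these defaults roughly 30% of compounds
  pass the looser threshold 7 (background tail + planted), a realistic
  virtual-screening hit rate; this is an emergent property, not a
  calibrated target.
* **Disease maps** — each disease links 1–5 random targets; one designated
  disease gets a fresh 5-target panel and one designated compound receives
  admissible edges near the top of the planted band to all of them, so
  its coefficient (≈ 54) dominates every competitor (≤ ~2 planted pairs
  ≈ 22) and the predictor should recover the pair at rank 1.

## Problem sizes and numerical choices

Test and acceptance runs use 300–2000 compounds, 25–250 targets, and
10 000-row descriptor tables — sizes at which every check completes in
seconds while leaving the statistical assertions (3·SE calibration, ±0.15
exponent recovery over 10 seeds, ≥9/10 planted-indication recovery)
well-powered. Eigenvalues are clipped at zero before computing variance
fractions (guarding against −1e−17 artifacts); degree-histogram fits
require ≥3 distinct degrees; percentile trims in the overlap metric
default to 1%. Output floats are written at 6 significant digits.

## Known limitations

* Descriptor values follow RDKit conventions; bit-exact parity with
  commercial descriptor engines (AlogP in particular) is explicitly not a
  goal.
* The prediction model's functional form is a documented reconstruction
  (see above), not a published formula.
* The synthetic generator reproduces marginal distributions and planted
  signals, not inter-descriptor correlations, target-class structure, or
  docking-pose realism — passing tests demonstrate the pipeline's
  correctness on data with the assumed statistical structure, not
  performance on any real screen.
* Power-law fitting by histogram OLS is known to be biased for heavy
  tails compared with maximum-likelihood fitting; it is retained as the
  convention of the published analyses this package mirrors.
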