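# Methods

## Data model

The unit of input is one **organ-effect finding** from one repeated-dose
animal study: compound id, species, route, duration (days), guideline
reliability (A/B/other), purity (%), organ, effect, and the LOEL in mg/kg
bw/day. Inclusion follows standard curation practice for this data type:
rat, oral or inhalation, reliability A or B, purity ≥ 90%, and duration in
the subacute (28–32 d) or subchronic (84–99 d) window. Inhalation records
must already carry a dose in mg/kg bw/day; no concentration-to-dose
conversion is attempted (documented limitation).

Organ-effect pairs are mapped onto **aggregated endpoints** via a
user-supplied YAML glossary (e.g. every liver finding → "liver"); within a
(compound, endpoint, duration class) cell the *minimum* LOEL over all
contributing records is retained — consistent with the lowest-LOEL study
rule and conservative toxicology practice — and converted to mmol/kg
bw/day using the molecular weight, since effects scale with moles at the
site of action. Endpoints observed for fewer than a prevalence cutoff
(default 5%) of compounds are dropped. Missing cells keep a derived
reason (`no_finding` / `not_investigated` / `no_information`); the reasons
are reported but treated identically downstream.

## Features

Descriptive attributes are binary substructure bits plus molecular weight
and logP (Crippen atom-contribution estimate, recorded in the column
metadata; logP is estimated rather than measured, which is the usual
situation for heterogeneous industrial chemical sets). Three default
pattern lists ship with the package: a MACCS-key-like list taken at run
time from RDKit's key definitions (keys not expressible as a single
SMARTS are skipped, leaving 163 of 166), and two hand-written
functional-group lists (55 and 70 named SMARTS) in the spirit of the
FP3/FP4 fingerprint tiers. Substructure-key dialects differ between
toolkits, so bit-for-bit agreement with any particular toolkit's lists is
not promised; users can supply their own YAML lists. Patterns occurring
in more than one list are kept as separate namespaced columns (harmless
for tree induction); constant columns are retained but flagged
`uninformative` so column indices stay stable across subsets. One
notational caveat: the nitro motif often written loosely as `ON(O)C` does
not match nitroaromatics under strict SMARTS semantics (aliphatic atoms,
single-bond defaults); the bundled list therefore encodes it
element-generically as `[#8]~[#7](~[#8])~[#6]`.

## Potency discretization

LOELs are noisy (dose spacing, inter-study variation), so each endpoint is
reduced to a binary high/low potency call with a data-adaptive threshold:

- deterministic 1-D two-means on log₁₀ dose, centers initialized at the
  25th/75th percentiles, iterated to convergence;
- candidate threshold = midpoint of the two group means in log space,
  back-transformed;
- clamped into [1.5, 2.0] mmol/kg bw/day (subacute), which keeps the
  class ratio near balance on real-world dose distributions.

LOEL ≤ threshold ⇒ high potency (boundary inclusive). Subchronic LOELs
are compared to threshold/2, the conventional subchronic→subacute
assessment factor. A compound with both duration classes is called high
if *either* class says high (conservative merge; the duration-merge rule
is this package's choice). An endpoint with no observed subacute values
falls back to the geometric midpoint of the band, with a warning. The
whole step is deterministic. Two numerical notes: units are mmol/kg
bw/day throughout (the field sometimes writes the band as "μmol" but all
worked values are mmol), and with a fixed threshold the call is monotone
in the LOEL; re-detecting the threshold after perturbing the data can
move the clamp point within the band.

## Imputation (Ensemble of Classifier Chains)

Typically ~82% of compound-endpoint cells are missing, and tree induction
needs complete targets. An ECC fills them: each of `n_chains` (default
10) chains draws a random endpoint order and a bootstrap bag of compounds
(fraction 0.67, with replacement), then fits one depth-limited decision
tree (max depth 6) per endpoint on the features augmented with the
chain's earlier endpoint values — observed where available, else the
chain's own prediction; missing predecessors inside the training rows are
filled with the endpoint's observed majority class (documented
convention). The final call per missing cell is the across-chain mean of
P(high) at a 0.5 vote threshold. The chain count, bagging scheme and vote
threshold follow the standard ECC configuration from the multi-label
classification literature; all are config-exposed, and everything is
reproducible from one seed. Imputed values feed *only* the clustering
step; every reported statistic masks them out.

## Predictive clustering tree

Standard top-down induction with variance reduction as split score.
Cluster variance of target rows (0/1 per endpoint) is

    Var(S) = (1/n) Σᵢ ‖yᵢ − ȳ‖²

which equals the sum of squared pairwise distances divided by 2n²; the
normalization is fixed everywhere. Candidate tests are bit presence for
every binary column and `x ≤ t` for midpoints t of consecutive sorted
unique values of MW and logP; tests leaving either side below
`min_leaf` = 3 are inadmissible. The maximal-reduction test wins, with
deterministic tie-breaking (lowest column index, then lowest threshold).
A split is kept only if the variance-ratio F-test — F = parent variance /
pooled child variance, referred to an F(n−1, n−2) distribution — has
upper-tail probability ≤ α = 0.125 (a deliberately tolerant level; the
df convention follows the predictive-clustering framework's stopping
test and is config-exposed). A perfect split (pooled variance 0) is
always accepted; a zero-variance node is a leaf. No post-pruning, no
ensembling. Requiring *both* children ≥ min_leaf is the stricter reading
of the leaf constraint and is intentional.

Binary-split scoring is vectorized: for 0/1 targets, Σ‖y‖² over a child
equals the sum of its per-endpoint sums, so all columns are scored from
one matrix product per node. Induction is invariant to row order (rows
are canonicalized by compound id) and fully deterministic.

Leaves are clusters; each carries its members and a majority-vote
endpoint profile. Assignment routes a feature row root-to-leaf and
returns the cluster id, profile and readable decision path. A manual
`split_leaf_by_feature` utility exists for expert post-hoc refinement of
a mixed leaf; it is never applied automatically.

## Cluster assessment

All statistics use observed cells only.

- **Toxic value**: Σ over endpoints of 0 (missing/imputed), 1 (low),
  2 (high) — a one-number severity profile, bounded by 2 × n_endpoints.
- **LOEL summary**: per compound, the representative LOEL is the
  geometric mean of its observed endpoint LOELs (subchronic values
  doubled to align durations — this package's definition, since the
  reference analyses do not fully specify it); per cluster, geometric
  mean, min, max and the gm/min ratio.
- **Read-across selection**: clusters with gm/min ≤ 5 (boundary kept)
  are quantitative read-across candidates; predictions from them should
  carry an additional assessment factor of 5.
- **Categories**: 1 = 100% structural and 100% toxicological similarity,
  2 = 100% / 75–99%, 3 = 100% / ≤ 74%, otherwise unassessed. The
  original similarity percentages were expert judgments; this package
  computes operational *proxies* (fraction of members equal to the
  cluster's modal bit signature; fraction consistent with the modal
  observed endpoint profile) and labels them as such. Expert scores and
  proxies will differ on real data.
- **Enrichment**: per feature, the 2×2 activity × presence table with a
  two-sided Pearson chi-square *without* continuity correction (this
  choice reproduces published reference p-values from their printed
  counts), Holm step-down by default, plain Bonferroni available.
- **Endpoint correlation**: pairwise Spearman on jointly observed
  compounds (≥ 3 pairs, else undefined); the log transform is a no-op
  for a rank correlation and is applied only for parity with the
  reference analysis.

## Synthetic data generator

Real inputs of this kind are confidential, so the generator emulates
their shape: `n_latent_clusters` scaffold families (nitroaromatics,
glycol ethers, azoles, chloroaromatics, alcohols, anilines, ketones,
thioethers — chemotypes these datasets actually contain) assemble valid
SMILES whose members share fingerprint bits; each cluster gets a distinct
endpoint profile drawn with P(high) = 0.49; LOELs are log-normal
(σ = 0.25 log₁₀ units) around modes placed `effect_separation` apart in
log₁₀ dose, centered on the discretization band; cells go missing
completely at random at rate 0.82 (an optional block mode correlates
missingness within compounds, mimicking uninvestigated panels); study
records are back-generated inside the duration windows with purity
≥ 90%, occasionally with a second, less sensitive finding so the
lowest-LOEL rule is exercised. Defaults (n = 300 compounds, 8 endpoints,
4 clusters) are the scale used throughout the examples and checks.

What passing tests on this generator do **not** show: real datasets have
correlated endpoints, non-random missingness, expert-curated glossaries,
assay noise far above σ = 0.25, and chemotypes without clean scaffold
signatures. Synthetic recovery results (ARI ≈ 1, imputation accuracy
≈ 100% at separation 2.0) are upper bounds demonstrating correctness of
the machinery, not expected field performance.

## Numerical choices and degenerate inputs

- Threshold detection: ties in the two-means assignment go to the lower
  center; a single observed value clamps itself (with a warning).
- F-test: pooled variance is floored at 0 against floating-point
  negatives before testing.
- Vote threshold: mean probability exactly 0.5 votes high (conservative).
- Duplicate SMILES with distinct ids are allowed; duplicate ids are
  fatal.
- Fewer compounds than `min_leaf` yields a single-leaf tree with a
  warning; an empty endpoint matrix is an error.

## Known limitations

- Published summary tables used as worked references are printed at 2
  decimals; statistics recomputed from them can differ from the printed
  summaries by one unit in the last digit, and the boundary read-across
  ratio (printed 5.0) recomputes to 5.36 from rounded inputs. Checks are
  therefore at printed precision, not exact equality.
- Structural/toxicological similarity percentages are proxies for expert
  judgment (see above).
- No NOAEL derivation, no benchmark-dose modeling, no metabolism or
  bioavailability information — categories are structural/potency-based
  only.
- The imputation model is not probabilistic downstream: hard high/low
  calls only.
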