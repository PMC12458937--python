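# Methods

This note records the models, conventions, and numerical choices behind
defensekit, and what the synthetic-data generators do and do not emulate.

## Coordinates and formats

All genomic coordinates are 0-based half-open internally; GenBank and GFF3
conventions (1-based inclusive) exist only at the I/O boundary, and BED6
output needs no conversion. Compound (join) gene locations are collapsed to
their min-start/max-end envelope with a warning: downstream logic uses only
gene order and span, never exon structure. Delimited tables are UTF-8 with
a header row; comma/tab is auto-detected, matching common plate-reader
exports. Every filter emits a structured log line (operation, threshold,
n_in, n_out) on the `defensekit` logger.

## Titer estimation and censoring

A spot-dilution titer is quantified from the **most dilute** spot whose
plaque count falls in the countable window, default [3, 100] — standard
plaque-assay practice; the window is configurable. If no spot is countable
but plaques were seen, the most dilute spot with ≥ 1 plaque is used. Spots
that cleared the lawn without discrete plaques are quantified from the most
dilute halo-positive spot with the count taken as ≥ 1 and flagged
(`lysis_halo_quantified`). An all-zero series yields a censored estimate
reported at the detection limit, one plaque at the *least dilute* spot
examined: lod = 1 / (spot volume × largest dilution factor).

Censoring propagates: a censored test titer makes the EOP an upper bound
and log-protection a lower bound; a censored reference titer is an error
(no valid denominator). A censored lower bound on log-protection that
already exceeds the protection threshold still supports a positive call; a
bound below it yields "not protected" rather than "unknown" — conservative
for the binary summary, with the flag preserved for inspection.

The conditional-bias property of the estimator is worth stating: selecting
the most dilute countable spot is upward-biased when the counted spot has
very few plaques (a Poisson(3) count conditioned on ≥ 3 averages 4.2), but
conditional on the counted spot holding ≥ 20 plaques the relative bias is
below 5%, and the selection bias cancels in EOP ratios because test and
reference titers are selected identically (the geometric-mean EOP over
replicates recovers the truth within a few percent at these counts).

### Classification thresholds

* protected: log-protection strictly > 1 (a > 10-fold titer reduction).
  The threshold is read as a fold reduction, not an absolute PFU/ml
  difference, which would be dimensionally meaningless for a serial
  dilution assay.
* at least modest protection: EOP < 0.01 **or** SFC < 0.5 (disjunction).
* SFC is a radius ratio by default (radii are what is measured); an area
  option is exposed in the configuration.
* Replicate aggregation: metrics per replicate first, then geometric mean
  for EOP (it lives on a log scale) and arithmetic mean for SFC.

## Epistatic coefficient

ε = |log₁₀ EOP_both| − |log₁₀ EOP_A| − |log₁₀ EOP_B|, zeroed when the mean
EOP of the two-system strain for that phage is ≥ 10⁻² (the boundary is
inclusive). For EOPs ≤ 1 this is log₁₀(EOP_A · EOP_B / EOP_both): zero for
exactly multiplicative protection, positive for super-multiplicative.
Zeroed results keep the would-be value in `epsilon_raw` for diagnostics.
ε inputs are per-phage mean EOPs (means over replicates first, then the
formula); censored EOPs enter at their bound and mark the result as a
bound with a recorded direction rather than inventing a value.

## Growth curves and AUC synergy

Baseline subtraction removes the optical density of the first time point;
AUC is the composite trapezoid rule over the full time range, reported in
OD600·hour. Synergy is a strict inequality — AUC_both > AUC_A + AUC_B —
so ties are not synergy. Confidence bands across replicates are pointwise
symmetric t intervals with n − 1 degrees of freedom (95% default); with
triplicates this is deliberately simple and exact under normality, and the
calibration suite verifies 95% ± 2% empirical coverage.

Reporter-dye normalization divides fluorescence by max(OD, floor) with a
default floor of 0.01 OD, flagging floored points: after lysis the OD
denominator collapses and raw ratios explode.

Hypothesis tests: the one-sided test is Welch's unpaired t (unequal
variances, a robust default) with alternative "greater"; Shapiro–Wilk runs
on each sample first and a failed check warns but never silently switches
tests. The all-vs-control procedure is one-way ANOVA plus Dunnett's
correction (the natural choice when every group is compared to one
control); Holm step-down over Welch tests is available via configuration.

## Island deduplication

Protein-family clustering is greedy and incremental: sequences sorted by
length (descending, ties by id) join the first existing representative
with identity ≥ 0.9 and mutual coverage ≥ 0.8, else found a new family.
Identity is matches / alignment columns (gaps count as columns) of a
global alignment under BLOSUM62 with gap open 11 / extend 1; coverage is
the fraction of each sequence aligned residue-to-residue, required of
*both* sequences. This is a reproducible, oracle-checkable approximation
of word-based clustering heuristics, not an emulation of any tool, and the
test suite verifies it against an exhaustive all-pairs simulation.

Gene-content difference between islands is the symmetric difference of
their combined content sets (defense genes plus adjacent ORF families;
presence/absence, copy number ignored — a multiset mode is configurable).
Islands within 3 differences are linked and families are the connected
components (single linkage): grouping is transitive by design, so chains
of small differences merge. Family ids are the smallest member id, making
runs bit-for-bit reproducible. Islands fewer than 10 ORFs from a contig
end are excluded before grouping (truncated context is not comparable);
flanks truncated by contig ends in neighborhood extraction are simply
shorter, since there is no principled way to count genes that are not in
the assembly.

## Direct-repeat scanner

Anchor window: last 25 nt of the tRNA plus 5 nt past its 3' end,
strand-aware. Integration sites typically overlap the 3' portion of tRNA
genes, and the small downstream slack absorbs annotation wobble; both
margins are configurable, and tmRNA anchors use the same window. Every
k-mer (16 ≤ k ≤ 20) starting in the window is searched downstream of the
3' end, in the tRNA's reading direction, up to 200 kb (islands of interest
span tens of kb; the bound is configurable), for same-strand occurrences
within Hamming distance 1 — substitutions only, since fixed 16–20 nt
repeat lengths with "one mismatch" imply no indels. The two copies are
treated symmetrically: a mismatch may sit in either copy. A bidirectional
mode (scanning the other side of the tRNA) exists but is off by default.

Overlapping hits at one tRNA are collapsed by **fewest mismatches, then
longest, then smallest distal start**. Mismatch count leads deliberately:
any perfect repeat shorter than the window maximum admits longer
one-mismatch extensions (the flanking bases almost never co-vary), so a
longest-first rule would systematically report a fuzzy extension of the
integration site instead of its maximal exact core. Preferring perfect
repeats makes the reported boundary the planted/true attachment-site
duplication whenever one exists. Element spans run between (and exclude)
the repeat copies; cargo genes must lie fully inside; overlapping element
candidates are resolved greedily, longest span first.

Mobility classification is keyword-based over the provided product
annotations — explicitly not an HMM or profile search. Keywords match
case-insensitively on word boundaries (so "repressor" does not satisfy
"rep"), and the vocabulary is user-extensible. predicted_active requires
an intact (non-pseudo) integrase/recombinase plus an excisionase or
rolling-circle replication initiator; an element whose only integrase
evidence is a pseudogene or fragment — the vestige of the delivering
recombinase — is immobilized, as is one with no integrase at all;
anything else is unclassified.

## Synthetic-data generators

Each generator is a pure function of its configuration; one pseudorandom
substream per generator is derived from the master seed by a fixed label,
so adding a generator never perturbs the others.

**Plaque assays** draw count ~ Poisson(titer × EOP × dilution × volume)
over a ten-fold series (defaults: titer 10¹⁰ PFU/ml, 3 µl spots,
dilutions 10⁻¹…10⁻⁹, triplicates), emulating spot-dilution designs. They
do not emulate plaque overlap at high density, edge effects, or pipetting
error beyond Poisson noise.

**Growth curves** integrate a minimal susceptible/infected/phage ODE —
logistic host growth (r = 1.4 h⁻¹, K = 1.2 OD), adsorption
(a = 3 × 10⁻⁹ ml PFU⁻¹ h⁻¹), lysis (δ = 1 h⁻¹) releasing β = 10 phage,
with 8 × 10⁸ cells/ml per OD linking MOI and burst to optical density —
by classical fixed-step RK4 at 0.5-min steps over 500 min, sampled every
10 min, with transient negatives clipped at zero. Defense systems scale
adsorption by (1 − e); the two-system strain uses a(1 − e_A)(1 − e_B)/γ,
so a single scalar γ separates multiplicative (γ = 1, ground truth
"additive") from synergistic (γ > 1) regimes. The default efficacies
(e_A = 0.5, e_B = 0.4) and phage parameters were chosen, by solving the
deterministic model across a coarse grid before any stochastic testing,
so that at MOI 0.1 the additive case sits ~1 OD·h below the additive
expectation and the γ = 2 case ~1 OD·h above it — an order of magnitude
beyond the AUC noise from 0.01-OD measurement error. Replicates share the
deterministic trajectory and differ only in i.i.d. Gaussian noise; the
model is an interaction testbed, not a mechanistic account of any
particular phage's biology (no latent-period distribution, resistance
evolution, or multiplicity-dependent lysis).

**Genomes** are uniform-random sequence carrying 76-nt tRNA genes whose
last k nt form the direct repeat; the distal copy sits a configured span
downstream with central substitutions placed so that no exact sub-repeat
of ≥ 16 nt survives, and the two bases flanking each copy are forced to
differ between the copies so repeats cannot be extended within the
mismatch budget — making the planted coordinates the unique maximal
answer. Cargo genes exercise every mobility class; decoy repeats each
violate exactly one scanner constraint (too short, too far, two
mismatches, not tRNA-anchored). After assembly the generator verifies
that the planted elements are the only anchored repeats the scan geometry
admits and regenerates (bounded retries, warning) if a background repeat
collides; the scanner's correctness is established independently against
a brute-force enumeration oracle in the test suite, so this check only
keeps ground truth exact.

**Island tables** plant families with disjoint core content (inter-family
distance 2 × content size); each island receives a configured number of
single-element edits (drop a core member or gain a decoy), so two islands
of one family differ by at most twice that number. ORF proteins of one
prototype diverge by at most 2.5% each from a common base (pairwise
identity ≥ 95%); different prototypes are unrelated random sequences
(expected identity ~5%). Real islands additionally vary in gene order,
orientation, and partial homology between families — none of which the
content-set statistics consume.

## Problem sizes

The shipped test and acceptance runs use: 1000 dilution-series replicates
for estimator bias; 200 growth datasets (four genotypes, triplicates,
MOI 0.1) for synergy classification; 20 genomes of ~12 kb against the
brute-force scanner oracle and 50 genomes of ~30 kb with two planted
elements each for recall; 20 islands across 4 planted families for
recovery; 1000 replicate draws for band coverage. These sizes give
binomial/Monte-Carlo resolution well inside each stated tolerance while
keeping a full run in tens of seconds.

## Known limitations

* Plaque radii are inputs; no image analysis.
* The AUC synergy call compares point estimates; it attaches no
  uncertainty to the call itself (the bands and t-tests quantify
  uncertainty separately).
* Clustering identity is alignment-based and will not exactly reproduce
  word-based heuristic tools near their thresholds.
* The scanner assumes substitution-only repeat degeneracy and
  one-directional integration geometry by default.
* Mobility classification trusts the input annotations; unannotated or
  mislabeled integrases are invisible to it.
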