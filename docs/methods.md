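# Methods

## Scope

`cotodelim` implements a reusable version of an integrative
species-delimitation workflow for the *Cotoneaster buxifolius* complex:
SNP filtering and LD pruning, admixture-model ancestry estimation,
morphometric distance/clustering/ordination, support-thresholded
monophyly testing, cytonuclear-discordance detection, and a decision
cascade that turns these evidence lines into per-taxon verdicts.
Upstream read mapping, variant calling, chloroplast assembly and
maximum-likelihood tree inference are out of scope; trees are consumed
as Newick with `SH-aLRT/UFboot` node labels, genotypes as VCF or
dosage tables.

## The admixture model and its EM fit

For diploid dosages g_ij ∈ {0, 1, 2} at unlinked biallelic sites, the
model places individual i's ancestry fractions q_i (Σ_k q_ik = 1) over
K pools with allele frequencies p_kj, and maximizes

L = Σ_ij [ g_ij log Σ_k q_ik p_kj + (2 − g_ij) log Σ_k q_ik (1 − p_kj) ].

The optimizer is plain EM: the E-step attributes each observed allele
draw to a pool of origin; the M-step re-estimates q by row-normalized
expected counts and p by expected alt/(alt+ref) draws. The
log-likelihood is non-decreasing by construction and the fit stops at
a relative gain below `tol` (default 1e-6) or `max_iter` (default
2000). Missing dosages are simply skipped in the likelihood.
Initialization draws q from a symmetric Dirichlet(1) and perturbs the
global allele frequencies for p (seeded); block-relaxation or
quasi-Newton acceleration was deliberately not used — the likelihood
is the contract, and plain EM converges comfortably at the problem
sizes this package targets (hundreds of samples, thousands of sites).
Frequencies are clipped to [1e-9, 1 − 1e-9] to keep the likelihood
finite at boundary solutions.

K is selected by masked cross-validation: a fraction (default 0.1) of
observed dosages is hidden, the model refit, and hidden entries
predicted as 2 Σ_k q_ik p_kj; the error is the mean squared deviation.
The package reports the grid and argmin but never auto-commits a K —
in this complex the CV curve stabilizes at one K and bottoms out at a
much larger one, and both resolutions carry taxonomic information.

Label switching across runs is resolved by optimal assignment
(Hungarian algorithm) on the column-correlation matrix; when the runs
differ in K, unmatched columns keep their order after the matched ones.

## Purity classes and the override window

Taxon profiles are unweighted means of member-sample q vectors. With
pure threshold 0.95 and override floor 0.70:

* `PURE` — q̄* ≥ 0.95 (the framework's "single gene pool");
* `SUBTHRESHOLD` — 0.70 ≤ q̄* < 0.95, a reusable encoding of the
  documented near-pure exception (*C. fulvidus*), decided downstream
  by monophyly + diagnosability rather than by a taxon whitelist;
* `ADMIXED` — otherwise; pools contributing ≥ 0.05 (the minor
  threshold; the source framework gives no numeric floor, 0.05 is this
  package's choice) are recorded as parent candidates.

Thresholds are inclusive on the keep side everywhere (≥ 0.95, ≥ 0.70,
≥ 0.05), mirroring the quoted inequalities of the filtering stack
(missingness ≤ 0.15, MAC ≥ 3, MAF ≥ 0.05 all inclusive).

## Trees, monophyly and discordance

Monophyly is bipartition-based (unrooted semantics): a target leaf set
is monophyletic iff it or its complement is one side of some edge,
which makes root placement immaterial; pendant edges count as
bipartitions, so a singleton target (single-population taxon) is
trivially monophyletic. Stem supports are read from the edge defining
the bipartition; when the rooted representation carries the label on
the complementary child, that label is used. Absent support is
distinct from zero support and *fails closed* against thresholds;
singleton targets pass only because their supports are waived by
default (`waive_singletons`), matching the acceptance of
single-population taxa — a strict mode reverses this.

Backbone clades are the smallest bipartition side containing all of a
label's exemplars and none of another's. For populations falling
outside every backbone side (typically hybrids of intermediate
placement), the pipeline assigns the label of the nearest assigned tip
by patristic distance — a deterministic fallback, logged, and only
used for the cytonuclear comparison, never for monophyly.

Cytonuclear discordance never assumes a clade-name correspondence: the
nuclear → plastid label mapping is the optimal assignment on the
population confusion matrix, a population is discordant iff its
plastid label differs from the image of its nuclear label, and a
species is discordant iff any of its populations is. This clade-level
contract is coarser than a tanglegram: a taxon can be discordant in a
branch-by-branch comparison yet concordant at clade level (see
Limitations).

The bundled NJ builder is a standard neighbor-joining implementation
(vectorized; negative branch lengths clamped to zero) over an
allele-sharing distance (mean |g_i − g_j| / 2 on pairwise-complete
sites). Site-resampling bootstrap percentages are written into *both*
support slots of the point tree; SH-aLRT is never simulated — trees
built here are for synthetic scenarios only, real analyses should
supply ML trees.

## Morphometrics

Gower distance with pairwise deletion: quantitative traits contribute
range-normalized absolute differences (a zero-range trait contributes
0), qualitative traits a 0/1 mismatch, averaged over traits observed
in both units. Clustering is average linkage (UPGMA, via scipy), with
merge heights d/2 so cophenetic distances reproduce the input scale.
Trait PCA standardizes all columns — qualitative traits enter as their
integer codes, the source convention, despite its statistical
crudeness — and eigendecomposes the correlation matrix; trait
contributions are squared loadings in percent. Diagnosability between
two taxa counts traits whose observed intervals (quantitative) or
state sets (qualitative) are disjoint; "discontinuous" is strict
disjointness by default, with an optional `gap_fraction` safety margin
because the framework never defines the term numerically. Traits
observed on only one side are excluded and logged.

## The decision cascade

Ordered rules (first match wins):

1. `PURE` ∧ supported monophyly ∧ ≥ 2 diagnostic traits against every
   shared-pool partner → `VALID`;
2. `PURE`/`SUBTHRESHOLD` sharing a pool with a partner it cannot be
   diagnosed from, and junior to that partner → `SYNONYM_CANDIDATE`;
3. `SUBTHRESHOLD` ∧ supported monophyly ∧ diagnosable →
   `VALID_BY_OVERRIDE` (disable with `enable_override=False`);
4. `ADMIXED` ∧ cytonuclear discordance ∧ (non-monophyletic ∨ < 2
   diagnostic traits against some parent candidate) → `HYBRID`;
5. otherwise `UNRESOLVED`.

Design choices the framework left open:

* Plastid discordance is recorded for all taxa but *required* only on
  the hybrid path; a pure, supported, diagnosable taxon stays VALID
  despite plastid capture (the complex contains exactly such cases).
* Seniority is nomenclature, not genomics: rank decides first (a
  species is senior to an infraspecific name), then an explicit
  config mapping, then lexicographic order as a deterministic
  fallback. An infraspecific taxon never threatens its parent species
  with synonymy; the infraspecific name itself can be sunk.
* A senior taxon failing diagnosability only against its own junior
  keeps VALID and records the absorption in its evidence trail.
* Species-rank tallies exclude infraspecific taxa; the gene-pool count
  is over dominant pools of VALID/VALID_BY_OVERRIDE taxa.

The hybrid-removal rebuild drops every taxon with purity `ADMIXED` or
status `HYBRID` (override taxa are retained) and rebuilds NJ +
bootstrap over the remaining samples.

## Synthetic data

`simulate_scenario` draws pool frequencies by the Balding–Nichols
construction (ancestral p0 ~ U(0.05, 0.95); pool p ~ Beta(p0(1−F)/F,
(1−p0)(1−F)/F)) and dosages Binomial(2, Σ_k q_ik p_kj) under planted
per-taxon ancestry. Default study conditions, chosen once to mirror a
reduced-representation dataset of this kind at desk scale: divergence
F = 0.2, 2000 sites, two populations of five samples per taxon, two
quantitative traits separated by 4 within-taxon SDs plus two
taxon-diagnostic qualitative states. Planted hybrids carry 0.6/0.4
parental ancestry, the major parent's quantitative means, one
qualitative state from each parent, and the *minor* parent's plastid —
so cytonuclear discordance and morphological intermediacy are emergent
signals the pipeline must detect, not annotations it reads back. The
truth table records every planted quantity.

What the simulator does **not** emulate: linkage between sites,
polyploid dosage (all taxa are treated as diploid, although much of
the real complex is polyploid), apomictic population structure,
phenotypic plasticity, and sequence-level plastome evolution (the
maternal pool is emitted directly as a plastid clade label). Passing
recovery tests therefore shows the pipeline is correct under its own
model, not that the model captures every property of real ddRAD data.

The worked-example dataset (`buxifolius_complex_fixture`) is a
synthetic encoding of the complex's published verbal structure: which
of the 29 taxa are single-pool versus admixed and from which of the
nine K = 9 pools, the 43 populations' nuclear (NA–NC) and plastid
(PA–PC) clade placements, the K = 19 pool sharing, and minimal traits
(two qualitative characters; documented indistinguishable pairs share
states, documented hybrids share one state with a putative parent).
Ancestry magnitudes are stand-ins (0.97 / 0.72 / 0.60) constrained
only by the documented inequalities; every summary count is invariant
to ± 0.02 jitter of these values, which the test suite and the
acceptance script both exercise. Per-taxon population counts are not
fully documented; the fixture uses the unique distribution consistent
with all published totals (43 populations; clade sizes 8/17/18; 20
non-admixed populations; 18 discordant populations).

## Numerical choices

* LD pruning: within each 50-site window (step 10, never spanning
  chromosomes) the retained pair with the highest r² above threshold
  loses its *later* member; ties drop the largest index involved —
  deterministic and order-stable. r² is composite (dosage)
  correlation, pairwise-complete over missing data; monomorphic sites
  have r² = 0.
* Genotype PCA standardizes by √(2p(1−p)) with per-site mean
  imputation of missing dosages.
* EM: p clipped to [1e-9, 1 − 1e-9]; CV masks are drawn per replicate
  and sites left all-missing by a mask are excluded from that
  replicate.
* All randomness (EM init, CV masks, bootstrap resampling, scenario
  draws) flows through seeded `numpy` generators; fixed seeds give
  bit-identical outputs.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen as the
package's own study conditions: EM recovery on 100 samples × 2000
sites (5 seeds), CV on 60 × 600 grids over K = 1..5 (10 runs),
end-to-end delimitation on 20 scenarios of 3–6 pools with 0–3 planted
hybrids (~30–90 samples, 2000 sites, 100 bootstrap replicates each),
and the 43-population fixture.

## Known limitations

* Diploid dosage coding throughout; polyploid genotypes are not
  modelled even though the real complex is largely polyploid.
* Discordance is clade-level, not tanglegram-level: after hybrid
  removal the detector reproduces the documented *count* of
  persistent discordances (three), but one of the three taxa differs
  from the branch-level reading (a clade-concordant taxon whose
  within-clade position conflicts is invisible at this granularity,
  while a clade-discordant one becomes visible).
* Bootstrap percentages stand in for both support slots on synthetic
  trees; SH-aLRT values are only meaningful on user-supplied trees.
* The EM optimizer is not ADMIXTURE's accelerated block relaxation;
  at very large n×L it will be slower, though identical in its
  optimum.
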