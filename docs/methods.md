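# Methods

This note documents the models, estimators and numerical choices behind
`eurydelim`, and what the synthetic validation does and does not show.

## Distances and the distance-based criteria

Divergences are Kimura two-parameter (K2P) distances,
`d = -½·ln((1-2P-Q)·√(1-2Q))`, with P and Q the proportions of transitional
(A↔G, C↔T) and transversional differences over compared sites. Sites where
either sequence carries a gap or an IUPAC ambiguity code are excluded
pairwise (pairwise deletion preserves the most data and is the common
default of distance tools in this field; the choice matters only for gappy
rRNA alignments). When the log argument is non-positive the pair is
*saturated*: the default is a hard error naming the offending pairs, with a
mask option (NaN replaced by the matrix maximum) for survey data containing
distant outgroups. Internally all values are proportions; report layers
format percentages to one decimal and proportions to three.

The barcoding gap compares the largest within-clade distance with the
smallest between-clade distance; with only singleton clades there are no
within-clade pairs and the status is reported as *undecidable* rather than
present. The 4× criterion is applied per clade pair exactly as its
operational form states: the minimum between-pair distance must strictly
exceed four times the larger of the two within-clade maxima (singletons
contribute 0); the population-genetic derivation behind the rule is not
re-implemented. Both reports are invariant under specimen order and clade
relabelling, and the 4× decision is scale-invariant.

`threshold_clusters` (single-linkage components of the d ≤ t graph) is the
de novo companion: whenever a gap is present, clustering at any t inside it
reproduces the clade partition exactly — this linking property is tested on
synthetic data. The de novo threshold proposal used by the pipeline when no
clades are supplied takes the midpoint of the widest empty interval in the
pairwise-distance distribution; with several well-separated clades the
widest interval need not be the barcoding gap (deep splits can leave wider
holes), so proposals are labelled as such and clade labels should be
supplied when known.

## Haplotypes and statistical-parsimony networks

Haplotype identity is exact string equality over all columns; a gap is a
state. Sequences containing ambiguity codes never merge — an N may hide a
difference — and are flagged. Labels (`H01, H02, …`) order by descending
total multiplicity with ties broken by smallest member id, so collapsing is
input-order invariant. Multiplicities let one deposited haplotype stand for
many specimens; totals are conserved.

The connection limit is the largest step count j whose *parsimony
probability* still reaches the threshold (default 0.95). The estimator is a
finite-sites computation: per-site substitution counts are Poisson with
intensity λ solved from the observed fraction of differing sites under a
symmetric s-state model (s = 4 for DNA; the per-site difference probability
is ((s-1)/s)(1-e^{-sλ/(s-1)})), and

    P_parsimony(j, L) = Pr(1 change | site differs)^j · Pr(0 changes | site same)^{L-j}.

It is deterministic, non-increasing in j, non-decreasing in sequence length
and non-increasing in the threshold, and is cross-checked in the tests by a
conditional Monte-Carlo simulation of the same model rather than by a second
copy of the formula. It is somewhat conservative relative to the limits the
classic TCS program reports (e.g. 8 steps at 658 sites vs TCS's typically
low teens); since components only change when between-cluster step counts
approach the limit, this rarely affects network membership, and a
`fixed_limit` argument can impose another tool's limit exactly.

Networks join haplotype pairs in order of increasing step distance (ties by
label); an edge is kept when its endpoints are not already connected through
strictly shorter edges, so all minimal alternative connections (loops) are
retained. Multi-step edges are subdivided by unlabelled hypothetical
haplotypes for display/export only; component structure is computed on
observed haplotypes and equals the connected components of the ≤-limit
graph. Gap handling at this stage is configurable: fifth state (default,
one step per gap/base mismatch) or missing (site skipped).

## The single-threshold GMYC model

An ultrametric genealogy of all sequences mixes two branching regimes:
between species (speciation, Yule-like) and within species (coalescent).
The model places a threshold age T on the tree; nodes older than T are
speciation events, the subtrees hanging below T are the delimited entities
(*clusters* when they contain ≥2 tips). The branching **times** are modelled
as one inhomogeneous point process with intensity

    b(t) = λ₁·n_div(t)^p₁ + λ₂·Σₖ (cₖ(t)·(cₖ(t)−1))^p₂ ,

where n_div counts diversification lineages (all branches older than T;
frozen at the entity count below T, where species lineages persist without
branching) and cₖ counts the k-th cluster's lineages. Each inter-event wait
x contributes `b·e^{-b·x}`, evaluated piecewise in the one interval that
straddles T. With p₁ = 1 the first term is the Yule process; with p₂ = 1 the
second is proportional to the Kingman coalescent rate c(c−1)/2 (the ½ and
the population-size scaling absorbed into λ₂). The c(c−1) form makes a
cluster that has reached its most recent common ancestor rate-free, so the
quiet span between the deepest cluster MRCA and the shallowest speciation
node is uninformative about T — the likelihood profile is flat across it,
which is the behaviour that lets the threshold sit anywhere in the gap.

Two alternative formulations were implemented and rejected during
development: scoring each event with its own process's rate double-charges
the within-species block for *which* cluster branches (an assignment
probability the one-species null never pays), destroying the likelihood-
ratio comparison; and attributing the event intensity from the younger side
of each node breaks point-process coherence (the intensity at events is not
the intensity integrated in survival) and inflates the type-I error to 1.

Fitting: candidate thresholds are T = 0 plus the midpoints between
consecutive distinct node heights (the classification is piecewise constant
between heights). At T = 0 the model collapses to the single-process null
`b = λ·n^p`, fitted exactly by profiling λ analytically and a bounded 1-D
search over p (21-point grid + Brent refinement); this same fit is the null
model, so the null is a boundary case of the alternative and
`lnL(GMYC) ≥ lnL(null)` by construction. At interior T the four parameters
are coupled through the below-threshold event factors and are maximised
jointly by L-BFGS-B on (ln λ₁, p₁, ln λ₂, p₂) from three deterministic
starts seeded at moment-matched rates. Bounds: λ ∈ [10⁻⁸, 10⁶],
p ∈ [0, 10]. The support set reports all candidate thresholds within 2
log-likelihood units of the maximum. The LRT uses 2·ΔlnL against χ² with a
configurable 3 degrees of freedom (threshold + one extra rate + one extra
exponent). On 200 simulated one-species (pure Yule, 20-tip) trees the
empirical rejection rate at α = 0.05 is 3–5%.

Trees come from Newick input (dendropy parsing; heights from root
distances; relative ultrametricity tolerance 10⁻⁶), or from the UPGMA
fallback (average linkage, node height = half the merge distance, ties
broken by smallest member label). Polytomies are resolved deterministically
(children ordered by smallest tip label) and tied internal heights are
separated bottom-up by 10⁻¹⁰ of tree height so heights are strictly ordered
along every path; this also handles fully collapsed (θ → 0) within-species
genealogies.

## Synthetic data generator

The generator emulates the structure a multi-criterion survey assumes: a
Yule species tree with an independent Kingman coalescent grafted below each
species tip, K80 (equal-frequency, κ-biased) sequence evolution along the
genealogy, and clade-level depth strata. Time is measured in expected
substitutions per site on the reference (COI-like) marker; slower markers
scale branch lengths by a relative rate. Key parameters (preset defaults in
brackets):

- `n_species` [9], `samples_per_species` [3] — 27 sequences per marker,
  matching the scale of the survey's 27 unique 16S haplotypes in 9 clades.
- `theta` [0.002] — expected within-species pairwise divergence; the
  pairwise coalescence rate is 2/θ so E[pairwise distance] = θ, and the
  n-sample TMRCA has mean θ(1−1/n) (verified against simulation).
- `birth_rate` [50] and `min_split_height` [0.04] — Yule waiting times plus
  a separation floor added to every split, modelling fully separated (not
  incipient) species-level lineages; the shallowest between-species
  divergence is then ≥ 2·0.04, an order of magnitude above θ, mirroring the
  observed gap between ~0.5% intraclade and ≥4.5% interclade COI
  divergence.
- `kappa` [3] — transition/transversion rate ratio, a typical mitochondrial
  value; `marker_lengths` [658/489/1274] and `relative_rates`
  [1.0/0.4/0.05] mirror a fast mitochondrial coding gene, a slower
  mitochondrial rRNA and a conserved nuclear rRNA.
- Strata: 2 bathyal species in (839, 2743) m and 7 abyssal in (3070, 4693)
  m — the depth ranges actually sampled in such surveys, leaving the
  (2743, 3070) m gap empty; depths are a clade property, specimens jitter
  ±200 m around a species-level centre within the stratum.

Within-species genealogies are redrawn per marker over a shared species
tree (free recombination between loci). A genealogy deeper than its
attachment point is redrawn (≤20 times, then rescaled below the ceiling);
with the preset this is vanishingly rare. All randomness flows from one
seed; identical seeds give byte-identical outputs.

What the generator does **not** emulate: indels and alignment error (gaps
can only enter via masking), rate variation across sites, base-composition
bias, gene flow or incomplete lineage sorting across the species boundary,
and geographically structured sampling within species. Passing tests
therefore show the estimators are correct under the assumed structure, not
that real rRNA alignments are this clean.

## Validation results and known limitations

The replicate studies (sizes chosen to keep a full run within a few
minutes on one CPU: 50 recovery replicates of 27 tips, 200 null replicates
of 20 tips) show: distance-based criteria (gap, 4×, 9 clusters, 9 networks,
depth break spanning 3,000 m) hold in essentially every preset replicate;
GMYC delimits exactly 9 entities in roughly 78–94% of replicates depending
on the seed block (86% at the documented example seed), with failures
almost always a single extra entity. The failure mode is informative: when
one species' deepest internal coalescence is several times its expected
depth, the maximum-likelihood threshold slides just below it, reclassifying
that node as a speciation event. The trade-off is scale-invariant (it
depends only on the wait in units of its expectation), so deeper species
separation does not remove it; it is the small-sample behaviour of
maximum-likelihood GMYC, consistent with the over-splitting this model
family shows on real surveys. The LRT itself is well calibrated (3–5%
type-I at nominal 5%) and rejects the one-species null decisively on every
structured replicate.

Out of scope by design: sequence alignment, substitution-model selection,
Bayesian/parsimony tree inference (trees are inputs; UPGMA is provided as
plumbing only), the multiple-threshold GMYC variant, and absolute GMYC
likelihood values from published trees (tree-scale dependent). The
connection-limit estimator is this package's own finite-sites computation
within the statistical-parsimony framework, not a transcription of any
particular program's internals.
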