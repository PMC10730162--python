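# Methods

This package reimplements, as tested library code, the computational arms of
an in vivo evolution experiment: a single *E. coli* strain colonizing
germ-free wild-type (WT) and *Il10*-deficient (KO) mice, with the KO gut
developing inflammation. The analyses ask (i) which mutations arise and
which are under parallel selection, (ii) whether a focal variant's rise
tracks inflammation, (iii) whether mutation profiles, metabolomes, and
metabolic-activity panels separate the two host genotypes, (iv) which
compound pairs are metabolically adjacent on the strain's metabolic network,
and (v) which metabolites the strain can produce from a given source under
flux constraints. Everything runs on synthetic data whose planted truth is
returned alongside the data, so recovery is self-validating.

## Synthetic study conditions

The generator's defaults are the study conditions, not tuning knobs.

**Cohort.** 14 WT + 11 KO mice sampled at weeks 1, 4, 8, 12. Half of each
genotype forms experiment 1 (one shared inoculum); the rest form
experiment 2 (one independent inoculum per mouse). This split is what makes
parallelism interpretable: a variant standing in a shared inoculum appears
in many mice without any repeated evolution.

**Background mutations.** 200 loci, mutated independently of genotype. Each
(mouse, locus) trajectory is a two-state Markov chain over the sampled
weeks: a detected mutation persists to the next sampling with probability
0.4, and per-week appearance probabilities are solved so the marginal
presence hits 0.435 / 0.17 / 0.225 / 0.18 at weeks 1/4/8/12. Those marginals
reproduce the observed per-mouse de-novo medians (~87 falling to ~36) and
leave roughly half of the endpoint mutations arising after week 8.
Frequencies are drawn as `0.05 + 0.95·Beta(1.5, 10)` — bounded, unimodal,
most mass below 0.3 — so null loci never mimic a sweep. With 200 loci
absorbing this many hits, most loci recur across mice and are *parallel* at
locus level by construction; as in the real data, discrimination comes from
the frequency scan, not from parallelism alone.

**Standing variants.** Each inoculum carries 10 ancestral variants
(frequencies U(0.1, 1)) that persist in all its mice at every week. They are
removed by inoculum subtraction, never by thresholding.

**The planted sweep.** One locus (`mprA_upstream`, an intergenic C>T at
position 3,009,211) rises only in KO mice along a logistic
`f(w) = F_m · logistic(r·(w − m_w/s_m))` with rate `r = 1` per week and
midpoint 5 weeks, truncated-Gaussian noise (sd 0.05), clipped to [0, 1];
calls below the 0.05 detection floor are not written. Two per-mouse features
come from a latent *severity* factor `s_m ~ N(1, 0.25)` clipped to
[0.5, 1.5]:

- the midpoint is divided by `s_m` (severe mice sweep earlier), and
- the attained final frequency is `F_m = F · clip(0.85 + 0.6·(s_m − 1), 0, 1)`,
  so most mice fix or nearly fix the allele while milder mice plateau at
  intermediate frequency.

The same `s_m` scales the KO lipocalin-2 slope. This common-cause coupling
is deliberate: inflammation drives selection, so a mouse with a steeper
marker rise should also carry a faster, higher sweep. Without it, the
within-week ranks of frequency and marker are independent and the pooled
Spearman correlation is capped near 0.85–0.94 no matter how strong the
trends are; with it the pooled rho is reproducibly above 0.9.

**Inflammation marker.** Lipocalin-2 per gram feces:
`(100 + 800·s_m·w)·(1 + ε)` for KO, flat `100·(1 + ε)` for WT, with
multiplicative Gaussian noise (cv 0.1), floored at 0. Units are arbitrary
marker units per gram; only ordering enters the rank-based analyses.

**Feature matrices.** Samples are mice; features are `|N(μ_j, 1)|` with
`μ_j ~ U(4, 8)`. The first `n_shifted` features get their KO mean moved by
`effect_size` standard deviations, direction ~70% higher-in-KO (echoing the
42-up/17-down split of the real metabolome). Defaults mirror the two
panels: 77 features with 59 shifts (metabolome) and 94 with 31 (Biolog-style
AUC panel); the planted-recovery analyses use effect size 2.5, a shift a
25-sample rank test detects with near-unit power.

**Determinism.** Every object draws from `default_rng([seed, crc32(labels)])`
keyed by stable labels ("mutations"/mouse-id, "metabolome"/feature index,
...), so identical configs are byte-identical and adding a mouse or feature
never shifts another object's draws.

**What the generator does not emulate.** No linkage or hitchhiking between
loci (presence is independent per locus), no clonal interference, no
compositionality in the metabolome, no host pathology scores, and no
read-level error model — the pipeline starts at variant tables. Passing
recovery tests therefore demonstrates correctness of the analysis
machinery under the planted model, not robustness to those real-data
complications.

## Variant analyses

Mutation identity is `(position, alt)`: a C>T and a C>A at the same position
are different mutations. De-novo calls are the sample calls whose key is
absent from the founding inoculum's set; the detection floor is
**inclusive** (`frequency ≥ 0.05`, strict mode switchable) — the floor
describes the smallest reportable frequency, and an observed 0.05 is a
detection. Parallelism collapses calls to locus level (gene or named
intergenic region) per mouse and requires carriers from ≥ 2 distinct
inocula. Persistence compares the endpoint key set against each earlier
week per mouse; an empty endpoint set is flagged undefined rather than
reported as 0/0. Locus-frequency matrices aggregate multiple calls in one
locus by maximum frequency, with absent loci as 0.

## Inferential layer

Bray-Curtis `Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)` on nonnegative matrices; a pair of all-zero
samples is undefined and rejected. PERMANOVA is the one-factor adonis form:
`F = (SS_among/(a−1))/(SS_within/(N−a))` from squared distances, free label
permutations, `p = (1 + #{F* ≥ F})/(1 + n_perm)`; the permutation stream is
seeded. Note the minimal attainable p is `1/(1+n_perm)` only while the
permutation space `C(N, n₁)` is large relative to `n_perm`; tiny designs
re-draw the observed labeling by chance. PLS-DA regresses the (centered,
unit-scaled by default) feature block on one-hot group encoding via NIPALS
with deflation (scikit-learn's `PLSRegression`); significance of separation
is tested by PERMANOVA, never read off the fit. Univariate scans use the
two-sample Wilcoxon rank-sum (Mann-Whitney) with midranks — the WT/KO
groups are independent and unequal (14 vs 11), for which the signed-rank
test is undefined; signed-rank remains available for genuinely paired
designs. BH adjustment is applied across each scan's panel. Trajectory vs
marker association pools all (mouse, week) pairs in scope (KO-only or all
mice) into one Spearman correlation: pooling uses the full information,
at the cost of mixing within- and between-week variation.

## Metabolite graph and path linkage

Internal reactions (not exchanges, not biomass) contribute an undirected
edge for every substrate×product pair — conversion edges, never
substrate×substrate. Parallel reactions merge into one edge keeping
reaction provenance. After construction, each edge is weighted by
`degree(u) + degree(v)` on the merged simple graph, which penalizes routes
through high-degree currency cofactors; weights must be recomputed after
any edit. Path scores are the mean total weight of up to five shortest
loopless paths (Yen-style generation over Dijkstra, networkx
`shortest_simple_paths`), averaging to buffer the uncertainty of any single
network route. "Length" is the weighted sum by default (a hop-count switch
exists). For a source's pathway set, the selection cutoff is the
nearest-rank 5% quantile (the `ceil(q·n)`-th smallest finite mean), ties at
the threshold admitted, unreachable targets (infinite sentinel) never
selected. Reaction reversibility is ignored in the default undirected
projection (a directed mode exists); compound-to-model id mapping is always
an explicit caller-supplied table.

## Producibility screen

Models are plain stoichiometric LPs: maximize flux subject to `S·v = 0` and
bounds, solved with HiGHS. For each (source, oxygen) scenario: close all
exchange uptakes, reopen the minimal-medium components (glucose removed by
default so the source is the sole added carbon), set oxygen uptake to
0 / 1 / 10 mmol h⁻¹ gDW⁻¹ (anoxic / microaerobic / aerobic), allow the
source 100 mmol h⁻¹ gDW⁻¹ uptake, maximize biomass, then require
`v_biomass ≥ 0.5·μ*` and maximize each target's exchange flux (a demand
reaction is added when the model has none). A target is producible when the
maximum exceeds 1e-6. Only maximal production is computed by default
(minimization is available). When `μ* = 0` the growth constraint is vacuous
and results carry a `zero_growth` flag; an infeasible scenario reports all
targets non-producible with an `infeasible` status rather than raising.
Solver tolerance is 1e-9; values in (−1e-9, 0) are clamped to zero before
the epsilon call. Only optimal objective values are contractual — flux
vectors are degenerate. The four toy models (linear chain, oxygen-gated
branch, blocked target, currency hub) each have ≤ 15 reactions and
documented ground truth; the blocked-target toy encodes the taurine
pattern: a metabolite with no producing reaction is non-producible under
every oxygen level, implying host rather than bacterial origin.

## Phenotyping arithmetic

AUC is the trapezoidal integral of OD over the recorded window (OD·hours),
no extrapolation, optional blank subtraction floored at zero (default: raw
OD, as no blank handling is specified for the assay); irregular sampling is
accepted even though the nominal design is 15-minute reads over 36 h.
Replicate handling is the arithmetic mean of per-replicate AUCs. Fecal
measures are normalized per gram of wet feces; expression uses
`RPKM = reads·10⁹/(length_bp·library_size)`. Panel-wide condition
comparisons delegate verbatim to the stats scan so both screens share one
inferential path.

## Problem sizes and numerical choices

Default analysis sizes: 25 mice × 4 weeks × ~200 loci; 999 permutations for
PERMANOVA (200 replicates in the calibration study); 50 replicates for the
scan-recovery study; 100 random graphs (≤ 8 nodes) for the path-oracle
study. These sizes give stable Monte-Carlo estimates (rejection-rate s.e.
~0.015) while keeping any single study in seconds. Ties use midranks
everywhere; rank tests switch to the tie-corrected normal approximation for
larger samples (scipy's default policy). BH adjustment delegates to
statsmodels. Quantile selection uses nearest-rank order statistics — no
interpolation, so thresholds are always attained lengths.

## Known limitations

- Locus-level parallelism saturates on the default synthetic cohort (most
  background loci recur); the sweep is pinpointed by the scan and the
  marker correlation, as in the motivating study.
- The minimal-medium composition for real genome-scale models ships as an
  editable config placeholder; the toy models carry their own media.
- The SBML reader/writer covers only the subset the models need (species,
  reactions, stoichiometry, reversibility, bounds as attributes); it is not
  a general SBML implementation.
- PLS-DA loadings are reported under a fixed centering/scaling convention;
  raw-abundance PLS-DA is available via `scale=False` since the original
  scaling choice is not documented.
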