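# Methods

## Models and procedures

### Functional profiles in copies per genome

Gene counts are TPM-normalized at gene level with gene lengths in kb
(`rate_g = count_g / length_kb_g`, scaled so each sample sums to 10⁶), then
summed per functional role; a gene annotated with several roles counts once
per role.  Each sample is divided by its median TPM over a list of universal
single-copy genes (USCGs), so the USCG median is exactly 1 and role
abundances read as mean copies per genome.  The median over an even number
of USCGs is the midpoint of the central pair.

The core microbiome is the smallest prefix of the genera ranked by mean
relative abundance whose cumulative mean reaches 90% of the total; genera
tied with the boundary genus are all included so the definition is
order-independent.  A configurable 10⁻⁴ mean-abundance taxon filter
(`filter_taxa`) can be applied beforehand.  Core relative abundances
renormalize each sample over the core.

### Reconstruction

Genus role sets are topped up to the expected role count (from reference
genomes) with the highest-scoring absent roles under a co-occurrence model:
Laplace-smoothed marginals p(j) = (n_j + c)/(N + 2c) and pairwise joints
with the same pseudocount; an absent role scores the mean of p(j | i) over
observed roles i.  This is a deliberately simple stand-in for a latent-
variable model of binary presence/absence data; the scorer is a plain
object, so an alternative can be plugged in.  Ties break lexicographically.

Roles map to reactions through annotation complexes.  In the default
`all_roles` mode a reaction is included iff some complex pointing to it has
all required roles present; `any_role` (one suffices) is available because
annotation pipelines differ on this rule.  Draft models get the Gram-matched
biomass template, a biomass sink, and an uptake reaction (bounds
[0, 100] mmol gDW⁻¹ h⁻¹) for every external metabolite touched by an
included transporter — only transporters grant exchanges.

Gap-filling solves one LP over the universal network: minimize
Σ_{r ∉ draft} w_r (v_r⁺ + v_r⁻) subject to S v = 0, v_biomass ≥ 0.001
mmol gDW⁻¹ h⁻¹ and reversibility-aware bounds, with reversible reactions
split into irreversible halves (equivalent to weighted total absolute flux).
Weights are database penalties, multiplied by 0.5 for candidates whose
subsystem is already represented in the draft (a bonus that preserves the
penalty ordering) and floored at 10⁻³ so no candidate is free.  Candidates
with |flux| > 10⁻⁶ (solver noise margin) are added.  The gap-fill medium
opens an uptake (bound 100) for every transporter-backed external of the
universal network, not only those of the draft: recruiting a missing
transporter is a legitimate gap-fill move, and with draft-only uptakes such
candidates could never carry flux.

### Phenotype screens

FBA maximizes biomass flux under S v = 0 and bounds (scipy's HiGHS LP).  An infeasible LP raises a distinct error; feasible-but-zero growth is
a normal result.  A per-model `FBAProblem` caches the constraint matrix so
media only move bounds; random-media viability results are additionally
memoized by uptake set, which makes both the Monte-Carlo screen and the
exact enumeration oracle cheap on models with few transporters.

*Main sources.*  Baseline: max biomass with Σᵢ atomsᵢ·vᵢ ≤ 10 over all
element-carrying uptakes.  Test: the same LP with the candidate exempted
from the sum and its own uptake bounded by 100.  Usable iff
test ≥ max(2 × baseline, 0.001); the viability floor guards the degenerate
baseline-zero case where "twice baseline" alone would be vacuous.
Compounds without an uptake are recorded unusable (strict mode errors
instead).

*Essentiality.*  Media open each transporter-backed uptake independently
with probability p = 0.9 at bound 10; media are drawn until 1000 viable
ones accumulate (cap: 50 × n attempts, then an error reporting the
viability fraction).  Within each viable medium every open metabolite is
closed singly; closing metabolite m in medium S is exactly the medium
S \ {m}, so essentiality reduces to lookups in the memoized viability
table.  Scores are essential/present counts per metabolite; the genus mean
is the unweighted mean over scored metabolites.  A robustness variant opens
direct uptakes for transporter-less metabolites with probability q,
injecting flux at a caller-specified target metabolite (typically the
cytosolic form) to emulate transporters missed by annotation.

Per-uptake bounds (10 in random media, 100 for exempted compounds and
complete media) are finite so LPs stay bounded, and configurable; the
viability floor reuses the gap-fill biomass floor (one threshold for
"supports growth" everywhere).  Batch seeds derive from a master seed and
the genus name via a stable 32-bit hash, so per-genus streams are
reproducible and independent of iteration order.

### Community metrics and statistics

Utilization potential and metabolic demand are abundance-weighted sums over
core genera; genera lacking a score for a metabolite (no transporter)
contribute zero demand for it — absence of demand, not missing data.  Both
metrics are convex combinations of per-genus values, hence bounded by the
per-genus extremes.

Mann-Whitney U: exact enumeration of all group assignments for
n₁ + n₂ ≤ 12 with mid-ranks (ties included in the enumeration), otherwise
the tie-corrected normal approximation.  Two-group Z ranking uses unbiased
(n−1) sample variances; a zero pooled variance yields Z = 0 at equal means
and a ±10⁶ sentinel otherwise.  Feature filters follow the prevalence rules
(nonzero in ≥ 2 samples for Z, ≥ 3 for the weight correlation).  Ranking
lists sort by (statistic desc, feature id asc) and drop non-finite values.

Metabolomics: per-metabolite median scaling over observed values (observed
median becomes 1), minimum-value imputation, Welch's t on natural-log values
with Welch–Satterthwaite df (the log base only rescales both group means and
standard deviations identically, so t is base-invariant), Benjamini-Hochberg
q over metabolites.

Preranked GSEA: weighted Kolmogorov–Smirnov running sum (hit steps weighted
by |statistic|^exponent, default 1; miss steps 1/(N−|S|)); the null pools
random same-size member selections (feature-label permutation), nominal p
and NES use the same-sign portion of the set's own null, FDR q the
sign-stratified pooled-null convention of the original method.  Minimum set
size 3.  Deterministic under a fixed seed.

## The synthetic generator: what it emulates, and what not

The toy universal database plants explicit routes: carbon sources (2–6 C)
and nitrogen sources (1–2 N) each with a transporter and a one- or two-step
conversion to a carbon-skeleton or nitrogen-carrier precursor with
atom-conserving yield; a mineral consumed directly by biomass; mixed
amino-acid-like compounds routed to carbon only; dead-end distractor
reactions; penalties uniform on [0.5, 5].  Genus plans choose usable
sources plus decoy transporters, so planted capabilities follow from the
routes by construction, and exact essentiality comes from enumerating all
2^k uptake subsets with binomial weights (k ≤ 10 by design, keeping the
enumeration the testing oracle).  Gap-fill toy instances use unit-
stoichiometry alternative paths, so the LP's flux-weighted objective ranks
paths exactly by penalty sum and the exhaustive-subset optimum is the
correct comparison.

Community studies draw control abundances from a Dirichlet around
decreasing base proportions (top genera ≈ 90% cumulative, concentration 60,
i.e. per-genus compositional noise of a few percent); the treated arm tilts
the base proportions by exp(demand_effect · (ē − e_g)) toward
low-essentiality genera.  The default demand_effect = 1.0 was fixed by an
a-priori power analysis: it shifts per-sample demand by ≈ 1.6 sampling
standard deviations, which puts the one-sided Mann-Whitney at n = 15 + 15
near-certain detection while demand_effect = 0 stays at the nominal false-
positive level.  Host weights are 2600 − 1200·D_s + N(0, 80²) grams —
negatively tied to demand with realistic day-35 broiler magnitudes.  Gene
counts are Poisson around abundance × gene-length expectations with ten
USCG roles at one copy per genome; metabolite intensities are log-normal
(σ = 0.4) with one pathway shifted down and one up by 0.7 natural-log units
in the treated arm and left-censored missingness (≈ 5%, the dimmest tail),
matching the rationale for minimum-value imputation.

What the generator does **not** emulate: real taxonomic structure,
strain-level gene-content variation, sequencing (reads, mapping error,
contamination), compositional biases of abundance estimation, reaction
reversibility/thermodynamics of real databases, cross-feeding between
genera (single-genus FBA only, weighted after the fact), or diet/litter
covariates.  Passing tests therefore demonstrate the correctness of the
algorithms under their stated models — not that the biological conclusions
would replicate on real sequencing data.

## Numerical choices

- LP solver: HiGHS via scipy.optimize.linprog; FBA oracle agreement checked
  to 10⁻⁷ against an independently assembled dense LP.
- Gap-fill flux tolerance 10⁻⁶; bonus floor 10⁻³; biomass floor 10⁻³.
- Exact Mann-Whitney and Spearman permutation p-values below n = 12 / n = 5;
  t-approximations above.
- Degenerate inputs: all-zero samples, never-observed metabolites, zero core
  abundance, unknown Gram status, infeasible LPs and non-viable models all
  raise errors naming the offending sample/genus; zero-variance statistics
  follow the sentinel rules above.
- Ties everywhere break lexicographically by id; all randomness flows
  through numpy Generators seeded explicitly.
- Problem sizes in tests and the acceptance script (toy databases of ~50–60
  reactions, six genera, ≤ 8 uptakes per genus, 1000-media screens, 100
  replicate cohorts) were chosen so exhaustive oracles remain exact
  references while the full suite stays quick.

## Known limitations

- The co-occurrence imputation is a marginal/pairwise approximation; roles
  that only co-occur conditionally on latent strain structure will be
  mis-scored.
- Gap-filling minimizes flux-weighted penalties; on networks where
  restoring growth needs high-flux loops the added set need not coincide
  with the minimum-penalty subset (the toy instances avoid this by
  construction, and the enumeration oracle guards the claim there).
- GSEA normalization follows the sign-stratified convention; with very few
  permutations the FDR q is coarse.
- Essentiality conditions on viable media only; metabolites of genera that
  are non-viable under random media are not scored (an error reports the
  viability fraction instead).
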