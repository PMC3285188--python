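# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices, and the known limitations of the package.  It is the
place where genuinely open design decisions are recorded.

## Study design and data model

The pipeline analyses paired pre/post-treatment expression studies with
two patient groups.  The canonical shape — used as the generator default —
is 6 insulin-free (IF) and 3 insulin-dependent (ID) patients, each with
one pre-treatment and one post-treatment PBMC profile on a log2 scale.
Loaders enforce the paired design (every patient exactly one `pre` and one
`post` sample), align samples to the design by id rather than position,
never reorder genes, and drop genes with missing values (correlation and
paired statistics need complete vectors; imputation at n ≤ 6 would
manufacture information).  Expression input is TSV or GCT `#1.2`; gene
sets are GMT; clinical tables are TSV with `-` for "not acquired".
Multiple probes per gene are not collapsed by default; an explicit option
keeps the first occurrence with a warning, because no principled collapse
rule exists without annotation data.

## Random variance model (moderated paired t)

For gene g, the per-patient paired differences d (post − pre, log2 units)
give the mean d̄, sample variance s² and m = n − 1 degrees of freedom.
The gene-wise precision is modelled as shared across genes,

    1/σ²_g ~ Gamma(shape a, scale b),

under which s²·a·b ~ F(m, 2a).  The hyperparameters are fitted once per
group by maximizing the marginal likelihood of all gene variances
(Nelder–Mead on (log a, log b), three starts, moment-based initial b;
non-convergence or a → ∞ raises an error carrying the last iterate, the
latter because equal variances make moderation a no-op and the ordinary
paired t is the right tool).  Each gene's variance is then replaced by the
posterior mean

    s̃² = (m·s² + 2/b) / (m + 2a),

and t = d̄ / √(s̃²/n) is referred to a t distribution with m + 2a degrees
of freedom.  s̃² is strictly increasing in s², so moderation preserves the
variance ranking.  Under the model the moderated t is exactly
t-distributed, which the type-I calibration test verifies empirically
(nominal 0.05 within [0.04, 0.06] on 10,000 null genes).  FDR control is
Benjamini–Hochberg (the standard choice where only "FDR" is specified);
adjusted q satisfies q ≥ p.  Genes pass at p < 0.05 and q < 0.05 by
default.  Direction is Up iff d̄ > 0 (higher expression after treatment);
across groups, a gene selected in both with discordant directions is
classed "Other", otherwise it keeps its (single- or concordant-group)
direction.  The two groups are tested separately, with the union of
selections feeding the network stage.

## Pathway over-representation

For each gene set, the 2×2 table of DE-membership × set-membership over a
background universe is scored with the one-sided Fisher exact test
(hypergeometric upper tail; a two-sided variant is available by flag) and
the chi-square test with continuity correction; both are reported, with
the Fisher p as the default significance gate and the BH q computed on
it.  The universe is the genes actually present in the expression matrix,
not all annotated genes — the standard guard against annotation bias.
Sets with zero overlap are reported with p = 1 rather than dropped.
Results are ranked by Fisher p with a top-20 default report.

## Differential connectivity (K, DiffK, hubs)

Four Pearson correlation networks are built over the combined DE gene set,
one per group × timepoint cell.  Before correlation, the IF group's six
samples per timepoint are merged down to three: samples are paired
greedily by smallest 1 − r distance within each timepoint (this greedy
mutually-closest pairing is the pair-merging special case of
average-linkage clustering), each merged profile is the arithmetic mean of
its pair, and merged pre/post profiles are matched into pseudo-patients by
patient overlap.  The merging map is logged and carried in the returned
study's metadata.  Whether the original analysis used one pairing for both
timepoints is unknowable from the published description; pairing per
timepoint independently is the weaker assumption and is what is
implemented.

Connectivity is unsigned: K_i = Σ_{j≠i} |r_ij| with the diagonal
excluded, normalized per network by its maximum, k_i = K_i / max_j K_j, so
every network has at least one gene at exactly k = 1 (ties all map to 1).
Unsigned |r| keeps k in [0, 1] and is the convention of the connectivity
framework this statistic descends from; a signed variant sits behind a
flag.  Genes constant within a condition are dropped with a warning.
DiffK_i = k_post,i − k_pre,i ∈ [−1, 1].

**Permutation null.**  The published description never defines the hub
p-value's null; the package's interpretation is the natural paired-design
null: swap pre and post within each patient, recompute everything
(including the sample merging) per permutation, and compare |DiffK*|
against |DiffK_obs| two-sidedly.  With n patients there are 2ⁿ swap
patterns; when 2ⁿ ≤ n_perm the patterns are enumerated exhaustively and
p = #{|DiffK*| ≥ |DiffK_obs|}/2ⁿ — an exact, deterministic test whose
floor is 2/2ⁿ (identity and full swap always tie the observed value).
Otherwise n_perm random patterns are drawn and the add-one estimator
(1 + #exceed)/(n_perm + 1) is used.  n_perm < 100 is refused.  A direct
consequence worth stating: a 3-patient group has only 8 patterns and a
floor of p = 0.25, so permutation-based hub calls are impossible there —
any published hub list for such a group must rest on a different (and
unstated) null.  An alternative gate on the DE p-value is available by
flag for that situation.

**Sectors and hubs.**  The (DiffK, p) plane is cut at DiffK = ±0.2 and
p = 0.05 into six sectors, numbered so that sector 1 = (DiffK > 0.2,
p < 0.05) and sector 3 = (DiffK < −0.2, p < 0.05) — the two significant
flanks; 2 and 4 are the corresponding non-significant flanks, 5 the
non-significant middle, 6 the significant middle.  A hub is a gene in
sector 1 or 3.  Node/edge tables (signed edges at |r| ≥ 0.8 by default —
no published threshold exists, so it is configurable) export to graph
viewers; node records carry k, the hub flag and the DE direction.

With only three profiles per condition a Pearson correlation is extremely
noisy — after centering, each gene is effectively an angle in a 2-D
sample space, and the magnitude of a null correlation averages 2/π ≈ 0.64.
Every conclusion at this depth leans on the permutation p, not on the
correlation point estimates; this is stated prominently because it also
shapes what synthetic scenarios can honestly guarantee (below).

## Synthetic data: what it emulates, what it guarantees, what it does not

The generator produces paired two-group studies from four ingredients:

* **Variances.**  Gene-wise true variances of the paired difference are
  drawn from the inverse-gamma prior (default a = 2, b = 1); per-condition
  noise has sd σ_g/√2 so the difference variance matches the prior and the
  RVM fit is testable by parameter recovery end-to-end.
* **Differential expression.**  A fraction (default 5%) of genes gets a
  ±δ (default 1.5 log2) post-treatment shift in both groups, disjoint
  from module genes.  With the study-shaped n this yields realistically
  limited power, which the selection tests acknowledge.
* **Baselines.**  Gene means ~ N(8, 1) log2 units, the typical range of
  RMA-style summaries.
* **Correlation modules.**  Latent-factor mixing
  x = √r·f + √(1−r)·ε gives pairwise correlation r within a block, with
  r switching from r_pre to r_post between timepoints.  Modules may load
  on a factor shared across the condition (`shared_factor`), which couples
  them to other shared-factor blocks at √(r·r′) — this is how a "network
  core" and modules that attach to or detach from it are built.

Two further knobs exist because three-profile correlation estimates are
not pinned down by population parameters:

* `decorrelate_noise` residualizes a module's idiosyncratic noise against
  the shared factor within each condition's sample space (and draws that
  noise from a unit-variance bimodal law bounded away from zero, so no
  single noise coordinate dominates a small-sample correlation).  This
  makes the planted correlation hold in-sample and gives designated hub
  genes a DiffK of known sign even at three profiles.
* `var_scale_post` inflates a module's post-treatment standard deviation,
  emulating the idiosyncratic volatility of genes that decouple from
  their regulatory program.  In the hub-recovery scenario this is what
  makes every single-patient label swap strictly damage the planted
  signal, so the exact permutation test resolves the planted hubs.

The canonical hub-recovery scenario (`hub_recovery_spec`) plants a
400-gene stable core (r = 0.98 on the shared factor) and a 15-gene module
that is wired into the core before treatment (r = 0.9) and fully decoupled
after (r = 0, 4× sd): its genes lose most of their normalized
connectivity (DiffK ≈ −0.8) and are recovered as sector-3 hubs.  Because
one 15-gene module quantizes recovery in steps of 1/15 and the exact
permutation floor leaves room for occasional single-pattern ties, the
recovery rate is reported as the mean over five generator replicates.
The same scenario with r_post = r_pre is the negative control: hub calls
stay at or below the nominal rate.

For merged-group scenarios the generator can emit an even-sized group as
near-duplicate pairs (`duplicate_pairs`): two jittered copies (relative
jitter 5% of the per-condition sd) of each latent profile, so the
similarity-based merging provably recovers the planted pairing.

**What passing these tests does not show.**  The generator's modules are
low-rank factor constructions with controlled sample-space geometry; real
PBMC co-expression has neither exact factor structure nor in-sample
decorrelation, and real rewiring is not accompanied by a convenient
variance signature.  Synthetic recovery demonstrates that the statistics
and their implementation behave as designed under conditions where the
truth is known — it does not certify sensitivity on real microarray data,
where the published hub counts additionally depend on unshared
preprocessing choices.  Nothing about probe-level artifacts or batch
effects is simulated.

## Clinical statistics

The group comparisons of a nine-patient table need exact tests.  The
Mann–Whitney U uses midranks for ties; its two-sided p is computed by
complete enumeration of all C(n1+n2, n1) assignments of the observed value
multiset, counting assignments whose U deviates from the null mean
n1·n2/2 by at least the observed deviation.  Under heavy ties this
deviation criterion is not the same as doubling the one-sided tail — six
zero insulin doses against three positive ones give p = 1/84 ≈ 0.012,
where 2× one-sided would give 0.024 — and it is the definition that
reproduces the published values; on tie-free data it coincides with the
classical exact two-sided test (verified against an independent
implementation).  Enumeration is refused above n1 + n2 = 25 with a
pointer to asymptotic alternatives.

Paired t is the ordinary d̄/(s_d/√n) with incomplete pairs dropped and
logged; identical columns give p = 1, and zero-variance differences with a
non-zero mean are an error rather than an infinite statistic.  Group
summaries report the arithmetic mean and the n−1 sample SD, with SD
undefined (missing, not zero) at n = 1.  GADA titers are natural-log
transformed before analysis (a no-op for rank tests, material for means);
non-positive titers are rejected at load time.  C-peptide stimulation
curves integrate by the trapezoid rule over strictly increasing times —
the published AUC's sampling scheme is unstated, so this is provided as
plumbing, not as a reproduction.

One documented discrepancy: the published IF-group GADA mean (864.8
U/mL) equals neither the arithmetic mean (1197.0) nor the geometric mean
(≈435) of the six printed titers.  The package reports the arithmetic
mean of the printed column and makes no attempt to reverse-engineer the
printed cell.

## Numerical choices and problem sizes

* RVM fit: Nelder–Mead, xatol 1e-8, three starts; requires ≥ 50 usable
  variances.
* Exact permutation enumeration caps at 2ⁿ ≤ n_perm; Monte-Carlo add-one
  beyond.  Permutation comparisons use a 1e-12 slack so identical values
  tie rather than flicker on rounding.
* Correlations are clipped to [−1, 1] before |·| sums; zero-variance
  genes are dropped, never imputed.
* Calibration and recovery checks run at 10,000 genes (variance prior,
  type-I error) and 500 genes × 5 replicates (hub recovery) — sizes at
  which the Monte-Carlo error is well inside the asserted tolerances
  while the full suite stays fast.
* With a fixed generator seed the entire pipeline is byte-identical
  across runs; exact-mode permutation p-values are seed-free.

## Limitations

* Correlation networks at three profiles are qualitative instruments;
  the package surfaces this rather than hiding it (exact p floors, noisy
  r documented).  The ID group's 8-pattern permutation null cannot reach
  p < 0.05 at all.
* The RVM assumes a single shared variance prior; strong
  variance-structure violations (e.g. bimodal variance populations) are
  fitted but not flagged.
* CEL-file preprocessing (RMA), probe annotation, and the original
  pathway database contents are out of scope; the pipeline starts from a
  normalized log2 matrix and user-supplied GMT sets.
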