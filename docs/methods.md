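# Methods

## The membership test and the budget

A Beacon answers Boolean presence queries about genomic variants. The
re-identification threat model is a likelihood-ratio test between H₀ (the
target's genome is not in the cohort) and H₁ (it is), over a series of
answers x₁…xₙ about variants the attacker knows the target carries. The
log-likelihood of a series is L(R) = Σ xᵢ ln Pr(xᵢ=1) + (1−xᵢ) ln Pr(xᵢ=0),
and Λ = L_{H₀} − L_{H₁}. With mismatch probability δ between the attacker's
copy of the genome and the Beacon content (`lrt_general`):

    Λ = Σ ln((1−fᵢ)²/δ) + xᵢ · ln( δ/(1−fᵢ)² · (1−(1−fᵢ)^{2N}) / (1−δ(1−fᵢ)^{2N−2}) )

In the attacker's best case δ = 0, every answer must be "yes" and the test
collapses to Λ = Σ ln(1 − (1−fᵢ)^{2N}) (`lrt_optimal`). The server-side
defence caps |Λ|: each (user, subject) pair starts with budget −ln p, and a
"yes" about a variant spends risk(f, N) = −ln(1 − (1−f)^{2N}) from every
carrier's budget. A variant whose risk exceeds any carrier's remaining
budget is occluded (a deliberate false negative) at zero cost. Consequences,
all property-tested:

* the evidence any single user can accumulate about any subject is bounded
  by −ln p (plus nothing: occlusion is checked *before* spending);
* occlusion costs nothing, so a blocked query cannot be used to drain
  budgets;
* budgets are conserved exactly: initial budget minus the debits of
  answered variants equals the stored remaining budget to 10⁻¹².

Budgets are global per (user, subject), not per dataset, so a subject
present in two datasets is protected jointly. Occlusion is per variant: a
range query returning several variants drops only the risky ones, and the
Boolean response reflects the survivors.

Natural logarithms are used throughout (budgets and risks in nats); any
base is self-consistent, and the natural log matches the likelihood-ratio
convention of the attack literature.

### Collusion

k colluders who know p can extract at most k·(−ln p) nats by skipping
unaffordable variants and handing over when a budget is exhausted, hence
`min_colluders(p, α) = ⌈ln α / ln p⌉` (5 at p = 0.5, α = 0.05). Colluders
who do *not* know p cannot avoid false negatives and must score them with
the RIP-aware statistic (`lrt_collusion`):

    Λ = Σ (1−xᵢ) ln((1−fᵢ)²/ρ) + xᵢ ln(1−(1−fᵢ)^{2N})

where ρ is the probability that a "no" is a RIP false negative. The
simulator estimates ρ from the running statistic as ρ = 1/(1+exp(Λ)), i.e.
a uniform prior on membership updated by the evidence so far; the source
only states that ρ can be estimated from the previous iteration, so the
uniform-prior form is this package's choice. For rare variants and a high
p, the false-negative set-back offsets the evidence an attacker gathers
before their budget runs out, so collusion without p makes no expected
progress — verified as a simulation property, not assumed.

## History, recall, and replay

Every RIP-mediated query is logged with its canonical key (sorted
parameters, case-folded bases, granularity excluded — RIP responses are
Boolean regardless), the stored Boolean answer, and the kept/occluded
variant ids. Repeats are recalled with budgets untouched. The ledger is
derivable from the history: `recompute_budgets` replays the debits of all
returned variants at the *current* cohort size. Replay never occludes (past
answers are immutable); since risk is strictly decreasing in N, growth can
only refund budget. The CLI treats the history as the single source of
truth and rebuilds the ledger before serving, so a crash between a debit
and a history append can never double-charge.

## The synthetic cohort generator

`generate_cohort(n_subjects, n_variants, sfs, seed)` draws per-variant
population frequencies from a density ∝ 1/f on [f_min, f_max] (inverse-CDF
of the rare-skewed neutral spectrum), defaulting to f_min = 1/(2·n_subjects)
and f_max = 0.5, and gives each subject carrier status independently with
probability 1 − (1−f)² (Hardy–Weinberg diploid carriage). Carriage is
binary — zygosity is never used, matching Boolean responses. The annotated
`population_frequency` is the generative f, not the realised in-cohort
fraction, mirroring a deployment where frequencies come from an external
reference panel rather than from the Beacon's own genotypes.

Two experiment-specific configurations build on this:

* **Attack cohort** (2504 subjects × 200 000 variants, default spectrum).
  The 200k catalog is exome-scale; with the cohort-floored spectrum the
  aggregate evidence carried by a typical subject (≈ 4 nats) comfortably
  exceeds the −ln 0.1 ≈ 2.3 budget, so rarest-first attacks terminate by
  occlusion after a handful-to-tens of queries. Attacks are capped at 100
  queries because a truncated spectrum leaves a small tail of subjects who
  carry too little aggregate evidence ever to be occluded.
* **Discovery catalog** (`make_discovery_dataset`: 2504 subjects × 10 000
  variants). Population frequencies extend down to a reference-panel floor
  of 10⁻⁶ (one allele in a biobank-scale panel of ~500k subjects), and
  every catalogued variant is guaranteed one uniformly chosen carrier
  (`ascertained=True`): a Beacon stores only variants observed in its
  cohort, and real cohorts are full of singletons whose panel frequency is
  far below 1/(2N). Without this ascertainment model, binomial sampling at
  N = 2504 would almost never realise a carrier for panel-rare variants and
  first-query occlusions — the phenomenon the experiment measures — would
  essentially never occur.

What the generator does **not** emulate: linkage disequilibrium between
variants, relatedness between subjects, frequency estimation error in the
external panel, sex chromosomes/ploidy, and genotyping error. Passing tests
therefore certify the budget arithmetic and the serving logic under an
idealised independent-sites cohort, not attack hardness against correlated
real genomes (kinship or LD-imputation attacks are out of scope).

## Experiment designs and problem sizes

* **Optimal attack**: 100 random targets, one fresh attacker each, p = 0.1,
  through the full query-engine + RIP stack. On the 2504 × 200k cohort this
  yields a mean of ~10 successful queries (range ~5–100 with the cap),
  the same order as reported for attacks on the 2504-subject reference
  dataset.
* **Discovery scaling**: 100 runs × up to 100 random variants per run at
  simulated sizes N ∈ {2504, 10000, 25000, 100000}, p = 0.1. All sizes
  share one genotyped cohort and spectrum; only the N in the risk formula
  varies (`size_override`), matching the design of varying the simulated
  dataset size rather than ingesting larger genotype sets. Sizes are
  compared with **common random numbers** — the same researchers issue the
  same query sequences at every size — which pairs the comparison and,
  because risk is monotone in N, makes run lengths per-run monotone rather
  than merely monotone in expectation. A run is a *zero run* iff its first
  variant satisfies risk(f, N) > −ln p; the simulation's flags are asserted
  equal to this closed form on every run.
* **Safety audit**: 200 randomized strategies (random sequence/range/gene
  query mixes) on a 500-subject cohort; for every user and subject the sum
  of risks over unique answered variants carried by the subject is checked
  against −ln p (tolerance 10⁻⁹). Observed worst case: ≈ 0.999 of the
  budget — tight but never exceeded.

## Numerical choices

* risk(f, N) is computed as −ln(−expm1(2N·log1p(−f))): stable both for
  tiny f with large N (power close to 1) and for common f, where the power
  underflows (below ~10⁻³⁰⁰) and the risk is exactly 0.
* Frequencies below the configured floor (default 1/(2·10⁶)) are clamped up
  to it before computing risk: f = 0 would make the risk infinite, which
  the budget model does not define; the floor makes unannotated or
  zero-frequency variants maximally protected but finite.
* Occlusion uses a strict comparison (risk > remaining), so a variant whose
  risk exactly equals the remaining budget is answered and the budget
  reaches exactly 0.
* A variant with no carriers is answered for free — no subject's membership
  is at stake.
* Rarest-first orderings break frequency ties by variant id, keeping attack
  simulations deterministic given the seed.
* `min_colluders` guards its ceiling against floating-point edge cases by
  adjusting ±1 until k·(−ln p) ≥ −ln α > (k−1)·(−ln p) holds exactly in
  floats.
* The ledger persists budgets with 17 significant digits, so TSV round
  trips are bit-exact; history replay with unchanged N reproduces the live
  ledger exactly (same floats, same order).

## Design choices where the design was open

* Count/record granularity under RIP is **downgraded** to Boolean rather
  than rejected: Boolean-only responses are mandated under the budget
  model, and downgrading preserves discovery utility.
* Inaccessible datasets are **omitted** from responses instead of appearing
  as "no access" entries — revealing a dataset's existence to an
  unauthenticated user is itself metadata leakage.
* Bracket bounds are inclusive on both ends; range overlap is half-open
  [start, end) on 0-based interbase coordinates (VCF input is 1-based and
  converted at the boundary). `variantMinLength`/`variantMaxLength` filter
  on the length of the alternate allele.
* Occluded variants cost nothing: under the δ = 0 attack model a "no"
  hands the attacker no H₁-favouring evidence, and the occlusion is
  recorded in history so the same false negative is replayed consistently.
* History recall is keyed per (user, dataset, canonical query), so the same
  query against two datasets is two history entries.
* The deployed p is read from configuration and never echoed in responses,
  logs, or `repr`.

## Known limitations

* The attack/discovery magnitudes are distribution-dependent: they reproduce
  the order of magnitude and the scaling trends of the reference
  deployment, not its exact table values, which additionally depend on an
  undisclosed p and on real (Ensembl) frequency annotations.
* Metadata queries, phenotype filtering terms, kinship attacks and
  LD-based imputation attacks are out of scope.
* Serving-time collusion *detection* is not attempted; the deployed
  mitigation is the confidentiality of p.
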