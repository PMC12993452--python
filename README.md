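# beaconrip

Beacon-style genomic variant discovery with a re-identification prevention
budget.

## The problem

A *Beacon* is a data-discovery API that answers whether a genomic variant is
present in a cohort. Even when the answer is a bare Boolean, it leaks: an
attacker who already holds (part of) a target's genome can issue a series of
queries about the target's variants and run a likelihood-ratio test between

* H₀ — the target's genome is **not** in the cohort, and
* H₁ — the target's genome **is** in the cohort.

For an all-"yes" answer series about variants with population allele
frequencies *fᵢ* in a diploid cohort of *N* subjects, the attacker's
statistic is

&nbsp;&nbsp;&nbsp;&nbsp;Λ = Σᵢ ln(1 − (1 − fᵢ)^{2N}),

which grows more negative (more evidence for membership) the rarer the
queried variants and the smaller the cohort. Confirming cohort membership is
a privacy breach in itself — the cohort may be a disease study.

`beaconrip` implements the mitigation known as the **budget strategy**, here
the Re-Identification Prevention (RIP) algorithm: every (user, data subject)
pair holds a budget initialised to −ln *p*, where *p* is the smallest
membership-test p-value the server will ever let a user reach about any
subject. Each answered variant spends, from every carrier's budget, its
evidence contribution

&nbsp;&nbsp;&nbsp;&nbsp;risk(f, N) = −ln(1 − (1 − f)^{2N});

a variant whose risk would overdraw any carrier's remaining budget is
*occluded* — silently removed, producing a deliberate false negative.
Repeated queries are recalled from a history log without further spending,
and budgets can be recomputed from that history when the cohort grows. The
deployed *p* is kept confidential: publishing it would let colluding users
skip unaffordable variants and pool budgets (with *p* = 0.5, five colluders
reach α = 0.05).

The package provides:

* `variant_store` — datasets (VCF 4.x + frequency-sidecar I/O), and a
  synthetic cohort generator with a rare-skewed 1/f site-frequency spectrum;
* `query_engine` — the six Beacon v2 genomic query subtypes (sequence,
  range, gene, bracket, genomic allele, amino-acid change), the three-tier
  access matrix (public / registered / controlled × unauthenticated /
  authenticated / researcher / authorized researcher), and RIP routing;
* `rip` — budgets, risk, occlusion, history recall, ledger replay;
* `attack_sim` — the likelihood-ratio machinery (general δ-mismatch test,
  optimal δ = 0 test, collusion-aware test), the rarest-first "optimal"
  attack, and single/colluding attacker simulations run through the real
  serving stack;
* `discovery_sim` — the utility side: how many honest random-variant queries
  a researcher gets before the first occlusion, across cohort sizes;
* a `beaconrip` command-line interface over all of the above.

## Worked example

Generate a synthetic 2504-subject cohort and query it as an authenticated
user without explicit access:

```sh
$ beaconrip generate --subjects 2504 --variants 5000 --seed 7 \
      --out-dir data --dataset-id demo
wrote demo: 2504 subjects, 5000 variants -> data
```

With `config.json` declaring the dataset (registered access), a user roster
(`alice`, authenticated) and `{"rip": {"p": 0.1}}`, a count-granularity query
for a rare variant (f ≈ 2.0 × 10⁻⁴) returns:

```sh
$ beaconrip query --config config.json --user alice --query query.json
[
  {
    "datasetId": "demo",
    "exists": true,
    "ripApplied": true
  }
]
```

The response is downgraded to a Boolean (`count` is withheld) because the
dataset is served through RIP, and alice's budget for each carrier of that
variant has been debited by risk(2.0 × 10⁻⁴, 2504) ≈ 0.46 nats out of
−ln(0.1) ≈ 2.30. Re-running the same command returns the identical response
and leaves the ledger file byte-identical — the answer is recalled from
history.

The discovery simulator quantifies what honest users keep:

```sh
$ beaconrip discovery-sim --p 0.1 --sizes 2504,10000,25000,100000 \
      --runs 100 --max-queries 100 --variants 10000 --seed 0
size    mean_queries    zero_run_pct
2504    3.49    20.0
10000   8.18    10.0
25000   15.44   7.0
100000  100.00  0.0
# linear fit: mean_queries ~ 1.017e-03 * N + -3.186
```

Reading: at the 2504-subject scale a researcher averages ~3.5 unadulterated
random-variant queries before the first occlusion and 20% of runs are
stopped on their very first query, while at 100 000 subjects the budget is
effectively never binding — discovery utility grows roughly linearly with
cohort size.

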