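# boswellia

Bioeconomic modelling and experiment-simulation toolkit for frankincense
tapping as a common-pool resource (CPR) problem.

Smallholder harvesters in Ethiopian drylands tap communal *Boswellia
papyrifera* woodland: wounding the bark releases resin, but every wound
degrades the tree's resin-bearing capacity. Under short-term use rights
(trees reallocated among users each period) harvesting is myopic and
over-extractive; communities respond with collectively voted, non-binding
extraction targets, and compliance may depend on the harvesters' social
capital and on whether individual decisions are publicly revealed. This
package implements, for researchers in ecological economics and
experimental resource management:

1. the tapping/health/payoff model with analytic and exhaustive-search
   extraction benchmarks under long- and short-term property rights,
2. scoring of a 13-item social-capital survey instrument (cognitive and
   structural-bonding z-score indices at individual and group level),
3. a synthetic cohort generator calibrated to the study population,
4. a simulator of the framed field experiment (groups of 5; six sessions
   of 3 rounds; 40-card tree envelopes; voted group targets; optional
   public disclosure, i.e. a reputation treatment), and
5. random-effects panel estimation of the target and extraction
   equations with group-clustered standard errors.

## The model

Tree health after `Q` cumulative wounds is `V = α − βQ`. Applying `q`
fresh wounds in a period yields harvest `h = ζ q (α − βQ)` (with `Q`
including the current period's wounds), cost `cq`, and payoff
`π = P h − c q`. Experiment economy: `P = 5` tokens, `ζ = 0.7`, `α = 21`,
`β = c = 0.5`, three periods, 40 cards.

* **Long-term rights** (keep the tree for life): the lifetime optimum is
  constant, `q* = (Pζα − c) / (Pζβ(T+1)) = 73/7 ≈ 10.43` per period;
  the best *constant integer* plan is **10 wounds per round** (payoff
  1140 tokens). Because the lifetime payoff is permutation-symmetric in
  the wound vector, unrestricted integer search places the 31st unit in
  any one round ((10, 10, 11) up to ordering, 1141.25 tokens); both
  solutions are exposed.
* **Short-term rights** (shuffling): one-period maximisation gives
  `q = (Pζ(α − βQ) − c) / (2Pζβ)`, a path that halves each period
  (20.86, 10.43, 5.21; integers 21, 10, 5) — more total cutting for less
  total payoff than the long-term optimum.

The panel specifications regress the voted group target (group × round)
and individual extraction (member × round) on the reputation treatment,
the cognitive and bonding social-capital indices and their
round interactions, round dummies, and — for extraction — the group
target (the "adherence" slope), with a group random intercept and SEs
clustered by group.

## Worked example

```sh
boswellia benchmarks
```

```
                    regime  total_payoff  total_wounds        q1        q2        q3
      long_term_continuous   1141.928571     31.285714 10.428571 10.428571 10.428571
long_term_constant_integer   1140.000000     30.000000 10.000000 10.000000 10.000000
         long_term_integer   1141.250000     31.000000 10.000000 10.000000 11.000000
         myopic_continuous    999.187500     36.500000 20.857143 10.428571  5.214286
            myopic_integer    998.750000     36.000000 21.000000 10.000000  5.000000
```

Reading: a harvester who keeps their tree cuts ~10 wounds per round and
earns 1140 tokens over the tree's life; a myopic harvester under
shuffling front-loads (21, 10, 5), cuts 6 more wounds in total, and earns
~141 tokens less.

A full synthetic study — cohort of 210 harvesters in 42 groups, survey
scoring, simulated experiment, all four regressions, round summary:

```sh
boswellia run-all --seed 7 --outdir demo
```

prints `gap test: t = 13.46, p = 0.0000` (the target−extraction gap is
significantly wider when decisions are disclosed) and writes
`demo/round_summary.csv`:

```
                   scenario  round  mean_target  mean_extraction   n  benchmark
           voting_shuffling      1    16.590909        15.586364 660         10
           voting_shuffling      2    14.348485        12.322727 660         10
           voting_shuffling      3    11.530303         8.133333 660         10
voting_shuffling_reputation      1    17.805556        14.822222 180         10
voting_shuffling_reputation      2    15.000000        11.266667 180         10
voting_shuffling_reputation      3    11.833333         7.611111 180         10
```

Group targets start well above the sustainable benchmark of 10 and
decline as trees degrade; extraction sits below the target, more so
under the reputation treatment. `demo/fit_group_round.txt` holds the
target-equation estimates with clustered SEs and significance stars;
`demo/fit_individual_round.txt` the extraction equation, whose
`group_target` row is the adherence slope (~0.2: a one-wound higher
target moves individual extraction by about a fifth of a wound).

Other subcommands: `cohort generate`, `survey score`,
`survey determinants`, `simulate`, `analyze`, `report`. All tabular I/O
is CSV; the treatment-sequence matrix and item catalog are editable JSON
(`src/boswellia/data/`). Library use mirrors the CLI:
`generate_cohort → score_respondents → simulate_experiment →
build_panel → fit_random_effects`.

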