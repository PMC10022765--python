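# rqit

Tools for **scoring the importance of clinical research questions** with the
ANZMUSC Research Question Importance Tool (RQIT) and for building instruments
of this kind: best-worst-scaling preference surveys fitted with Thurstone's
paired-comparison model, and the reliability/validity statistics used during
instrument development.

Research funders and clinical-trial networks must rank competing research
questions. The RQIT operationalizes "importance" as a multi-attribute score:
an instrument defines a handful of dimensions (stakeholder consensus, patient
burden, social burden, anticipated intervention effect, health equity), each
with ordered levels, and a *profile* — one level per dimension — receives a
score on a 0–1000 interval scale.

## The model

Each (dimension, level) combination is an *element* `e` with utility `u_e`.
A profile's score is additive,

    score = Σ_e u_e ,        SE² = Σ_e Σ_e' ρ_{e,e'} σ_e σ_e' ,

where `σ_e` are element standard errors and `ρ` the correlation matrix of the
utility estimates. The utilities come from a best-worst scaling survey:
respondents see three options per choice-task (each option pairs one level
from each of two dimensions) and pick the most and least important, implying
three paired comparisons per answer. Under Thurstone's model a respondent
prefers option *i* over *j* with probability

    P(i ≻ j) = Φ( (U_i − U_j) / (s√2) ) ,

with `U` the option's summed element utilities and `s` the respondent's
standard error of measurement. Maximum likelihood is computed for a
per-respondent-SEM variant (Model 1) and a common-SEM variant (Model 2a, and
its sum-to-zero reparameterization 2b which yields comparable standard errors
for every element). Fitted utilities are rescaled so each dimension's lowest
level is 0 and the best possible profile scores exactly 1000.

The package also implements the instrument-development statistics: two-way
random-effects ICC (absolute agreement, single/average/committee ratings),
Gwet's AC2, modal percent agreement, the RAND/UCLA disagreement index with
the Delphi re-rating rule and theme summaries, Cramér's V, tertile logistic
regression and log-citation regression — plus seeded synthetic-data
generators for every input kind.

## Worked example

Score a profile with the packaged published utility table — a question that
is important to all stakeholders (A4), addresses a mildly symptomatic (B1)
but common (C3) condition, tests a potentially curative treatment (D3) and
does not address equity (E1):

```sh
$ rqit score --profile A4,B1,C3,D3,E1
score: 582
se: 12.44
```

The score is the sum of the published element utilities (198 + 0 + 119 + 265
+ 0 = 582 points on the 0–1000 scale); the standard error propagates the
element SEs through their correlation matrix.

Recovering a utility table from survey data (here simulated from the
published utilities; with real data, read responses with `rqit.io`):

```python
import rqit

table = rqit.load_default_table()
tasks = rqit.generate_tasks(table.instrument)        # 73 anti-chain tasks
cfg = rqit.SimulationConfig(seed=7, n_respondents=200)
responses = rqit.simulate_bws_responses(cfg, tasks)  # 14600 answers
comps = rqit.expand_comparisons(responses, tasks)    # 43727 comparisons
result = rqit.fit(comps, model="2b", seed=7)
fitted = rqit.rescale(result, table.instrument)
```

which recovers, e.g., `A4: 196.1 (SE 4.2)` vs the published 198 and
`D3: 278.0 (SE 4.3)` vs 265 — correlation 0.999 with the published table.

The `rqit` command also exposes `design`, `fit-bws`, `agreement`, `delphi`,
`validate` and `simulate` subcommands; every run writes a provenance record
with its seed and options.

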