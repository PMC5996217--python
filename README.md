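# healthdea

Health-system-adapted data envelopment analysis (DEA) for policy
decision-making.

Choosing between health policies means trading off unlike outcomes — deaths
averted, households kept out of poverty, equity — against resources
consumed, without knowing how the population weights those outcomes against
each other. `healthdea` scores and rank-orders a set of candidate policies
on *all* of their inputs and outcomes at once, letting each policy pick the
preference weights most favourable to itself, so a low score cannot be
blamed on an imposed weighting. It also computes the traditional
cost-effectiveness frontier (dominance + ICERs) on a single (cost, effect)
pair as the baseline to compare against.

## The method

Each policy *o* consumes inputs `x_o` (cost, personnel, ...) and produces
outputs `y_o`. Its efficiency is the optimum of the input-oriented radial
envelopment program under variable returns to scale (VRS):

```
min θ   s.t.   Σ_k λ_k x_kj ≤ θ x_oj   for every input j
               Σ_k λ_k y_kr ≥ y_or     for every output r
               Σ_k λ_k = 1,  λ ≥ 0
```

θ = 1 means no convex combination of the comparison set produces *o*'s
outputs with uniformly fewer inputs. The optimal dual multipliers are the
implicit preference weights (u over outputs, v over inputs).

Four adaptations make the method usable for health policy:

1. **Policies as the unit of analysis** — the rows are policies, not
   hospitals or providers.
2. **Superefficiency for rank-ordering** — each policy is also scored with
   itself *excluded* from the comparison set, so efficient policies obtain
   scores above 1 and all policies can be ranked.
3. **Variable returns to scale**, since a first surgeon in an unstaffed
   hospital buys more health than a fifth. Under VRS the superefficiency
   program can be infeasible (a policy holds an output level no convex
   combination of the others reaches); such policies are scored by a
   two-stage fallback: maximize the retained output fraction *s*, then
   minimize the radial input factor θ\*, and score `θ* + 1/s*`.
4. **Adverse outcomes as inputs** — a policy that *creates* catastrophic
   expenditure has that harm counted as an extra cost (input), rather than
   shifting everyone's outcomes by a constant.

## Worked example

Nine unrelated preventive and curative interventions (bundled fixture;
government expenditure in US$ ×1000 as the single input; household
expenditure averted, deaths averted and impoverishment averted as outputs):

```python
from healthdea import load_fixture, rank_policies

table = load_fixture("ethiopia_interventions")
report = rank_policies(table, icer_pair=("govt_expenditure", "deaths_averted"))
print(report.to_text())
```

```
policy                 icer                           dea_score  super_score  rank
     Rotavirus vaccine                     Dominated 0.46       0.46         9
  Pneumococcal vaccine  US$ 1 160 per deaths averted 1.00       2.84         1
       Measles vaccine    US$ 292 per deaths averted 1.00       2.43         3
   Diarrhoea treatment                     Dominated 1.00       2.36         4
   Pneumonia treatment US$ 16 067 per deaths averted 1.00       2.75         2
     Malaria treatment                     Dominated 0.70       0.70         8
     Caesarean section                     Dominated 1.00       1.51         6
Tuberculosis treatment  US$ 6 333 per deaths averted 1.00       1.79         5
Hypertension treatment                     Dominated 0.88       0.88         7
```

Standard DEA rules out only three policies (score < 1) and the ICER column
rules out five, but neither orders the rest; the superefficiency column
ranks all nine. Pneumococcal vaccination — the *least* attractive policy by
ICER — ranks first once financial risk protection is counted. Diarrhoea and
pneumonia treatment are the two fallback cases: each holds an output
maximum (impoverishment averted and deaths averted respectively) that no
mix of the other eight policies can reach.

The same pipeline runs from the shell:

```
healthdea rank --input interventions.csv \
    --inputs govt_expenditure \
    --outcomes household_expenditure_averted,deaths_averted,impoverishment_averted \
    --icer govt_expenditure:deaths_averted
```

Subcommands `dea`, `super`, `icer` expose the individual stages and
`simulate` writes reproducible synthetic policy tables.

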