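# kinconflict

Who reproduces first — the parent or the adolescent?

`kinconflict` implements an inclusive-fitness, sequential hawk–dove model of
intergenerational conflict over reproductive opportunities in a shared
household. It is aimed at evolutionary anthropologists and behavioural
ecologists studying why parental absence in childhood is so often associated
with *earlier* reproductive maturity: when family members share the resources
needed to rear infants, a parent and her adolescent offspring can find
themselves competing over who gets to reproduce, and the asymmetry between
grandparent–grandchild relatedness (r = 0.25) and full-sibling relatedness
(r = 0.5) usually hands the parent the upper hand — unless a parent's absence
turns future siblings into half siblings and makes the game symmetric.

## The model

Two actors, a parent (G1) and her adolescent offspring (G2), each choose to
reproduce (R) or not (N). Three parameters define a game instance:

- **s ∈ [0, 1]** — survival ratio of an infant sharing the household with a
  second infant, relative to being the sole infant;
- **c ∈ [0, 1]** — parental continuity, the probability the parent's next
  infant has the same second parent as the adolescent (full vs half sibling);
- **y > 0** — youth benefit, the fitness of the adolescent's infant relative
  to the parent's (y > 1 encodes parental reproductive senescence).

Payoffs are expected inclusive-fitness contributions:

| | both reproduce | only G1 | only G2 |
|---|---|---|---|
| V₁ (parent) | 0.5s + 0.25sy | 0.5 | 0.25y |
| V₂ (adolescent) | 0.5sy + 0.25s(1+c) | 0.25(1+c) | 0.5y |

Play is sequential: the second mover best-responds to the first mover's
choice, which yields four closed-form critical survival ratios, e.g. the
adolescent adds a second infant iff s > (1+c)/(2y+1+c) and the parent iff
s > y/(y+2). These two bounds split the parameter space into three zones:
only one actor reproduces (zone 1), the infant count depends on who moves
first (zone 2), or both reproduce (zone 3). An actor's *loss-to-second* —
her payoff moving first minus her payoff when the other moves first —
measures what she would pay to win the first-mover position; the actor with
the larger loss is the predicted winner of the conflict. The package also
derives the comparative statics: parental-absence effect sizes (the percent
gap between the c = 1 and c = 0 thresholds, 100·y/(2y+1)), a mapping from
family household structures to continuity values with predicted
age-at-first-birth ordering, and a seeded Monte Carlo household simulator
that recovers the analytic payoffs from realised survival and
sibling-identity draws.

## Worked example

```sh
$ kinconflict analyze --s 0.2 --c 0 --y 1
{
  "s": 0.2,
  "c": 0.0,
  "y": 1.0,
  "loss_parent": 0.25,
  "loss_adolescent": 0.25,
  "zone": 1,
  "zone_lower": 0.333333,
  "zone_upper": 0.333333,
  "on_boundary": false,
  "winner": "tie",
  "endogenous_timing": false,
  "parent_abstains_first": false,
  "adolescent_abstains_first": false
}
```

With no parental continuity and no senescence the game is symmetric: below
the both-reproduce boundary s = 1/3 each actor loses exactly 0.25
inclusive-fitness units if the other reproduces first, and neither is
predicted to win. Raise continuity to c = 1 (`--c 1`) and the adolescent's
loss drops to 0 (she is indifferent between her own child and a full
sibling) while the parent still stands to lose 0.25 — the parent wins.
Raise the youth benefit to 3 instead and the winner flips to the adolescent,
with the parent now preferring to abstain even as first mover.

The same library surface is available in Python:

```python
from kinconflict import GameParams, predict_winner
res = predict_winner(GameParams(s=0.2, c=1.0, y=1.0))
res.winner.value      # 'parent'
res.loss_adolescent   # 0.0
```

Other subcommands: `payoffs`, `thresholds`, `sweep` (tidy CSV grids),
`absence-effect`, `table1` (family-structure report), `simulate` (seeded
Monte Carlo), and `figures`, which regenerates the data tables behind the
threshold curves, the eight loss-profile panels, and the absence-effect
curve (`--plot` adds quick-look PNGs).

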