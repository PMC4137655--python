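# Methods

## The game

One household, two actors of reproductive age: a parent (G1) and her
adolescent offspring (G2), each choosing reproduce (R) or not (N) at a single
point in time. The model is deliberately minimal: no mate-search costs, no
spouse or sibling-helper payoffs, no repeated play or discounting — the
payoff of a decision is its instantaneous expected inclusive-fitness
contribution. Household resources (alloparental care, calories) are shared,
so an infant that shares the household with a second infant survives at a
ratio s ∈ [0, 1] of a sole infant's survivorship, which is normalised to 1
(s is defined as a ratio, so the sole-infant baseline is the natural unit).
Co-residence is never beneficial (s ≤ 1).

Each actor values a surviving infant at relatedness × quality. Own infants
carry r = 0.5; the parent values the adolescent's infant (her grandchild) at
r = 0.25 weighted by its relative quality y; the adolescent values the
parent's new infant at the expected sibling relatedness 0.25·(1+c), where c
is the probability the parent reproduces with the same partner who produced
the adolescent (full sibling, r = 0.5) rather than a new one (half sibling,
r = 0.25). This produces the eight conditional payoffs tabulated in the
README; V(N|N) = 0 for both.

## Parameters

| parameter | meaning | range | notes |
|---|---|---|---|
| s | survival ratio, 2 vs 1 infants in the household | [0, 1] | dimensionless ratio; sole-infant survivorship normalised to 1 |
| c | parental continuity (full- vs half-sibling probability) | [0, 1] | affects only the adolescent's payoffs |
| y | youth benefit, fitness of G2's infant relative to G1's | > 0 | y > 1: parental senescence; y < 1: advantage to the older generation; both analysed |

Construction is strictly validated; out-of-range or non-finite values are
rejected. A single package-wide absolute tolerance `ATOL = 1e-9` decides
every indifference/threshold-equality question.

## Solving the game

Decision-making is sequential: the second mover observes the first mover's
action and best-responds. "Wants to reproduce" conditions are strict
inequalities; exact indifference (within ATOL) resolves to N with a tie flag,
which keeps threshold behaviour testable and is conservative about adding
infants. The four closed-form critical survival ratios are

- adolescent adds a second infant (parent reproduced): s > (1+c)/(2y+1+c);
- parent *wants* the adolescent to add one: s > 2/(y+2);
- parent adds a second infant (adolescent reproduced): s > y/(y+2);
- adolescent wants the parent to add one: s > 2y/(2y+1+c).

`sequential_outcome` follows the convention that the first mover reproduces
and the second mover best-responds, yielding piecewise first-mover payoffs.
`bruteforce_solve` is an independent oracle: it enumerates the two-stage game
tree using only the payoff table (never the closed forms) and additionally
lets the first mover optimise, reporting voluntary abstention — with y > 2
even a first-moving parent cedes sole reproduction to the adolescent. The
loss-to-second used for winner prediction follows the first-mover-reproduces
convention (so that negative losses are visible and meaningful), while the
abstention view is exposed separately through the `*_abstains_first` flags;
the two views answer different questions and both appear in
`ConflictAnalysis`.

Zones: with bounds b₁ = (1+c)/(2y+1+c) and b₂ = y/(y+2) (ordering flips at
y = √(1+c), where zone 2 is empty), s below both is zone 1 (one reproducer),
between them zone 2 (order-dependent), above both zone 3 (both reproduce,
zero losses). Zone intervals are open; an s exactly on a bound (within ATOL)
is assigned to the adjacent lower-numbered zone and flagged rather than
silently classified — a measure-zero case made visible.

Winner logic: the actor with the strictly larger loss-to-second wins; losses
equal within ATOL and positive is a `tie` (the symmetric game at c = 0,
y = 1 — the model does not invent a tie-break the theory does not supply);
both losses ≤ ATOL is `no_conflict`. `endogenous_timing` marks any negative
loss: that actor prefers the second-mover position, so both actors agree on
the order of play.

## Comparative statics

The parental-absence effect compares the adolescent's add-second threshold
with both genetic parents present (c = 1, threshold 1/(y+1)) against one
absent (c = 0, threshold 1/(2y+1)). The effect size is the percent
difference **with the c = 1 threshold as denominator** — stated prominently
because the verbal definition is easy to read the other way round — which
reduces to 100·y/(2y+1): strictly increasing in y, vanishing as y → 0.

Family structures map onto continuity values: two genetic parents c = 1.0
(for "approximately 1"), parent + stepparent c = 0.0, widowed single parent
c = 0.0, other single parent c = 0.5 (for "some chance of continuity");
the qualitative assignments are defaults and every one is overridable.
Non-kin-present and mate-search-cost flags are carried as metadata only and
never modify payoffs — the model does not formalise them. The
age-at-first-birth rank check verifies, at a user-chosen conflict point
(default s = 0.2, y = 1), that the adolescent's loss-to-second is weakly
larger — and the parent's winner margin weakly smaller — for structures
predicted to have earlier first births; the two intermediate-ranked
structures are not ordered against each other. Points in zone 3 raise an
error (no conflict, ordering undefined).

`sweep` evaluates thresholds, losses, zone and winner over a grid of up to
two swept parameters and returns a tidy DataFrame; it is fully deterministic
and is what the `figures` subcommand uses. Loss-figure panels A–D sweep s at
c = 0.25 and E–H at c = 1, each c with youth benefits {0.3, 1, √(1+c), 3};
the panel at y = √(1+c) per column shows the zone-2 collapse, and panel H
(c = 1, y = 1) is the reference whose zone bounds are (1/3, 1/2).

## Monte Carlo validation

The simulator is a generative transcription of the parameter definitions,
used to validate the analytic payoffs rather than to extend them. Per
replicate: each R actor produces one infant; a sole infant survives with
probability 1, and two co-resident infants survive **independently** with
marginal probability s each — the model specifies only marginal survivorship
ratios, so independence is the minimal assumption (a shared-household-shock
correlation would change nothing in expectation, which is all the analytic
payoffs state). If the parent reproduces, her infant is a full sibling of
the adolescent with probability c. Quality y is a deterministic multiplier
on a surviving infant's fitness contribution, not a survival modifier,
because the payoffs apply y multiplicatively outside s. Realised payoffs sum
relatedness × quality over surviving infants; means, standard errors and
z-scores against the analytic values are reported. One
`numpy.random.default_rng(seed)` per call, no global state; identical
configurations are bit-reproducible. Degenerate cells (sole infants,
c ∈ {0, 1} sibling draws) have zero variance and are checked exactly.

What the simulator does and does not emulate: it realises exactly the
stochastic structure the payoffs assume (Bernoulli survival, Bernoulli
sibling identity, fixed quality weights). It contains no demography, no
repeated bouts, no behavioural response — so agreement with the analytic
payoffs validates the algebra and the expectation structure, not the model's
fit to any real household data.

## Numerical choices and problem sizes

- ATOL = 1e-9 everywhere an equality is decided; winner ties use it too.
- The parent's sole-reproducer indifference point (y = 2) is also computed
  numerically with Brent root-finding on V₁(R|N) − V₁(N|R); the closed form
  is the oracle in tests.
- Oracle-equivalence testing uses 10⁴ uniform parameter draws, excluding a
  1e-6 neighbourhood of the thresholds where the strict-inequality and
  tie conventions make closed-form and enumerated branches legitimately
  diverge.
- Monte Carlo checks use 10⁵ replicates per cell on a 3×3×3 design
  (s, c ∈ {0.2, 0.5, 0.8} × {0, 0.5, 1}, y ∈ {0.5, 1, 2}), with per-cell
  seeds spawned from a fixed `SeedSequence`; convergence checks use a
  schedule up to 10⁶ replicates on two cells. These sizes make the whole
  suite run in seconds while leaving standard errors small enough (~1e-3)
  for 3-SE comparisons to be meaningful.

## Known limitations

- One-shot, two-actor game: no tug-of-war effort dynamics (losses are
  reported, not converted into win probabilities), no mixed strategies for
  simultaneous play, no third actors (stepparent interests, spouses,
  sibling helpers), no coercion, and senescence is extrinsic rather than
  evolving.
- The family-structure mapping is ordinal where the theory is ordinal: it
  predicts rank order of ages at first birth, not ages.
- Ties are conventions, not predictions: the symmetric game genuinely does
  not determine a winner, and behaviour exactly on a threshold depends on
  the tie-break conventions documented above.
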