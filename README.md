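# plfcm — probabilistic linguistic fuzzy cognitive maps

`plfcm` simulates fuzzy cognitive maps whose concept states and edge weights
are **probabilistic linguistic term sets** (PLTSs), and ranks the causal
factors driving an outcome concept by similarity of steady states.  It is
aimed at health-determinants and policy analysts who elicit causal maps from
expert panels and survey data — the packaged case study models the health of
rural older adults in China as a 13-concept map — but the machinery is
generic: any directed concept map with linguistic, probability-weighted
judgements fits.

## The model

A linguistic scale `s_-τ … s_τ` (e.g. "very strong negative impact" … "very
strong positive impact", τ = 3 for weights; an 11-term state scale, τ = 5)
carries judgements; a PLTS attaches probabilities to the terms an assessor
hesitates over, e.g. `{s-3:0.5, s-2:0.1, s-1:0.1, s0:0.3}`.  Judgements from
several experts pool by per-term weighted averaging of probability mass.

Arithmetic uses the equivalent transformation g(α) = (α + τ)/(2τ), mapping
term indices onto memberships η ∈ [0, 1], with the probabilistic sum
x ⊕ y = x + y − xy and product x ⊗ y = xy as the aggregation pair.  After
aligning all PLTSs on a common position template, the map iterates two
channels per node i and position k:

    memberships:    η_i^k ← f( η_i^k ⊕ [1 − ∏_{j→i} (1 − η_j^k · w_ji^k)] )
    probabilities:  p_i^k ← f( p_i^k ⊕ [1 − ∏_{j→i} (1 − p_j^k · q_ji^k)] ),
                    then renormalized per node,

with the threshold f(x) = tanh(λx), λ > 0 (default 1).  Iteration ends at a
fixed point (max-norm change ≤ tol, default 1e-6), a limit cycle, or the
iteration cap (classified chaotic).  The membership channel never reads
probabilities — dropping probabilities (the hesitant baseline) reproduces
the membership trajectory exactly.

Factors are ranked by the similarity of their steady PLTS to the outcome's,

    S(a, b) = (Z(d(a, b)) − Z(1)) / (Z(0) − Z(1)),

where d is a probabilistic linguistic Euclidean distance (position value =
membership × probability) and Z is a decreasing recalibration — linear
(1 − t), rational ((1 − t)/(1 + t), the default), exponential (1 − t·e^{t−1})
or quadratic (1 − t²).  Rank 1 = most influential; first-level groups score
by mean member rank.  Degenerate baselines (hesitant/probability-free, and
a classical crisp map via score-defuzzification) are included for
comparison.

## Worked example

Draw a seeded synthetic 7-concept map, iterate it, and rank its factors:

```sh
plfcm synth --n-nodes 7 --edge-density 0.4 --seed 11 --out model.yaml
plfcm simulate --model model.yaml --out out/
plfcm rank     --model model.yaml --out out/
plfcm sensitivity --model model.yaml --out out/
```

which prints

```
wrote model.yaml: 7 nodes, 19 edges (seed 11)
status: fixed_point after 754 iterations
    F6  similarity=0.9989  rank=1
    F3  similarity=0.9957  rank=2
    F2  similarity=0.9955  rank=3
    F5  similarity=0.9944  rank=4
    F4  similarity=0.9876  rank=5
    F1  similarity=0.9616  rank=6
group G1: mean rank 5.5
group G2: mean rank 3.5
group G3: mean rank 1.5
ranks agree across Z forms: True
```

The map converged to a fixed point; factor F6's steady state is closest to
the outcome's (similarity 0.9989), making it the top-ranked driver, and the
ranking is invariant to the choice of Z recalibration.  `simulate` exits 0
on a fixed point, 2 on a limit cycle and 3 on a chaotic run (an unusable
map that should be re-elicited).

The packaged case study loads with `--fixture` or
`plfcm.load_case_study()`: 13 concepts (self-rated health plus twelve
factors in four groups) with initial PLTSs from national ageing surveys.
Its expert-elicited connection matrix is not redistributable; transcribe it
into the blank CSV template at `plfcm.matrix_template_path()` and attach it
with `--matrix` to run the full ranking.

Library use mirrors the CLI:

```python
import plfcm

model = plfcm.generate_synthetic(plfcm.SyntheticSpec(n_nodes=7, seed=11))
ranking = plfcm.rank_factors(model, plfcm.IterationSettings(lam=1.0))
print(ranking.to_frame())
```

## Layout

- `src/plfcm/plts.py` — PLTS data model, g/g⁻¹, algebra, expert pooling
- `src/plfcm/measures.py` — distance and Z-mapping similarity
- `src/plfcm/model.py` — concept map, YAML model files, matrix tables
- `src/plfcm/engine.py` — alignment and two-channel iteration
- `src/plfcm/analysis.py` — ranking, sensitivity sweeps, baselines
- `src/plfcm/case_study.py`, `src/plfcm/synthetic.py` — packaged fixture
  and seeded generator
- `docs/methods.md` — modelling assumptions and numerical conventions
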