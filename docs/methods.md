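# Methods

## Problem and transformation model

`anonlattice` de-identifies a table of categorical quasi-identifiers with
*full-domain generalization followed by record suppression*. Each attribute
`a_i` has a user-defined generalization hierarchy of height `h_i`: level 0
holds the original values, higher levels increasingly coarse labels, level
assignments forming a tree (two values sharing a label at level ℓ share
labels at every level above ℓ). A *policy* `x = (x_1, …, x_m)` picks one
level per attribute; applying it means

1. replace every value of attribute `i` by its level-`x_i` label,
2. suppress every record in an equivalence class (maximal group of
   indistinguishable records) smaller than `k`,
3. accept the policy as a solution candidate iff the number of suppressed
   records is within the suppression limit.

The set of all policies forms a bounded ranked lattice under the
componentwise order, with `bottom = (0,…,0)`, `top = (h_1−1,…,h_m−1)`,
`rank(x) = Σ x_i` and size `s = Π h_i` — exponential in `m`, which is why
the lattice is never materialized anywhere in this package.

## Privacy and quality models

**k-anonymity.** A dataset is k-anonymous when every record is
indistinguishable from at least `k−1` others; the worst-case
re-identification risk is `1/min(class size)`, so k-anonymity caps it at
`1/k`. Suppression removes outlier classes rather than forcing the whole
table to a coarse level; the fraction of suppressible records is bounded by
the *suppression limit*, interpreted as an exact integer budget
`floor(limit · n)` so that a "5 %" limit is reproducible.

**Loss-based quality (Iyengar).** Each cell contributes the fraction of its
attribute's domain covered by its value, normalized per cell as
`(M_g − 1)/(M − 1)` where `M_g` is the number of base values merged into
the label and `M` the domain size; ungeneralized cells contribute 0,
suppressed cells 1, and quality is `u = 1 − mean cell loss ∈ [0, 1]`. This
normalization reproduces the model's analytic anchors: original data
100 %, everything removed 0 %, and exactly 50 % for a two-attribute table
with one attribute collapsed to a single root label. Degenerate choices:
a singleton domain (`M = 1`) contributes loss 0 unless suppressed — the
`0/0` normalization is resolved by noting a constant column carries no
re-identifiable information — and an empty table has quality 1 and is
anonymous by convention, keeping the search code total.

`u` is *not* monotone along generalization (coarser levels may need less
suppression), but the generalization-only quality `u′` is monotone
non-increasing and satisfies `u ≤ u′`. The implementation guarantees
`u ≤ u′` exactly under floating-point summation by computing `u` as
`u′ − max(0, s·m − suppressed loss)/(n·m)`.

## Predictive properties and the antichain store

Two facts about a policy's output propagate through the lattice:
*insufficient protection* (more suppression required than the limit allows)
is inherited by all specializations, because distinguishability decreases
monotonically with generalization; *insufficient quality* (`u′` at or below
the incumbent's quality) is inherited by all generalizations, because `u′`
is monotone. A `PropertyStore` keeps the policies for which a property was
observed and answers "does policy x inherit it?" by searching for a stored
strict specialization (UP) or generalization (DOWN) — complete information
about an exponentially large excluded region, held implicitly.

Two stored comparable policies are redundant (one implies the other), so
inserting `x` removes every stored element that inherits from `x`; the
stored set is therefore always an antichain. Four implementations share
one contract and must answer identically:

1. plain list (no removal) — the baseline;
2. list with the antichain invariant;
3. prefix tree over policy components with the invariant: depth `i` holds
   levels for attribute `i`, each root-to-leaf path spells one policy, and
   a query descends only children whose level can belong to a
   specialization (UP: `level ≤ x_i`; DOWN mirrored);
4. the tree plus a per-node rank bound (min over stored ranks below for
   UP, max for DOWN): a subtree is skipped when the bound shows none of
   its elements can have rank strictly below (UP) / above (DOWN)
   `rank(x)`.

Numerical/structural choices: children are visited in ascending level
order (deterministic traversal, early exit once `level > x_i` for UP);
emptied inner nodes are reclaimed immediately while backtracking from a
removal; bounds are updated **only along insert paths** — a removal leaves
remaining bounds untouched, which keeps them *sound* (UP: never above the
true subtree minimum) though possibly stale, and soundness is all the
query pruning needs. `check_bounds()` verifies soundness by full
traversal, and tightness on removal-free workloads. The strict bound
comparison (`bound < rank(x)` to descend) also excludes equal-rank
specializations — the only such element is `x` itself, so a range query
can never find the queried element; option 3, which lacks the bound,
excludes the exact path explicitly so all options agree. Inserts are
unguarded by default (in a search, an associated policy is excluded and
hence never inserted); `guarded=True` adds the pre-insert query for
standalone use. `insert_count` counts attempted inserts — the `c` of the
cost analysis — separately from the surviving element count.

Complexities: list insert O(1)/query O(c); antichain variants pay O(c)
per insert to scan/remove; the tree degenerates to a list in the worst
case but prunes heavily in practice. Query memory is O(m) stack; store
memory is proportional to elements currently held, never to `s`.

## Search strategies

All three strategies evaluate a policy at most once and share the
`Evaluator` (integer-coded columns; per-level label and loss lookup
tables; class sizes via row uniqueness), so one evaluation is a handful of
vectorized array operations.

**Exhaustive** — rank-ordered sweep of the whole lattice (refused above a
configurable cap, default 100 000); the correctness oracle. Ties on
quality resolve to the first policy found, i.e. lowest rank then
lexicographic, for deterministic reproducible results.

**Optimal sweep** — the same enumeration with complete predictive
information: skip any policy covered by either store; otherwise evaluate,
insert into the protection (DOWN) store when non-anonymous, insert into
the quality (UP) store when `u′ ≤` incumbent quality, and update the
incumbent on anonymous improvement. Memory follows the number of checked
policies. A property of this traversal worth knowing: because the sweep is
strictly bottom-up by rank, a stored generalization always lies at a
higher rank than the policy currently queried, so the DOWN store never
produces hits here — it is maintained for reporting and for algorithms
with interleaved traversals, while the pruning work is done by the quality
store.

**Best-first branch and bound (BFS)** — bottom-up best-first search. The
queue is ordered by evaluated output quality `u`, highest first, ties by
lower rank then lexicographic order (the bottom-up bias). Evaluation
happens once, when a policy is first reached; popping triggers only
best-update, pruning and expansion. A popped policy already covered by the
insufficient-quality store is discarded; one whose `u′` cannot beat the
incumbent is inserted into the store and not expanded (the comparison uses
`≤`: an equal bound cannot strictly improve the optimum, so the guarantee
is unchanged and pruning is stronger). The "seen" set holds enqueued
policies, so memory is proportional to evaluated policies. Run to queue
exhaustion the result is globally optimal; with a time or evaluation
budget the search stops early and returns the best solution found so far
with `optimal_guarantee=False` and the full (evaluations, best-quality)
trajectory — an anytime heuristic. Incumbent updates happen at evaluation
time, so evaluations already paid for under a budget count toward the
reported solution. Non-anonymous policies never become the incumbent, but
their `u′` still feeds bound pruning. With `use_prediction=False` the
insufficient-quality machinery is disabled entirely — no store *and* no
bound-based non-expansion, since the bound comparison is precisely the
discovery step of that predictive property — and the search traverses the
whole lattice; this is the comparison baseline for measuring what
prediction buys. An optional flag adds the protection store to BFS; it is
off by default (the algorithm's design uses exactly one property).

Pruning soundness: a policy skipped via the DOWN store has a non-anonymous
specialization, hence is non-anonymous; one skipped via the UP store has
`u′ ≤` the incumbent at insertion time `≤` the final optimum, so no
skipped policy can beat the returned solution. Both facts are re-checked
by direct evaluation in the test suite.

## Synthetic workloads

The generator emulates the shape of demographic microdata used in
de-identification studies: `m` categorical attributes with integer-coded
domains, balanced interval hierarchies (level ℓ groups `b^ℓ` consecutive
values, single-root top, height `⌈log_b M⌉ + 1`), uniform or Zipf
(exponent 1.0) value distributions for realistic class-size skew, and an
*outlier fraction* of records forced to be unique attribute combinations —
singleton classes under the bottom policy, which is what creates genuine
suppression and pruning behavior. Everything is deterministic given the
seed, down to byte-identical CSV output.

What the generator does **not** emulate: inter-attribute correlation,
real marginal distributions, missing values, or hierarchy asymmetries of
curated taxonomies. Passing tests therefore demonstrate correctness of
the machinery (agreement of all strategies and store options, exactness
of the quality anchors, monotonicity, budget respect) on workloads with
realistic skew and outlier pressure — not performance claims about any
particular real dataset.

A small fixed demonstration instance (`figure2_fixture`) ships two
attributes (age-like, height 3; sex-like, height 2), built so that exactly
one record is unique after one level of age generalization: policy
`(1, 0)` becomes 2-anonymous by suppressing that record, leaving a
residual re-identification risk of 50 %.

## Defaults and parameters

| Parameter | Default | Meaning |
|---|---|---|
| `k` | 5 | minimum equivalence-class size; risk cap `1/k` |
| `suppression_limit` | 0.05 | max fraction of suppressible records |
| `store_option` | 4 | rank-bounded antichain prefix tree |
| `use_prediction` | true | predictive-property pruning on |
| `oracle_cap` | 100 000 | refuse exhaustive search above this lattice size |
| Zipf exponent | 1.0 | skew of the synthetic value distribution |

`k = 5` with a 5 % limit is common practice for biomedical microdata and
is the package-wide default.

Problem sizes in the test suite are chosen so the whole suite and the
acceptance script each run in minutes on one core: randomized
cross-algorithm checks use `m ≤ 6`, lattices up to 5 000 policies and up
to 200 records; store workloads use `m ≤ 6`, heights ≤ 5.

## Known limitations

- Only k-anonymity and the Iyengar loss model are implemented; the
  predictive-property framework extends to other monotone risk and
  quality models, but none are wired in.
- Suppression is whole-record only; cell-level (local) suppression and
  local recoding are out of scope.
- The optimal sweep iterates the full lattice (skipping covered policies
  without evaluating them, but still enumerating); for very large `m` only
  the BFS strategy is practical, as a heuristic under a budget.
- Worst-case store complexity remains O(c) per operation; the tree
  degenerates on adversarial antichains.
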