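# Methods

## Model and definitions

A phylogeny is a rooted tree `T` with node set `V` (|V| = n), edge set `E`,
tip set `S` (|S| = s) and a non-negative weight `w_e` per edge (time,
molecular distance — the math does not care). Each edge is identified with
its child node, so |E| = n − 1 always holds. `s(e)` is the number of tips in
the subtree below edge `e`; for a tip sample `R`, `s_R(e) = |S(e) ∩ R|`.
`cost(u, v)` is the weight of the unique path between two tips.

Two pairwise measures are implemented for samples A (|A| = a) and B
(|B| = b):

- **Community Distance**: `CD = (1/ab) Σ_{u∈A} Σ_{v∈B} cost(u,v)`. A
  dispersion measure, not a metric — CD(A, A) is generally nonzero.
- **Common Branch Length**: the total weight of edges in both minimal
  spanning subtrees, `T(A) ∩ T(B)`; an edge lies in `T(R)` iff
  `0 < s_R(e) < |R|`. A similarity measure.

**Null model.** A and B are drawn independently and uniformly from all
a-subsets and b-subsets of S; overlap is allowed and samples are never
de-duplicated, because the moment formulas integrate over overlaps. The
standardized indices are `(value − mean) / sd` under this null: `NRI_β`
for the CD, the Common Length Index for the CBL. Both indices are
symmetric in (A, B), invariant under rescaling of all branch lengths, and
undefined (NaN, with a logged warning) when the null sd is zero.

## Closed-form moments

*CD.* With `TC(T) = Σ_e w_e·s(e)(s − s(e))` (the total path cost),
`E[CD] = 2·TC(T)/s²`, independent of (a, b). The variance is

```
k1·TC(T)² + (k2−k1)·Σ_u TC(u)² + (k1−2k2+k3)·Σ_e w_e·TC(e) − E[CD]²
```

where `TC(e)` is the summed cost of the tip-pair paths through `e`, `TC(u)`
the summed cost of paths ending at tip `u`, and k1–k3 depend only on
(a, b, s). The three coefficients arise from classifying ordered pairs of
tip pairs by how many endpoints they share (0, 1 or 2);
`Σ_e w_e·TC(e)` equals the sum of squared path costs.

*CBL.* Edge `e` is absent from `T(A)` iff A falls entirely inside or
entirely outside its subtree, so with `C(·,·)` binomial coefficients the
presence probability is `p_r(e) = 1 − [C(s(e),r) + C(s−s(e),r)]/C(s,r)` and
`E[CBL] = Σ_e w_e · p_a(e) · p_b(e)`. The second moment needs, for every
ordered edge pair, `Pr[e,l ∈ T(A)] = 1 − F(S,e,l,r)`, where F has three
cases according to whether one subtree contains the other or they are
disjoint; the diagonal `e = l` is routed to the nested case, where F
collapses to the single-edge absence probability.

## Algorithms

- `s(e)` and `s_R(e)`: one post-order accumulation each, O(n). The
  implementation vectorizes the accumulation by processing nodes grouped by
  depth, deepest group first — equivalent to a post-order sweep and
  deterministic for a fixed tree.
- `TC(e)`/`TC(u)`: two sweeps, O(n). A post-order pass computes `down(v)`,
  the summed distance from `v` to the tips below it; a pre-order pass turns
  these into `sumd(v)`, the summed distance from `v` to all tips
  (`sumd(child) = sumd(parent) + w·(s − 2·s(child))`). Then
  `TC(e) = (s−s(e))·down(c) + s(e)·out(p) + s(e)(s−s(e))·w_e` with
  `out(p) = sumd(p) − down(c) − s(e)·w_e`, and `TC(u) = sumd(u)` for tips.
  Both sweeps are verified against brute-force path enumeration in the
  tests.
- CD and CBL raw values: per-edge crossing counts
  (`Num(A,B,e) = s_A(e)(b−s_B(e)) + s_B(e)(a−s_A(e))`) resp. the membership
  rule, O(n) per query.
- CBL sd: the double sum over ordered edge pairs is evaluated directly.
  Subtree containment is decided by half-open DFS tip intervals
  `[lo, hi)` (0-based): `l` is inside `e` iff `lo(e) ≤ lo(l)` and
  `hi(l) ≤ hi(e)`. The evaluation is blocked row-wise so memory stays
  O(block·n). A sub-quadratic evaluation (grouping ancestor–descendant
  pairs, cost proportional to Sackin's index) is possible but not built;
  the `mode` parameter exists so one could be added and validated against
  the quadratic contract.

## Numerical policies

- **Binomial ratios** `C(x,r)/C(s,r)` use exact integer arithmetic
  (`math.comb`) up to s ≤ 10⁴ or min(r, s−r) ≤ 500, and log-gamma
  differences beyond; the vectorized per-tree tables use the downward
  recurrence `C(k,r)/C(k+1,r) = (k+1−r)/(k+1)` from `c[s] = 1` (one rounded
  multiply per entry). Convention: `C(x,r) = 0` for x < r, including
  negative x.
- **Exact rational mode.** On trees with at most 30 tips both variances are
  evaluated with `fractions.Fraction` (branch lengths are floats, hence
  exact dyadic rationals). This removes catastrophic cancellation entirely
  — important because variances can be *exactly* zero not only in the
  degenerate cases but accidentally (e.g. equal weights making all
  outcomes equal), and a cancellation residue of ~1e−7 would otherwise
  masquerade as a real sd.
- **Degenerate cases**, short-circuited to exact zeros: CBL moments with a
  singleton sample (a spanning subtree needs two tips); both sds when
  a = b = s (a single possible outcome).
- **Clamping.** In the float paths, a variance more negative than
  −1e−9·scale raises an internal-consistency error; tiny negatives within
  that band are clamped to 0.
- Zero-length branches are accepted (with a logged warning — no formula
  divides by a weight); negative lengths and missing lengths are hard
  errors, the latter overridable by an explicit imputation value. Unary
  nodes are collapsed at parse time by summing the incident weights.

## Oracles

`null_oracle` defines ground truth independently of the production code:
`direct_cd` walks every A×B path explicitly; `direct_cbl` builds both
Steiner subtrees by climbing each tip to the sample's common ancestor;
`exhaustive_moments` enumerates every ordered pair of subsets (population
sd, exactly rounded sums, hence order-independent) and refuses above a
configurable pair cap; `monte_carlo_moments` draws samples by partial
Fisher–Yates (one uniform swap per drawn element — the documented,
portable stream) and evaluates values vectorized across draws.

## Synthetic data

`fixtures` generates caterpillar (maximal Sackin index), balanced, star,
Yule (uniformly chosen lineage splits until the target tip count — the
"relatively balanced" shape of real phylogenies) and random multifurcating
topologies, with constant or i.i.d. exponential branch lengths, fully
determined by a seeded recipe. These trees exercise topology extremes but
not features of real data such as ultrametric depth structure, rate
heterogeneity along lineages, or correlated community assembly; passing
tests demonstrate the *mathematics* (values and moments are exact for any
weighted tree), not ecological realism of any particular dataset.

Default problem sizes used by the checks, chosen to make the statistical
assertions sharp at interactive runtimes: the oracle-equivalence gate runs
every fixture shape at 2–7 tips over all (a, b); the fast-vs-direct check
uses 500 random triples on trees of 5–40 tips; Monte-Carlo consistency
uses a 200-tip Yule tree with sizes (20, 35) and 10⁵ draws (mean within 4
standard errors, sd within 5%); the linearity check times CD moments on
Yule trees of 4k–64k tips.

## Known limitations

- The CBL sd is quadratic in the edge count; beyond ~10⁴ edges it becomes
  the dominant cost (the CD pipeline stays linear).
- The uniform null is the only null model: no abundance weighting, no
  fixed-overlap conditioning.
- No PhyloSor/UniFrac transforms and no alpha-diversity measures; plain
  tables, not rasters, for the focal-map application.
- Tip identity is exact, case-sensitive string match with community-matrix
  column names.
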