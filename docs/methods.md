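# Methods

## Model and assumptions

`sigflow` is a static model: it runs on a fixed tree architecture after
shoot growth has ended, which matches when floral induction occurs in adult
apple trees. Annual shoots are sources of two signals — each fruit
contributes one normalized unit of inhibiting signal, and a shoot's leaf
area, divided by the mean shoot leaf area of the (untreated) reference
tree, is its activating signal. SAMs are identical targets; transport has
no preferred direction (acropetal and basipetal influences are treated
symmetrically) and no explicit vascular mechanism — distance attenuation is
purely phenomenological.

Allocation conserves each source exactly: the attenuation kernel
`(1/(1+d))^r` is normalized per source over all SAMs, so the column sums of
the accumulated field always equal the total emitted quantity. This means
removing organs elsewhere in the tree *increases* what every remaining SAM
receives from a given source — the property that makes organ-removal
treatments informative.

Per-SAM probabilities are combined into part-level FI proportions as plain
means over the SAMs in each labelled part; no Bernoulli sampling enters any
calibration or reporting path (a seeded sampler exists for simulation
studies only).

## Distances and geometry

The distance from source shoot *i* to SAM *j* follows the topological path:
(base→barycenter of the source shoot) + (Euclidean lengths between the
successive component bases along the unique path between the two shoot
attachments) + (base→extremity of the SAM-bearing shoot). The shoot
barycenter is the arithmetic mean of its segments' base and tip points.
The canonical unit is the metre and is recorded in structure files; the
`+1` in the kernel is dimensionally naive, so fitted `r` values are tied to
metre-scale distances and are not transferable across units.

Distances are computed with Dijkstra on the undirected component graph
(weights = base-to-base Euclidean lengths); on a rooted tree this equals
the unique-path walk, which the tests verify against an independent
root-path enumeration oracle.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| r− , r+ | attenuation exponents (dimensionless, metre-scale distances) | 2.7 / 5.0 | 0 = uniform spreading; ≥ 15 is effectively local |
| t− , t+ | transition values (normalized signal quantity) | 0.47 / 0.09 | probability crosses 0.5 here |
| v− , v+ | shape factors (slope of the sigmoid) | 0.25 / 0.25 | v = 0 selects an explicit step mode (0/0.5/1) |

Defaults are the orchard-calibrated estimates; they say the activating
signal acts at shorter range but much lower doses suffice. Sigmoid
arguments are clamped to ±500 before exponentiation; elsewhere results are
exact in double precision.

## Hypothetical structures and the synthetic generator

Three builders reproduce the demonstration architectures: a linear branch
of equidistant shoots (default six, 15 cm apart, fruit on shoots 1, 2, 4),
two opposite branches with organ removal at branch or shoot scale, and four
branches crossing leaf presence with fruit presence. Shoots are modelled
as 10 cm vertical segments with the barycenter at mid-length, so the
self-distance of a shoot is 0.05 + 0.10 = 0.15 m. The exact attachment
offsets and shoot lengths of the historical demonstration figure are not
fully specified anywhere, so printed distance sums for that figure are not
used as oracles; the builders expose spacing, shoot length and attachment
offset as parameters instead.

`generate_digitized_like_tree` is a synthetic stand-in for a 3D-digitized
orchard tree: one vertical trunk (solaxe, TCSA 20.4 cm²) or two inclined
trunks (Y-shape, 24.7 cm²), golden-angle branch azimuths, and leaf areas
drawn from a normal with scale `la_spread/1.2` clipped at 1 cm², putting
≈77 % of shoots within mean ± spread (the narrow spread observed on mature
orchard shoots). It emulates realistic path-length distributions and
labelling (branch ids, sides) but not measured geometry, shoot-length
allometry, or within-shoot leaf placement — so passing tests demonstrate
correctness of the machinery on realistic scales, not fidelity to any
particular orchard tree. The ON configuration bears exactly one fruit per
shoot, as after commercial thinning.

## Treatments and crop load

Organ removal zeroes `leaf_area` or `fruit_count` on selected shoots and
relabels parts treated/untreated; topology and geometry are never touched.
"Half of the shoots/branches" uses deterministic alternation in sorted-id
order by default — the field protocol's selection rule is unrecorded, so a
seeded uniform sampler is provided as the robustness alternative.
Half-tree removal treats all shoots on the first side of a two-sided
structure. Crop-load series remove fruit from a seeded uniform sample of
shoots per kept-fraction and report fruit count / TCSA against the
tree-mean FI probability; the packaged reference logistic
`exp(−0.3721x + 2.9273)/(1 + exp(·))` is the field-fitted FI–crop-load
relationship used for comparison.

When a treatment defoliates shoots, the activating normalization must use
the untreated reference tree's mean leaf area (pass `mean_leaf_area`
explicitly); the auto mode averages over the leafy shoots of the tree at
hand and errors on a fully defoliated tree rather than guessing.

## Calibration

Each sign is fitted separately by exhaustive grid search: candidates in
deterministic (r outer, t, v inner) order; per candidate the model runs on
every condition and per-part mean probabilities are pooled against the
observations. RMSE is the primary criterion (it is the headline fit
statistic), bias = |Σ(sim − obs)| / replicate count breaks ties, then grid
order; the full score table and tie set are returned. R² is the squared
Pearson correlation between simulated and observed values — users wanting
1 − SSE/SST can compute it from the returned table. Grid axes are built by
integer index arithmetic (`lo + k·step`), which keeps the 151-point wide
axis exact and the wide grid at exactly 151 × 11 × 4 = 6,644 candidates.
The refinement step re-centres r and t on the incumbent (defaults ± 0.5 /
step 0.05 and ± 0.05 / step 0.01, clipped to the original bounds) and keeps
the incumbent's neighbourhood on the discrete v axis; the original
second-pass ranges were never published, so the window and step are
configurable rather than fixed.

Transport is factored so each r shares its allocation across all (t, v)
pairs, and distances/source vectors are computed once per structure; the
wide grid on the test fixtures runs in seconds on one CPU.

The orchard calibration data (digitized trees plus observed FI
proportions) is external and not redistributable, so the package's
calibration claims are validated by parameter recovery: observations are
generated by the model itself at known (r, t, v) on the fixture structures,
optionally with Gaussian noise (σ = 0.02) clipped to [0, 1], and the grid
search must return the truth within one grid step. The recovery tests use
two eight-shoot two-branch structures (removal at shoot and at branch
scale), six observation rows, and a 9 × 11 × 3 grid — sizes chosen so the
full suite stays interactive while leaving the search genuinely
non-trivial (the two scales disambiguate r from t).

## Numerical choices and edge cases

- Conservation is exact to machine precision by construction; tests bound
  the relative row error at 1e−12.
- The large-r concentration diagnostic evaluates the kernel at finite
  r = 50 and checks mass lands on each source's nearest SAM; production
  code never takes the limit. Fixtures are built so every shoot's own SAM
  is strictly nearest (ties would split mass and are flagged by the
  nearest-SAM test).
- v = 0 is an explicit step mode returning 0 / 0.5 / 1 around t, matching
  the v → 0 limit except exactly at t.
- Empty parts in proportion tables are reported with count 0, NaN mean and
  an `empty` flag instead of being dropped or propagating NaN silently.
- Structure files are a line-based UTF-8 dialect (documented in
  `treegraph.py`): header with unit and scales, one record per component
  (parents before children) and per shoot; parse errors carry line
  numbers. Round-tripping preserves all documented fields and distances.

## Known limitations

- No directional bias in transport, no explicit phloem/xylem mechanism, no
  time dynamics: the model cannot represent within-season signal buildup.
- Axillary meristems are out of scope; only terminal SAMs get a fate.
- The synthetic generator does not reproduce measured orchard geometry;
  quantitative agreement with field FI proportions is outside what the
  test suite can establish.
- Fitted parameter values are unit-bound (metres) because of the kernel's
  `+1` offset.
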