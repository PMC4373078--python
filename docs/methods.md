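# Methods

`melinvade` re-implements, as a tested pipeline, three analyses used to
detect "camouflaged" invasions of the Asian freshwater snail *Melanoides
tuberculata* in sub-Saharan Africa: a morphospace ordination of categorical
shell scores, maximum-likelihood ancestral-range reconstruction on a dated
phylogeny, and a spatial randomization test linking invasion localities to
human population density. This note records the models, the defaults and
why they are set where they are, and the design choices made where the
original description left the method open.

## 1. Morphospace (`characters`, `distance`, `ordination`, `overlap`)

**Scoring system.** Fifteen ordinal shell characters (`IN TI HE DO SP SO HO
SH SC CO RO GR CD RI RD`) with small integer state spaces (2–5 states
each). Three dependency rules make characters conditionally inapplicable:
pattern type/size/heterogeneity (SP, SO, HO) when no colour patterning is
present (DO = 0), columellar-band size (SC) when the band is absent
(SH = 1), and rib depth (RD) when axial ribs are absent (RI = 0).
Inapplicable cells are treated as *missing*, not as an extra state: the
rules define them as "not applicable", and coding them 0 would manufacture
similarity between, say, two unpatterned shells on three characters at
once. Cells scored differently by two independent examiners carry both
states ("2, 3") and collapse to the arithmetic mean (2.5) before distance
computation. Unbleached specimens (organic coating obscuring colour
characters) are kept by default and carry a flag permitting exclusion.

**Distances.** Two metrics are exposed:

* `mixed_distance` — Gower: per character |x−y|/range, averaged over
  jointly observed characters; range either observed (column max−min, the
  default, matching common ecological practice) or theoretical (the
  character's full span). Zero-range characters are dropped with a warning.
  This is the recommended metric for new mixed data.
* `euclidean_distance` — Euclidean with pairwise deletion and the p/p_shared
  rescaling convention of R's `dist()`. This is the *reproduction* metric:
  running the published score table through `dist()` + `isoMDS(k = 3)` in R
  reproduces the published stress of 8.99 exactly, which identifies the
  pipeline the original ordination used. The published ordination covered
  the 38 *M. tuberculata* rows; the 11 rows of the endemic Congo species
  (*M.* cf. *liebrechtsi*, *M.* cf. *nsendweensis*) belong to the scoring
  table but not to the published morphospace figure.

**Non-metric MDS.** From scratch, in the monotone-regression tradition:
Kruskal stress-1, s = sqrt(Σ(d−d̂)²/Σd²) over pairs, where d are
configuration distances and d̂ disparities from pool-adjacent-violators
isotonic regression on the dissimilarity order. Ties are primary (tied
dissimilarities do not constrain their disparities; implemented by
pre-sorting tied blocks by current distance). The configuration is improved
by Guttman-transform majorization; a step that fails to reduce normalized
stress terminates the run with the previous configuration, so the reported
stress history is monotone. Defaults: 1 classical-scaling (PCoA) start +
19 seeded random starts, `max_iter` 500, relative tolerance 1e-7, lowest
stress wins. Output convention: centered coordinates, principal-axes
rotation, each axis signed so its largest-magnitude coordinate is positive.
Stress is reported ×100 (the scale on which 8.99 is printed). On the
reproduction configuration this implementation reaches 8.62, identical to
vegan's `monoMDS` to three decimals and slightly below `isoMDS`'s 8.99
(the two optimizers differ in tie handling and step rules; ours, like
`monoMDS`, finds the lower-stress solution).

**Overlap.** Descriptive only (no significance test): per group, the
bounding box, convex-hull volume and mean distance to centroid
(disparity); per pair, vol(A∩B)/min(vol A, vol B) estimated by uniform
Monte Carlo sampling inside each hull (20,000 points by default, seeded).
Groups with fewer than 4 points get no hull.

## 2. Ancestral ranges (`phylo`, `mk`)

**Model.** Equal-rates Mk on a rooted tree with branch lengths: generator
off-diagonals q, diagonals −(k−1)q, closed-form transition probabilities
P_same(t) = 1/k + (1−1/k)e^{−kqt}. The likelihood is computed by
Felsenstein pruning with per-node rescaling; polytomies are handled
natively and zero-length branches give identity transitions. The root
prior is uniform (which equals the stationary distribution for this
chain); it is configurable.

**Fit.** Single rate q, maximized by bounded scalar search on log q over
[1e-8, 1e3] × (tree height)⁻¹. Monomorphic data return the lower-boundary
fit with a warning. On small, unbalanced datasets the saturated solution
(q → upper bound, all marginals uniform) can genuinely dominate; this is
the MLE, not a failure of the optimizer.

**Marginal reconstruction.** For each internal node, the posterior over
states given all tips, computed by combining the downward (subtree)
conditional likelihoods with the complementary rest-of-tree flow in a
preorder pass — equivalent to re-rooting at every node, at linear cost.
Verified against exhaustive enumeration over internal-state assignments on
small trees (1e-9).

**Invasion calls.** A tip is a candidate when its observed region is the
focal region (Africa). Each candidate climbs to its *anchor*: the highest
ancestor all of whose descendant tips are focal. The tip is flagged when
the anchor's **parent** carries probability mass ≥ threshold (default 0.9)
on non-focal states; the inferred source is the most probable non-focal
state there, and tips sharing an anchor merge into one clade-level call.
The anchor construction is deliberate: inside a monomorphic focal clade
every node reconstructs as focal (a single stem change explains all its
tips), so a per-tip rule tied to the immediate parent could never flag a
multi-tip invasion; the anchor's parent is exactly the node whose foreign
ancestry the argument from reconstruction rests on. For an isolated focal
tip the anchor is the tip itself and the rule reduces to "is my parent
confidently foreign". The 0.9 threshold is a declared convention, not an
estimate; it is configurable. A tip observed outside the focal region is
never flagged.

The method cannot distinguish a planted (human-mediated) invasion from a
genuine recent natural colonization — both are recent transitions into the
focal region — so false positives in the recovery experiments are tips on
genuine recent region shifts. At the default simulation conditions these
average ≤ 5% of tips.

## 3. Geographic randomization (`grid`)

**Split test.** Masked cells divide at threshold_density × cell_area
(default 100 people/km² × 21 km² = 2100 people/cell), strict `>` for the
high group (a cell exactly at the threshold is low). The headline quantity
is p_exact = (n_high/n_total)^k — the chance that k independently,
uniformly placed localities all land high. The without-replacement
(hypergeometric product) analogue and the general binomial tail (for
k_in_high < k) are reported alongside; at continental scale they are
numerically indistinguishable. With the published grid numbers (76,391
high of 988,224 cells, k = 6), p_exact = 2.13e-07.

**Resampling null.** The summed count over the k invaded cells is ranked
against 10,000 (default) draws of k distinct masked cells, uniform without
replacement within a draw. p_empirical = (#draws strictly greater)/n_draws
— ties do not count, and no +1 correction is applied, matching the
"2 of 10,000 higher than observed" form of the published result. One
locality = one grid cell: records within one cell deduplicate. Unmasked
and NODATA cells are never sampled or counted.

**Calibration and power.** `power_curve` places k sites with probability
∝ (count+1)^β and reports the rejection rate at α = 0.05. At β = 0 the
empirical p is uniform on (0,1) (the test is exact up to Monte Carlo
error); rejection climbs with β and exceeds 0.9 at β = 2 on a heavy-tailed
grid. The (count+1) kernel keeps zero-count cells reachable at β > 0.

## 4. Synthetic data (`synth`)

All generators are pure functions of configuration + seed.

* **Trees**: Yule (pure birth) conditioned on n_tips, in 1/birth_rate time
  units; pendant edges are extended by the Exp(n·λ) waiting time to the
  next (unrealized) birth, since the raw simulator stops at the n-th
  birth event and would otherwise leave its newest tips with zero pendant
  edges. Default n_tips = 200, birth_rate = 5, so total tree length
  ≈ (n−1)/λ ≈ 40 and the default dispersal rate q_true = 0.1 yields a
  handful of region changes per tree — the sparse-intercontinental-
  dispersal regime the real phylogenies show.
* **Regions**: forward Gillespie simulation of the ER chain (so change
  counts are available; their mean matches (k−1)·q·total length). The
  planted-invasion scenario forces the root to the source region (an
  exotic backbone), picks a seeded internal node with the requested
  descendant-tip count whose parent truly carries the source state, and
  relabels its tips to the focal region while the truth table keeps the
  lineage history. Default: 5-tip clade, source Asia, focal Africa, two
  regions.
* **Morphs**: each morph draws a centroid uniformly over valid states
  (respecting the dependency rules); specimens perturb each applicable
  character to an adjacent valid state with probability π (plasticity),
  recording a border cell 25% of the time. π = 0 gives identical clones;
  within-morph Gower distance increases with π. Adjacent-state
  perturbation (an ordinal random walk) mimics the graded variation of
  real shell characters better than uniform resampling would.
* **Grids**: lognormal(μ = 4.5, σ = 2.2) background counts — putting
  ≈ 7.7% of background cells above the 2100 people/cell threshold, the
  high-density fraction of the real sub-Saharan grid — plus Gaussian
  hotspot surges at random centers (urban cores), a border band masked out
  as a stand-in for the region polygon, 21 km² cells.

What the generator does *not* emulate: spatial autocorrelation beyond
hotspots, realistic coastlines or drainage networks, rate variation across
the tree, morph-specific character correlations, and observer error
structure. Passing tests therefore show the pipeline is correct and
calibrated under its stated assumptions, not that those assumptions hold
for any particular field dataset.

## 5. Problem sizes in the shipped experiments

The recovery experiment runs 50 replicates of 200-tip trees; calibration
uses 200 replicates × 500 draws and power 100 replicates × 400 draws on a
60×60 grid; the enumeration check compares 10,000 draws against the exact
C(400,3) tail on a 20×20 grid. These sizes give Monte Carlo error well
inside the asserted margins while keeping the whole suite fast.

## 6. Known limitations

* The single-rate Mk model ignores asymmetric dispersal and range
  inheritance at splits; it is a deliberate simplification of richer
  range-evolution models, and on these data the two were reported to agree.
* Invasion calls depend on the declared 0.9 threshold and on branch-length
  adequacy; saturated or near-monomorphic data yield uninformative
  marginals rather than calls.
* The exact split probability treats localities as independent uniform
  draws; spatial clustering of sampling effort is not modeled (the
  resampling null shares this assumption).
* `nmmds` is best-of-n-starts on a non-convex objective; with few starts a
  local optimum is possible (20 starts reproduce the published optimum
  robustly across seeds).
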