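# Methods

## Problem and model

Single-cell bisulfite sequencing produces very low, very uneven read
coverage: the average depth per cell is 0.1× or less, and the set of CpG
sites that are measurable differs strongly between cells and between
patients. Any cross-patient comparison therefore starts with a feature
selection step, and a naive one (keep the sites that are well covered in
many patients) systematically favors the deeply sequenced patients.

The package formulates fair selection as a combinatorial optimization.
The input is an `n × m` patient-by-site matrix `S` whose entry `s_ij` is
the fraction of patient `i`'s cells in which CpG site `j` has sufficient
depth (at least `depth_threshold` reads; default 1). Three preprocessing
steps produce the binary matrix `S̄`:

1. **delta filter** — entries (or, in the default cohort-level mode,
   whole sites) with `s_ij < δ` are removed; default `δ = 0.1`.
2. **binarization** — `s̄_ij = 1` iff `s_ij ≥ p`; default `p = 0.5`.
3. **k filter** — keep sites with `Σ_i s̄_ij ≥ k` (default
   `k = ⌊n/2⌋`), optionally with per-group minima (e.g. at least two
   left-colon, one right-colon, one rectum patient) so that no tumor
   subtype is silently excluded.

All thresholds are inclusive. The selection itself maximizes the total
patient coverage of the chosen site set subject to a per-patient fairness
constraint: with binary decision variables `r_j`,

    maximize   Σ_j r_j Σ_i s̄_ij
    s.t.       Σ_j r_j s̄_ij ≥ q · Σ_j r_j    for every patient i,

i.e. every patient must have good coverage in at least a fraction `q`
(default 0.75) of the selected sites. The empty set is always feasible
and is returned (with a warning) only when no nonempty set is. The
decision version of the problem is NP-hard by reduction from Exact Cover
by 3-Sets; the reduction (`x3c_to_falafl`) and an exhaustive decision
procedure are part of the package and are cross-checked against direct
exact-cover enumeration in the tests.

## Solving

Models are solved with HiGHS through `scipy.optimize.milp`, single
threaded, which makes repeated runs return the same optimum among ties.
Two numerical choices matter:

- **Identical-column compression.** Columns with equal 0/1 patterns are
  merged into one integer variable bounded by the pattern multiplicity
  and re-expanded after solving (lowest column indices first). With `n`
  patients there are at most `2^n` distinct patterns, so cohort-scale
  instances (millions of sites, `n ≤ 12` or so) solve in seconds.
- **Exactness and limits.** The solver proves optimality; an optional
  wall-clock limit returns the best incumbent with status
  `feasible_nonoptimal`. On dense random matrices whose columns are
  mostly *distinct* patterns (roughly `n ≥ 14` at `m ≥ 2^n`),
  branch-and-bound stalls on a wide plateau of near-optimal solutions —
  the same behavior the branch-and-bound of commercial solvers exhibits
  on this instance family — so the packaged scaling experiment uses a
  grid of 4–10 patients at 5 000 sites, where optimality is proven in
  well under a minute per instance. Exactness is verified against subset
  enumeration on over 200 random instances with up to 5 patients and 15
  sites.

`FalaflSelector` wraps the solver as a scikit-learn selector
(`fit`/`transform`/`get_support`) so it composes with sklearn pipelines;
`CoveragePreprocessor` and `NaiveCoverageSelector` do the same for the
preprocessing mask and the coverage-count baseline. The functional API
(`preprocess`, `select`, `naive_half`, …) operates on the domain
containers and is what the CLI uses.

## Lineage-informativeness scoring

Given per-cell methylated/unmethylated read counts `N`, `M` and a rooted
cell tree (Newick; produced by any single-cell phylogeny method — tree
inference is out of scope here), the methylation level of a covered cell
at a site is `N/(N+M)`; cells with no reads are excluded, never imputed.
For each internal node except the root, the levels inside the clade and
in the remainder of the tree are histogrammed on `[0,1]` with `bins`
equal-width bins (default 10) and compared with the Jensen–Shannon
distance (base-2 logs, hence bounded by 1). The site's score is the
maximum over nodes; a high score means the site's methylation state
switched once at that node and was stably inherited.

Nodes where either side has fewer than `min_cells` covered cells
(default 3) are skipped. This matters: a histogram estimated from one or
two cells is essentially noise, and because the score is a maximum over
~`n_cells` nodes, tiny clades otherwise dominate it — on planted-clade
simulations the informative/background AUC drops from ~0.94 to ~0.66
when `min_cells = 1`. Setting `min_cells = 1` recovers the pure
skip-empty-sides behavior. The binning estimator itself is a choice (an
empirical-CDF distance would also be defensible); results at `bins` from
5 to 10 are similar on the synthetic fixtures, and exact numeric
agreement with any particular upstream tool's scores is not promised.

## Universality metrics

Across `n` patients a site's informativeness is a vector
`v ∈ [0,1]^n`. Its deviation from perfect correlation is the Euclidean
distance from `v` to the diagonal line through the origin and
`(1,…,1)`, which reduces to `sqrt(Σ_i (v_i − v̄)²)`, normalized by the
maximum attainable in the unit hypercube,

    max_distance(n) = sqrt(n/4)               (n even)
                      sqrt((n+1)(n−1)/(4n))   (n odd),

attained at corner vectors with half the coordinates 1. The radical is
required for the normalized deviation to be bounded by 1 (the `n = 2`
corner `(0,1)` has raw distance `sqrt(0.5)`); the implementation's
`max_distance` is verified against corner enumeration for `n = 2..8`.

A site is **universally lineage-informative** when its mean JS distance
across patients strictly exceeds the cohort mean of those means and its
normalized deviation is strictly below the cohort mean deviation;
**universally uninformative** when both are strictly below; anything
else (including exact threshold ties) is `other`, so the three labels
partition the site set.

Genomic context is assigned from a CGI BED track: inside an island →
`island`, gap ≤ 2 kb from the nearest island edge → `shore`, ≤ 4 kb →
`shelf`, else `interCGI`, with inclusive boundaries and precedence
island > shore > shelf. Site coordinates are 1-based cytosine
positions, converted by `pos − 1` for the 0-based half-open BED
intervals; the module is agnostic to genome build and CGI source.

## Baselines and robustness protocols

- `naive_half`: sites covered in at least `⌈n/2⌉` patients (2 of 4,
  5 of 9).
- `greedy_pairwise`: per patient pair, sites with covered-cell fraction
  ≥ 0.5 in both patients (defined on depth-threshold-1 fraction
  matrices; it can be run on the raw or the delta-filtered universe —
  default raw).
- `random_select`: uniform without replacement from the unpreprocessed
  site universe, five replicates by default, one seeded stream per
  replicate.
- `shuffle_robustness`: rerun the ILP on three (default) random column
  permutations, map selections back, and report all pairwise Jaccard
  indices. Objectives are provably permutation-invariant; because the
  compressed model depends only on the multiset of column patterns, the
  selected *sets* also coincide whenever every pattern is taken fully,
  and the minimum pairwise Jaccard is 1.0 on such instances.
- `balance_report`: per-patient counts of covered selected sites and
  the histogram of selected sites by number of covering patients; the
  Pearson correlation of per-pair informativeness is a plain
  `DataFrame.corr` utility.

## Synthetic data

The generators encode the study conditions rather than exposing free
dials: random binary coverage matrices use i.i.d. Bernoulli entries with
density 0.66 (the empirical per-entry coverage of the real cohort);
perturbed cohorts resample patient rows with replacement (needed to grow
9 patients to up to 50) and flip each entry with probability 0.1;
coverage-fraction fixtures draw Beta(2, 1) fractions. Methylation
fixtures build a balanced binary cell tree, plant an informative clade
(by default the root's first child), and give informative sites per-cell
levels whose means differ by `clade_effect` between clade and rest
(Gaussian jitter `noise`, clipped to `[0,1]`), background sites uniform
levels; read totals are uniform on 1–5 reads per cell and site to mimic
low coverage, with binomially sampled methylated counts. Every generator
is a pure function of its seed.

What the fixtures do not emulate: genome-aware CpG spacing, correlated
coverage along the genome, realistic cell-lineage topologies, or
patient-specific error profiles. Passing tests therefore demonstrate the
algorithmic contracts (exact optimization, metric correctness, planted
signal recovery), not biological performance on real cohorts.

## Problem sizes used in the packaged checks

Oracle-equivalence runs 200+ instances with `n ≤ 5`, `m ≤ 15`; shuffle
robustness uses a 4 × 5000 Bernoulli(0.85) matrix at `q = 0.75` (the
full column set is feasible there, so the expected minimum pairwise
Jaccard is exactly 1.0); planted-clade recovery uses 32 cells and 100
sites per class at `clade_effect = 0.8`, `noise = 0.1`; the scaling grid
is 4–10 patients × 5 000 sites. The full-cohort reproduction check
(27 227 230 → 2 133 129 → 1 346 130 sites for the four-patient
left-colon subcohort; 18 991 006 → 1 175 877 → 195 809 for the
nine-patient cohort) runs only when the deposited patient matrices are
placed under `data/crc_cohort/`; they are far too large to ship.

## Known limitations

- Exact set identity of the selected sites across solvers is not
  guaranteed under objective ties; only the objective value is.
- The ILP becomes impractical for exact solution when the number of
  *distinct* column patterns exceeds a few thousand; real cohorts with
  few patients are far below this, dense random matrices with many
  patients are not.
- The JS scoring operates on a fixed tree; uncertainty in the tree is
  not propagated.
- `deviation` treats patients symmetrically; it does not down-weight
  patients with fewer cells.
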