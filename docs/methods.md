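# Methods

This note documents the models and procedures implemented in `diagnet`, the
assumptions behind them, the parameters that matter, and the design choices
made where the design was genuinely open.

## Differential scoring

Each cohort is scored independently. The statistic is the two-sample Welch
t (unbiased variances, tumor minus normal); although cohorts with paired
case/control sampling exist in this setting, the pairing is deliberately
ignored — the statistic is the unpaired formula, applied uniformly across
paired and unpaired cohorts. P-values use the t reference distribution with
Welch–Satterthwaite degrees of freedom (the helper `t_to_p` falls back to the
pooled df n₁+n₂−2 when group variances are not supplied). Empirical-Bayes
moderated statistics are an intentional non-goal and a natural extension
point.

Benjamini–Hochberg adjustment is applied within the candidate gene set, not
genome-wide: the method's premise is a pre-specified candidate universe
(e.g. a published subtyping signature), and the multiplicity burden is that
universe. The selection cutoff for "diagnostic diff-genes" defaults to
adjusted p < 0.05 — no canonical value exists for this step, and 0.05 is the
field's default; it is a parameter (`alpha`) everywhere it is used. Selection
ranks by |t|: a strongly down-regulated gene is as diagnostic as an
up-regulated one, so ranking on signed t would silently discard
down-regulated markers. Genes whose variance is zero in both groups have no
defined statistic; they are flagged, kept in the table with NaN statistics,
and excluded from selection rather than silently dropped.

## Greedy active-subnetwork search

A module's score aggregates its members' |t|. The default aggregate is the
size-normalized sum Σ|t|/√k, the classical active-module score: a plain sum
is monotone in module size, so greedy growth would absorb an entire connected
component and could never prefer a succinct module; the √k penalty makes
growth stop once frontier genes would dilute the average signal. The plain
`sum` variant is retained for completeness. A third variant (`mi`) scores a
module by the histogram mutual information (8 equal-width bins by default)
between the |t| samples of the module and of its neighbor frontier; a
mutual-information module score over scalar per-node statistics has no
canonical estimator, so this operational definition is provided as a
configurable variant only and carries no recovery guarantees.

One greedy expansion runs from every gene as seed (deterministically — no
random seed selection, since enumerating all seeds dominates any random
subset), each step adding the frontier node with the largest strict score
increase. For the monotone aggregates the best candidate is simply the
frontier node of largest |t|, so expansion uses a max-heap and runs in
near-linear time. All ties (candidate gains, module ranking) break
lexicographically on gene symbols, making the whole search deterministic.
The top-10 modules by score are merged, and the search repeats on the merged
subgraph until the node count reaches the stopping size — "approximately 50"
is implemented as stop_size 50 with a slack of 5 (n ≤ 55) — or stops
decreasing.

Greedy expansion is myopic by design: it will not cross a low-score bridge
node even when the region beyond would raise the normalized score. The
exhaustive-enumeration oracle in the test suite verifies the greedy score
never exceeds the true connected-subgraph optimum and attains it on
star-shaped fixtures; on bridge fixtures the greedy result is strictly
smaller, which is the expected and documented behavior of the one-step rule.

## Consensus integration

The overlap rate of n networks is implemented with the denominator written
literally as ΣᵢGⁱ − G^{1…n}. For n = 2 this is the Jaccard index in percent;
for n > 2 it is *not* the union size (genes shared by some but not all
networks count multiply), so the rate of n identical networks is 100/(n−1),
not 100. The consensus ("integrated diagnostic") network keeps genes **and**
edges supported by ≥ k input networks (default 3), both thresholds applied
jointly; a supported gene whose supported edges all lost an endpoint is
dropped by default (`keep_isolated=False`), since the integrated network is
presented as an interaction network.

## Pivotal-gene selection

Degree-quartile intervals are computed from the background degrees of the
consensus-network genes (floor of the linear-interpolation quartiles,
yielding four contiguous integer intervals covering [1, ∞)); both interval
schemes printed for the reference interactome ship as presets because the
two published variants conflict. The permutation test draws random gene sets
of the selected size from the background without replacement; because the
statistic — the top-level representation Per — depends only on how many
drawn genes land in the top interval, the draws are sampled through the
exact hypergeometric marginal of that count, which is distributionally
identical and O(1) per draw. The add-one estimator (1+exceedances)/(B+1)
avoids reporting p = 0; B defaults to 1000.

Connectivity enrichment EC_j divides a gene's consensus-network degree by
its background degree, so EC ∈ (0, 1]. Genes are ranked by descending EC
(ties lexicographic). "Significant drop" has no canonical criterion; the
implemented drop score after position i is (EC_i − EC_{i+1})/EC_i, and a
position is a break point when its drop exceeds 1.5× the median drop (at most
two break points, largest drops first). A geometric EC profile has all drops
equal and therefore reports no break point. Candidate panel sizes are the
break-point positions, extended one position left when the flanking genes
tie in EC, and filled between break points when they lie within 4 positions
of each other. Survival-based screening of candidates is out of scope; an
external per-gene keep/drop table can be applied via
`apply_external_filter`.

## Gene-set enrichment

Fisher exact over-representation p-values are hypergeometric upper tails;
the BH adjustment across a library's terms shares the scoring module's
implementation. The rank-deviation Z compares a term's rank (by Fisher p,
average ranks on ties) for the observed query against the rank distribution
over n_random = 200 seeded random queries of the same size drawn from the
background universe (the precomputation scale of public enrichment servers
is unpublished; 200 is a configurable compromise between stability and
cost). The combined score C = log₁₀(p)·Z uses the *unadjusted* p, the
convention of the Enrichr family of tools; published tables pairing adjusted
p with C-scores cannot be reproduced from their own printed columns under
either convention, so no attempt is made to match them numerically. Terms
with zero null-rank variance have undefined Z (flagged, C = NaN, sorted
last).

## Panel evaluation

Classification targets are the four receptor classes — [ER+|PR+]HER2−,
[ER+|PR+]HER2+, [ER−|PR−]HER2+, and TNG (triple negative) — derived from
ER/PR/HER2 calls; ER–PR discordant samples are assigned by ER and flagged.
The native classifier is k-nearest-neighbor (k = 10, Euclidean distance on
the panel features) with fully deterministic tie-breaking: distance ties by
training-sample order, vote ties by the class of the nearest tied-class
neighbor. Any object with fit/predict plugs in; an SVM is deliberately not
re-implemented, since the classifier here is off-the-shelf evaluation
machinery rather than part of the method.

Leave-one-out with a deterministic classifier yields a single accuracy;
reports collapse to that value and say so (`collapsed=True`) instead of
fabricating min/max spread over repeats. Stratified 10-fold CV reshuffles
folds every repeat; when the smallest class has fewer members than 10 the
fold count drops to that size, and a class with fewer than 2 members is an
error. Repeated-CV defaults are scaled to the cohort sizes simulated here
(50 repeats in the pipeline; the spread stabilizes well before that).

## Synthetic data: what it emulates, and what it does not

The generator emulates the ingredients the method consumes, with defaults
describing one realistic multi-cohort study: a Barabási–Albert
preferential-attachment interactome (n = 400 genes, m = 2; curated
interactomes are hub-dominated), a connected 40-gene diagnostic module grown
by random BFS, six cohorts of 30 tumor + 30 normal samples, differential
shifts of 2 noise-SD for module members and for a 5% scatter of outside
genes, per-cohort per-gene batch offsets (SD 0.5), and i.i.d. Gaussian noise
(SD 1). Tumor subtypes are drawn with probabilities (0.45, 0.20, 0.15, 0.20)
over the four classes, roughly the clinical mix.

Four design choices matter for interpretation:

* **Outside differential genes are scattered.** They are sampled at graph
  distance ≥ 2 from the planted module, modeling differential signal from
  unrelated processes while keeping the planted module identifiable as *the*
  connected signal region. With outside signal planted adjacent to the
  module, the size-normalized greedy legitimately absorbs it and
  module-recovery metrics conflate generator ambiguity with search error.
* **Pivotal genes concentrate their connectivity in the module.** Each of
  the 4 pivotal genes (chosen among modest-degree module members) gains
  within-module edges up to degree ≈ 8, while every other differential gene
  is padded with edges to non-differential genes until at most half its
  interactions stay inside the differential set. This plants the EC contrast
  the selection stage is meant to detect (pivotal EC ≈ 0.8 vs ≤ 0.5).
* **Subtype shifts are mean-centered.** Pivotal genes carry per-class shifts
  (default 3 noise-SD, a clearly subtype-defining marker effect; the value
  is a package choice, as no reference value exists) centered over the
  subtype mix, so subtype heterogeneity widens tumor variance without
  canceling the planted tumor-vs-normal contrast. Shift patterns cycle
  through ER-splitting, TNG-splitting and HER2-splitting so the four classes
  are jointly separable by the panel.
* **Tumor shifts have random signs**, so up- and down-regulated markers both
  exist and |t|-based ranking is actually exercised.

Not emulated: microarray platform effects, probe-to-gene mapping, missing
values, correlated (co-expression) noise, copy-number or methylation
structure, and survival outcomes. Passing recovery tests on this generator
shows the pipeline recovers the structure it is designed to detect under
realistic noise, batch and subtype heterogeneity — not that it would recover
panels from any particular clinical cohort.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds; the pipeline splits one
master seed per stage via a seed sequence, and a rerun with the same
configuration is bit-identical (checksums recorded in the manifest). Greedy
acceptance requires a *strict* score increase, so zero-score additions never
occur. Degenerate inputs fail loudly: empty parsed networks, all-equal
degree quartiles, selected sets larger than the background, p ≤ 0 in the
combined score, sub-2-sample groups. BioGRID TAB3 ingest keeps human
(taxon 9606) physical interactions by default — both filters configurable,
since published analyses rarely state them — upper-cases official symbols,
drops self-loops and duplicate rows, and accounts for every input row in a
parse report.

Problem sizes in the test and acceptance suites (400-gene graphs, 10–25
simulation seeds, B = 199–1000 permutation draws, 20–50 CV repeats) are
chosen so the full study re-runs in seconds while leaving the measured
margins (module-recovery Jaccard, pivotal-recovery rate, calibration bands)
far from their thresholds.

## Known limitations

The greedy search is a local method; no optimality is claimed beyond the
tested bound. The mutual-information module score is an operational stand-in
and excluded from guarantees. The overlap rate for n > 2 is a conservative,
non-standard quantity (kept for fidelity to the printed formula). LOO spread
statistics with deterministic classifiers are degenerate by construction.
The synthetic generator's independence assumptions (no gene–gene expression
correlation beyond planted shifts) make recovery easier than on real data
with correlated co-expression modules.
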