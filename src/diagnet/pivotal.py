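"""Pivotal-gene selection by connectivity enrichment.

Genes of the integrated diagnostic network are assessed against the full
background interactome in two ways:

* **Degree-quantile representation.**  The background degrees of the selected
  genes define quartile cutoffs; within each of the four degree levels the
  representation Per_i = N_{s,i} / N_{D,i} is the fraction of background genes
  of that level that were selected.  A permutation test (random gene sets of
  the same size drawn from the background) asks whether the representation of
  the top (most highly connected) level could arise by chance.

* **Per-gene connectivity enrichment.**  EC_j = C_{s,j} / C_{D,j}, the gene's
  degree in the consensus network divided by its degree in the background
  graph.  Genes are ranked by EC; positions where EC drops sharply (break
  points of the relative drop score) bound the candidate pivotal-gene panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: the two degree-interval schemes printed for the reference interactome
#: (quartiles of the selected genes' background degrees vs of the full graph)
INTERVAL_PRESETS = {
    "selected-quartiles": ((1, 27), (28, 52), (53, 111), (112, None)),
    "background-quartiles": ((1, 12), (13, 35), (36, 76), (77, None)),
}


def _interval_index(intervals):
    """Return a function mapping a degree to its level index (or None)."""
    def level_of(d: int):
        for i, (lo, hi) in enumerate(intervals):
            if d >= lo and (hi is None or d <= hi):
                return i
        return None

    return level_of


def degree_quantile_cutoffs(selected_genes, background_degrees) -> tuple:
    """Quartile-based degree intervals from the background degrees of the
    selected genes.

    Returns four contiguous integer intervals ``((1, c1), (c1+1, c2),
    (c2+1, c3), (c3+1, None))`` covering [1, ∞); ``None`` is an open upper
    bound.  Fewer than 4 selected genes, or degenerate quartiles (all cutoffs
    equal), raise ``ValueError``.
    """
    selected = [str(g).upper() for g in selected_genes]
    if len(selected) < 4:
        raise ValueError("need at least 4 selected genes for quartiles")
    missing = [g for g in selected if g not in background_degrees]
    if missing:
        raise KeyError(f"selected genes without background degree: {missing[:5]}")
    degs = np.array([background_degrees[g] for g in selected], dtype=float)
    q1, q2, q3 = (int(math.floor(q)) for q in np.percentile(degs, [25, 50, 75]))
    if not q1 < q2 < q3:
        raise ValueError(f"degenerate degree quartiles: {q1}, {q2}, {q3}")
    return ((1, q1), (q1 + 1, q2), (q2 + 1, q3), (q3 + 1, None))


def per_level_representation(selected_genes, background_degrees, intervals) -> pd.DataFrame:
    """Per_i = (# selected genes in level i) / (# background genes in level i).

    Returns a DataFrame with one row per level (columns ``interval``,
    ``n_selected``, ``n_background``, ``per``); an empty background level
    leaves ``per`` as NaN and is flagged in the ``defined`` column.
    """
    selected = {str(g).upper() for g in selected_genes}
    level_of = _interval_index(intervals)
    n_sel = [0] * len(intervals)
    n_bg = [0] * len(intervals)
    for gene, d in background_degrees.items():
        lvl = level_of(d)
        if lvl is None:
            continue
        n_bg[lvl] += 1
        if gene in selected:
            n_sel[lvl] += 1
    rows = []
    for i, (lo, hi) in enumerate(intervals):
        defined = n_bg[i] > 0
        rows.append(
            {
                "level": i + 1,
                "interval": f"{lo}-{hi if hi is not None else 'inf'}",
                "n_selected": n_sel[i],
                "n_background": n_bg[i],
                "per": n_sel[i] / n_bg[i] if defined else np.nan,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows).set_index("level")


def permutation_test_top_level(
    selected_genes,
    background_degrees,
    intervals,
    B: int = 1000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for the representation of the top degree level.

    The observed statistic is Per for the highest-degree level.  The null
    draws B gene sets of the same size uniformly without replacement from the
    background; since the statistic depends only on how many drawn genes land
    in the top level, the null draws are sampled through the exact
    hypergeometric marginal of that count.  The add-one estimator
    p = (1 + #{null ≥ observed}) / (B + 1) avoids p = 0.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    selected = {str(g).upper() for g in selected_genes}
    n_total = len(background_degrees)
    if len(selected) > n_total:
        raise ValueError("selected set larger than background")
    level_of = _interval_index(intervals)
    top = len(intervals) - 1
    n_top = sum(1 for d in background_degrees.values() if level_of(d) == top)
    if n_top == 0:
        raise ValueError("empty top degree level in background")
    observed = sum(
        1 for g in selected if g in background_degrees and level_of(background_degrees[g]) == top
    )
    rng = np.random.default_rng(seed)
    null_counts = rng.hypergeometric(n_top, n_total - n_top, len(selected), size=B)
    exceed = int((null_counts >= observed).sum())
    return (1 + exceed) / (B + 1)


def connectivity_enrichment(subnet_degrees, background_degrees) -> pd.Series:
    """EC_j = consensus-network degree / background degree, per gene.

    Every subnetwork gene must carry a positive background degree (a gene
    cannot be in a network its background does not connect).
    """
    ec = {}
    for gene, c_s in subnet_degrees.items():
        if gene not in background_degrees:
            raise KeyError(f"gene missing from background: {gene}")
        c_d = background_degrees[gene]
        if c_d <= 0:
            raise ValueError(f"background degree must be positive: {gene}")
        ec[gene] = c_s / c_d
    return _sort_ec(pd.Series(ec, name="ec"))


def _sort_ec(series: pd.Series) -> pd.Series:
    """Descending EC, ties in lexicographic gene order."""
    return series.sort_index().sort_values(ascending=False, kind="stable")


@dataclass
class BreakpointResult:
    """EC ranking with break points and candidate panel sizes."""

    genes: list
    ec: pd.Series
    drop_scores: pd.Series  # drop after position i (1-based), length n-1
    breakpoints: list
    candidate_sizes: list

    def panel(self, size: int) -> list:
        return self.genes[:size]


def rank_breakpoints(
    ec_table: pd.Series,
    rel_threshold: float = 1.5,
    max_breakpoints: int = 2,
) -> BreakpointResult:
    """Rank genes by descending EC and locate break points.

    The drop score after position i is (EC_i − EC_{i+1}) / EC_i; positions
    whose drop exceeds ``rel_threshold`` times the median drop are break
    points (largest drops first, at most ``max_breakpoints``).  Candidate
    panel sizes are the break-point positions, extended one position left
    when the genes flanking a break-point boundary tie in EC; when the
    break points lie close together (span ≤ 4 positions) the sizes between
    them are candidates too.  An all-equal drop profile (e.g. a geometric EC
    sequence) yields no break point.
    """
    ec = pd.Series(ec_table).astype(float)
    if len(ec) < 3:
        raise ValueError("need at least 3 genes to locate break points")
    ec = _sort_ec(ec)
    genes = list(ec.index)
    vals = ec.to_numpy()
    drops = (vals[:-1] - vals[1:]) / vals[:-1]
    drop_scores = pd.Series(drops, index=range(1, len(vals)), name="drop")
    median_drop = float(np.median(drops))
    cut = rel_threshold * median_drop
    candidates = [int(i) for i in drop_scores.index if drop_scores[i] > cut and drop_scores[i] > 0]
    candidates.sort(key=lambda i: (-drop_scores[i], i))
    breakpoints = sorted(candidates[:max_breakpoints])
    sizes = set()
    for pos in breakpoints:
        sizes.add(pos)
        if pos >= 2 and vals[pos - 1] == vals[pos - 2]:
            sizes.add(pos - 1)
    if sizes and max(sizes) - min(sizes) <= 4:
        sizes = set(range(min(sizes), max(sizes) + 1))
    return BreakpointResult(
        genes=genes,
        ec=ec,
        drop_scores=drop_scores,
        breakpoints=breakpoints,
        candidate_sizes=sorted(sizes),
    )


def apply_external_filter(result: BreakpointResult, keep_table) -> BreakpointResult:
    """Drop genes flagged by an external per-gene keep/drop screen (e.g. a
    survival-association filter) from the EC ranking and recompute break
    points on the survivors."""
    keep = {str(g).upper() for g, k in dict(keep_table).items() if k}
    filtered = result.ec[[g in keep for g in result.ec.index]]
    return rank_breakpoints(filtered)
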