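"""Gene-set enrichment with Fisher p, rank-deviation Z, and combined C-score.

For a query gene list against a GMT library, each term receives

* a one-sided Fisher exact (hypergeometric upper-tail) over-representation
  p-value, BH-adjusted across the library's terms;
* a rank-deviation Z-score: terms are ranked by Fisher p for the observed
  query and for ``n_random`` random queries of the same size; Z is the
  observed rank's deviation from its null mean in null-SD units (negative Z
  means the term ranks better than expected);
* the combined score C = log10(p) · Z, using the unadjusted Fisher p.  For an
  enriched term both factors are negative, so larger C means stronger
  enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from diagnet.scoring import bh_adjust


def read_gmt(path: str) -> dict:
    """Parse a GMT library: one term per line, ``term<TAB>description<TAB>genes…``."""
    library = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            library[parts[0]] = {g.strip().upper() for g in parts[2:] if g.strip()}
    if not library:
        raise ValueError(f"{path}: no terms parsed")
    return library


def write_gmt(library: dict, path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term in sorted(library):
            genes = "\t".join(sorted(library[term]))
            fh.write(f"{term}\t{description}\t{genes}\n")


def fisher_p(overlap: int, query_size: int, term_size: int, background_size: int) -> float:
    """One-sided over-representation p: P(X ≥ overlap) for X hypergeometric
    with ``term_size`` successes among ``background_size`` genes and
    ``query_size`` draws."""
    if not (
        0 <= overlap <= min(query_size, term_size)
        and term_size <= background_size
        and query_size <= background_size
    ):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, query={query_size}, "
            f"term={term_size}, background={background_size}"
        )
    return float(min(1.0, stats.hypergeom.sf(overlap - 1, background_size, term_size, query_size)))


def c_score(p: float, z: float) -> float:
    """Combined score C = log10(p) · Z; requires p in (0, 1]."""
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return float(np.log10(p) * z)


def _term_pvalues(query_idx: set, term_cols: list, term_sizes, query_size, background_size):
    """Fisher p for every term given the query as a set of universe indices."""
    overlaps = np.array([len(query_idx & cols) for cols in term_cols])
    return stats.hypergeom.sf(overlaps - 1, background_size, term_sizes, query_size), overlaps


def enrich(
    query_genes,
    library: dict,
    background_size: int | None = None,
    n_random: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Enrichment of ``query_genes`` against every term of ``library``.

    ``background_size`` defaults to the number of distinct genes in the
    library; it may be larger (genes outside every term).  Returns one row
    per term — columns ``overlap``, ``p``, ``p_adj``, ``z``, ``c``,
    ``genes`` — sorted by descending C (undefined C last, then by p).  The
    null ranks behind Z are recomputed from ``n_random`` seeded random
    queries, so results are deterministic given ``seed``.
    """
    query = {str(g).upper() for g in query_genes}
    if not query:
        raise ValueError("empty query")
    if not library:
        raise ValueError("empty library")
    universe = sorted(set.union(*map(set, library.values())))
    if background_size is None:
        background_size = len(universe)
    if background_size < len(universe):
        raise ValueError("background smaller than the library's gene universe")
    gene_idx = {g: i for i, g in enumerate(universe)}
    terms = sorted(library)
    term_cols = [
        frozenset(gene_idx[g] for g in library[t] if g in gene_idx) for t in terms
    ]
    term_sizes = np.array([len(library[t]) for t in terms])
    q = len(query)

    obs_idx = {gene_idx[g] for g in query if g in gene_idx}
    obs_p, obs_overlap = _term_pvalues(obs_idx, term_cols, term_sizes, q, background_size)
    obs_rank = stats.rankdata(obs_p, method="average")

    rng = np.random.default_rng(seed)
    null_ranks = np.empty((n_random, len(terms)))
    for r in range(n_random):
        draw = rng.choice(background_size, size=q, replace=False)
        draw_idx = {int(i) for i in draw if i < len(universe)}
        p_r, _ = _term_pvalues(draw_idx, term_cols, term_sizes, q, background_size)
        null_ranks[r] = stats.rankdata(p_r, method="average")
    mean_rank = null_ranks.mean(axis=0)
    sd_rank = null_ranks.std(axis=0, ddof=1) if n_random > 1 else np.zeros(len(terms))

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_rank > 0, (obs_rank - mean_rank) / sd_rank, np.nan)
    p_adj = bh_adjust(obs_p)
    c = np.log10(obs_p) * z
    result = pd.DataFrame(
        {
            "overlap": obs_overlap,
            "p": obs_p,
            "p_adj": p_adj,
            "z": z,
            "c": c,
            "genes": [
                ";".join(sorted(query & library[t])) for t in terms
            ],
        },
        index=pd.Index(terms, name="term"),
    )
    result["z_defined"] = sd_rank > 0
    result = result.sort_values(
        by=["c", "p"], ascending=[False, True], kind="stable", na_position="last"
    )
    result.attrs["background_size"] = background_size
    result.attrs["n_random"] = n_random
    return result


def write_enrichment(result: pd.DataFrame, path: str) -> None:
    result.to_csv(path, sep="\t", index_label="term", float_format="%.6g")
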