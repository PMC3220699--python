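"""Per-mountain enrichment statistics.

Two kinds of over-representation test are run against the genome-wide
background:

* GO-term enrichment of a mountain's genes — hypergeometric upper tail
  P(X >= k) with Bonferroni correction over the tested terms (the top three
  corrected terms summarize each mountain).
* Niche / taxonomy enrichment of a mountain's phylogenetic profiles —
  each genome with a qualifying hit for a mountain protein contributes one
  count to its category (host-associated or not; gamma-proteobacterium or
  not); the pooled mountain tallies are compared to the genome-wide tallies
  with a two-sided Fisher exact test, labelled Over or Under by the sample
  odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

from .profiles import ProfileMatrix

__all__ = [
    "CategoryEnrichment",
    "go_enrichment",
    "profile_category_counts",
    "fisher_category_test",
    "mountain_profile_enrichment",
]


@dataclass(frozen=True)
class CategoryEnrichment:
    """Result of one 2x2 Fisher test for a (mountain, category) pair.

    ``contingency`` rows are (mountain, background-minus-mountain), columns
    (in category, not in category).  ``direction`` is "Over" when the sample
    odds ratio exceeds 1, "Under" otherwise, and None for degenerate tables
    (a zero margin), which are reported with p = 1 and ``degenerate=True``.
    """

    mountain_id: int | str
    category: str
    contingency: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    direction: str | None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# GO-term enrichment
# ---------------------------------------------------------------------------

def go_enrichment(
    mountain_genes: Iterable[str],
    background_genes: Iterable[str],
    annotations: Mapping[str, set[str]],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a mountain.

    For each term annotated to at least one mountain gene the upper-tail
    probability P(X >= k) is computed for X ~ Hypergeom(N = background size,
    K = term count in background, n = mountain size).  ``correction`` is one
    of ``none``, ``bonferroni`` (multiply by the number of tested terms,
    capped at 1) or ``bh`` (Benjamini-Hochberg step-up).  Rows are sorted by
    corrected then raw p; the ``top3`` column flags the three best terms,
    the conventional per-mountain summary.
    """
    mountain = set(mountain_genes)
    background = set(background_genes)
    if not mountain <= background:
        extra = sorted(mountain - background)[:5]
        raise ValueError(
            f"mountain genes missing from background: {extra}..."
        )
    if correction not in ("none", "bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")

    term_bg: dict[str, int] = {}
    term_mt: dict[str, int] = {}
    for gene in background:
        for term in annotations.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in mountain:
                term_mt[term] = term_mt.get(term, 0) + 1

    n_bg, n_mt = len(background), len(mountain)
    rows = []
    for term in sorted(term_mt):
        k, big_k = term_mt[term], term_bg[term]
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_mt))
        rows.append((term, k, big_k, n_mt, n_bg, p))
    result = pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "p_value"]
    )
    # the hypothesis family is every term in the background, including
    # those absent from the mountain (reported rows cover k >= 1 only)
    m = len(term_bg)
    if len(result) == 0:
        result["p_corrected"] = []
        result["top3"] = []
        return result
    r = len(result)
    if correction == "none":
        result["p_corrected"] = result["p_value"]
    elif correction == "bonferroni":
        result["p_corrected"] = np.minimum(result["p_value"] * m, 1.0)
    else:  # Benjamini-Hochberg step-up over the m-term family
        order = np.argsort(result["p_value"].to_numpy(), kind="stable")
        ranked = result["p_value"].to_numpy()[order] * m / np.arange(1, r + 1)
        adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(r)
        out[order] = np.minimum(adjusted, 1.0)
        result["p_corrected"] = out
    result = result.sort_values(
        ["p_corrected", "p_value", "term"], ignore_index=True
    )
    result["top3"] = np.arange(r) < 3
    return result


# ---------------------------------------------------------------------------
# profile-based category tallies and Fisher tests
# ---------------------------------------------------------------------------

def profile_category_counts(
    proteins: Iterable[str],
    matrix: ProfileMatrix,
    organism_category: Mapping[str, str],
) -> dict[str, int]:
    """Tally organism categories over the profiles of a protein set.

    Every genome with a strictly positive profile cell for a protein
    contributes one count to that genome's category; counts are summed over
    proteins (an organism appearing in several profiles is counted once per
    protein, not deduplicated).
    """
    missing = sorted(set(matrix.genome_ids) - set(organism_category))
    if missing:
        raise KeyError(
            f"organisms missing category metadata: {missing[:10]}"
        )
    index = {pid: i for i, pid in enumerate(matrix.protein_ids)}
    tally: dict[str, int] = {}
    for pid in proteins:
        if pid not in index:
            raise KeyError(f"protein {pid!r} not in profile matrix")
        row = matrix.scores[index[pid]]
        for j in np.flatnonzero(row > 0):
            cat = organism_category[matrix.genome_ids[j]]
            tally[cat] = tally.get(cat, 0) + 1
    return tally


def fisher_category_test(
    mountain_tally: Mapping[str, int],
    background_tally: Mapping[str, int],
    category: str,
    mountain_id: int | str = 0,
    *,
    subtract_mountain: bool = True,
) -> CategoryEnrichment:
    """Two-sided Fisher exact test of one category's over/under-representation.

    The 2x2 table compares (in category, not in category) counts for the
    mountain's pooled profiles against the genome-wide pooled profiles.
    With ``subtract_mountain`` (default) the mountain counts are removed
    from the background row so the table is disjoint; the genome-wide totals
    may alternatively be used as-is.
    """
    a = int(mountain_tally.get(category, 0))
    b = int(sum(mountain_tally.values())) - a
    bg_cat = int(background_tally.get(category, 0))
    bg_tot = int(sum(background_tally.values()))
    if subtract_mountain:
        c = bg_cat - a
        d = (bg_tot - bg_cat) - b
    else:
        c = bg_cat
        d = bg_tot - bg_cat
    if min(c, d) < 0:
        raise ValueError(
            "mountain tallies exceed background tallies; is the background "
            "genome-wide?"
        )
    table = ((a, b), (c, d))
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return CategoryEnrichment(
            mountain_id=mountain_id,
            category=category,
            contingency=table,
            odds_ratio=float("nan"),
            p_value=1.0,
            direction=None,
            degenerate=True,
        )
    odds, p = fisher_exact(table, alternative="two-sided")
    direction = "Over" if (a * d) > (b * c) else "Under"
    return CategoryEnrichment(
        mountain_id=mountain_id,
        category=category,
        contingency=table,
        odds_ratio=float(odds),
        p_value=float(p),
        direction=direction,
    )


def mountain_profile_enrichment(
    mountain_map,
    matrix: ProfileMatrix,
    organism_category: Mapping[str, str],
    *,
    subtract_mountain: bool = True,
) -> pd.DataFrame:
    """Fisher niche/taxonomy enrichment for every mountain and category.

    The background is the pooled profile tally of every protein on the map
    (the whole-genome gene set).  Returns one row per (mountain, category).
    """
    background = profile_category_counts(
        mountain_map.protein_ids, matrix, organism_category
    )
    categories = sorted(set(organism_category.values()))
    rows = []
    for mid in range(1, mountain_map.n_mountains + 1):
        members = mountain_map.members(mid)
        tally = profile_category_counts(members, matrix, organism_category)
        for cat in categories:
            res = fisher_category_test(
                tally, background, cat, mountain_id=mid,
                subtract_mountain=subtract_mountain,
            )
            rows.append(
                (
                    mid, len(members), cat,
                    res.contingency[0][0], res.contingency[0][1],
                    res.contingency[1][0], res.contingency[1][1],
                    res.odds_ratio, res.p_value, res.direction,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mountain_id", "n_genes", "category", "a", "b", "c", "d",
            "odds_ratio", "p_value", "direction",
        ],
    )
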