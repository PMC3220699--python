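"""Threshold-based ortholog calling, Venn partitioning and class extraction.

Orthologs between two genomes are called as reciprocal best hits among
homology-search hits that pass two inclusive thresholds: minLrap >= 0.6 and
percent identity >= 30.  minLrap is the alignment length divided by the
shorter of the two protein lengths (the alignment-length ratio convention of
the MicroScope annotation platform), capped at 1.

The resulting one-to-one ortholog table supports two summaries:

* an n-set Venn partition — for each anchor genome, its genes are split
  into the 2^(n-1) regions defined by which other genomes carry an ortholog;
* include/exclude class extraction — genes with an ortholog in every
  required genome and none in any excluded genome (e.g. genes shared by the
  insect-pathogen genera but absent from enteric outgroups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .profiles import SearchHit

__all__ = [
    "HomologyParams",
    "OrthologTable",
    "VennPartition",
    "minlrap",
    "call_orthologs",
    "venn_partition",
    "class_extract",
]


@dataclass(frozen=True)
class HomologyParams:
    """Inclusive homology-calling thresholds."""

    min_minlrap: float = 0.6
    min_identity: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.min_minlrap <= 1:
            raise ValueError("min_minlrap must be in (0, 1]")
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")


def minlrap(align_len: int, q_len: int, s_len: int) -> float:
    """Alignment length over the shorter protein length, capped at 1."""
    if q_len < 1 or s_len < 1 or align_len < 1:
        raise ValueError(
            f"lengths must be >= 1, got align_len={align_len}, "
            f"q_len={q_len}, s_len={s_len}"
        )
    ratio = align_len / min(q_len, s_len)
    if ratio > 1.0:
        warnings.warn(
            f"alignment length {align_len} exceeds shorter protein "
            f"({min(q_len, s_len)}); minLrap capped at 1.0",
            stacklevel=2,
        )
        return 1.0
    return ratio


@dataclass
class OrthologTable:
    """Reciprocal-best-hit ortholog pairs plus per-genome gene universes."""

    pairs: pd.DataFrame  # gene_a, genome_a, gene_b, genome_b, identity_pct, minlrap
    universes: dict[str, set[str]]

    @property
    def genomes(self) -> list[str]:
        return sorted(self.universes)

    def partners(self, gene: str, genome: str) -> set[str]:
        """Genomes holding an ortholog of ``gene``."""
        hit_a = self.pairs[self.pairs["gene_a"] == gene]["genome_b"]
        hit_b = self.pairs[self.pairs["gene_b"] == gene]["genome_a"]
        return set(hit_a) | set(hit_b)

    def presence_index(self) -> dict[tuple[str, str], set[str]]:
        """(genome, gene) -> set of genomes with an ortholog to that gene."""
        index: dict[tuple[str, str], set[str]] = {
            (genome, gene): set()
            for genome, genes in self.universes.items()
            for gene in genes
        }
        for row in self.pairs.itertuples(index=False):
            index[(row.genome_a, row.gene_a)].add(row.genome_b)
            index[(row.genome_b, row.gene_b)].add(row.genome_a)
        return index


def _rank(hit: SearchHit) -> tuple[float, float, str]:
    return (-hit.bit_score, hit.e_value, hit.subject_id)


def call_orthologs(
    hits: Iterable[SearchHit],
    query_genome: Mapping[str, str],
    params: HomologyParams | None = None,
    universes: Mapping[str, set[str]] | None = None,
) -> OrthologTable:
    """Call reciprocal-best-hit orthologs from cross-genome search hits.

    ``query_genome`` resolves every query id to its genome.  Hits must carry
    ``q_len``/``s_len`` (needed for minLrap); a missing length raises,
    naming the offending hit.  After threshold filtering, the best hit per
    (query, target genome) is chosen by bit score (ties: lower e-value, then
    lexicographic subject id), and a pair is emitted when best hits are
    reciprocal.  ``universes`` fixes each genome's full gene set; by default
    it is inferred from the query ids seen.
    """
    params = params or HomologyParams()
    best: dict[tuple[str, str], SearchHit] = {}
    seen_universe: dict[str, set[str]] = {}
    ratios: dict[tuple[str, str], float] = {}
    for hit in hits:
        if hit.query_id not in query_genome:
            raise KeyError(f"query id {hit.query_id!r} missing from genome map")
        qg = query_genome[hit.query_id]
        seen_universe.setdefault(qg, set()).add(hit.query_id)
        if qg == hit.subject_genome:
            continue
        if hit.q_len is None or hit.s_len is None:
            raise ValueError(
                f"hit {hit.query_id}->{hit.subject_id} lacks q_len/s_len "
                f"required for minLrap"
            )
        ratio = minlrap(hit.align_len, hit.q_len, hit.s_len)
        if ratio < params.min_minlrap or hit.identity_pct < params.min_identity:
            continue
        key = (hit.query_id, hit.subject_genome)
        held = best.get(key)
        if held is None or _rank(hit) < _rank(held):
            best[key] = hit
            ratios[key] = ratio

    rows = []
    for (query, _), hit in best.items():
        qg = query_genome[query]
        # reciprocity: the subject's best hit in the query's genome is the query
        back = best.get((hit.subject_id, qg))
        if back is None or back.subject_id != query:
            continue
        if (qg, query) >= (hit.subject_genome, hit.subject_id):
            continue  # emit each unordered pair once, smaller genome first
        rows.append(
            (
                query, qg, hit.subject_id, hit.subject_genome,
                hit.identity_pct, ratios[(query, hit.subject_genome)],
            )
        )
    pairs = pd.DataFrame(
        rows,
        columns=["gene_a", "genome_a", "gene_b", "genome_b",
                 "identity_pct", "minlrap"],
    ).sort_values(["genome_a", "genome_b", "gene_a"], ignore_index=True)
    table_universes = (
        {g: set(u) for g, u in universes.items()}
        if universes is not None
        else seen_universe
    )
    return OrthologTable(pairs=pairs, universes=table_universes)


@dataclass
class VennPartition:
    """Per-anchor-genome region counts over all non-empty genome subsets.

    ``regions[anchor][subset]`` lists the anchor's genes whose presence set
    (anchor plus genomes holding an ortholog) equals ``subset`` (a sorted
    tuple of genome ids).  Per anchor, region sizes sum to the anchor's
    universe size.
    """

    genomes: list[str]
    regions: dict[str, dict[tuple[str, ...], list[str]]]

    def counts(self) -> pd.DataFrame:
        rows = []
        for anchor, parts in self.regions.items():
            for subset, genes in sorted(parts.items()):
                rows.append((anchor, "&".join(subset), len(genes)))
        return pd.DataFrame(rows, columns=["anchor", "region", "count"])

    def region_count(self, anchor: str, subset: Sequence[str]) -> int:
        key = tuple(sorted(subset))
        return len(self.regions[anchor].get(key, []))


def venn_partition(
    table: OrthologTable, genomes: Sequence[str] | None = None
) -> VennPartition:
    """Partition each genome's genes by which other genomes share them.

    Each anchor gene's presence set is the anchor genome plus every genome
    with a reciprocal-best-hit ortholog to it; genes are grouped by presence
    set, giving the regions of an n-set Venn diagram anchored on each genome
    in turn.
    """
    genomes = sorted(genomes) if genomes is not None else table.genomes
    gset = set(genomes)
    index = table.presence_index()
    regions: dict[str, dict[tuple[str, ...], list[str]]] = {
        g: {} for g in genomes
    }
    for (genome, gene), partners in index.items():
        if genome not in gset:
            continue
        subset = tuple(sorted((partners & gset) | {genome}))
        regions[genome].setdefault(subset, []).append(gene)
    for parts in regions.values():
        for genes in parts.values():
            genes.sort()
    return VennPartition(genomes=list(genomes), regions=regions)


def class_extract(
    table: OrthologTable,
    anchor_genome: str,
    require_genomes: Sequence[str],
    exclude_genomes: Sequence[str],
) -> list[str]:
    """Anchor genes with orthologs in every required genome and none in any
    excluded genome.

    With requires = the other insect-pathogen genomes and excludes = enteric
    outgroups this yields the shared-lifestyle gene classes; an empty
    exclude set reduces to an intersection-region query.
    """
    require = set(require_genomes)
    exclude = set(exclude_genomes)
    overlap = require & exclude
    if overlap:
        raise ValueError(
            f"genomes in both require and exclude sets: {sorted(overlap)}"
        )
    for g in {anchor_genome} | require | exclude:
        if g not in table.universes:
            raise KeyError(f"genome {g!r} not in ortholog table universe")
    index = table.presence_index()
    out = []
    for gene in sorted(table.universes[anchor_genome]):
        partners = index[(anchor_genome, gene)]
        if require <= partners and not (exclude & partners):
            out.append(gene)
    return out
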