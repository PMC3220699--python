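"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the three kinds of real input the pipeline consumes:

* :func:`simulate_profile_matrix` — a proteins x genomes bit-score matrix with
  planted correlated modules, standing in for an all-vs-all protein search
  against a panel of sequenced genomes.
* :func:`simulate_genome_pair` — two nucleotide sequences derived from a common
  ancestor by per-site point mutation (and optional single-base indels), with
  the realized divergence reported exactly, so whole-genome identity metrics
  have an analytic oracle.
* :func:`simulate_annotations` — a gene -> category table with one planted
  enriched gene set, so over-representation statistics can be validated
  against a known effect size.

plus :func:`simulate_ortholog_hits`, which emits homology-search hit tables for
a pair of proteomes with a known one-to-one ortholog structure.

All generators are deterministic given their spec's ``seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import FilterParams, ProfileMatrix

__all__ = [
    "ModulePlantSpec",
    "GenomePairSpec",
    "AnnotationPlantSpec",
    "simulate_profile_matrix",
    "simulate_genome_pair",
    "simulate_annotations",
    "simulate_ortholog_hits",
]

_BASES = np.array(list("ACGT"))


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ModulePlantSpec:
    """Parameters for planting correlated modules in a profile matrix.

    Each module is assigned a fixed *characteristic genome set* (a random
    subset of the genome panel).  A module protein registers a qualifying hit
    in a characteristic genome with probability ``presence_prob_in`` and in
    any other genome with probability ``presence_prob_out``; proteins outside
    every module use ``presence_prob_out`` throughout.  Finally each cell's
    presence state is flipped independently with ``noise_flip_prob``.
    Bit scores of present cells are normal(``bitscore_mean``,
    ``bitscore_sd``) truncated below just above the 50-bit retention
    threshold, so every present cell survives downstream filtering.
    """

    n_proteins: int
    n_genomes: int
    n_modules: int
    module_sizes: tuple[int, ...]
    presence_prob_in: float = 0.9
    presence_prob_out: float = 0.05
    bitscore_mean: float = 150.0
    bitscore_sd: float = 30.0
    noise_flip_prob: float = 0.0
    characteristic_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(self.module_sizes))
        if self.n_proteins <= 0 or self.n_genomes <= 0:
            raise ValueError("n_proteins and n_genomes must be positive")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must have n_modules entries")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module_sizes must be positive")
        if sum(self.module_sizes) > self.n_proteins:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} > "
                f"n_proteins={self.n_proteins}"
            )
        for name in ("presence_prob_in", "presence_prob_out",
                     "noise_flip_prob", "characteristic_fraction"):
            _check_prob(name, getattr(self, name))
        if self.bitscore_sd < 0:
            raise ValueError("bitscore_sd must be non-negative")


@dataclass(frozen=True)
class GenomePairSpec:
    """Parameters for a mutated genome pair from a common ancestor."""

    length_bp: int
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        _check_prob("substitution_rate", self.substitution_rate)
        _check_prob("indel_rate", self.indel_rate)
        _check_prob("gc_content", self.gc_content)


@dataclass(frozen=True)
class AnnotationPlantSpec:
    """Parameters for a gene-annotation table with one planted enrichment.

    ``background_freq`` maps each category label to the per-gene probability
    of carrying it.  Genes inside the enriched set carry
    ``enriched_category`` with probability
    ``min(1, background_freq * enrichment_factor)`` (the clamp is logged),
    or with ``enriched_prob`` when that override is given — the override
    expresses degenerate designs such as a category absent from the
    background yet fully covering the enriched set.
    """

    n_genes: int
    categories: tuple[str, ...]
    background_freq: float
    enriched_set_size: int
    enriched_category: str
    enrichment_factor: float = 1.0
    enriched_prob: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        _check_prob("background_freq", self.background_freq)
        if self.background_freq * len(self.categories) > 1.0 + 1e-9:
            raise ValueError("background frequencies sum to more than 1")
        if not 0 <= self.enriched_set_size <= self.n_genes:
            raise ValueError("enriched_set_size must be in [0, n_genes]")
        if self.enriched_category not in self.categories:
            raise ValueError(
                f"enriched_category {self.enriched_category!r} not in categories"
            )
        if self.enrichment_factor < 0:
            raise ValueError("enrichment_factor must be non-negative")
        if self.enriched_prob is not None:
            _check_prob("enriched_prob", self.enriched_prob)


# ---------------------------------------------------------------------------
# profile matrices with planted modules
# ---------------------------------------------------------------------------

def simulate_profile_matrix(
    spec: ModulePlantSpec,
) -> tuple[ProfileMatrix, np.ndarray]:
    """Simulate a thresholded phylogenetic-profile matrix with planted modules.

    Returns the matrix and the true module label per protein (1..n_modules
    for planted proteins, 0 for background proteins).  Protein ids are
    ``P0000, P0001, ...``; genome ids ``G000, G001, ...``.

    Rows are NOT re-filtered by the minimum-genome rule: the matrix reports
    exactly the planted presence states so that downstream recovery can be
    scored against an unaltered truth vector.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_proteins, spec.n_genomes

    labels = np.zeros(n, dtype=int)
    start = 0
    for m, size in enumerate(spec.module_sizes, start=1):
        labels[start:start + size] = m
        start += size

    # one characteristic genome subset per module
    n_char = max(1, int(round(spec.characteristic_fraction * g)))
    char_sets = [
        rng.choice(g, size=n_char, replace=False) for _ in spec.module_sizes
    ]

    prob = np.full((n, g), spec.presence_prob_out)
    for m, cols in enumerate(char_sets, start=1):
        prob[np.ix_(labels == m, cols)] = spec.presence_prob_in

    present = rng.random((n, g)) < prob
    if spec.noise_flip_prob > 0:
        flips = rng.random((n, g)) < spec.noise_flip_prob
        present ^= flips

    scores = rng.normal(spec.bitscore_mean, spec.bitscore_sd, size=(n, g))
    scores = np.maximum(scores, 50.0 + 1e-6)  # truncate below the >50 filter
    scores = np.where(present, scores, 0.0)

    matrix = ProfileMatrix(
        protein_ids=[f"P{i:04d}" for i in range(n)],
        genome_ids=[f"G{j:03d}" for j in range(g)],
        scores=scores,
        params=FilterParams(),
    )
    return matrix, labels


# ---------------------------------------------------------------------------
# mutated genome pairs
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(4, size=length, p=p)


def simulate_genome_pair(spec: GenomePairSpec) -> tuple[str, str, float]:
    """Derive a genome pair from a common ancestor by point mutation.

    Sequence A is the ancestor; sequence B is produced by, at each ancestral
    site, deleting it with probability ``indel_rate/2``, otherwise
    substituting it with probability ``substitution_rate`` (uniformly over
    the three alternative bases), and inserting a random base after it with
    probability ``indel_rate/2``.

    Returns ``(seq_a, seq_b, realized_divergence)`` where the divergence is
    the exact fraction of substituted sites among ancestral sites retained
    in both sequences.
    """
    rng = np.random.default_rng(spec.seed)
    anc = _random_sequence(rng, spec.length_bp, spec.gc_content)

    sub = rng.random(spec.length_bp) < spec.substitution_rate
    # uniform over the 3 alternatives: shift by 1..3 mod 4
    shift = rng.integers(1, 4, size=spec.length_bp)
    derived = np.where(sub, (anc + shift) % 4, anc)

    if spec.indel_rate > 0:
        deleted = rng.random(spec.length_bp) < spec.indel_rate / 2
        inserted = rng.random(spec.length_bp) < spec.indel_rate / 2
        pieces: list[np.ndarray] = []
        keep = ~deleted
        n_sub = int(np.count_nonzero(sub & keep))
        n_aligned = int(np.count_nonzero(keep))
        ins_bases = _random_sequence(rng, int(inserted.sum()), spec.gc_content)
        ins_iter = iter(ins_bases)
        for i in range(spec.length_bp):
            if keep[i]:
                pieces.append(derived[i:i + 1])
            if inserted[i]:
                pieces.append(np.array([next(ins_iter)]))
        derived = np.concatenate(pieces) if pieces else np.empty(0, dtype=int)
    else:
        n_sub = int(np.count_nonzero(sub))
        n_aligned = spec.length_bp

    divergence = n_sub / n_aligned if n_aligned else 0.0
    return (
        "".join(_BASES[anc]),
        "".join(_BASES[derived]),
        divergence,
    )


# ---------------------------------------------------------------------------
# annotation tables with a planted enriched category
# ---------------------------------------------------------------------------

def simulate_annotations(
    spec: AnnotationPlantSpec,
) -> tuple[pd.DataFrame, set[str]]:
    """Simulate a (gene_id, category) annotation table with one planted
    enrichment.

    Returns the long-format table and the set of gene ids forming the true
    enriched set (a seeded random sample of ``enriched_set_size`` genes).
    Every gene appears in the table's gene universe; genes without any
    category are emitted with an empty category string is NOT done — instead
    callers treat absence from the table as "not annotated".
    """
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"g{i:05d}" for i in range(spec.n_genes)])
    enriched_idx = rng.choice(
        spec.n_genes, size=spec.enriched_set_size, replace=False
    )
    enriched = np.zeros(spec.n_genes, dtype=bool)
    enriched[enriched_idx] = True

    if spec.enriched_prob is not None:
        p_enriched = spec.enriched_prob
    else:
        p_enriched = spec.background_freq * spec.enrichment_factor
        if p_enriched > 1.0:
            warnings.warn(
                f"enriched-category probability {p_enriched:.3g} clamped to 1",
                stacklevel=2,
            )
            p_enriched = 1.0

    rows: list[tuple[str, str]] = []
    for cat in spec.categories:
        p = np.full(spec.n_genes, spec.background_freq)
        if cat == spec.enriched_category:
            p[enriched] = p_enriched
        carry = rng.random(spec.n_genes) < p
        rows.extend((gene, cat) for gene in genes[carry])

    table = pd.DataFrame(rows, columns=["gene_id", "category"])
    table = table.sort_values(["gene_id", "category"], ignore_index=True)
    return table, set(genes[enriched])


# ---------------------------------------------------------------------------
# homology hits with known ortholog structure
# ---------------------------------------------------------------------------

def simulate_ortholog_hits(
    n_orthologs: int = 40,
    n_unique_a: int = 10,
    n_unique_b: int = 10,
    n_paralog_hits: int = 0,
    identity_mean: float = 70.0,
    protein_len: int = 300,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[tuple[str, str]]]:
    """Emit a symmetric homology hit table for two proteomes A and B with a
    known one-to-one ortholog structure.

    Each of the ``n_orthologs`` ortholog pairs produces a reciprocal pair of
    full-length, high-identity hits that dominate any paralogous hit.
    ``n_paralog_hits`` adds weaker off-diagonal cross hits (lower bit score
    and identity) that a reciprocal-best-hit rule must reject.  Species-unique
    genes produce no cross-genome hits.

    Returns ``(hits, truth)`` where hits columns follow 14-column tabular
    search output (std 12 + qlen, slen, plus query/subject genome columns)
    and truth is the set of (gene_a, gene_b) ortholog pairs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth: set[tuple[str, str]] = set()
    for i in range(n_orthologs):
        ga, gb = f"A_{i:04d}", f"B_{i:04d}"
        truth.add((ga, gb))
        ident = float(np.clip(rng.normal(identity_mean, 5.0), 35.0, 99.9))
        bits = 2.0 * protein_len * ident / 100.0
        for q, s, qg, sg in ((ga, gb, "A", "B"), (gb, ga, "B", "A")):
            rows.append(
                (q, s, ident, protein_len, 0, 0, 1, protein_len, 1,
                 protein_len, 1e-50, bits, protein_len, protein_len, qg, sg)
            )
    for _ in range(n_paralog_hits):
        i, j = rng.integers(0, n_orthologs, size=2)
        ga, gb = f"A_{i:04d}", f"B_{j:04d}"
        ident = float(np.clip(rng.normal(identity_mean - 25.0, 5.0), 30.0, 60.0))
        aln = int(protein_len * 0.8)
        bits = 2.0 * aln * ident / 100.0
        for q, s, qg, sg in ((ga, gb, "A", "B"), (gb, ga, "B", "A")):
            rows.append(
                (q, s, ident, aln, 0, 0, 1, aln, 1, aln, 1e-20, bits,
                 protein_len, protein_len, qg, sg)
            )
    hits = pd.DataFrame(
        rows,
        columns=[
            "query_id", "subject_id", "identity_pct", "align_len",
            "mismatches", "gap_opens", "q_start", "q_end", "s_start",
            "s_end", "e_value", "bit_score", "q_len", "s_len",
            "query_genome", "subject_genome",
        ],
    )
    return hits, truth
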