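"""Phylogenetic-profile construction from all-vs-all protein search output.

A phylogenetic profile is, per protein, the vector of best homology-search
bit scores across a panel of genomes.  The pipeline here consumes 12-column
tabular search output (the common ``outfmt 6`` layout, optionally extended
with query/subject lengths), reduces it to the best hit per (query, genome),
applies the retention filter — bit score strictly above 50, e-value strictly
below 1e-5, qualifying hits in at least 5 genomes — and assembles the
retained rows into a proteins x genomes bit-score matrix.  Cells without a
qualifying hit hold 0 bits, which keeps rank correlations downstream
well-defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SearchHit",
    "FilterParams",
    "ProfileMatrix",
    "SearchFormatError",
    "UnknownSubjectError",
    "NoProteinsRetainedError",
    "read_search_hits",
    "best_hit_per_genome",
    "build_profile_matrix",
]


class SearchFormatError(ValueError):
    """A line of tabular search output could not be parsed."""


class UnknownSubjectError(KeyError):
    """A subject id could not be resolved to a genome."""


class NoProteinsRetainedError(ValueError):
    """The retention filter removed every protein."""


@dataclass(frozen=True)
class SearchHit:
    """One pairwise homology-search hit.

    ``q_len``/``s_len`` are optional in profile construction but required by
    the orthology module (for the alignment-length ratio).
    """

    query_id: str
    subject_id: str
    subject_genome: str
    identity_pct: float
    align_len: int
    e_value: float
    bit_score: float
    q_len: int | None = None
    s_len: int | None = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")
        if self.bit_score < 0:
            raise ValueError(f"bit_score must be >= 0, got {self.bit_score}")
        if self.align_len < 1:
            raise ValueError(f"align_len must be >= 1, got {self.align_len}")


@dataclass(frozen=True)
class FilterParams:
    """Profile retention thresholds.

    Both score thresholds are strict inequalities: a hit qualifies when its
    bit score exceeds ``min_bitscore`` AND its e-value is below
    ``max_evalue``; a protein is retained when it qualifies in at least
    ``min_genomes`` genomes.
    """

    min_bitscore: float = 50.0
    max_evalue: float = 1e-5
    min_genomes: int = 5

    def __post_init__(self) -> None:
        if self.min_bitscore < 0:
            raise ValueError("min_bitscore must be >= 0")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")
        if self.min_genomes < 1:
            raise ValueError("min_genomes must be >= 1")

    def qualifies(self, bit_score: float, e_value: float) -> bool:
        return bit_score > self.min_bitscore and e_value < self.max_evalue


@dataclass
class ProfileMatrix:
    """Proteins x genomes matrix of best qualifying bit scores (0 = none)."""

    protein_ids: list[str]
    genome_ids: list[str]
    scores: np.ndarray
    params: FilterParams = field(default_factory=FilterParams)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.protein_ids), len(self.genome_ids)):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.genome_ids)} genomes"
            )

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.protein_ids, columns=self.genome_ids
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("protein_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, params: FilterParams | None = None
    ) -> "ProfileMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            protein_ids=[str(i) for i in frame.index],
            genome_ids=[str(c) for c in frame.columns],
            scores=frame.to_numpy(dtype=float),
            params=params or FilterParams(),
        )

    def iter_hits(self) -> Iterator[SearchHit]:
        """Re-express positive cells as hits (subject ids are synthetic);
        useful for idempotence checks."""
        for i, pid in enumerate(self.protein_ids):
            for j, gid in enumerate(self.genome_ids):
                score = self.scores[i, j]
                if score > 0:
                    yield SearchHit(
                        query_id=pid,
                        subject_id=f"{gid}:{pid}",
                        subject_genome=gid,
                        identity_pct=0.0,
                        align_len=1,
                        e_value=0.0,
                        bit_score=float(score),
                    )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def read_search_hits(
    path: str | Path,
    genome_map: Mapping[str, str],
    *,
    strict: bool = True,
    exclude_own_genome: bool = True,
) -> Iterator[SearchHit]:
    """Stream hits from 12-column (or 14-column, with qlen/slen) tabular
    search output.

    ``genome_map`` resolves subject ids to genome ids.  Exact self hits
    (query id == subject id) are always dropped; when ``exclude_own_genome``
    is set and the query id itself resolves through ``genome_map``, hits to
    the query's own genome are dropped too, so a protein's profile covers
    only *other* genomes.  Unmappable subjects raise
    :class:`UnknownSubjectError` in strict mode and are skipped with a
    warning otherwise.  Malformed lines always raise, naming the line number.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 14):
                raise SearchFormatError(
                    f"{path}:{lineno}: expected 12 or 14 tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                query_id, subject_id = fields[0], fields[1]
                identity_pct = float(fields[2])
                align_len = int(fields[3])
                e_value = float(fields[10])
                bit_score = float(fields[11])
                q_len = int(fields[12]) if len(fields) == 14 else None
                s_len = int(fields[13]) if len(fields) == 14 else None
            except ValueError as exc:
                raise SearchFormatError(
                    f"{path}:{lineno}: could not parse hit fields: {exc}"
                ) from None
            if query_id == subject_id:
                continue
            if subject_id not in genome_map:
                if strict:
                    raise UnknownSubjectError(
                        f"{path}:{lineno}: subject id {subject_id!r} missing "
                        f"from genome map"
                    )
                warnings.warn(
                    f"{path}:{lineno}: skipping unmappable subject "
                    f"{subject_id!r}",
                    stacklevel=2,
                )
                continue
            subject_genome = genome_map[subject_id]
            if exclude_own_genome and genome_map.get(query_id) == subject_genome:
                continue
            yield SearchHit(
                query_id=query_id,
                subject_id=subject_id,
                subject_genome=subject_genome,
                identity_pct=identity_pct,
                align_len=align_len,
                e_value=e_value,
                bit_score=bit_score,
                q_len=q_len,
                s_len=s_len,
            )


def read_genome_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (subject_id, genome_id) TSV."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SearchFormatError(
                    f"{path}:{lineno}: expected 2 columns, found {len(parts)}"
                )
            mapping[parts[0]] = parts[1]
    return mapping


# ---------------------------------------------------------------------------
# reduction and matrix assembly
# ---------------------------------------------------------------------------

def _hit_rank(hit: SearchHit) -> tuple[float, float, str]:
    # best = highest bit score; ties by lower e-value, then lexicographic id
    return (-hit.bit_score, hit.e_value, hit.subject_id)


def best_hit_per_genome(hits: Iterable[SearchHit]) -> list[SearchHit]:
    """Reduce hits to one per (query, subject genome): the best-scoring hit.

    Ties on bit score break by lower e-value, then lexicographically smaller
    subject id, making the reduction deterministic and independent of input
    order.
    """
    best: dict[tuple[str, str], SearchHit] = {}
    order: list[tuple[str, str]] = []
    for hit in hits:
        key = (hit.query_id, hit.subject_genome)
        held = best.get(key)
        if held is None:
            best[key] = hit
            order.append(key)
        elif _hit_rank(hit) < _hit_rank(held):
            best[key] = hit
    return [best[key] for key in order]


def build_profile_matrix(
    hits: Iterable[SearchHit],
    params: FilterParams | None = None,
    *,
    reduce: bool = True,
) -> ProfileMatrix:
    """Assemble the thresholded profile matrix from (reduced) hits.

    Cells failing either score threshold are set to 0; proteins qualifying
    in fewer than ``params.min_genomes`` genomes are dropped entirely.  Row
    and column order follow first appearance in the hit stream.
    """
    params = params or FilterParams()
    hits = list(hits)
    if reduce:
        hits = best_hit_per_genome(hits)

    proteins: dict[str, int] = {}
    genomes: dict[str, int] = {}
    for hit in hits:
        proteins.setdefault(hit.query_id, len(proteins))
        genomes.setdefault(hit.subject_genome, len(genomes))

    scores = np.zeros((len(proteins), len(genomes)))
    for hit in hits:
        if params.qualifies(hit.bit_score, hit.e_value):
            scores[proteins[hit.query_id], genomes[hit.subject_genome]] = (
                hit.bit_score
            )

    keep = (scores > 0).sum(axis=1) >= params.min_genomes
    if not keep.any():
        raise NoProteinsRetainedError(
            f"no proteins retained: none qualified in >= {params.min_genomes} "
            f"genomes at bit score > {params.min_bitscore} and e-value < "
            f"{params.max_evalue}"
        )
    protein_ids = [p for p, flag in zip(proteins, keep) if flag]
    return ProfileMatrix(
        protein_ids=protein_ids,
        genome_ids=list(genomes),
        scores=scores[keep],
        params=params,
    )
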