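"""Whole-genome identity metrics: ANIb, tetranucleotide correlation, pairwise
identity and basic sequence statistics.

ANIb fragments the query genome into consecutive 1,020-bp windows, aligns
each fragment against the reference, and averages the percent identity of
fragments whose best alignment reaches at least 30% identity over at least
70% of the fragment length.  The fragment aligner here is edit-distance
based (edlib, semi-global so the fragment aligns in full against any
reference region); any aligner producing per-fragment best-hit records can
feed :func:`anib` instead.

The tetranucleotide signature (TETRA) is the 256-vector of z-scores of
observed 4-mer counts against a maximal-order Markov expectation
E(w1w2w3w4) = N(w1w2w3) * N(w2w3w4) / N(w2w3), counted on both strands;
two genomes are compared by the Pearson correlation of their z-vectors.
Counting is circular by default (bacterial chromosomes are circular), which
also makes the expectation exact on homopolymers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable

import edlib
import numpy as np
from Bio import Align
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Fragment",
    "FragmentSet",
    "FragmentAlignment",
    "TetraVector",
    "fragment_genome",
    "align_fragments",
    "anib",
    "anib_pair",
    "tetra_zscores",
    "tetra_correlation",
    "pairwise_identity",
    "genome_stats",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# ANIb
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    fragment_id: str
    start: int  # 0-based half-open
    end: int
    seq: str
    short: bool = False  # tail fragment below nominal size


@dataclass
class FragmentSet:
    source_id: str
    size: int
    fragments: list[Fragment]

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass(frozen=True)
class FragmentAlignment:
    """Best alignment of one fragment against a reference genome."""

    fragment_id: str
    identity_pct: float
    aligned_fraction: float


def fragment_genome(seq: str, size: int = 1020, source_id: str = "genome") -> FragmentSet:
    """Cut a genome into consecutive non-overlapping fixed-size windows.

    The final fragment is retained even when shorter than ``size`` and
    flagged.  Coordinates are 0-based half-open against the input sequence.
    """
    if size < 1:
        raise ValueError("fragment size must be >= 1")
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    fragments = []
    for idx, start in enumerate(range(0, len(seq), size)):
        end = min(start + size, len(seq))
        fragments.append(
            Fragment(
                fragment_id=f"{source_id}_frag{idx:05d}",
                start=start,
                end=end,
                seq=seq[start:end],
                short=(end - start) < size,
            )
        )
    return FragmentSet(source_id=source_id, size=size, fragments=fragments)


def align_fragments(
    fragments: FragmentSet, reference: str
) -> list[FragmentAlignment]:
    """Best semi-global alignment of each fragment against a reference.

    Each fragment is aligned in full (edit distance; gaps at the reference
    ends are free) against the reference and its reverse complement; the
    orientation with the smaller edit distance wins.  Identity is
    1 - distance / alignment length; the full fragment participates, so the
    aligned fraction is 1 by construction.
    """
    reference = reference.upper()
    rc = _revcomp(reference)
    out = []
    for frag in fragments.fragments:
        best = None
        for target in (reference, rc):
            res = edlib.align(frag.seq, target, mode="HW", task="distance")
            if best is None or res["editDistance"] < best:
                best = res["editDistance"]
        aln_len = len(frag.seq)  # edit path length >= fragment length
        identity = 100.0 * (1.0 - best / aln_len)
        out.append(
            FragmentAlignment(
                fragment_id=frag.fragment_id,
                identity_pct=max(identity, 0.0),
                aligned_fraction=1.0,
            )
        )
    return out


def anib(
    alignments: Iterable[FragmentAlignment],
    min_identity: float = 30.0,
    min_aln_fraction: float = 0.70,
) -> float:
    """One-directional ANIb: mean identity over qualifying fragments.

    A fragment qualifies when its best hit reaches ``min_identity`` percent
    identity over at least ``min_aln_fraction`` of its length; fragments
    without a qualifying hit are excluded from the mean.  Returns NaN when
    no fragment qualifies.
    """
    kept = [
        a.identity_pct
        for a in alignments
        if a.identity_pct >= min_identity
        and a.aligned_fraction >= min_aln_fraction
    ]
    if not kept:
        return float("nan")
    return float(np.mean(kept))


def anib_pair(
    seq_a: str,
    seq_b: str,
    size: int = 1020,
    min_identity: float = 30.0,
    min_aln_fraction: float = 0.70,
) -> dict[str, float]:
    """ANIb in both directions plus their mean for a genome pair."""
    ab = anib(
        align_fragments(fragment_genome(seq_a, size, "A"), seq_b),
        min_identity, min_aln_fraction,
    )
    ba = anib(
        align_fragments(fragment_genome(seq_b, size, "B"), seq_a),
        min_identity, min_aln_fraction,
    )
    return {"a_vs_b": ab, "b_vs_a": ba, "mean": (ab + ba) / 2.0}


# ---------------------------------------------------------------------------
# tetranucleotide signature
# ---------------------------------------------------------------------------

_WORDS = {
    k: ["".join(w) for w in product("ACGT", repeat=k)] for k in (2, 3, 4)
}
_INDEX = {k: {w: i for i, w in enumerate(ws)} for k, ws in _WORDS.items()}


@dataclass
class TetraVector:
    """256 tetranucleotide z-scores (both strands, Markov-model expectation)."""

    zscores: np.ndarray  # length 256, indexed like _WORDS[4]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.zscores = np.asarray(self.zscores, dtype=float)
        if self.zscores.shape != (256,):
            raise ValueError("tetranucleotide vector must have 256 entries")
        if not np.isfinite(self.zscores).all():
            raise ValueError("tetranucleotide z-scores must be finite")

    def __getitem__(self, word: str) -> float:
        return float(self.zscores[_INDEX[4][word]])


def _count_kmers(seq: str, k: int, circular: bool) -> np.ndarray:
    counts = np.zeros(len(_WORDS[k]))
    index = _INDEX[k]
    extended = seq + seq[: k - 1] if circular else seq
    for i in range(len(extended) - k + 1):
        word = extended[i:i + k]
        idx = index.get(word)
        if idx is not None:  # words containing ambiguous bases are skipped
            counts[idx] += 1
    return counts


def tetra_zscores(
    seq: str, source_id: str = "", circular: bool = True
) -> TetraVector:
    """Tetranucleotide z-scores against the maximal-order Markov model.

    Counts are pooled over the sequence and its reverse complement (words
    never span the junction).  The expectation for each 4-mer is
    N(prefix3) * N(suffix3) / N(core2) and z = (O - E) / sqrt(E), with
    z = 0 where E = 0.  With ``circular`` counting (default) every position
    contributes one word of each length, so homopolymers have O = E exactly.
    """
    seq = seq.upper()
    informative = sum(seq.count(b) for b in "ACGT")
    if informative == 0:
        raise ValueError("sequence has no unambiguous bases")
    if len(seq) < 4:
        raise ValueError("sequence too short for tetranucleotide counting")
    counts = {}
    for k in (2, 3, 4):
        counts[k] = _count_kmers(seq, k, circular) + _count_kmers(
            _revcomp(seq), k, circular
        )
    n2, n3, n4 = counts[2], counts[3], counts[4]
    z = np.zeros(256)
    i3, i2 = _INDEX[3], _INDEX[2]
    for i, word in enumerate(_WORDS[4]):
        core = n2[i2[word[1:3]]]
        if core == 0:
            continue
        expected = n3[i3[word[:3]]] * n3[i3[word[1:]]] / core
        if expected > 0:
            z[i] = (n4[i] - expected) / math.sqrt(expected)
    return TetraVector(zscores=z, source_id=source_id)


def tetra_correlation(vec_a: TetraVector, vec_b: TetraVector) -> float:
    """Pearson correlation of two tetranucleotide z-score vectors.

    Returns NaN when either vector has zero variance.
    """
    a, b = vec_a.zscores, vec_b.zscores
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# pairwise global identity
# ---------------------------------------------------------------------------

def pairwise_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Percent identity of a global alignment of two nucleotide sequences.

    Identity is matches over alignment columns (gap columns included) x 100
    under simple match/mismatch/gap scoring, and is symmetric in argument
    order.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


# ---------------------------------------------------------------------------
# genome statistics from annotated records
# ---------------------------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for start, end in sorted(intervals):
        if start > last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


def genome_stats(record: SeqRecord) -> dict[str, float | int]:
    """Summary statistics of an annotated genome record.

    Returns replicon length, G+C percent (of unambiguous bases, 2 decimals),
    CDS count, percent of the genome covered by the union of CDS spans, and
    rRNA/tRNA feature counts.
    """
    seq = str(record.seq).upper()
    if not seq:
        raise ValueError(f"record {record.id!r} has no sequence")
    base_counts = {b: seq.count(b) for b in "ACGT"}
    unambiguous = sum(base_counts.values())
    if unambiguous == 0:
        raise ValueError(f"record {record.id!r} has no unambiguous bases")
    gc = round(
        100.0 * (base_counts["G"] + base_counts["C"]) / unambiguous, 2
    )
    cds_spans: list[tuple[int, int]] = []
    n_cds = n_rrna = n_trna = 0
    for feature in record.features:
        if feature.type == "CDS":
            n_cds += 1
            for part in feature.location.parts:
                cds_spans.append((int(part.start), int(part.end)))
        elif feature.type == "rRNA":
            n_rrna += 1
        elif feature.type == "tRNA":
            n_trna += 1
    return {
        "length_bp": len(seq),
        "gc_percent": gc,
        "n_cds": n_cds,
        "percent_coding": 100.0 * _union_length(cds_spans) / len(seq),
        "n_rrna": n_rrna,
        "n_trna": n_trna,
    }
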