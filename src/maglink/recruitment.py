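"""Read recruitment: per-MAG read fractions and major-member filtering.

Reads are competitively assigned to the genome sharing the most
canonical k-mers (default k = 21); ties and zero-hit reads are left
unassigned and excluded from the denominator.  A contig-length filter
(> 1,000 bp, strict) and a major-member rule (recruiting strictly more
than 1% of assigned reads) mirror common MAG-profiling practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._alignment import canonical_kmer_codes_2d, encode
from .errors import DegenerateInputError, InvalidParameterError
from .synthetic import Genome, ReadSet

DEFAULT_MIN_CONTIG_LENGTH = 1000
DEFAULT_MAJOR_THRESHOLD = 0.01
DEFAULT_K = 21


@dataclass
class Contig:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def filter_contigs(contigs: list[Contig], min_length: int = DEFAULT_MIN_CONTIG_LENGTH) -> list[Contig]:
    """Keep contigs strictly longer than min_length, preserving order."""
    if min_length < 0:
        raise InvalidParameterError(f"min_length must be >= 0, got {min_length}")
    return [c for c in contigs if c.length > min_length]


def pseudo_map(reads: ReadSet, genomes: list[Genome], k: int = DEFAULT_K,
               chunk_size: int = 50_000) -> tuple[dict[str, int], int]:
    """Competitively assign reads to genomes by shared canonical k-mers.

    Each read goes to the genome sharing the most exact length-k
    substrings with it (either strand, via canonical k-mers).  Reads
    tying for the maximum, or sharing no k-mer with any genome, are
    counted as unassigned.

    Returns (per-genome assigned counts, number of unassigned reads).
    """
    if not genomes:
        raise InvalidParameterError("genome list is empty")
    if k < 11:
        raise InvalidParameterError(f"k must be >= 11, got {k}")
    if reads.read_length < k:
        raise InvalidParameterError(
            f"read length {reads.read_length} shorter than k = {k}")
    genome_kmers = [np.unique(canonical_kmer_codes_2d(encode(g.sequence)[None, :], k).ravel())
                    for g in genomes]
    counts = {g.id: 0 for g in genomes}
    unassigned = 0
    n_per_read = reads.read_length - k + 1

    for start in range(0, len(reads.reads), chunk_size):
        chunk = reads.reads[start:start + chunk_size]
        # bulk-encode the chunk: one (n_reads, read_length) code matrix
        flat = "".join(seq for _rid, seq, _o in chunk)
        codes = encode(flat).reshape(len(chunk), reads.read_length)
        flat_kmers = canonical_kmer_codes_2d(codes, k).ravel()
        uniq, inverse = np.unique(flat_kmers, return_inverse=True)
        hits = np.empty((len(chunk), len(genomes)), dtype=np.int64)
        for gi, gk in enumerate(genome_kmers):
            idx = np.searchsorted(gk, uniq)
            idx[idx == len(gk)] = 0
            member_uniq = gk[idx] == uniq
            hits[:, gi] = member_uniq[inverse].reshape(len(chunk), n_per_read).sum(axis=1)
        best = hits.max(axis=1)
        is_tie = (hits == best[:, None]).sum(axis=1) > 1
        assigned = (best > 0) & ~is_tie
        unassigned += int((~assigned).sum())
        winner_counts = np.bincount(hits.argmax(axis=1)[assigned],
                                    minlength=len(genomes))
        for gi, g in enumerate(genomes):
            counts[g.id] += int(winner_counts[gi])
    return counts, unassigned


def recruitment_fractions(counts: dict[str, int]) -> dict[str, float]:
    """Normalise assigned counts to fractions of the assigned total."""
    if any(c < 0 for c in counts.values()):
        raise InvalidParameterError("counts must be nonnegative")
    total = sum(counts.values())
    if total <= 0:
        raise DegenerateInputError("all counts are zero; no reads were assigned")
    return {gid: c / total for gid, c in counts.items()}


def major_members(fractions: dict[str, float],
                  threshold: float = DEFAULT_MAJOR_THRESHOLD) -> set[str]:
    """MAGs recruiting strictly more than the threshold fraction of
    reads (default 1%); a MAG at exactly the threshold is excluded."""
    return {gid for gid, f in fractions.items() if f > threshold}
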