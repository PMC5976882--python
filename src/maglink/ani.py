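"""Average nucleotide identity and discrete-population clustering.

ANI is computed with the classical fragment scheme: the query genome is
cut into consecutive non-overlapping 1,020-bp fragments, each fragment
is locally aligned to the reference (shared-15-mer seeding, banded
affine extension), and fragments aligning at >= 30% identity over
>= 70% of their length are retained.  ANI(query -> reference) is the
mean identity of retained fragments; the aligned fraction is the share
of fragments retained.  Pairwise ANI is the mean of the two directed
values.

Genomes are grouped into discrete sequence populations by
single-linkage clustering at a 97% identity cutoff: populations are
the connected components of the graph with an edge wherever
ANI >= 97%.  Genomes from different environments are called distinct
when their best cross-environment ANI is below 90%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._alignment import ReferenceIndex, align_fragment, encode, revcomp_codes
from .errors import InvalidParameterError
from .synthetic import Genome

log = logging.getLogger(__name__)

DEFAULT_FRAGMENT_LENGTH = 1020
DEFAULT_MIN_IDENTITY = 0.30
DEFAULT_MIN_COVERAGE = 0.70
DEFAULT_POPULATION_THRESHOLD = 97.0
DEFAULT_DISTINCT_THRESHOLD = 90.0
SEED_K = 15
BAND = 32


@dataclass
class ANIMatrix:
    """Symmetric pairwise percent-identity matrix; NaN marks pairs with
    no retained fragments (undefined ANI)."""

    ids: list[str]
    values: np.ndarray           # percent identity in [0, 100], NaN undefined
    aligned_fraction: np.ndarray  # in [0, 1]; 0 where undefined

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        self.aligned_fraction = np.asarray(self.aligned_fraction, dtype=float)
        if self.values.shape != (n, n) or self.aligned_fraction.shape != (n, n):
            raise InvalidParameterError("ANI matrices must be n x n")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass
class PopulationClustering:
    threshold: float
    #: genome id -> population id (the lexicographically smallest member id)
    assignment: dict[str, str]

    def populations(self) -> dict[str, set[str]]:
        pops: dict[str, set[str]] = {}
        for gid, pid in self.assignment.items():
            pops.setdefault(pid, set()).add(gid)
        return pops


class _IndexedGenome:
    """Per-genome alignment indexes, built once and reused."""

    def __init__(self, genome: Genome, k: int = SEED_K):
        self.genome = genome
        self.codes = encode(genome.sequence)
        self.fwd = ReferenceIndex(self.codes, k)
        self.rc = ReferenceIndex(revcomp_codes(self.codes), k)


def fragment_ani(query: Genome, reference: Genome, *,
                 fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
                 min_identity: float = DEFAULT_MIN_IDENTITY,
                 min_coverage: float = DEFAULT_MIN_COVERAGE,
                 _ref_index: _IndexedGenome | None = None) -> tuple[float | None, float]:
    """Directed fragment ANI(query -> reference).

    Returns (percent identity, aligned fraction); identity is None when
    no fragment is retained.
    """
    if len(query) < fragment_length or len(reference) < fragment_length:
        raise InvalidParameterError(
            f"both sequences must be >= fragment_length ({fragment_length} bp); "
            f"got {len(query)} and {len(reference)}")
    ref = _ref_index if _ref_index is not None else _IndexedGenome(reference)
    q_codes = encode(query.sequence)
    n_fragments = len(q_codes) // fragment_length
    identities = []
    for f in range(n_fragments):
        frag = q_codes[f * fragment_length:(f + 1) * fragment_length]
        hit = align_fragment(frag, ref.fwd, ref.rc, band=BAND)
        if hit is None:
            continue
        _score, matches, columns, qspan = hit
        identity = matches / columns
        coverage = qspan / fragment_length
        if identity >= min_identity and coverage >= min_coverage:
            identities.append(identity)
    if not identities:
        return None, 0.0
    return 100.0 * float(np.mean(identities)), len(identities) / n_fragments


def ani_matrix(genomes: list[Genome], **kwargs) -> ANIMatrix:
    """Symmetrised pairwise ANI over a genome list.

    Entry (i, j) is the mean of the two directed estimates when both
    are defined, the defined one when only one is, and NaN otherwise.
    """
    if not genomes:
        raise InvalidParameterError("genome list is empty")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise InvalidParameterError("duplicate genome ids")
    n = len(genomes)
    values = np.full((n, n), np.nan)
    frac = np.zeros((n, n))
    np.fill_diagonal(values, 100.0)
    np.fill_diagonal(frac, 1.0)
    indexes = [_IndexedGenome(g) for g in genomes]
    for i in range(n):
        for j in range(i + 1, n):
            a_ij, f_ij = fragment_ani(genomes[i], genomes[j],
                                      _ref_index=indexes[j], **kwargs)
            a_ji, f_ji = fragment_ani(genomes[j], genomes[i],
                                      _ref_index=indexes[i], **kwargs)
            defined = [a for a in (a_ij, a_ji) if a is not None]
            if defined:
                values[i, j] = values[j, i] = float(np.mean(defined))
            frac[i, j] = frac[j, i] = float(np.mean([f_ij, f_ji]))
    return ANIMatrix(ids=ids, values=values, aligned_fraction=frac)


def cluster_populations(matrix: ANIMatrix,
                        threshold: float = DEFAULT_POPULATION_THRESHOLD,
                        inclusive: bool = True) -> PopulationClustering:
    """Single-linkage partition: connected components of the
    ANI >= threshold graph.  Undefined (NaN) ANI never links.  The
    population id is the lexicographically smallest member id.

    ``inclusive`` controls whether a pair exactly at the threshold is
    linked (>=, the default) or not (>); the two conventions disagree
    only on pairs at exactly the cutoff.
    """
    if not inclusive:
        log.warning("clustering with strict > %s threshold; pairs exactly at the "
                    "cutoff will not be linked", threshold)
    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            v = matrix.values[i, j]
            if np.isfinite(v) and (v >= threshold if inclusive else v > threshold):
                g.add_edge(matrix.ids[i], matrix.ids[j])
    assignment: dict[str, str] = {}
    for comp in nx.connected_components(g):
        pid = min(comp)
        for gid in comp:
            assignment[gid] = pid
    return PopulationClustering(threshold=threshold, assignment=assignment)


def cross_match(culture_genomes: list[Genome], environment_genomes: list[Genome],
                distinct_below: float = DEFAULT_DISTINCT_THRESHOLD,
                match_threshold: float = DEFAULT_POPULATION_THRESHOLD,
                **kwargs) -> dict[str, tuple[str | None, float | None, str]]:
    """Best-hit ANI of each culture genome against an environment set.

    Status per culture genome: ``distinct`` when the best ANI is below
    ``distinct_below`` (or undefined everywhere), ``matched`` when it
    reaches the population threshold, ``ambiguous`` in between.
    """
    if not culture_genomes or not environment_genomes:
        raise InvalidParameterError("both genome lists must be nonempty")
    env_indexes = [_IndexedGenome(g) for g in environment_genomes]
    out: dict[str, tuple[str | None, float | None, str]] = {}
    for cg in culture_genomes:
        best_id: str | None = None
        best_ani: float | None = None
        for eg, idx in zip(environment_genomes, env_indexes):
            a_ce, _ = fragment_ani(cg, eg, _ref_index=idx, **kwargs)
            a_ec, _ = fragment_ani(eg, cg, **kwargs)
            defined = [a for a in (a_ce, a_ec) if a is not None]
            if not defined:
                continue
            ani = float(np.mean(defined))
            if best_ani is None or ani > best_ani:
                best_ani, best_id = ani, eg.id
        if best_ani is None or best_ani < distinct_below:
            status = "distinct"
        elif best_ani >= match_threshold:
            status = "matched"
        else:
            status = "ambiguous"
        out[cg.id] = (best_id, best_ani, status)
    return out
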