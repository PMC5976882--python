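"""Synthetic MAG communities with known ground truth.

Everything downstream of assembly/binning in the analysis chain —
recruitment fractions, ANI population clustering, auxotrophy calls,
complementarity graphs, cooccurrence correlation — is exercised here on
simulated communities whose population structure, composition, pathway
presence/absence and correlation blocks are planted and therefore
exactly known.

Divergence is substitution-only: a mutant differs from its parent at
exactly round(d * L) positions, so the true nucleotide identity of a
parent/mutant pair is 100 * (1 - d) analytically, with no sampling
noise.  All randomness flows through one explicit integer seed per
operation; derived seeds are spawned with numpy's SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._alignment import decode, encode
from .errors import InvalidParameterError
from .pathways import PathwayDefinition
from .tables import AbundanceTable


@dataclass
class Genome:
    """A genome (or MAG): an id, a nucleotide sequence and an optional
    gene-family inventory."""

    id: str
    sequence: str
    gene_families: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise InvalidParameterError(f"genome {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CommunitySpec:
    """A simulated community plus its planted ground truth."""

    genomes: list[Genome]
    true_population: dict[str, str]
    true_proportions: dict[str, float]
    #: (genome id, metabolite) -> True when the genome is planted auxotrophic
    auxotrophy_truth: dict[tuple[str, str], bool]

    def __post_init__(self) -> None:
        ids = [g.id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError("duplicate genome ids in community")
        total = sum(self.true_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(f"proportions sum to {total}, not 1")
        for gid in ids:
            if gid not in self.true_population:
                raise InvalidParameterError(f"genome {gid!r} has no population id")

    def genome(self, gid: str) -> Genome:
        for g in self.genomes:
            if g.id == gid:
                return g
        raise KeyError(gid)


@dataclass
class ReadSet:
    """Simulated shotgun reads; each read remembers its origin genome."""

    reads: list[tuple[str, str, str]]  # (read id, sequence, origin genome id)
    read_length: int

    def __post_init__(self) -> None:
        for rid, seq, _origin in self.reads:
            if len(seq) != self.read_length:
                raise InvalidParameterError(
                    f"read {rid!r} has length {len(seq)}, expected {self.read_length}")


def simulate_genome(length: int, gc: float, seed: int, id: str = "genome") -> Genome:
    """Draw an i.i.d. random genome with the given GC content.

    P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2.
    """
    if length < 1:
        raise InvalidParameterError(f"genome length must be >= 1, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise InvalidParameterError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return Genome(id=id, sequence=decode(codes))


def mutate_genome(parent: Genome, divergence: float, seed: int,
                  id: str | None = None) -> Genome:
    """Substitute exactly round(divergence * L) positions of the parent.

    Positions are chosen without replacement; each receives a uniformly
    random *different* base.  No indels, so the Hamming distance to the
    parent is exactly round(divergence * L).
    """
    if not 0.0 <= divergence < 1.0:
        raise InvalidParameterError(f"divergence must be in [0, 1), got {divergence}")
    rng = np.random.default_rng(seed)
    codes = encode(parent.sequence).copy()
    n_mut = round(divergence * len(codes))
    if n_mut > 0:
        pos = rng.choice(len(codes), size=n_mut, replace=False)
        shift = rng.integers(1, 4, size=n_mut).astype(np.uint8)
        codes[pos] = (codes[pos] + shift) % 4
    return Genome(id=id if id is not None else f"{parent.id}_mut",
                  sequence=decode(codes),
                  gene_families=set(parent.gene_families))


def _plant_gene_families(population: str, panel: list[PathwayDefinition],
                         pathway_truth: dict[tuple[str, str], bool],
                         rng: np.random.Generator,
                         n_core_families: int = 40) -> tuple[set[str], dict[str, bool]]:
    """Gene families for one genome: a shared background plus, per panel
    pathway, either the full gene set (planted prototroph) or the set
    with one randomly chosen step knocked out (planted auxotroph)."""
    fams = {f"fam_core_{i:03d}" for i in range(n_core_families)}
    auxo: dict[str, bool] = {}
    for pw in panel:
        key = (population, pw.metabolite)
        present = pathway_truth.get(key, True)
        auxo[pw.metabolite] = not present
        if present:
            for step in pw.steps:
                fams |= set(step)
        else:
            knocked = rng.integers(0, len(pw.steps))
            for i, step in enumerate(pw.steps):
                if i != int(knocked):
                    fams |= set(step)
    return fams, auxo


def simulate_community(n_populations: int, members_per_population: int,
                       within_divergence: float, between_divergence: float,
                       pathway_truth: dict[tuple[str, str], bool],
                       seed: int, *, genome_length: int = 20_000, gc: float = 0.5,
                       panel: list[PathwayDefinition] | None = None,
                       proportions: dict[str, float] | None = None) -> CommunitySpec:
    """Simulate a mixed-culture-like community with nested ANI structure.

    Each population descends from its own ancestor; population ancestors
    are mutants of a shared root at ``between_divergence`` and members
    are mutants of their ancestor at ``within_divergence``.  With the
    default 97%-identity population cutoff in mind, within-population
    pairs stay well above the cutoff and between-population pairs well
    below it whenever between_divergence exceeds within_divergence by a
    comfortable margin.

    ``pathway_truth`` maps (population id, metabolite) to presence; the
    planted per-genome auxotrophies are recorded in the returned spec.
    ``proportions`` (genome id -> fraction) defaults to a symmetric
    Dirichlet draw.
    """
    if n_populations < 1 or members_per_population < 1:
        raise InvalidParameterError("need at least one population and one member")
    if not between_divergence > within_divergence:
        raise InvalidParameterError(
            f"between_divergence ({between_divergence}) must exceed "
            f"within_divergence ({within_divergence})")
    ss = np.random.SeedSequence(seed)
    root_seed, *rest = ss.spawn(2 + 2 * n_populations * (1 + members_per_population))
    root = simulate_genome(genome_length, gc, _as_seed(root_seed), id="root")

    genomes: list[Genome] = []
    true_population: dict[str, str] = {}
    auxotrophy_truth: dict[tuple[str, str], bool] = {}
    if panel is None:
        from .pathways import default_panel
        panel = default_panel()

    seed_iter = iter(rest)
    for p in range(n_populations):
        pop_id = f"pop{p + 1}"
        ancestor = mutate_genome(root, between_divergence, _as_seed(next(seed_iter)),
                                 id=f"{pop_id}_ancestor")
        fam_rng = np.random.default_rng(_as_seed(next(seed_iter)))
        for m in range(members_per_population):
            gid = f"P{p + 1}M{m + 1}"
            g = mutate_genome(ancestor, within_divergence,
                              _as_seed(next(seed_iter)), id=gid)
            fams, auxo = _plant_gene_families(pop_id, panel, pathway_truth, fam_rng)
            g.gene_families = fams
            genomes.append(g)
            true_population[gid] = pop_id
            for metabolite, is_auxo in auxo.items():
                auxotrophy_truth[(gid, metabolite)] = is_auxo

    if proportions is None:
        prop_rng = np.random.default_rng(_as_seed(next(seed_iter)))
        draw = prop_rng.dirichlet(np.ones(len(genomes)))
        draw = draw / draw.sum()
        proportions = {g.id: float(x) for g, x in zip(genomes, draw)}
    return CommunitySpec(genomes=genomes, true_population=true_population,
                         true_proportions=proportions,
                         auxotrophy_truth=auxotrophy_truth)


def simulate_reads(community: CommunitySpec, n_reads: int, read_length: int,
                   error_rate: float, seed: int) -> ReadSet:
    """Shotgun reads at the community's planted proportions.

    Per-genome read counts are multinomial in ``true_proportions``;
    start positions are uniform; each base is substituted with a
    different base with probability ``error_rate``.
    """
    if n_reads < 1:
        raise InvalidParameterError("n_reads must be >= 1")
    if not 0.0 <= error_rate < 1.0:
        raise InvalidParameterError(f"error_rate must be in [0, 1), got {error_rate}")
    shortest = min(len(g) for g in community.genomes)
    if read_length > shortest:
        raise InvalidParameterError(
            f"read_length {read_length} exceeds shortest genome length {shortest}")
    rng = np.random.default_rng(seed)
    gids = [g.id for g in community.genomes]
    probs = np.array([community.true_proportions[g] for g in gids], dtype=float)
    counts = rng.multinomial(n_reads, probs / probs.sum())

    reads: list[tuple[str, str, str]] = []
    idx = 0
    for gid, c in zip(gids, counts):
        if c == 0:
            continue
        codes = encode(community.genome(gid).sequence)
        starts = rng.integers(0, len(codes) - read_length + 1, size=c)
        for s in starts:
            r = codes[s:s + read_length].copy()
            err = rng.random(read_length) < error_rate
            n_err = int(err.sum())
            if n_err:
                r[err] = (r[err] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
            reads.append((f"read_{idx:06d}", decode(r), gid))
            idx += 1
    return ReadSet(reads=reads, read_length=read_length)


def simulate_time_series(n_focal: int, n_environment: int, n_samples: int,
                         block_assignments: dict[str, str], block_rho: float,
                         seed: int, *, log_sigma: float = 1.0,
                         background_factor: float = 9.0,
                         start_date: str = "2007-05-01",
                         period_days: int = 7) -> AbundanceTable:
    """Relative-abundance time series with planted correlation blocks.

    Latent Gaussian vectors are equicorrelated at ``block_rho`` within a
    block and independent across blocks (Gaussian copula); marginals are
    log-normal; each sample row is closed to relative abundances.

    Closing a composition divides every taxon by the same sample sum,
    which would distort ranks if the simulated taxa dominated the
    community.  As in real lake metagenomes — where binned MAGs recruit
    only a minor share of the reads — the community carries a large
    constant unbinned remainder (``background_factor`` times the
    expected summed biomass of the simulated taxa, reported in the
    ``unbinned`` column).  The closure divisor is then nearly constant,
    so the monotone log-normal transform preserves the planted rank
    (Spearman) correlations to close approximation.

    Taxon ids are ``culture_XX`` for the focal set and ``ts_XX`` for
    the environment set; every id must appear in ``block_assignments``
    (taxon id -> block label).
    """
    if n_samples < 3:
        raise InvalidParameterError(f"n_samples must be >= 3, got {n_samples}")
    if not -1.0 < block_rho < 1.0:
        raise InvalidParameterError(f"block_rho must be in (-1, 1), got {block_rho}")
    taxa = [f"culture_{i:02d}" for i in range(1, n_focal + 1)] + \
           [f"ts_{i:02d}" for i in range(1, n_environment + 1)]
    missing = [t for t in taxa if t not in block_assignments]
    if missing:
        raise InvalidParameterError(f"taxa without block assignment: {missing[:5]}")

    rng = np.random.default_rng(seed)
    z = np.empty((n_samples, len(taxa)))
    blocks: dict[str, list[int]] = {}
    for i, t in enumerate(taxa):
        blocks.setdefault(block_assignments[t], []).append(i)
    for members in blocks.values():
        k = len(members)
        if k == 1:
            z[:, members[0]] = rng.standard_normal(n_samples)
            continue
        if 1.0 + (k - 1) * block_rho <= 0:
            raise InvalidParameterError(
                f"block_rho {block_rho} not positive-definite for block of size {k}")
        cov = np.full((k, k), block_rho)
        np.fill_diagonal(cov, 1.0)
        z[:, members] = rng.multivariate_normal(np.zeros(k), cov, size=n_samples,
                                                method="cholesky")
    mu = rng.normal(0.0, 1.0, size=len(taxa))
    biomass = np.exp(mu + log_sigma * z)
    expected_total = float(np.exp(mu + log_sigma**2 / 2).sum())
    background = background_factor * expected_total
    abundance = np.hstack([biomass, np.full((n_samples, 1), background)])
    abundance /= abundance.sum(axis=1, keepdims=True)

    dates = np.datetime64(start_date) + period_days * np.arange(n_samples)
    sample_ids = [str(d) for d in dates]
    return AbundanceTable(sample_ids=sample_ids, taxon_ids=taxa + ["unbinned"],
                          values=abundance, kind="fractions")


def _as_seed(ss: np.random.SeedSequence) -> int:
    """Collapse a SeedSequence into a plain int seed (< 2**31) so every
    operation can be called with an explicit recordable integer."""
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
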