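"""Core/flexible pangenome partitioning.

Given a genomes x gene-families presence matrix, the core genome is the
set of families present in at least a given fraction of genomes
(default 1.0: the strict core, families shared by every genome).  The
flexible-genome share is then 100 * (1 - core_size / mean_genome_size):
the share of an average genome's gene content that is accessory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError


@dataclass
class GeneFamilyMatrix:
    """Boolean genomes x gene-families presence matrix."""

    presence: pd.DataFrame  # index = genome ids, columns = family ids, dtype bool

    def __post_init__(self) -> None:
        self.presence = self.presence.astype(bool)
        if self.presence.shape[0] == 0 or self.presence.shape[1] == 0:
            raise InvalidParameterError("presence matrix is empty")
        empty = self.presence.sum(axis=1) == 0
        if empty.any():
            gid = self.presence.index[empty][0]
            raise InvalidParameterError(f"genome {gid!r} has no gene families")

    @classmethod
    def from_annotations(cls, annotations: dict[str, set[str]]) -> "GeneFamilyMatrix":
        """Build from genome id -> gene-family set."""
        if not annotations:
            raise InvalidParameterError("no annotations given")
        families = sorted(set().union(*annotations.values()))
        genomes = sorted(annotations)
        data = [[f in annotations[g] for f in families] for g in genomes]
        return cls(pd.DataFrame(data, index=genomes, columns=families, dtype=bool))

    @property
    def genome_ids(self) -> list[str]:
        return list(self.presence.index)

    def mean_genome_size(self) -> float:
        """Arithmetic mean number of families per genome."""
        return float(self.presence.sum(axis=1).mean())


def core_genome(matrix: GeneFamilyMatrix, core_fraction: float = 1.0) -> set[str]:
    """Families present in >= core_fraction of genomes (default: all)."""
    if not 0.0 < core_fraction <= 1.0:
        raise InvalidParameterError(f"core_fraction must be in (0, 1], got {core_fraction}")
    share = matrix.presence.mean(axis=0)
    return set(share.index[share >= core_fraction])


def flexible_fraction(core_size: float, mean_genome_size: float) -> float:
    """Percent of the average genome outside the core.

    For a core of ~800 families and ~1,600 families per genome this is
    50%: about half the genome is flexible.
    """
    if core_size <= 0:
        raise InvalidParameterError(f"core_size must be positive, got {core_size}")
    if core_size > mean_genome_size:
        raise InvalidParameterError(
            f"core_size ({core_size}) exceeds mean genome size ({mean_genome_size})")
    return 100.0 * (1.0 - core_size / mean_genome_size)


def pangenome_summary(matrix: GeneFamilyMatrix,
                      core_fraction: float = 1.0) -> dict[str, float]:
    core = core_genome(matrix, core_fraction)
    mean_size = matrix.mean_genome_size()
    return {
        "n_genomes": float(len(matrix.genome_ids)),
        "n_families": float(matrix.presence.shape[1]),
        "core_size": float(len(core)),
        "mean_genome_size": mean_size,
        "flexible_percent": flexible_fraction(len(core), mean_size) if core else float("nan"),
    }
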