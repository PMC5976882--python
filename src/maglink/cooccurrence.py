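"""Culture-versus-environment cooccurrence correlation.

Spearman rank correlation between the relative abundances of focal
(culture) MAGs and candidate partner (time-series) MAGs over a shared
set of dated samples.  Significance is assessed by a permutation test
(permuting the sample order of the focal vectors, two-sided, add-one
corrected) with Benjamini-Hochberg adjustment over the whole matrix.
The significance machinery is an artifact policy layered on top of the
correlation itself: the defaults (|rho| >= 0.5, q <= 0.05, 999
permutations) are configurable, not facts about any dataset.

Rows and columns of the correlation matrix can be ordered by
agglomerative hierarchical clustering (average linkage) for block
display; a promiscuity summary then counts, per focal MAG, how many
significant positive partners it has and how many distinct taxonomy
groups they span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError
from .tables import AbundanceTable

log = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 999
DEFAULT_RHO_MIN = 0.5
DEFAULT_Q_MAX = 0.05


@dataclass
class CorrelationResult:
    focal_ids: list[str]
    partner_ids: list[str]
    rho: pd.DataFrame  # focal x partner, NaN where undefined
    p: pd.DataFrame
    q: pd.DataFrame | None = None
    row_order: list[str] | None = None
    col_order: list[str] | None = None

    def reordered(self) -> "CorrelationResult":
        """Apply the stored hierarchical ordering to all matrices."""
        rows = self.row_order or self.focal_ids
        cols = self.col_order or self.partner_ids
        return CorrelationResult(
            focal_ids=rows, partner_ids=cols,
            rho=self.rho.loc[rows, cols], p=self.p.loc[rows, cols],
            q=None if self.q is None else self.q.loc[rows, cols],
            row_order=rows, col_order=cols)


@dataclass
class PromiscuitySummary:
    #: focal id -> (n significant positive partners, n distinct partner groups,
    #:             sorted partner id list, promiscuous flag)
    records: dict[str, tuple[int, int, list[str], bool]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"focal_id": fid, "n_partners": n, "n_groups": g,
                 "promiscuous": flag, "partners": ",".join(partners)}
                for fid, (n, g, partners, flag) in sorted(self.records.items())]
        return pd.DataFrame(rows, columns=["focal_id", "n_partners", "n_groups",
                                           "promiscuous", "partners"])


def normalize_abundance(counts: AbundanceTable,
                        genome_lengths: dict[str, int]) -> AbundanceTable:
    """Genome-length-normalised relative abundances.

    Counts are divided by genome length (longer genomes recruit more
    reads at equal cell abundance), then each sample row is closed to
    sum 1.  Samples with all-zero counts are dropped with a warning.
    """
    lengths = np.array([genome_lengths.get(t, 0) for t in counts.taxon_ids], dtype=float)
    missing = [t for t, L in zip(counts.taxon_ids, lengths) if L <= 0]
    if missing:
        raise InvalidParameterError(f"missing or nonpositive genome length for {missing[:5]}")
    weighted = counts.values / lengths
    rowsum = weighted.sum(axis=1)
    keep = rowsum > 0
    if not keep.all():
        dropped = [s for s, k in zip(counts.sample_ids, keep) if not k]
        log.warning("dropping %d all-zero sample(s): %s", len(dropped), dropped[:5])
    weighted = weighted[keep] / rowsum[keep][:, None]
    return AbundanceTable(sample_ids=[s for s, k in zip(counts.sample_ids, keep) if k],
                          taxon_ids=list(counts.taxon_ids), values=weighted,
                          kind="fractions")


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    _rej, q, _a, _b = multipletests(np.asarray(p_values, dtype=float),
                                    method="fdr_bh")
    return q


def _rank_standardise(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-rank each column and z-standardise; returns (Z, constant
    mask).  Pearson on these columns equals Spearman with average ranks."""
    n, m = values.shape
    ranks = np.empty_like(values, dtype=float)
    for j in range(m):
        ranks[:, j] = rankdata(values[:, j], method="average")
    constant = ranks.std(axis=0) == 0
    z = ranks - ranks.mean(axis=0)
    sd = ranks.std(axis=0)
    sd[constant] = 1.0
    z /= sd * np.sqrt(n)
    z[:, constant] = 0.0
    return z, constant


def spearman_matrix(focal: AbundanceTable, partners: AbundanceTable,
                    n_permutations: int = DEFAULT_N_PERMUTATIONS,
                    seed: int = 0) -> CorrelationResult:
    """All-pairs Spearman rho between focal and partner taxa with
    permutation p-values and BH q-values.

    Both tables must carry an identical, identically ordered sample
    set.  Constant vectors yield NaN rho/p (rank correlation is
    undefined) and are excluded from the BH adjustment.
    """
    if focal.sample_ids != partners.sample_ids:
        raise InvalidParameterError(
            "focal and partner tables must share an identical ordered sample set")
    n = len(focal.sample_ids)
    if n < 3:
        raise InvalidParameterError(f"need >= 3 shared samples, got {n}")
    if n_permutations < 99:
        raise InvalidParameterError(f"n_permutations must be >= 99, got {n_permutations}")

    zf, const_f = _rank_standardise(focal.values)
    zp, const_p = _rank_standardise(partners.values)
    rho = zf.T @ zp  # (F x P); z-columns are unit-norm so this is Pearson on ranks
    np.clip(rho, -1.0, 1.0, out=rho)
    undefined = const_f[:, None] | const_p[None, :]
    rho[undefined] = np.nan

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(rho, dtype=np.int64)
    abs_obs = np.abs(rho)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        null = zf[perm].T @ zp
        exceed += np.abs(null) >= abs_obs - 1e-12
    p = (exceed + 1) / (n_permutations + 1)
    p[undefined] = np.nan

    q = np.full_like(p, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        q[finite] = bh_adjust(p[finite])

    mk = lambda m: pd.DataFrame(m, index=focal.taxon_ids, columns=partners.taxon_ids)
    return CorrelationResult(focal_ids=list(focal.taxon_ids),
                             partner_ids=list(partners.taxon_ids),
                             rho=mk(rho), p=mk(p), q=mk(q))


def _hclust_order(dist_matrix: pd.DataFrame) -> list[str]:
    """Average-linkage leaf order over rows of a distance-feature
    matrix; ids are sorted first so the result is invariant to the
    caller's row order."""
    ids = sorted(dist_matrix.index)
    if len(ids) < 3:
        return ids
    feats = dist_matrix.loc[ids].to_numpy()
    linkage = average(pdist(feats))
    return [ids[i] for i in leaves_list(linkage)]


def order_by_hclust(result: CorrelationResult) -> CorrelationResult:
    """Order rows and columns independently by hierarchical clustering
    of the correlation structure (distance 1 - rho, missing entries at
    distance 2, i.e. rho = -1)."""
    dist = 1.0 - result.rho.fillna(-1.0)
    row_order = _hclust_order(dist)
    col_order = _hclust_order(dist.T)
    return CorrelationResult(focal_ids=result.focal_ids,
                             partner_ids=result.partner_ids,
                             rho=result.rho, p=result.p, q=result.q,
                             row_order=row_order, col_order=col_order)


def significant_partners(result: CorrelationResult,
                         rho_min: float = DEFAULT_RHO_MIN,
                         q_max: float = DEFAULT_Q_MAX,
                         sign: str = "positive") -> dict[str, set[str]]:
    """Per focal MAG, the partner MAGs with sign-matching rho of
    magnitude >= rho_min and q <= q_max."""
    if result.q is None:
        raise InvalidParameterError("result has no q matrix; run spearman_matrix first")
    if sign not in ("positive", "negative"):
        raise InvalidParameterError(f"sign must be 'positive' or 'negative', got {sign!r}")
    out: dict[str, set[str]] = {f: set() for f in result.focal_ids}
    for f in result.focal_ids:
        for p_id in result.partner_ids:
            r = result.rho.at[f, p_id]
            q = result.q.at[f, p_id]
            if not (np.isfinite(r) and np.isfinite(q)):
                continue
            if sign == "positive" and r < 0:
                continue
            if sign == "negative" and r > 0:
                continue
            if abs(r) >= rho_min and q <= q_max:
                out[f].add(p_id)
    return out


def promiscuity_summary(partners: dict[str, set[str]],
                        taxonomy: dict[str, str]) -> PromiscuitySummary:
    """Count partners and distinct partner taxonomy groups per focal
    MAG.  A focal MAG is promiscuous when its partners span >= 2
    distinct groups and at least one differs from its own group."""
    records: dict[str, tuple[int, int, list[str], bool]] = {}
    for fid, pset in partners.items():
        missing = [p for p in pset if p not in taxonomy]
        if missing:
            raise InvalidParameterError(f"missing taxonomy for partner(s) {missing[:5]}")
        if fid not in taxonomy:
            raise InvalidParameterError(f"missing taxonomy for focal {fid!r}")
        groups = {taxonomy[p] for p in pset}
        promiscuous = len(groups) >= 2 and any(g != taxonomy[fid] for g in groups)
        records[fid] = (len(pset), len(groups), sorted(pset), promiscuous)
    return PromiscuitySummary(records=records)
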