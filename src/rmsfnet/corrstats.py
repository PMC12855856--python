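"""Statistics on per-residue RMSF magnitudes.

The coupling statistic is the Spearman rank correlation rho_s of two residues'
RMSF vectors across all trajectories (conditions pooled).  Each rho_s is
converted to

    t = rho_s * sqrt((n - 2) / (1 - rho_s^2)),

where n is the number of trajectories, and assessed two-tailed against a
permutation null built once from pseudo-randomly paired resamples of two
sequential integer arrays 1..n (rank correlation depends only on ranks, so
sequential integers are fully general for tie-free data).  Raw p-values over
the upper triangle are Benjamini-Hochberg adjusted to control FDR, and a
coupling is flagged significant when p_adj < alpha and |rho_s| >= rho_min.

Also here: the exact paired Wilcoxon signed-rank test used for condition
effects at single residues, the rank-biserial immunogenicity screen, and
UPGMA clustering on the rank-correlation distance 1 - rho_s.
"""

from __future__ import annotations

import itertools
import logging

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .io_formats import RmsfDataset
from .residues import ResidueKey

log = logging.getLogger(__name__)

# |rho_s| = 1 gives an infinite t; np.inf orders above every finite null
# value and inf >= inf holds, so the sentinel is "more extreme than or equal
# to any null draw", the conservative limit the estimator needs.
T_SENTINEL = np.inf


def t_from_rho(rho: np.ndarray | float, n: int) -> np.ndarray | float:
    """Convert rank correlation(s) to the permutation test statistic t.

    ``|rho| == 1`` maps to a signed infinite sentinel.
    """
    if n < 3:
        raise ValueError(f"need at least 3 samples, got n={n}")
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho_arr) > 1 + 1e-12):
        raise ValueError("|rho| must be <= 1")
    rho_arr = np.clip(rho_arr, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho_arr * np.sqrt((n - 2) / (1.0 - rho_arr**2))
        t = np.where(np.abs(rho_arr) == 1.0, np.sign(rho_arr) * T_SENTINEL, t)
    if np.isscalar(rho):
        return float(t)
    return t


def spearman_matrix(dataset: RmsfDataset) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho_s of per-residue RMSF vectors.

    Returns ``(rho, degenerate)`` where ``rho`` is the symmetric correlation
    matrix with unit diagonal and ``degenerate`` a boolean vector marking
    residues whose RMSF vector is constant (their correlations are undefined,
    set to NaN off-diagonal, and excluded from significance testing).
    Ties are handled by average ranks.
    """
    m = dataset.matrix
    if m.shape[1] < 3:
        raise ValueError("need at least 3 trajectories for correlation analysis")
    degenerate = np.ptp(m, axis=1) == 0
    if degenerate.any():
        flagged = [str(dataset.residues[i]) for i in np.flatnonzero(degenerate)]
        log.warning("constant RMSF vectors for residues %s; correlations undefined", flagged)
    ranks = stats.rankdata(m, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho[degenerate, :] = np.nan
    rho[:, degenerate] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0, out=rho)
    return rho, degenerate


@dataclass
class NullDistribution:
    """Permutation null of the Spearman t statistic for sample size n.

    ``kind='resampled'`` distributions use the add-one p estimator;
    ``kind='exhaustive'`` (all n! relative rank permutations) give exact p.
    """

    n_sims: int
    t_values: np.ndarray
    seed: int | None
    kind: Literal["resampled", "exhaustive"] = "resampled"
    _abs_sorted: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.t_values = np.sort(np.asarray(self.t_values, dtype=float))
        self._abs_sorted = np.sort(np.abs(self.t_values))

    @property
    def resamples(self) -> int:
        return len(self.t_values)

    def count_at_least(self, abs_t: np.ndarray | float) -> np.ndarray | int:
        """Number of null values with |t_null| >= |t_obs| (vectorized).

        The comparison uses a tiny relative tolerance so that atoms of the
        discrete permutation distribution are counted even when the observed
        and null statistics of the same rank configuration differ by a few
        ulps (they travel different floating-point paths).
        """
        query = np.abs(abs_t) * (1.0 - 1e-10)
        idx = np.searchsorted(self._abs_sorted, query, side="left")
        return self.resamples - idx


def _rho_from_permutation_pairs(perm_a: np.ndarray, perm_b: np.ndarray, n: int) -> np.ndarray:
    # tie-free ranks: classical d^2 formula is exact
    d = perm_a - perm_b
    return 1.0 - 6.0 * (d.astype(float) ** 2).sum(axis=1) / (n * (n**2 - 1))


def build_null(
    n: int,
    resamples: int = 100_000,
    seed: int | None = None,
    chunk: int = 1_000_000,
) -> NullDistribution:
    """Monte-Carlo permutation null: each resample independently permutes two
    sequential integer arrays 1..n, correlates them, and converts to t.

    Generation is chunked so very large resample counts stream through a
    bounded working set.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if resamples < 1_000:
        raise ValueError("resamples must be >= 1000")
    rng = np.random.default_rng(seed)
    out = np.empty(resamples, dtype=float)
    done = 0
    while done < resamples:
        size = min(chunk, resamples - done)
        perm_a = np.argsort(rng.random((size, n)), axis=1) + 1
        perm_b = np.argsort(rng.random((size, n)), axis=1) + 1
        rho = _rho_from_permutation_pairs(perm_a, perm_b, n)
        out[done : done + size] = t_from_rho(rho, n)
        done += size
    return NullDistribution(n_sims=n, t_values=out, seed=seed, kind="resampled")


def exhaustive_null(n: int) -> NullDistribution:
    """Exact null over all n! relative rank permutations (n <= 8).

    Permuting both arrays only shifts which relative order appears; the
    distribution over relative permutations is identical, so enumerating one
    array against the identity is exhaustive.
    """
    if n > 8:
        raise ValueError("exhaustive enumeration limited to n <= 8")
    identity = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(range(1, n + 1))))
    rho = _rho_from_permutation_pairs(perms, identity[None, :], n)
    return NullDistribution(n_sims=n, t_values=t_from_rho(rho, n), seed=None, kind="exhaustive")


def pvalue_two_tailed(t_obs: np.ndarray | float, null: NullDistribution, n: int) -> np.ndarray | float:
    """Two-tailed permutation p-value of observed t against the null.

    Resampled nulls use the add-one estimator (count+1)/(N+1), which is never
    zero; exhaustive nulls return the exact count/N.
    """
    if n != null.n_sims:
        raise ValueError(f"null was built for n={null.n_sims}, data has n={n}")
    count = null.count_at_least(np.abs(t_obs))
    if null.kind == "exhaustive":
        p = count / null.resamples
    else:
        p = (count + 1) / (null.resamples + 1)
    if np.isscalar(t_obs):
        return float(p)
    return np.asarray(p, dtype=float)


def bh_adjust(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(p_adj, flags)``; NaN entries are excluded from the procedure
    (reported via log) and stay NaN / unflagged.
    """
    p = np.asarray(p_values, dtype=float)
    p_adj = np.full_like(p, np.nan)
    flags = np.zeros(p.shape, dtype=bool)
    valid = ~np.isnan(p)
    if (~valid).any():
        log.warning("bh_adjust: excluding %d NaN p-values", int((~valid).sum()))
    if valid.any():
        if np.any((p[valid] < 0) | (p[valid] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        reject, adj, _, _ = multipletests(p[valid], alpha=q, method="fdr_bh")
        p_adj[valid] = adj
        flags[valid] = adj < q
    return p_adj, flags


@dataclass
class CorrelationResult:
    """Full significance analysis of the residue-residue coupling matrix."""

    residues: list[ResidueKey]
    n_sims: int
    rho: np.ndarray
    t_stat: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    mask: np.ndarray
    alpha: float
    rho_min: float
    degenerate: np.ndarray

    def index_of(self, key: ResidueKey) -> int:
        return self.residues.index(key)

    def significant_pairs(self) -> list[tuple[ResidueKey, ResidueKey]]:
        iu = np.triu_indices(len(self.residues), k=1)
        return [
            (self.residues[i], self.residues[j])
            for i, j in zip(*iu)
            if self.mask[i, j]
        ]

    def volcano_table(self, labels: dict[ResidueKey, str] | None = None) -> pd.DataFrame:
        """Long-format (pair, rho_s, p_adj) table over the upper triangle."""
        labels = labels or {}
        iu = np.triu_indices(len(self.residues), k=1)
        rows = []
        for i, j in zip(*iu):
            a, b = self.residues[i], self.residues[j]
            rows.append(
                {
                    "residue_a": labels.get(a, str(a)),
                    "residue_b": labels.get(b, str(b)),
                    "rho_s": self.rho[i, j],
                    "p_raw": self.p_raw[i, j],
                    "p_adj": self.p_adj[i, j],
                    "significant": bool(self.mask[i, j]),
                }
            )
        return pd.DataFrame(rows)


def correlate(
    dataset: RmsfDataset,
    null: NullDistribution | None = None,
    resamples: int = 100_000,
    seed: int | None = None,
    alpha: float = 0.05,
    rho_min: float = 0.5,
) -> CorrelationResult:
    """Run the full coupling-significance pipeline on a dataset.

    The permutation null is built once (or passed in pre-built, e.g. the
    5e7-resample production null) and reused across all residue pairs.
    Significance requires both p_adj < alpha and |rho_s| >= rho_min; the
    magnitude filter mirrors the practice of discarding weak correlations
    even when nominally significant.
    """
    n = dataset.n_trajectories
    rho, degenerate = spearman_matrix(dataset)
    if null is None:
        null = build_null(n, resamples=resamples, seed=seed)
    t = t_from_rho(rho, n)
    k = len(dataset.residues)
    iu = np.triu_indices(k, 1)
    p_raw = np.full((k, k), np.nan)
    p_raw[iu] = pvalue_two_tailed(t[iu], null, n)
    p_raw.T[iu] = p_raw[iu]
    adj_flat, _ = bh_adjust(p_raw[iu], q=alpha)
    p_adj = np.full((k, k), np.nan)
    p_adj[iu] = adj_flat
    p_adj.T[iu] = adj_flat
    with np.errstate(invalid="ignore"):
        mask = (p_adj < alpha) & (np.abs(rho) >= rho_min)
    mask &= ~np.isnan(rho)
    np.fill_diagonal(mask, False)
    return CorrelationResult(
        residues=list(dataset.residues),
        n_sims=n,
        rho=rho,
        t_stat=t,
        p_raw=p_raw,
        p_adj=p_adj,
        mask=mask,
        alpha=alpha,
        rho_min=rho_min,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Exact paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    p_value: float
    n_used: int
    n_zero: int


def wilcoxon_exact_paired(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["two_sided", "greater", "less"] = "two_sided",
    zero_method: Literal["wilcox", "pratt"] = "wilcox",
) -> WilcoxonResult:
    """Exact paired Wilcoxon signed-rank test by full enumeration of the
    2^n sign assignments (dynamic programming over the signed-rank sum).

    ``alternative='greater'`` tests whether x tends to exceed y.  Zero
    differences are dropped by default (Wilcoxon convention, count logged);
    ``zero_method='pratt'`` ranks them but removes their contribution.
    Tied absolute differences get average ranks; the enumeration stays exact
    with midranks (ranks are scaled x2 to integers internally).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    d = x - y
    n_zero = int((d == 0).sum())
    if n_zero == len(d):
        raise ValueError("degenerate pairing: all paired differences are zero")
    if zero_method == "wilcox":
        d = d[d != 0]
        if n_zero:
            log.warning("wilcoxon_exact_paired: dropped %d zero differences", n_zero)
        ranks = stats.rankdata(np.abs(d))
    elif zero_method == "pratt":
        ranks = stats.rankdata(np.abs(d))
        ranks = ranks[d != 0]
        d = d[d != 0]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n = len(d)
    if n > 25:
        raise ValueError(f"exact enumeration limited to 25 informative pairs, got {n}")

    scaled = np.round(ranks * 2).astype(int)  # midranks are multiples of 1/2
    w_obs = int(np.round(scaled[d > 0].sum()))
    total = int(scaled.sum())
    # counts[w] = number of sign assignments with scaled W+ == w
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n_assignments = 2.0**n
    p_greater = counts[w_obs:].sum() / n_assignments
    p_less = counts[: w_obs + 1].sum() / n_assignments
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    elif alternative == "two_sided":
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return WilcoxonResult(statistic=w_obs / 2.0, p_value=float(p), n_used=n, n_zero=n_zero)


# ---------------------------------------------------------------------------
# Rank-biserial immunogenicity screen
# ---------------------------------------------------------------------------

def rank_biserial(group_hi: Sequence[float], group_lo: Sequence[float]) -> float:
    """Rank-biserial correlation r_rb = 2U/(n1*n2) - 1.

    U counts pairs where a value from the more-immunogenic group exceeds one
    from the less-immunogenic group, with half-credit for ties; positive r_rb
    means the more-immunogenic group tends to larger values.
    """
    hi = np.asarray(group_hi, dtype=float)
    lo = np.asarray(group_lo, dtype=float)
    if hi.size == 0 or lo.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = hi[:, None] - lo[None, :]
    u = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(2.0 * u / (hi.size * lo.size) - 1.0)


@dataclass
class GroupScreenResult:
    residues: list[ResidueKey]
    r_rb: np.ndarray  # per residue, aligned with residues
    p_values: dict[ResidueKey, float]  # only for screened (top_k) residues
    resamples: int
    seed: int | None
    alternative: str

    def to_frame(self, labels: dict[ResidueKey, str] | None = None) -> pd.DataFrame:
        labels = labels or {}
        return pd.DataFrame(
            {
                "residue": [labels.get(r, str(r)) for r in self.residues],
                "r_rb": self.r_rb,
                "p_perm": [self.p_values.get(r, np.nan) for r in self.residues],
            }
        )


def immunogenicity_screen(
    dataset: RmsfDataset,
    resamples: int = 100_000,
    seed: int | None = None,
    top_k: int = 5,
    alternative: Literal["two_sided", "greater", "less"] = "two_sided",
) -> GroupScreenResult:
    """Screen residues for association between RMSF and immunogenicity.

    Trajectories of the proline condition (P) are treated as the
    more-immunogenic group.  r_rb is computed for every residue; the top_k
    residues by |r_rb| get a condition-label permutation p-value using r_rb
    itself as statistic (r_rb is monotone in U, so any U-based statistic
    gives the same two-sided decisions).
    """
    idx_p = dataset.condition_indices("P")
    idx_v = dataset.condition_indices("V")
    if idx_p.size == 0 or idx_v.size == 0:
        raise ValueError("dataset must contain both conditions")
    m = dataset.matrix
    r_obs = np.array([rank_biserial(m[i, idx_p], m[i, idx_v]) for i in range(m.shape[0])])
    order = np.argsort(-np.abs(r_obs))[:top_k]
    rng = np.random.default_rng(seed)
    labels_all = np.concatenate([idx_p, idx_v])
    n_p = idx_p.size
    p_values: dict[ResidueKey, float] = {}
    for i in order:
        vals = m[i, labels_all]
        count = 0
        for _ in range(resamples):
            perm = rng.permutation(vals)
            r_perm = rank_biserial(perm[:n_p], perm[n_p:])
            if alternative == "two_sided":
                count += abs(r_perm) >= abs(r_obs[i]) - 1e-12
            elif alternative == "greater":
                count += r_perm >= r_obs[i] - 1e-12
            else:
                count += r_perm <= r_obs[i] + 1e-12
        p_values[dataset.residues[i]] = (count + 1) / (resamples + 1)
    return GroupScreenResult(
        residues=list(dataset.residues),
        r_rb=r_obs,
        p_values=p_values,
        resamples=resamples,
        seed=seed,
        alternative=alternative,
    )


# ---------------------------------------------------------------------------
# UPGMA clustering on rank-correlation distance
# ---------------------------------------------------------------------------

@dataclass
class ClusterTree:
    """UPGMA merge tree over residues with distance d = 1 - rho_s."""

    linkage: np.ndarray  # scipy hierarchical linkage matrix
    leaves: list[ResidueKey]

    def cut(self, height: float) -> list[set[ResidueKey]]:
        assignments = hierarchy.fcluster(self.linkage, t=height, criterion="distance")
        clusters: dict[int, set[ResidueKey]] = {}
        for leaf, c in zip(self.leaves, assignments):
            clusters.setdefault(int(c), set()).add(leaf)
        return list(clusters.values())


def upgma_cluster(rho: np.ndarray, residues: Sequence[ResidueKey]) -> ClusterTree:
    """Average-linkage (UPGMA) agglomerative clustering on d = 1 - rho_s."""
    rho = np.asarray(rho, dtype=float)
    if np.isnan(rho).any():
        raise ValueError("correlation matrix contains NaN; drop degenerate residues first")
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    condensed = d[np.triu_indices(len(residues), k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    return ClusterTree(linkage=linkage, leaves=list(residues))


def cut_containing(tree: ClusterTree, focal: ResidueKey) -> tuple[list[set[ResidueKey]], float]:
    """Smallest cophenetic height at which the focal residue joins a cluster
    of size >= 2, plus the partition obtained by cutting there."""
    if focal not in tree.leaves:
        raise ValueError(f"focal residue {focal} not among the clustered leaves")
    n = len(tree.leaves)
    focal_idx = tree.leaves.index(focal)
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    threshold = float(tree.linkage[-1, 2])  # root height fallback
    for step, (a, b, height, _size) in enumerate(tree.linkage):
        merged = members.pop(int(a)) | members.pop(int(b))
        members[n + step] = merged
        if focal_idx in merged and len(merged) >= 2:
            threshold = float(height)
            break
    return tree.cut(threshold), threshold
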