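"""OTU clustering of clone sequences and alpha-diversity estimators.

Implements pairwise p-distance on pre-aligned sequences, agglomerative OTU
clustering at a fractional-identity cutoff, Shannon/Margalef/Chao1 summaries,
the analytic (hypergeometric) rarefaction expectation, and presence/absence
incidence summaries across water-mass groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "OTUTable",
    "DiversitySummary",
    "IncidenceSummary",
    "pdistance",
    "cluster_otus",
    "diversity_summary",
    "rarefaction_curve",
    "incidence_summary",
    "rank_abundance",
]

_GAPS = set("-.")
_UNAMBIGUOUS = set("ACGT")


@dataclass
class OTUTable:
    """Integer clone counts per OTU per sample."""

    otu_ids: List[str]
    sample_ids: List[str]
    counts: np.ndarray  # shape (n_otus, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("all-zero OTU rows are not allowed")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OTUTable":
        return cls(
            otu_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            counts=df.to_numpy(),
        )


@dataclass(frozen=True)
class DiversitySummary:
    """Alpha-diversity indices for one sample or pooled layer."""

    s_obs: int
    n: float
    shannon: float
    margalef: Optional[float]
    chao1: Optional[float]


@dataclass
class IncidenceSummary:
    """Presence/absence bookkeeping of OTUs across sample groups."""

    n_total: int
    n_ubiquitous: int
    pct_ubiquitous: int
    n_unique: int
    pct_unique: int
    n_prevalent: int
    pct_prevalent: int
    prevalence: pd.Series  # fraction of samples in which each OTU occurs
    groups_per_otu: pd.Series


def pdistance(a: str, b: str) -> float:
    """Uncorrected p-distance between two pre-aligned sequences.

    Columns where either sequence carries a gap or an ambiguity code are
    excluded from the denominator.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be pre-aligned to equal length")
    a, b = a.upper(), b.upper()
    compared = 0
    diffs = 0
    for ca, cb in zip(a, b):
        if ca in _GAPS or cb in _GAPS:
            continue
        if ca not in _UNAMBIGUOUS or cb not in _UNAMBIGUOUS:
            continue
        compared += 1
        if ca != cb:
            diffs += 1
    if compared == 0:
        raise ValueError("no comparable columns")
    return diffs / compared


def _cluster_distance(
    dist: np.ndarray, a: Sequence[int], b: Sequence[int], linkage: str
) -> float:
    block = dist[np.ix_(list(a), list(b))]
    if linkage == "average":
        return float(block.mean())
    if linkage == "nearest":
        return float(block.min())
    if linkage == "furthest":
        return float(block.max())
    raise ValueError(f"unknown linkage {linkage!r}")


def cluster_otus(
    distances: np.ndarray,
    cutoff: float = 0.02,
    linkage: str = "average",
) -> np.ndarray:
    """Agglomerative clustering into OTUs at a distance cutoff (inclusive).

    Merges proceed while the smallest inter-cluster distance is <= cutoff;
    ties are resolved by merging the lexicographically smallest pair of
    clusters (ordered by their smallest member index). Returns an integer
    label per sequence, labelled by order of each cluster's smallest member.
    """
    dist = np.asarray(distances, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix must have zero diagonal")

    clusters: List[Tuple[int, ...]] = [(i,) for i in range(n)]
    while len(clusters) > 1:
        best: Optional[Tuple[float, Tuple[int, ...], Tuple[int, ...]]] = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = _cluster_distance(dist, clusters[i], clusters[j], linkage)
                key = (d, clusters[i][0], clusters[j][0])
                if best is None or key < (best[0], best[1][0], best[2][0]):
                    best = (d, clusters[i], clusters[j])
        assert best is not None
        if best[0] > cutoff:
            break
        a, b = best[1], best[2]
        clusters = [c for c in clusters if c is not a and c is not b]
        clusters.append(tuple(sorted(a + b)))
        clusters.sort(key=lambda c: c[0])
    labels = np.empty(n, dtype=int)
    for label, members in enumerate(sorted(clusters, key=lambda c: c[0])):
        for m in members:
            labels[m] = label
    return labels


def diversity_summary(
    counts: Sequence[float], base: float = math.e
) -> DiversitySummary:
    """Shannon, Margalef and bias-corrected Chao1 from a count vector.

    Shannon H' = -sum p_i log p_i (natural log by default). Margalef
    SR = (S-1)/ln N and Chao1 = S + n1(n1-1)/(2(n2+1)) require integer
    counts; for relative-abundance input (fingerprint rows) only H' is
    defined and the others are returned as None.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("at least one positive count required")
    total = x.sum()
    p = x / total
    shannon = float(-(p * np.log(p)).sum() / np.log(base))
    s_obs = int(x.size)
    integer_input = np.allclose(x, np.round(x))
    if not integer_input:
        return DiversitySummary(s_obs=s_obs, n=float(total), shannon=shannon,
                                margalef=None, chao1=None)
    n = float(total)
    if s_obs == 1 or n <= 1:
        margalef = 0.0
    else:
        margalef = (s_obs - 1) / math.log(n)
    ints = np.round(x).astype(int)
    n1 = int((ints == 1).sum())
    n2 = int((ints == 2).sum())
    chao1 = s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1))
    return DiversitySummary(s_obs=s_obs, n=n, shannon=shannon,
                            margalef=float(margalef), chao1=float(chao1))


def rarefaction_curve(
    counts: Sequence[int], sizes: Sequence[int]
) -> pd.DataFrame:
    """Expected OTU richness in random subsamples (analytic, no Monte Carlo).

    E[S_n] = sum_i (1 - C(N-N_i, n)/C(N, n)); the ratio is the probability
    that a hypergeometric draw of n misses OTU i entirely.
    """
    x = np.asarray(counts)
    if not np.allclose(x, np.round(x)) or (x < 0).any():
        raise ValueError("counts must be non-negative integers")
    x = np.round(x[x > 0]).astype(int)
    N = int(x.sum())
    rows = []
    for n in sizes:
        n = int(n)
        if n > N:
            raise ValueError(f"subsample size {n} exceeds total count {N}")
        if n == 0:
            rows.append((0, 0.0))
            continue
        p_missed = hypergeom.pmf(0, N, x, n)
        rows.append((n, float((1.0 - p_missed).sum())))
    return pd.DataFrame(rows, columns=["n", "expected_S"])


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def incidence_summary(
    matrix: Union[pd.DataFrame, "OTUTable"],
    groups: Mapping[str, str],
    prevalence_threshold: float = 0.70,
) -> IncidenceSummary:
    """Classify OTUs as ubiquitous / unique across sample groups.

    ``matrix`` is samples x OTUs (a fingerprint frame) or an
    :class:`OTUTable` (transposed internally); an OTU is present in a group
    iff it is nonzero in at least one of that group's samples. Percentages
    round half away from zero to integers. ``n_prevalent`` counts OTUs
    present in more than ``prevalence_threshold`` of all samples.
    """
    if isinstance(matrix, OTUTable):
        df = matrix.to_frame().T
    else:
        df = matrix
    if df.empty:
        raise ValueError("empty matrix")
    missing = [s for s in df.index if s not in groups]
    if missing:
        raise ValueError(f"samples without a group assignment: {missing}")
    present = df.to_numpy() > 0
    group_labels = pd.Series({s: groups[s] for s in df.index})
    all_groups = sorted(group_labels.unique())
    per_group = {
        g: present[(group_labels == g).to_numpy()].any(axis=0) for g in all_groups
    }
    n_groups_present = np.sum([per_group[g] for g in all_groups], axis=0)
    occurs = n_groups_present > 0
    n_total = int(occurs.sum())
    if n_total == 0:
        raise ValueError("no OTU present in any sample")
    n_ub = int((n_groups_present == len(all_groups)).sum())
    n_unique = int((n_groups_present == 1).sum())
    prevalence = pd.Series(present.mean(axis=0), index=df.columns)
    n_prev = int((prevalence > prevalence_threshold).sum())
    return IncidenceSummary(
        n_total=n_total,
        n_ubiquitous=n_ub,
        pct_ubiquitous=_round_half_away(100.0 * n_ub / n_total),
        n_unique=n_unique,
        pct_unique=_round_half_away(100.0 * n_unique / n_total),
        n_prevalent=n_prev,
        pct_prevalent=_round_half_away(100.0 * n_prev / n_total),
        prevalence=prevalence,
        groups_per_otu=pd.Series(n_groups_present, index=df.columns),
    )


def rank_abundance(counts: Sequence[float]) -> np.ndarray:
    """Descending relative abundances (ties keep input order)."""
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("at least one positive count required")
    order = np.argsort(-x, kind="stable")
    ranked = x[order]
    return ranked / ranked.sum()
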