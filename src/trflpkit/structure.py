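"""Resemblance matrices, sample clustering and matrix correlation.

Bray-Curtis similarity between fingerprint rows (stored as percent, matching
figure conventions), normalized Euclidean environmental distances, group-
average (UPGMA) agglomeration with deterministic tie-breaks, and a
Mantel-type rank correlation between two resemblance matrices with a
label-permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, rankdata

from .trflp import FingerprintMatrix

__all__ = [
    "ResemblanceMatrix",
    "Dendrogram",
    "MantelResult",
    "bray_curtis_matrix",
    "env_distance_matrix",
    "upgma",
    "relate",
]


@dataclass
class ResemblanceMatrix:
    """Symmetric pairwise similarity (percent) or distance with labels."""

    sample_ids: List[str]
    values: np.ndarray
    kind: str = "similarity-percent"  # or "distance"
    metric: str = "bray-curtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("resemblance matrix must be symmetric")
        if self.kind not in ("similarity-percent", "distance"):
            raise ValueError(f"unknown kind {self.kind!r}")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    def as_distance(self) -> "ResemblanceMatrix":
        """Convert percent similarity to distance (100 - S); no-op for
        distance matrices."""
        if self.kind == "distance":
            return self
        return ResemblanceMatrix(
            sample_ids=list(self.sample_ids),
            values=100.0 - self.values,
            kind="distance",
            metric=self.metric,
        )

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in row-major order."""
        idx = np.tril_indices(len(self.sample_ids), k=-1)
        return self.values[idx]

    def similarity(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])


@dataclass
class Dendrogram:
    """Ordered list of (members_a, members_b, merge_height) merges."""

    merges: List[Tuple[Tuple[str, ...], Tuple[str, ...], float]]
    leaves: List[str]

    def heights(self) -> List[float]:
        return [h for _, _, h in self.merges]

    def to_newick(self) -> str:
        """Ultrametric Newick; leaf-to-node branch lengths are half the
        merge height (cophenetic convention)."""
        node: Dict[frozenset, Tuple[str, float]] = {
            frozenset([leaf]): (leaf, 0.0) for leaf in self.leaves
        }
        rep = ""
        for a, b, h in self.merges:
            (na, ha), (nb, hb) = node.pop(frozenset(a)), node.pop(frozenset(b))
            height = h / 2.0
            rep = f"({na}:{height - ha:g},{nb}:{height - hb:g})"
            node[frozenset(a + b)] = (rep, height)
        return rep + ";" if rep else ";"


@dataclass(frozen=True)
class MantelResult:
    """Rank correlation between two resemblance matrices."""

    rho: float
    p: float
    n_perm: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.rho <= 1.0 + 1e-9:
            raise ValueError("rho out of range")
        if not 0 < self.p <= 1:
            raise ValueError("permutation p must lie in (0, 1]")


def _as_frame(m: Union[FingerprintMatrix, pd.DataFrame]) -> pd.DataFrame:
    return m.to_frame() if isinstance(m, FingerprintMatrix) else m


def bray_curtis_matrix(
    m: Union[FingerprintMatrix, pd.DataFrame],
) -> ResemblanceMatrix:
    """Pairwise Bray-Curtis similarity S = 100*(1 - sum|x-y|/sum(x+y)).

    A pair of all-zero rows has no defined resemblance and is reported as
    similarity 0 with a warning.
    """
    df = _as_frame(m)
    if len(df) < 2:
        raise ValueError("at least 2 samples required")
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    row_sums = x.sum(axis=1)
    sims = np.full((n, n), 100.0)
    for i in range(n - 1):
        num = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        den = row_sums[i] + row_sums[i + 1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(den > 0, 100.0 * (1.0 - num / den), 0.0)
        sims[i, i + 1:] = sims[i + 1:, i] = s
        for j in np.where(den == 0)[0]:
            warnings.warn(
                f"samples {df.index[i]!r} and {df.index[i + 1 + j]!r} are "
                "both empty; similarity set to 0"
            )
    return ResemblanceMatrix(
        sample_ids=[str(i) for i in df.index], values=sims,
        kind="similarity-percent", metric="bray-curtis",
    )


def env_distance_matrix(
    metadata: pd.DataFrame,
    variables: Sequence[str],
    normalize: bool = True,
    log_transform: Sequence[str] = (),
    sample_id_col: str = "sample_id",
) -> ResemblanceMatrix:
    """Euclidean distance between samples on (optionally normalized)
    environmental variables.

    Normalization centers each variable and scales to unit standard
    deviation (ddof=1); zero-variance variables are dropped with a warning.
    Variables listed in ``log_transform`` are log10(x + eps) transformed
    first (for skewed biological quantities such as cell abundance).
    """
    if len(metadata) < 2:
        raise ValueError("at least 2 samples required")
    missing = [v for v in variables if v not in metadata.columns]
    if missing:
        raise ValueError(f"variables not in metadata: {missing}")
    ids = (
        metadata[sample_id_col].astype(str).tolist()
        if sample_id_col in metadata.columns
        else [str(i) for i in metadata.index]
    )
    cols = []
    for v in variables:
        col = metadata[v].to_numpy(dtype=float)
        if v in log_transform:
            col = np.log10(col + 1e-12)
        if normalize:
            sd = col.std(ddof=1)
            if sd == 0:
                warnings.warn(f"variable {v!r} has zero variance; dropped")
                continue
            col = (col - col.mean()) / sd
        cols.append(col)
    if not cols:
        raise ValueError("no usable variables left")
    x = np.column_stack(cols)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return ResemblanceMatrix(
        sample_ids=ids, values=d, kind="distance", metric="euclidean"
    )


def upgma(resemblance: ResemblanceMatrix) -> Dendrogram:
    """Group-average agglomeration of a resemblance matrix.

    Similarity input is converted to distance 100 - S. Inter-cluster
    distance is the mean over all cross pairs of the original matrix; ties
    break on the lexicographically smallest pair of cluster leaders.
    """
    dm = resemblance.as_distance()
    dist = dm.values
    ids = dm.sample_ids
    n = len(ids)
    clusters: List[Tuple[int, ...]] = [(i,) for i in range(n)]
    merges: List[Tuple[Tuple[str, ...], Tuple[str, ...], float]] = []
    while len(clusters) > 1:
        best_key: Optional[Tuple[float, int, int]] = None
        best_pair = (0, 1)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = float(dist[np.ix_(clusters[i], clusters[j])].mean())
                key = (d, clusters[i][0], clusters[j][0])
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        i, j = best_pair
        a, b = clusters[i], clusters[j]
        merges.append(
            (tuple(ids[k] for k in a), tuple(ids[k] for k in b), best_key[0])
        )
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(tuple(sorted(a + b)))
        clusters.sort(key=lambda c: c[0])
    return Dendrogram(merges=merges, leaves=list(ids))


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra, rb = rankdata(a), rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    if denom == 0:
        return 0.0
    return float((ra * rb).sum() / denom)


def relate(
    mA: ResemblanceMatrix,
    mB: ResemblanceMatrix,
    n_perm: int = 9999,
    seed: Optional[int] = None,
    method: str = "spearman",
) -> MantelResult:
    """Mantel-type matrix correlation with a label-permutation null.

    rho is the rank correlation between the lower triangles of the two
    matrices; the null permutes the sample labels of ``mB`` (rows and
    columns jointly) and p = (1 + #{perm rho >= observed}) / (1 + n_perm).
    """
    if mA.sample_ids != mB.sample_ids:
        raise ValueError("matrices must share the same samples in the same order")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(mA.sample_ids)
    tril = np.tril_indices(n, k=-1)
    a = mA.values[tril]
    if method == "spearman":
        corr = _spearman
    elif method == "kendall":
        corr = lambda u, v: float(kendalltau(u, v).statistic)  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")
    rho_obs = corr(a, mB.values[tril])
    rng = np.random.default_rng(seed)
    count = 0
    vb = mB.values
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rho_p = corr(a, vb[np.ix_(perm, perm)][tril])
        if rho_p >= rho_obs:
            count += 1
    return MantelResult(
        rho=rho_obs, p=(1 + count) / (1 + n_perm), n_perm=n_perm
    )
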