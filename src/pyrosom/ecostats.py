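"""Ecological statistics on compound and class abundance profiles.

Diversity (Shannon, Gini-Simpson), Bray-Curtis dissimilarity, hierarchical
clustering of log-transformed abundances, distance-based PERMANOVA with
seeded label permutations, and Pearson correlation between ecosystem
compound profiles. Relative abundances are computed from integrated peak
heights; they describe detector response shares, not carbon mass shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from .errors import ParameterError, UndefinedSimilarityError


@dataclass
class AbundanceTable:
    """Samples x compounds (or classes) non-negative abundance matrix."""

    values: pd.DataFrame                  # rows = samples, cols = compounds
    group: dict[str, str] | None = None   # sample -> factor label

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ParameterError("sample and compound ids must be unique")
        if (self.values.values < 0).any():
            raise ParameterError("abundances must be non-negative")

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.values.index]

    def replicate_averaged(self) -> "AbundanceTable":
        """Mean abundance per group (replicate averaging)."""
        if not self.group:
            raise ParameterError("replicate averaging requires a group map")
        g = pd.Series({s: self.group[s] for s in self.samples})
        avg = self.values.groupby(g).mean()
        return AbundanceTable(avg, {str(s): str(s) for s in avg.index})


def class_relative_abundance(
    features: Mapping[str, Sequence[tuple[str, float]]],
    use_area: bool = False,
) -> AbundanceTable:
    """Per-sample class shares from classified features.

    ``features`` maps sample_id -> [(class, height), ...] (or areas when the
    caller extracted areas; ``use_area`` only documents intent). Shares per
    sample sum to 1 over classes. Samples with zero classified abundance are
    excluded with a warning.
    """
    rows: dict[str, dict[str, float]] = {}
    for sid, feats in features.items():
        acc: dict[str, float] = {}
        for cls, height in feats:
            if height < 0:
                raise ParameterError("heights must be non-negative")
            acc[cls] = acc.get(cls, 0.0) + float(height)
        total = sum(acc.values())
        if total <= 0:
            warnings.warn(
                f"sample {sid!r} has zero classified abundance; excluded",
                RuntimeWarning, stacklevel=2,
            )
            continue
        rows[sid] = {k: v / total for k, v in acc.items()}
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index()
    return AbundanceTable(df.reindex(sorted(df.columns), axis=1))


def _as_shares(p: Sequence[float]) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.size == 0:
        raise ParameterError("share vector is empty")
    if np.any(v < 0):
        raise ParameterError("shares must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ParameterError("share vector sums to zero")
    if not np.isclose(total, 1.0, atol=1e-8):
        warnings.warn(
            f"shares sum to {total:.6g}; renormalizing to 1",
            RuntimeWarning, stacklevel=3,
        )
        v = v / total
    return v


def shannon(p: Sequence[float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log; 0 ln 0 := 0)."""
    v = _as_shares(p)
    nz = v[v > 0]
    return float(-np.sum(nz * np.log(nz)))


def simpson(p: Sequence[float]) -> float:
    """Gini-Simpson diversity 1 - sum p_i^2 (larger = more diverse)."""
    v = _as_shares(p)
    return float(1.0 - np.sum(v * v))


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    vx = np.asarray(x, dtype=float)
    vy = np.asarray(y, dtype=float)
    if vx.shape != vy.shape:
        raise ParameterError("vectors must have equal length")
    if np.any(vx < 0) or np.any(vy < 0):
        raise ParameterError("abundances must be non-negative")
    denom = float(np.sum(vx + vy))
    if denom == 0:
        raise UndefinedSimilarityError(
            "Bray-Curtis is undefined for two all-zero vectors"
        )
    return float(np.sum(np.abs(vx - vy)) / denom)


def bray_curtis_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Symmetric sample x sample Bray-Curtis distance matrix."""
    X = table.values.to_numpy()
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bray_curtis(X[i], X[j])
    return pd.DataFrame(D, index=table.values.index, columns=table.values.index)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and integer group labels."""
    n = len(labels)
    groups = np.unique(labels)
    a = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    if n - a <= 0 or ss_within <= 0:
        return np.inf, ss_between / ss_total if ss_total > 0 else np.nan
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else np.nan
    return float(f), float(r2)


def permanova(
    d: np.ndarray | pd.DataFrame,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Distance-based PERMANOVA with whole-row label permutations.

    Decomposes the sum of squared distances into between- and within-group
    parts; significance is the fraction of label permutations whose
    pseudo-F reaches the observed one, with the +1 correction:
    p = (1 + #{F* >= F}) / (1 + n_perm).
    """
    D = np.asarray(d, dtype=float)
    labels = np.asarray([str(g) for g in groups])
    n = len(labels)
    if D.shape != (n, n):
        raise ParameterError("distance matrix shape must match group length")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ParameterError("distance matrix must be symmetric with zero diagonal")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ParameterError("PERMANOVA needs at least 2 groups")
    if n <= a:
        raise ParameterError(
            f"insufficient residual degrees of freedom: n={n}, groups={a}"
        )
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    d2 = D * D
    f_obs, r2 = _pseudo_f(d2, codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        f_star, _ = _pseudo_f(d2, perm)
        if f_star >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(f_obs, r2, float(p), n_perm)


@dataclass
class Dendrogram:
    """Average-linkage tree over samples with Bray-Curtis distances."""

    linkage: np.ndarray           # scipy linkage matrix
    labels: list[str]

    def cophenetic_matrix(self) -> pd.DataFrame:
        d = squareform(sch.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hclust_profiles(table: AbundanceTable) -> Dendrogram:
    """Hierarchical clustering of log-transformed abundances.

    Abundances are ln(x+1)-transformed (handles zeros), pairwise sample
    distances are Bray-Curtis, and merging is average linkage. Ties in the
    merge order follow scipy's deterministic ordering.
    """
    if table.values.shape[0] < 2:
        raise ParameterError("clustering needs at least 2 samples")
    logged = np.log1p(table.values.to_numpy())
    n = logged.shape[0]
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            cond.append(bray_curtis(logged[i], logged[j]))
    Z = sch.linkage(np.asarray(cond), method="average")
    return Dendrogram(Z, [str(s) for s in table.values.index])


def pearson_profiles(
    x: Mapping[str, float] | Sequence[float],
    y: Mapping[str, float] | Sequence[float],
) -> tuple[float, float]:
    """Pearson r and two-sided p between two compound profiles.

    Mapping inputs are matched on the union of compound ids, with absent
    compounds counted as 0; sequences must have equal length >= 3.
    """
    if isinstance(x, Mapping) or isinstance(y, Mapping):
        if not (isinstance(x, Mapping) and isinstance(y, Mapping)):
            raise ParameterError("mix of mapping and sequence profiles")
        keys = sorted(set(x) | set(y))
        vx = np.array([float(x.get(k, 0.0)) for k in keys])
        vy = np.array([float(y.get(k, 0.0)) for k in keys])
    else:
        vx = np.asarray(x, dtype=float)
        vy = np.asarray(y, dtype=float)
        if vx.shape != vy.shape:
            raise ParameterError("vectors must have equal length")
    if len(vx) < 3:
        raise ParameterError("need at least 3 points for a correlation")
    if np.ptp(vx) == 0 or np.ptp(vy) == 0:
        raise UndefinedSimilarityError(
            "Pearson correlation is undefined for a zero-variance profile"
        )
    r, p = sps.pearsonr(vx, vy)
    return float(r), float(p)


def diversity_table(table: AbundanceTable) -> pd.DataFrame:
    """Shannon and Gini-Simpson per sample, computed on compound shares."""
    rows = []
    for sid in table.samples:
        v = table.values.loc[sid].to_numpy()
        total = v.sum()
        if total <= 0:
            continue
        p = v / total
        rows.append({"sample": sid, "shannon": shannon(p),
                     "simpson": simpson(p), "richness": int((v > 0).sum())})
    return pd.DataFrame(rows)


def write_distance_matrix(d: pd.DataFrame, path: str | Path) -> None:
    d.to_csv(path)


def write_newick(dendro: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(dendro.to_newick() + "\n")
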