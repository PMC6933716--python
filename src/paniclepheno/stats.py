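"""Downstream statistics of the trait table.

Pairwise-complete Pearson correlation matrices (r, two-sided p from the
t distribution with n-2 df, and the complete-pair count n), agglomerative
clustering of genotype voxel-count trajectories (Euclidean + Ward by
default), and compact letter displays from all pairwise Student t-tests.
P-values are reported raw, matching common practice for these trait
panels; a Benjamini-Hochberg option exists but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scistats
from scipy.cluster import hierarchy as _hier

from .errors import DegenerateTestError, ValidationError


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson r / p / n matrices over a trait list.

    ``undefined`` marks pairs where r does not exist (a constant trait or
    fewer than 3 complete pairs); their r and p are NaN, never silently
    propagated.
    """

    traits: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    undefined: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """(trait_i, trait_j, r, p, n) rows for the upper triangle."""
        rows = []
        for i, a in enumerate(self.traits):
            for b in self.traits[i + 1:]:
                rows.append({"trait_i": a, "trait_j": b,
                             "r": self.r.loc[a, b], "p": self.p.loc[a, b],
                             "n": self.n.loc[a, b]})
        return pd.DataFrame(rows, columns=["trait_i", "trait_j", "r", "p", "n"])


def pearson_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r and two-sided p for one complete pair of vectors.

    p comes from t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 complete pairs")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise DegenerateTestError("constant trait: correlation undefined")
    r = float((xc * yc).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * _scistats.t.sf(abs(t), df=n - 2))
    return r, p, n


def pearson_matrix(
    table: pd.DataFrame,
    traits: Sequence[str],
    *,
    bh_correct: bool = False,
) -> CorrelationMatrix:
    """Pairwise-complete correlation matrix over ``traits`` columns.

    Rows with a missing value in either trait are dropped per pair.
    Undefined entries (constant trait, n < 3) are flagged, not NaN-
    propagated into neighbors.  ``bh_correct`` applies Benjamini-Hochberg
    across the upper triangle.
    """
    traits = list(traits)
    missing = [t for t in traits if t not in table.columns]
    if missing:
        raise ValidationError(f"traits not in table: {missing}")
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    undef = np.zeros((k, k), dtype=bool)
    cols = {t: pd.to_numeric(table[t], errors="coerce").to_numpy(dtype=float)
            for t in traits}
    for i in range(k):
        n[i, i] = np.isfinite(cols[traits[i]]).sum()
        for j in range(i + 1, k):
            x, y = cols[traits[i]], cols[traits[j]]
            ok = np.isfinite(x) & np.isfinite(y)
            n[i, j] = n[j, i] = int(ok.sum())
            try:
                rij, pij, _ = pearson_pair(x[ok], y[ok])
            except (ValidationError, DegenerateTestError):
                undef[i, j] = undef[j, i] = True
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    if bh_correct:
        iu = np.triu_indices(k, 1)
        raw = p[iu]
        ok = np.isfinite(raw)
        if ok.any():
            adj = _bh_adjust(raw[ok])
            new = raw.copy()
            new[ok] = adj
            p[iu] = new
            p.T[iu] = new
    def frame(m):
        return pd.DataFrame(m, index=traits, columns=traits)
    return CorrelationMatrix(traits, frame(r), frame(p), frame(n),
                             frame(undef))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        val = min(prev, p[idx] * m / (rank_from_top + 1))
        adj[idx] = val
        prev = val
    return adj


# ---------------------------------------------------------------------------
# trajectory clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Genotype cluster labels (1..k) plus the linkage tree."""

    labels: pd.Series          # index: genotype, values 1..k
    linkage: np.ndarray        # scipy (n-1, 4) linkage matrix
    k: int
    imputed: list[str]         # genotypes that had missing cells filled


def cluster_genotypes(
    trajectories: pd.DataFrame,
    k: int,
    *,
    metric: str = "euclidean",
    method: str = "ward",
) -> ClusterResult:
    """Agglomerative clustering of genotype x week voxel-count rows.

    Missing cells are imputed by the genotype's own row mean first (and
    the affected genotypes flagged); the tree is cut to ``k`` clusters.
    """
    if k > len(trajectories):
        raise ValidationError(
            f"k={k} exceeds the {len(trajectories)} genotypes")
    data = trajectories.astype(float).copy()
    imputed = []
    if data.isna().any().any():
        for genotype, row in data.iterrows():
            if row.isna().any():
                if row.dropna().empty:
                    raise ValidationError(
                        f"genotype {genotype!r} has no observed weeks")
                data.loc[genotype] = row.fillna(row.mean())
                imputed.append(str(genotype))
    link = _hier.linkage(data.to_numpy(), method=method, metric=metric)
    raw = _hier.fcluster(link, t=k, criterion="maxclust")
    # renumber clusters 1..k in order of first appearance (row-stable)
    seen: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, c in enumerate(raw):
        labels[i] = seen.setdefault(c, len(seen) + 1)
    return ClusterResult(pd.Series(labels, index=trajectories.index,
                                   name="cluster"),
                         link, k, imputed)


# ---------------------------------------------------------------------------
# pairwise t-tests with compact letter display
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """All pairwise two-sample t-tests plus the letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    """

    groups: list[str]
    letters: dict[str, str]
    pvalues: pd.DataFrame
    alpha: float


def group_compare(
    values: dict[str, Sequence[float]],
    alpha: float = 0.1,
    *,
    welch: bool = False,
) -> GroupComparison:
    """Student (or Welch) t-tests over every group pair, then a compact
    letter display via the insert-and-absorb algorithm.

    Raises
    ------
    DegenerateTestError
        When some pair has zero variance in both groups (no test can be
        formed).
    """
    names = list(values.keys())
    if len(names) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    for g, arr in arrays.items():
        if len(arr) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")
    k = len(names)
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[names[i]], arrays[names[j]]
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                if a.mean() == b.mean():
                    p = 1.0   # identical constants: indistinguishable
                else:
                    raise DegenerateTestError(
                        f"zero within-group variance for {names[i]!r} vs "
                        f"{names[j]!r} with unequal means")
            else:
                p = float(_scistats.ttest_ind(a, b,
                                              equal_var=not welch).pvalue)
            pmat[i, j] = pmat[j, i] = p
    significant = pmat < alpha
    letters = _compact_letter_display(names, significant)
    return GroupComparison(
        names, letters,
        pd.DataFrame(pmat, index=names, columns=names), alpha)


def _compact_letter_display(
    names: list[str], significant: np.ndarray
) -> dict[str, str]:
    """Insert-and-absorb: start from one all-member column; for every
    significant pair found together in a column, split that column into
    two copies, one without each member; absorb columns contained in
    another."""
    k = len(names)
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                columns.append(col - {i})
                columns.append(col - {j})
            # absorb duplicates/subsets
            columns = [c for c in columns if c]
            keep = []
            for c in columns:
                if any(c < d or (c == d and d in keep) for d in columns
                       if d is not c):
                    continue
                keep.append(c)
            columns = keep
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    # stable order: by smallest member index
    columns.sort(key=lambda c: min(c))
    out = {name: "" for name in names}
    for letter, col in zip(alphabet, columns):
        for i in sorted(col):
            out[names[i]] += letter
    return out
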