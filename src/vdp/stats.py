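"""Community statistics: Shannon diversity, Bray-Curtis, PCoA, Mantel,
Pearson correlation and Student's t-test.

Implemented directly in numpy so every convention (log base, permutation
scheme, p-value sidedness) is explicit and auditable; scipy is used only for
reference distributions.  Conventions:

* Shannon uses the natural log.
* Bray-Curtis: ``d = 1 - 2 * sum(min(x, y)) / (sum(x) + sum(y))``.
* PCoA is raw classical scaling (double-centred ``-D**2/2``); negative
  eigenvalues are reported, never folded into coordinates.
* Mantel correlates upper-triangle vectors (Spearman by default, the rho the
  field reports), permutes one matrix's labels jointly, one-sided "greater",
  ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io import ValidationError


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric, zero-diagonal dissimilarity matrix with sample ids."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(v)):
            raise ValidationError("distance matrix has non-finite entries")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix is not symmetric within 1e-12")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be exactly zero")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_permutations: int | None = None
    extra: dict = field(default_factory=dict)


def shannon(abundances) -> float:
    """Shannon index H = -sum p_i ln p_i over positive entries."""
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValidationError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValidationError("shannon undefined for an all-zero vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("bray_curtis: length mismatch")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValidationError("bray_curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def bray_curtis_matrix(table, ids=None) -> DistanceMatrix:
    """Pairwise Bray-Curtis between the *columns* of an abundance table."""
    import pandas as pd

    if isinstance(table, pd.DataFrame):
        ids = tuple(map(str, table.columns)) if ids is None else tuple(ids)
        m = table.to_numpy(dtype=float)
    else:
        m = np.asarray(table, dtype=float)
        ids = tuple(ids) if ids is not None else tuple(str(i) for i in range(m.shape[1]))
    n = m.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(m[:, i], m[:, j])
    return DistanceMatrix(ids, d)


def euclidean_matrix(values, ids) -> DistanceMatrix:
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    d = np.sqrt(((v[:, None, :] - v[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(ids), d)


def pcoa(dm: DistanceMatrix, k: int):
    """Classical scaling of a dissimilarity matrix.

    Returns ``(coordinates n x k, eigenvalues, variance_explained)``.
    Coordinates come from positive eigenvalues only (axes beyond the positive
    spectrum are zero); ``variance_explained`` is over positive eigenvalues.
    Sign convention: the first non-zero loading of each axis is positive.
    """
    n = dm.n
    if not 1 <= k < n:
        raise ValidationError(f"pcoa: need 1 <= k < n, got k={k}, n={n}")
    d2 = dm.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > max(1e-10 * max(evals.max(), 1.0), 0.0)
    coords = np.zeros((n, k))
    m = min(k, int(pos.sum()))
    if m:
        coords[:, :m] = evecs[:, :m] * np.sqrt(evals[:m])
    for j in range(k):
        col = coords[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, j] = -col
    pos_sum = evals[pos].sum()
    var_exp = np.where(pos, evals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    return coords, evals, var_exp


def _spearman_stat(a_ranked: np.ndarray, b: np.ndarray) -> float:
    return _pearson_r(a_ranked, sps.rankdata(b))


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValidationError("correlation undefined for a constant vector")
    return float((xc @ yc) / denom)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    method: str = "spearman",
    seed: int | None = None,
    exhaustive: bool = False,
) -> TestResult:
    """Mantel permutation test of association between two distance matrices.

    The statistic is the Spearman (default) or Pearson correlation of the
    upper-triangle vectors; the null permutes the row/column labels of ``d2``
    jointly.  ``exhaustive=True`` enumerates all n! permutations (identity
    included), equivalent in p to sampling all non-identity permutations.
    """
    if d1.ids != d2.ids:
        raise ValidationError("mantel: distance matrices have different ids")
    if n_perm < 1 and not exhaustive:
        raise ValidationError("mantel: n_perm must be >= 1")
    n = d1.n
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    if method == "spearman":
        v1s = sps.rankdata(v1)
        stat_of = lambda w: _spearman_stat(v1s, w)  # noqa: E731
    elif method == "pearson":
        stat_of = lambda w: _pearson_r(v1, w)  # noqa: E731
    else:
        raise ValidationError(f"mantel: unknown method {method!r}")
    observed = stat_of(d2.values[iu])

    if exhaustive:
        ge = 0
        count = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            w = d2.values[np.ix_(p, p)][iu]
            if stat_of(w) >= observed - 1e-12:
                ge += 1
            count += 1
        # identity permutation plays the role of the observed draw
        p_value = ge / count
        return TestResult(observed, p_value, f"mantel-{method}-exhaustive", count - 1)

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        w = d2.values[np.ix_(p, p)][iu]
        if stat_of(w) >= observed - 1e-12:
            ge += 1
    p_value = (1 + ge) / (1 + n_perm)
    return TestResult(observed, p_value, f"mantel-{method}", n_perm)


def pearson(x, y) -> TestResult:
    """Product-moment correlation with a two-sided t-reference p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("pearson: length mismatch")
    n = x.size
    if n < 3:
        raise ValidationError("pearson: need n >= 3")
    r = _pearson_r(x, y)
    if abs(r) >= 1.0:
        return TestResult(float(np.clip(r, -1, 1)), 0.0, "pearson", extra={"n": n})
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return TestResult(r, float(p), "pearson", extra={"n": n, "t": t})


def t_test(a, b, variant: str = "student") -> TestResult:
    """Two-sample t-test, pooled-variance (student) or Welch."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValidationError("t_test: each sample needs n >= 2")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            return TestResult(0.0, 1.0, f"t-{variant}", extra={"df": na + nb - 2})
        raise ValidationError("t_test: zero variance with unequal means")
    if variant == "student":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    elif variant == "welch":
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    else:
        raise ValidationError(f"t_test: unknown variant {variant!r}")
    t = diff / se
    p = 2 * sps.t.sf(abs(t), df=df)
    return TestResult(float(t), float(p), f"t-{variant}", extra={"df": df})


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values, reported alongside raw p in screening panels."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
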