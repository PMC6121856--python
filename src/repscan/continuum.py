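"""Mantel-type association between repeatability and the speciation continuum.

Population pairs are placed along the speciation continuum by scalar
proxies of reproductive isolation (hybrid-zone width in km, percent
hybrids, cytochrome-b p-distance, autosomal tree distance).  Each proxy is
expanded into a symmetric pair-by-pair matrix and compared with a
repeatability matrix by (partial) Mantel tests: Spearman rank correlation
of vectorized lower triangles with permutation significance, controlling a
phylogenetic-distance matrix in the partial form.  Small numbers of pairs
(eight here) make the non-parametric permutation machinery essential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .io_core import RepscanError, ValidationError

__all__ = [
    "MantelResult",
    "p_distance",
    "scalar_to_matrix",
    "drop_missing_labels",
    "mantel",
    "partial_mantel",
]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    ci: tuple[float, float] | None = None
    n_perm: int = 0


# ---------------------------------------------------------------------------
# scalar inputs
# ---------------------------------------------------------------------------

def p_distance(alignment, group_a: Sequence[str], group_b: Sequence[str]) -> float:
    """Mean proportion of differing nucleotide sites between two groups.

    ``alignment`` is a FASTA path or a mapping of id -> sequence of
    equal-length aligned sequences.  For every cross-group sequence pair,
    sites where either member carries a gap or ambiguity code are excluded;
    the pairwise distance is (differing sites / compared sites) and the
    group distance is the mean over all cross pairs.
    """
    if isinstance(alignment, (str, Path)):
        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(alignment), "fasta")}
    else:
        seqs = {k: str(v).upper() for k, v in alignment.items()}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValidationError("aligned sequences must have equal length")
    for gid in list(group_a) + list(group_b):
        if gid not in seqs:
            raise ValidationError(f"sequence {gid!r} not in alignment")
    dists = []
    for ida in group_a:
        sa = seqs[ida]
        for idb in group_b:
            sb = seqs[idb]
            compared = differing = 0
            for x, y in zip(sa, sb):
                if x in _VALID_BASES and y in _VALID_BASES:
                    compared += 1
                    differing += x != y
            if compared == 0:
                raise RepscanError(
                    f"no comparable sites between {ida!r} and {idb!r}"
                )
            dists.append(differing / compared)
    return float(np.mean(dists))


def scalar_to_matrix(values: Mapping[str, float] | pd.Series,
                     mode: str = "mean") -> pd.DataFrame:
    """Expand one scalar per pair into a symmetric pair-by-pair matrix.

    ``mode="mean"`` (default) sets entry (i, j) to the mean of the two
    scalars — small when both pairs sit at the same end of the continuum —
    while ``mode="absdiff"`` uses the absolute difference.  Pairs with a
    missing scalar are dropped with a warning.  Diagonal is zero.
    """
    s = pd.Series(values, dtype=float)
    missing = s.index[s.isna()]
    if len(missing):
        warnings.warn(f"pairs dropped for missing scalar: {list(missing)}")
        s = s.dropna()
    v = s.to_numpy()
    if mode == "mean":
        m = (v[:, None] + v[None, :]) / 2.0
    elif mode == "absdiff":
        m = np.abs(v[:, None] - v[None, :])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(m, 0.0)
    return pd.DataFrame(m, index=s.index, columns=s.index)


# ---------------------------------------------------------------------------
# Mantel machinery
# ---------------------------------------------------------------------------

def _tri(m: np.ndarray) -> np.ndarray:
    return m[np.tril_indices(m.shape[0], k=-1)]


def _as_aligned(a: pd.DataFrame, b: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    labels = list(a.index)
    if set(labels) != set(b.index):
        raise ValidationError("matrices must share labels")
    return (a.to_numpy(dtype=float),
            b.loc[labels, labels].to_numpy(dtype=float), labels)


def drop_missing_labels(*matrices: pd.DataFrame) -> list[pd.DataFrame]:
    """Restrict matrices to labels with complete off-diagonal data everywhere.

    A pair without data for one statistic (an all-NaN row/column in its
    repeatability matrix) is removed from every matrix so that all
    off-diagonal entries entering a Mantel test are defined.
    """
    labels = list(matrices[0].index)
    nan_mask = np.zeros((len(labels), len(labels)), dtype=bool)
    for m in matrices:
        v = m.loc[labels, labels].to_numpy(dtype=float).copy()
        np.fill_diagonal(v, 0.0)
        nan_mask |= np.isnan(v)
    keep = list(range(len(labels)))
    # greedily drop the label implicated in the most missing entries
    while nan_mask[np.ix_(keep, keep)].any():
        counts = nan_mask[np.ix_(keep, keep)].sum(axis=1)
        keep.pop(int(np.argmax(counts)))
    kept = [labels[i] for i in keep]
    dropped = sorted(set(labels) - set(kept))
    if dropped:
        warnings.warn(f"labels dropped for missing matrix entries: {dropped}")
    return [m.loc[kept, kept] for m in matrices]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _one_sided_count(r_perm: float, r_obs: float, alternative: str) -> bool:
    if alternative == "greater":
        return r_perm >= r_obs
    if alternative == "less":
        return r_perm <= r_obs
    return abs(r_perm) >= abs(r_obs)  # two-sided


def mantel(a: pd.DataFrame, b: pd.DataFrame, method: str = "spearman",
           n_perm: int = 9999, alternative: str = "two-sided",
           seed: int | None = None,
           rng: np.random.Generator | None = None) -> MantelResult:
    """Mantel test between two symmetric pair matrices.

    The statistic is the correlation (Spearman by default) of the
    vectorized lower triangles; significance comes from jointly permuting
    the row/column order of ``b`` ``n_perm`` times, with the add-one
    p-value estimator.
    """
    A, B, labels = _as_aligned(a, b)
    n = len(labels)
    if n < 4:
        raise RepscanError(f"need >= 4 labels for a Mantel test, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    x = _tri(A)
    r_obs = _corr(x, _tri(B), method)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _corr(x, _tri(B[np.ix_(perm, perm)]), method)
        if _one_sided_count(r_p, r_obs, alternative):
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm)


def _residuals(v: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Residuals of v on c (with intercept)."""
    X = np.column_stack([np.ones_like(c), c])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def _partial_r(x: np.ndarray, y: np.ndarray, z: np.ndarray, method: str) -> float:
    if method == "spearman":
        x, y, z = stats.rankdata(x), stats.rankdata(y), stats.rankdata(z)
    ex = _residuals(x, z)
    ey = _residuals(y, z)
    # residual variance at floating-point noise level: fully explained by the
    # control, so the partial association is zero by construction
    tol_x = 1e-10 * (x.std() + 1.0)
    tol_y = 1e-10 * (y.std() + 1.0)
    if ex.std() <= tol_x or ey.std() <= tol_y:
        return 0.0
    return float(np.corrcoef(ex, ey)[0, 1])


def partial_mantel(a: pd.DataFrame, b: pd.DataFrame, c: pd.DataFrame,
                   method: str = "spearman", n_perm: int = 9999,
                   n_boot: int = 1000, alternative: str = "two-sided",
                   seed: int | None = None,
                   rng: np.random.Generator | None = None) -> MantelResult:
    """Partial Mantel test of ``a`` versus ``b`` controlling ``c``.

    The statistic is the correlation of the residual triangle vectors of
    ``a`` and ``b`` after regressing each on ``c`` (ranks first under
    Spearman).  Significance permutes the label order of ``a``;
    the confidence interval is a percentile bootstrap over label
    resampling.  A control matrix nearly collinear with ``b`` triggers a
    warning (the partial coefficient is then uninformative).
    """
    A, B, labels = _as_aligned(a, b)
    _, C, _ = _as_aligned(a, c)
    n = len(labels)
    if n < 4:
        raise RepscanError(f"need >= 4 labels for a Mantel test, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    y = _tri(B)
    z = _tri(C)
    if z.std() > 0 and y.std() > 0:
        ryz = _corr(y, z, method)
        if abs(ryz) > 0.999:
            warnings.warn("control matrix is collinear with B (|r| > 0.999)")
    r_obs = _partial_r(_tri(A), y, z, method)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _partial_r(_tri(A[np.ix_(perm, perm)]), y, z, method)
        if _one_sided_count(r_p, r_obs, alternative):
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    ci = None
    if n_boot > 0:
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if len(set(idx.tolist())) < 4:
                continue
            ta = _tri(A[np.ix_(idx, idx)])
            tb = _tri(B[np.ix_(idx, idx)])
            tc = _tri(C[np.ix_(idx, idx)])
            # duplicated labels index the undefined diagonal; drop those entries
            ok = np.isfinite(ta) & np.isfinite(tb) & np.isfinite(tc)
            if ok.sum() < 6:
                continue
            rb = _partial_r(ta[ok], tb[ok], tc[ok], method)
            if np.isfinite(rb):
                boots.append(rb)
        if len(boots) >= 20:
            lo, hi = np.percentile(boots, [2.5, 97.5])
            ci = (float(lo), float(hi))
    return MantelResult(r=r_obs, p=p, ci=ci, n_perm=n_perm)
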