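"""Cross-pair repeatability of windowed differentiation landscapes.

Two complementary views: (i) correlation matrices over harmonized window
sets, and (ii) overlap of outlier windows (upper 5% tail of F_ST, lower 5%
tail of d_XY) against a hypergeometric null in which every window is
equally likely to be an outlier.  Because adjacent outlier windows are not
independent, outliers can also be merged into peaks and the shared-peak
count tested by permuting peak locations while holding their number and
size constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import GenomeLayout, RepscanError, ValidationError, window_key
from .windowed_stats import harmonize

__all__ = [
    "OutlierSet",
    "OverlapResult",
    "Peak",
    "correlate_pairs",
    "variance_explained",
    "call_outliers",
    "overlap_test",
    "merge_peaks",
    "peak_overlap_permutation",
    "repeatability_count",
    "adjust_pvalues",
]

WindowID = tuple[str, int]


@dataclass(frozen=True)
class OutlierSet:
    """Outlier windows of one pair for one statistic and tail."""

    statistic: str
    tail: str  # "upper" or "lower"
    q: float
    members: frozenset
    universe: frozenset

    def __post_init__(self) -> None:
        if not self.members <= self.universe:
            raise ValidationError("outlier members must lie in the universe")


@dataclass(frozen=True)
class OverlapResult:
    """Observed vs hypergeometric-expected shared outliers for two pairs."""

    k: int
    expected: float
    z: float
    p_one_sided: float
    p_adjusted: float | None = None


@dataclass(frozen=True)
class Peak:
    """Maximal run of adjacent outlier windows on one chromosome.

    ``start_idx``/``end_idx`` are inclusive window indices (start // window
    size) on ``chrom``.
    """

    chrom: str
    start_idx: int
    end_idx: int

    @property
    def length(self) -> int:
        return self.end_idx - self.start_idx + 1


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def correlate_pairs(tables: Mapping[str, pd.DataFrame], statistic: str = "fst",
                    method: str = "pearson") -> pd.DataFrame:
    """Pairwise correlation matrix of windowed estimates across pairs.

    Tables are harmonized first: only windows non-missing in every
    contributing pair enter the correlations, so every entry is computed on
    the same window set.  Diagonal is NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    common, kept = harmonize(tables, statistic)
    if len(common) < 3:
        raise RepscanError(
            f"only {len(common)} common windows for {statistic}; need >= 3"
        )
    mat = pd.DataFrame({
        name: tables[name].set_index(window_key(tables[name]))
        .loc[common, statistic].to_numpy()
        for name in kept
    })
    corr = mat.corr(method=method)
    np.fill_diagonal(corr.values, np.nan)
    return corr


def variance_explained(matrix: pd.DataFrame,
                       triangle: str = "lower") -> tuple[float, int]:
    """Maximum off-diagonal coefficient and its square as a rounded percent.

    ``triangle`` selects which half of a matrix holding two statistics to
    read (by convention F_ST below the diagonal, d_XY above); ``"both"``
    scans all off-diagonal entries.
    """
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    if n == 0:
        raise RepscanError("empty matrix")
    if triangle == "lower":
        sel = values[np.tril_indices(n, k=-1)]
    elif triangle == "upper":
        sel = values[np.triu_indices(n, k=1)]
    elif triangle == "both":
        sel = values[~np.eye(n, dtype=bool)]
    else:
        raise ValueError(f"unknown triangle {triangle!r}")
    sel = sel[~np.isnan(sel)]
    if sel.size == 0:
        return 0.0, 0
    r = float(sel.max())
    return r, int(round(100 * r * r))


# ---------------------------------------------------------------------------
# outliers and overlap
# ---------------------------------------------------------------------------

def call_outliers(values: pd.Series, statistic: str, tail: str,
                  q: float = 0.05) -> OutlierSet:
    """Windows beyond the empirical ``q`` tail of one pair's distribution.

    The threshold is the order-statistic quantile (method "higher" for the
    upper tail, "lower" for the lower tail) so ties at the boundary are all
    included — the outlier fraction may therefore slightly exceed ``q``.
    The universe is the set of non-missing windows the values were computed
    on.
    """
    if tail not in ("upper", "lower"):
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    vals = values.dropna()
    if len(vals) < 20:
        raise RepscanError(f"need >= 20 non-missing windows, got {len(vals)}")
    universe = frozenset(vals.index)
    arr = vals.to_numpy(dtype=float)
    if np.ptp(arr) == 0:
        warnings.warn("constant values: no outliers called")
        members: frozenset = frozenset()
    elif tail == "upper":
        cut = np.quantile(arr, 1 - q, method="higher")
        members = frozenset(vals.index[arr >= cut])
    else:
        cut = np.quantile(arr, q, method="lower")
        members = frozenset(vals.index[arr <= cut])
    return OutlierSet(statistic, tail, q, members, universe)


def overlap_test(a: OutlierSet, b: OutlierSet) -> OverlapResult:
    """Observed vs expected shared outlier windows under a hypergeometric null.

    With universe size N and outlier counts a, b: E = ab/N,
    Var = ab(N-a)(N-b) / (N^2 (N-1)), z = (k-E)/sqrt(Var), and the one-sided
    p-value is P(X >= k) for X ~ Hypergeometric(N, a, b).
    """
    if a.universe != b.universe:
        raise ValidationError("outlier sets must share a universe")
    N = len(a.universe)
    if N == 0:
        raise RepscanError("empty universe")
    na, nb = len(a.members), len(b.members)
    k = len(a.members & b.members)
    expected = na * nb / N
    var = (na * nb * (N - na) * (N - nb)) / (N**2 * (N - 1)) if N > 1 else 0.0
    if var > 0:
        z = (k - expected) / np.sqrt(var)
    else:
        warnings.warn("degenerate overlap null (zero variance); z undefined")
        z = np.nan
    p = float(stats.hypergeom.sf(k - 1, N, na, nb))
    return OverlapResult(k=k, expected=expected, z=float(z), p_one_sided=min(p, 1.0))


def repeatability_count(outlier_sets: Mapping[str, OutlierSet]) -> pd.Series:
    """Per-window count of pairs in which the window is an outlier.

    All sets must live on the same harmonized universe; counts are bounded
    by the number of contributing pairs.
    """
    sets = list(outlier_sets.values())
    if not sets:
        raise RepscanError("no outlier sets given")
    universe = sets[0].universe
    for s in sets[1:]:
        if s.universe != universe:
            raise ValidationError("outlier sets must share a universe")
    idx = pd.MultiIndex.from_tuples(sorted(universe), names=["chrom", "start"])
    counts = pd.Series(0, index=idx, name="repeatability")
    for s in sets:
        if s.members:
            counts.loc[list(s.members)] += 1
    return counts


def adjust_pvalues(pvals: Sequence[float], method: str = "holm") -> np.ndarray:
    """Multiple-testing adjustment (Holm by default, Benjamini-Hochberg optional)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if ((arr < 0) | (arr > 1) | np.isnan(arr)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    key = {"holm": "holm", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(arr, method=key)[1]


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def merge_peaks(outliers: OutlierSet, layout: GenomeLayout) -> list[Peak]:
    """Merge adjacent outlier windows into maximal peaks per chromosome."""
    by_chrom: dict[str, list[int]] = {}
    ws = layout.window_size
    for chrom, start in outliers.members:
        by_chrom.setdefault(chrom, []).append(start // ws)
    peaks: list[Peak] = []
    for chrom in layout.names:
        idxs = sorted(by_chrom.get(chrom, []))
        if not idxs:
            continue
        run_start = prev = idxs[0]
        for i in idxs[1:]:
            if i == prev + 1:
                prev = i
                continue
            peaks.append(Peak(chrom, run_start, prev))
            run_start = prev = i
        peaks.append(Peak(chrom, run_start, prev))
    return peaks


def _count_intersecting(peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]) -> int:
    """Number of peaks in A overlapping at least one peak in B."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks_b:
        by_chrom.setdefault(p.chrom, []).append((p.start_idx, p.end_idx))
    count = 0
    for p in peaks_a:
        for s, e in by_chrom.get(p.chrom, ()):
            if p.start_idx <= e and s <= p.end_idx:
                count += 1
                break
    return count


def _shared_windows(peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]) -> int:
    """Number of windows covered by peaks of both sets."""
    cover_b: dict[str, set[int]] = {}
    for p in peaks_b:
        cover_b.setdefault(p.chrom, set()).update(range(p.start_idx, p.end_idx + 1))
    shared = 0
    for p in peaks_a:
        covered = cover_b.get(p.chrom)
        if covered:
            shared += sum(1 for i in range(p.start_idx, p.end_idx + 1) if i in covered)
    return shared


def _place_random(peaks: Sequence[Peak], layout: GenomeLayout,
                  rng: np.random.Generator) -> list[Peak]:
    """Randomly relocate peaks on their own chromosomes.

    Number and length of peaks are held constant; placements within a set
    are non-overlapping.  Sampling uses the compressed-coordinate trick:
    with blocks of total length L on W windows, offsets of the (shuffled)
    blocks are sorted iid draws from {0..W-L}.
    """
    by_chrom: dict[str, list[int]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p.length)
    placed: list[Peak] = []
    for chrom, lengths in by_chrom.items():
        W = layout.n_windows(chrom)
        free = W - sum(lengths)
        if free < 0:
            raise RepscanError(
                f"cannot place peaks totalling {sum(lengths)} windows on "
                f"{chrom} ({W} windows)"
            )
        lengths = [lengths[i] for i in rng.permutation(len(lengths))]
        offsets = np.sort(rng.integers(0, free + 1, size=len(lengths)))
        pos = 0
        for off_prev_len, (t, ln) in zip(np.cumsum([0] + lengths[:-1]),
                                         zip(offsets, lengths)):
            s = int(t + off_prev_len)
            placed.append(Peak(chrom, s, s + ln - 1))
    return placed


def peak_overlap_permutation(peaks_a: Sequence[Peak], peaks_b: Sequence[Peak],
                             layout: GenomeLayout, n_perm: int = 1000,
                             seed: int | None = None,
                             rng: np.random.Generator | None = None,
                             statistic: str = "intersecting") -> dict:
    """Permutation test for shared differentiation peaks.

    The observed statistic (by default the number of A-peaks intersecting
    any B-peak; ``statistic="shared_windows"`` counts shared windows
    instead) is compared with a null built by relocating every peak of both
    sets uniformly at random on its own chromosome, holding the number and
    size of peaks constant, ``n_perm`` times.  The one-sided p-value uses
    the add-one estimator ``(1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    stat = {"intersecting": _count_intersecting,
            "shared_windows": _shared_windows}[statistic]
    observed = stat(peaks_a, peaks_b)
    geq = 0
    eq = 0
    for _ in range(n_perm):
        pa = _place_random(peaks_a, layout, rng)
        pb = _place_random(peaks_b, layout, rng)
        s = stat(pa, pb)
        if s >= observed:
            geq += 1
            if s == observed:
                eq += 1
    p = (1 + geq) / (n_perm + 1)
    return {"observed_shared": observed, "p_one_sided": p,
            "n_perm": n_perm, "n_geq": geq, "n_eq": eq}
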