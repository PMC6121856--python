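"""Per-window differentiation statistics from per-site allele counts.

Relative differentiation (F_ST) uses Hudson's estimator with sample-size
correction, combined per window as a ratio of averages (sum of per-site
numerators over sum of per-site denominators).  Absolute differentiation
(d_XY) is the per-SNP quantity ``p1*(1-p2) + p2*(1-p1)`` summed over the
SNPs of a window and normalized by the number of callable sites (variant
and invariant) in that window.  Windows with too few callable sites are
reported as missing because d_XY is highly variable at low coverage.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .io_core import GenomeLayout, RepscanError, ValidationError, window_key

__all__ = [
    "dxy_site",
    "fst_site",
    "window_fst",
    "callable_sites",
    "window_dxy",
    "window_ld",
    "harmonize",
]

DEFAULT_MIN_DXY_SITES = 5000


def dxy_site(p1, p2):
    """Per-site absolute differentiation ``p1*(1-p2) + p2*(1-p1)``.

    Accepts scalars or arrays; symmetric in its arguments and bounded in
    [0, 1] for frequencies in [0, 1].
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if ((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)).any():
        raise ValidationError("allele frequencies must lie in [0, 1]")
    out = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return float(out) if out.ndim == 0 else out


def fst_site(ac1, n1, ac2, n2):
    """Hudson per-site F_ST components with sample-size correction.

    numerator   = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)

    Sites with fewer than two sampled alleles in either population carry no
    information about within-population variance and are returned as NaN
    components (callers drop them with a warning).
    """
    ac1 = np.asarray(ac1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    ac2 = np.asarray(ac2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = ac1 / n1
        p2 = ac2 / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(valid, num, np.nan)
    den = np.where(valid, den, np.nan)
    if num.ndim == 0:
        return float(num), float(den)
    return num, den


def window_fst(sites: pd.DataFrame, layout: GenomeLayout,
               clamp_negative: bool = False) -> pd.DataFrame:
    """Hudson F_ST per window: ratio of averages over the SNPs of each window.

    Returns a table over *all* layout windows with columns ``fst`` and
    ``n_snps``; windows with no SNPs, or with zero summed denominator, are
    missing.  Negative window values are retained unless ``clamp_negative``
    (they carry rank information used downstream).
    """
    win = layout.windows().set_index(["chrom", "start"])
    fst = pd.Series(np.nan, index=win.index, name="fst")
    n_snps = pd.Series(0, index=win.index, name="n_snps")
    if len(sites):
        num, den = fst_site(sites["ac1"], sites["n1"], sites["ac2"], sites["n2"])
        skipped = np.isnan(num)
        if skipped.any():
            warnings.warn(f"skipped {int(skipped.sum())} sites with n < 2")
        starts = np.concatenate([
            layout.assign_starts(chrom, sub["pos"].to_numpy())
            for chrom, sub in sites.groupby("chrom", sort=False)
        ])
        df = pd.DataFrame({
            "chrom": sites["chrom"].to_numpy(), "start": starts,
            "num": num, "den": den,
        }).dropna(subset=["num"])
        grp = df.groupby(["chrom", "start"])
        sums = grp[["num", "den"]].sum()
        counts = grp.size()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = sums["num"] / sums["den"]
        ratio[sums["den"] == 0] = np.nan
        fst.loc[ratio.index] = ratio
        n_snps.loc[counts.index] = counts
    if clamp_negative:
        fst = fst.clip(lower=0.0)
    out = win.copy()
    out["fst"] = fst
    out["n_snps"] = n_snps
    return out.reset_index()[["chrom", "start", "end", "fst", "n_snps"]]


def callable_sites(depth: pd.DataFrame, sample_size: int,
                   layout: GenomeLayout) -> pd.Series:
    """Count callable sites per window from a per-site depth table.

    A site is callable when ``3 * sample_size <= depth <= 3 * mean_depth``,
    with the mean taken over all sites of the dataset.  The lower bound
    targets roughly three reads per individual; the upper bound discards
    likely collapsed repeats / copy-number artefacts.
    """
    if depth.empty:
        raise RepscanError("empty depth table")
    mean_depth = depth["depth"].mean()
    lo, hi = 3 * sample_size, 3 * mean_depth
    ok = depth[(depth["depth"] >= lo) & (depth["depth"] <= hi)]
    counts = pd.Series(0, index=layout.window_index(), name="n_callable")
    if len(ok):
        starts = np.concatenate([
            layout.assign_starts(chrom, sub["pos"].to_numpy())
            for chrom, sub in ok.groupby("chrom", sort=False)
        ])
        per_win = pd.DataFrame({"chrom": ok["chrom"].to_numpy(), "start": starts}) \
            .groupby(["chrom", "start"]).size()
        counts.loc[per_win.index] = per_win
    return counts


def window_dxy(sites: pd.DataFrame, callable_profile: pd.Series,
               layout: GenomeLayout,
               min_sites: int = DEFAULT_MIN_DXY_SITES) -> pd.DataFrame:
    """d_XY per window: summed per-SNP d_XY over the callable-site count.

    Windows whose callable count is ``<= min_sites`` are missing.  A SNP in
    a window with zero callable sites is an inconsistency (the SNP itself
    must have been callable) and raises.
    """
    win = layout.windows().set_index(["chrom", "start"])
    callable_profile = callable_profile.reindex(win.index, fill_value=0)
    dxy_sum = pd.Series(0.0, index=win.index)
    if len(sites):
        vals = dxy_site(sites["ac1"] / sites["n1"], sites["ac2"] / sites["n2"])
        starts = np.concatenate([
            layout.assign_starts(chrom, sub["pos"].to_numpy())
            for chrom, sub in sites.groupby("chrom", sort=False)
        ])
        sums = pd.DataFrame({
            "chrom": sites["chrom"].to_numpy(), "start": starts, "dxy": vals,
        }).groupby(["chrom", "start"])["dxy"].sum()
        bad = callable_profile.loc[sums.index] == 0
        if bad.any():
            chrom, start = sums.index[bad.to_numpy()][0]
            raise RepscanError(
                f"SNPs present in window {chrom}:{start} with zero callable sites"
            )
        dxy_sum.loc[sums.index] = sums
    with np.errstate(divide="ignore", invalid="ignore"):
        dxy = dxy_sum / callable_profile.astype(float)
    dxy[callable_profile <= min_sites] = np.nan
    out = win.copy()
    out["dxy"] = dxy
    out["n_callable"] = callable_profile
    return out.reset_index()[["chrom", "start", "end", "dxy", "n_callable"]]


def window_ld(pairs: pd.DataFrame, layout: GenomeLayout,
              max_kb: float = 100.0, maf: float = 0.05) -> pd.Series:
    """Mean r^2 per window from a SNP-pair LD table.

    Each SNP pair is assigned to the window containing the midpoint of its
    two positions; pairs farther apart than ``max_kb`` kilobases are
    excluded.  If the table carries ``maf1``/``maf2`` columns, pairs with a
    minor allele frequency at or below ``maf`` are excluded; otherwise the
    MAF filter is assumed to have been applied upstream.
    """
    df = pairs.copy()
    df = df[(df["pos2"] - df["pos1"]).abs() <= max_kb * 1000]
    if {"maf1", "maf2"}.issubset(df.columns):
        df = df[(df["maf1"] > maf) & (df["maf2"] > maf)]
    out = pd.Series(np.nan, index=layout.window_index(), name="mean_ld")
    if df.empty:
        return out
    mid = ((df["pos1"] + df["pos2"]) // 2).to_numpy()
    starts = np.concatenate([
        layout.assign_starts(chrom, mid[(df["chrom"] == chrom).to_numpy()])
        for chrom in df["chrom"].unique()
    ])
    order = np.concatenate([
        np.flatnonzero((df["chrom"] == chrom).to_numpy())
        for chrom in df["chrom"].unique()
    ])
    means = pd.DataFrame({
        "chrom": df["chrom"].to_numpy()[order],
        "start": starts,
        "r2": df["r2"].to_numpy()[order],
    }).groupby(["chrom", "start"])["r2"].mean()
    out.loc[means.index] = means
    return out


def harmonize(tables: Mapping[str, pd.DataFrame],
              statistic: str) -> tuple[pd.MultiIndex, list[str]]:
    """Common non-missing window set across population pairs, per statistic.

    Pairs whose table lacks the statistic entirely (e.g. no d_XY for a
    reduced-representation dataset) are dropped from that statistic's
    analyses with a warning.  Returns the intersection index and the list
    of retained pair names.  Disjoint window sets raise.
    """
    if len(tables) < 2:
        raise RepscanError("harmonize needs at least two pair tables")
    kept: list[str] = []
    common: pd.MultiIndex | None = None
    universe: pd.MultiIndex | None = None
    for name, df in tables.items():
        key = window_key(df)
        universe = key if universe is None else universe.intersection(key)
        if statistic not in df.columns or df[statistic].isna().all():
            warnings.warn(f"pair {name!r} has no {statistic} data; dropped "
                          f"from {statistic} analyses")
            continue
        ok = key[df[statistic].notna().to_numpy()]
        common = ok if common is None else common.intersection(ok)
        kept.append(name)
    if universe is not None and len(universe) == 0:
        raise RepscanError("window tables are on disjoint layouts")
    if common is None:
        common = pd.MultiIndex.from_arrays([[], []], names=["chrom", "start"])
    if len(common) == 0:
        warnings.warn(f"no common non-missing windows for {statistic}")
    return common.sortlevel([0, 1])[0], kept
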