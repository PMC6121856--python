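"""Genomic-feature predictors of repeatability via Poisson regression.

Per-window repeatability counts (the number of pairs in which a window is
an outlier) are modelled as a Poisson response with log link on scaled
genomic features: GC fraction (recombination proxy), synonymous
substitution rate d_s (mutation proxy), gene count, mean LD r^2,
chromosome size class (micro < 20 Mb vs macro > 40 Mb), standardized
position toward the chromosome center, and centromere overlap.  One model
is fitted per species pair's feature set; the response is shared across
models, so the fits are not mutually independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io_core import GenomeLayout, RepscanError, ValidationError

__all__ = [
    "GlmFit",
    "position_index",
    "size_class",
    "size_class_series",
    "centromere_flag",
    "fit_repeatability_glm",
    "CONTINUOUS_FEATURES",
]

MICRO_MAX_BP = 20_000_000
MACRO_MIN_BP = 40_000_000

CONTINUOUS_FEATURES = ["gc", "ds", "gene_count", "ld", "position"]


@dataclass
class GlmFit:
    """Per-predictor estimates with deviance significance and model fit.

    ``table`` holds one row per term (scaled estimate, standard error,
    deviance p-value); ``model_fit_r`` is the Pearson correlation between
    observed counts and fitted means.
    """

    table: pd.DataFrame
    model_fit_r: float
    n_obs: int
    degenerate: bool = False
    notes: list = field(default_factory=list)
    result: object = None


# ---------------------------------------------------------------------------
# positional predictors
# ---------------------------------------------------------------------------

def position_index(layout: GenomeLayout) -> pd.Series:
    """Standardized window position: rises from the chromosome ends to 1 at
    the center.

    The k-th window from the nearer end scores ``k / ceil(W/2)`` on a
    chromosome of W windows, so the measure is symmetric about the center.
    """
    out = {}
    for chrom, _ in layout.chromosomes:
        W = layout.n_windows(chrom)
        half = -(-W // 2)
        for j in range(W):
            k = min(j, W - 1 - j) + 1
            out[(chrom, j * layout.window_size)] = k / half
    s = pd.Series(out, name="position")
    s.index = pd.MultiIndex.from_tuples(s.index, names=["chrom", "start"])
    return s


def size_class(length_bp: int | float) -> str:
    """Chromosome size class: micro (< 20 Mb), macro (> 40 Mb) or intermediate."""
    if length_bp <= 0:
        raise ValidationError("chromosome length must be positive")
    if length_bp < MICRO_MAX_BP:
        return "micro"
    if length_bp > MACRO_MIN_BP:
        return "macro"
    return "intermediate"


def size_class_series(layout: GenomeLayout) -> pd.Series:
    """Per-window size class of the hosting chromosome."""
    classes = {chrom: size_class(length) for chrom, length in layout.chromosomes}
    idx = layout.window_index()
    return pd.Series([classes[c] for c, _ in idx], index=idx, name="size_class")


def centromere_flag(layout: GenomeLayout, centromeres: pd.DataFrame,
                    mode: str = "indicator") -> pd.Series:
    """Centromere predictor per window.

    ``indicator`` (default): 1 if the window overlaps a centromeric
    interval, else 0.  ``proximity``: 1 minus the distance from the window
    midpoint to the nearest centromeric interval, standardized by half the
    chromosome length (1 inside an interval, falling toward 0 at the far
    end); chromosomes with no interval score 0 throughout.
    """
    win = layout.windows()
    vals = np.zeros(len(win))
    for chrom, sub in centromeres.groupby("chrom"):
        mask = (win["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = win.loc[mask, "start"].to_numpy()
        ends = win.loc[mask, "end"].to_numpy()
        if mode == "indicator":
            hit = np.zeros(mask.sum(), dtype=bool)
            for _, iv in sub.iterrows():
                hit |= (starts < iv["end"]) & (iv["start"] < ends)
            vals[mask] = hit.astype(float)
        elif mode == "proximity":
            mid = (starts + ends) / 2.0
            dist = np.full(mask.sum(), np.inf)
            for _, iv in sub.iterrows():
                d = np.where((mid >= iv["start"]) & (mid < iv["end"]), 0.0,
                             np.minimum(np.abs(mid - iv["start"]),
                                        np.abs(mid - iv["end"])))
                dist = np.minimum(dist, d)
            half = layout.length(chrom) / 2.0
            vals[mask] = np.clip(1.0 - dist / half, 0.0, 1.0)
        else:
            raise ValueError(f"unknown centromere mode {mode!r}")
    idx = pd.MultiIndex.from_arrays([win["chrom"], win["start"]],
                                    names=["chrom", "start"])
    return pd.Series(vals, index=idx, name="centromere")


# ---------------------------------------------------------------------------
# the GLM
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def fit_repeatability_glm(counts: pd.Series, features: pd.DataFrame,
                          predictors: list[str] | None = None,
                          deviance: str = "sequential",
                          include_intermediate: bool = False) -> GlmFit:
    """Poisson GLM of repeatability counts on scaled genomic features.

    Continuous predictors are z-scored so estimates are per-SD effects on
    the log mean; ``size_class`` enters as a macro-vs-micro indicator
    (windows on intermediate chromosomes are excluded unless
    ``include_intermediate``, which adds a separate level); ``centromere``
    enters as given (0/1 indicator or proximity score).  Per-predictor
    significance is an analysis-of-deviance chi-square, sequential
    (type-I, in predictor order) by default or ``deviance="marginal"`` for
    drop-one tests.  ``model_fit_r`` correlates observed counts with
    fitted means.
    """
    if predictors is None:
        predictors = [c for c in CONTINUOUS_FEATURES if c in features.columns]
        if "size_class" in features.columns:
            predictors.append("size_class")
        if "centromere" in features.columns:
            predictors.append("centromere")
    df = features.copy()
    df["_y"] = counts
    df = df.dropna(subset=["_y"] + [p for p in predictors if p != "size_class"])
    notes: list[str] = []
    y = df["_y"].to_numpy(dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValidationError("repeatability counts must be non-negative integers")

    # build design columns per term
    term_cols: dict[str, np.ndarray] = {}
    if "size_class" in predictors:
        sc = df["size_class"].astype(str)
        if include_intermediate:
            keep = sc.isin(["micro", "macro", "intermediate"])
        else:
            keep = sc.isin(["micro", "macro"])
            dropped = int((~keep).sum())
            if dropped:
                notes.append(f"excluded {dropped} windows on intermediate "
                             f"chromosomes from the size contrast")
        df = df[keep]
        y = df["_y"].to_numpy(dtype=float)
    for term in predictors:
        if term == "size_class":
            sc = df["size_class"].astype(str)
            term_cols["size_macro"] = (sc == "macro").to_numpy(dtype=float)
            if include_intermediate:
                term_cols["size_intermediate"] = \
                    (sc == "intermediate").to_numpy(dtype=float)
        elif term in CONTINUOUS_FEATURES:
            term_cols[term] = _zscore(df[term].to_numpy(dtype=float))
        else:  # indicator-like terms (centromere) enter unscaled
            term_cols[term] = df[term].to_numpy(dtype=float)

    n = len(y)
    k = len(term_cols)
    if n < 10 * max(k, 1):
        raise RepscanError(f"need >= {10 * k} complete rows for {k} predictors, "
                           f"got {n}")
    X = np.column_stack([np.ones(n)] + list(term_cols.values()))
    cond = np.linalg.cond(X)
    if cond > 1e8:
        warnings.warn(f"ill-conditioned design (condition number {cond:.2g})")
        notes.append(f"condition number {cond:.2g}")

    if y.max() == 0:
        # IRLS cannot converge on an all-zero response; report the
        # intercept-only degenerate fit explicitly
        warnings.warn("all repeatability counts are zero: intercept-only "
                      "degenerate fit")
        table = pd.DataFrame({"term": list(term_cols.keys()),
                              "estimate": np.nan, "se": np.nan, "p": np.nan})
        return GlmFit(table=table, model_fit_r=np.nan, n_obs=n,
                      degenerate=True, notes=notes)
    degenerate = False

    def _fit(cols: list[str]):
        Xc = np.column_stack([np.ones(n)] + [term_cols[c] for c in cols])
        return sm.GLM(y, Xc, family=sm.families.Poisson()).fit()

    names = list(term_cols.keys())
    full = _fit(names)
    fitted = np.asarray(full.fittedvalues)
    if np.std(fitted) == 0 or np.std(y) == 0:
        model_fit_r = np.nan
    else:
        model_fit_r = float(np.corrcoef(y, fitted)[0, 1])

    rows = []
    for i, name in enumerate(names):
        est = full.params[i + 1]
        se = full.bse[i + 1]
        if deviance == "sequential":
            prev = _fit(names[:i])
            cur = _fit(names[:i + 1])
            pval = float(sps.chi2.sf(prev.deviance - cur.deviance, 1))
        elif deviance == "marginal":
            reduced = _fit([c for c in names if c != name])
            pval = float(sps.chi2.sf(reduced.deviance - full.deviance, 1))
        else:
            raise ValueError(f"unknown deviance scheme {deviance!r}")
        rows.append({"term": name, "estimate": float(est), "se": float(se),
                     "p": pval})
    table = pd.DataFrame(rows)
    return GlmFit(table=table, model_fit_r=model_fit_r, n_obs=n,
                  degenerate=degenerate, notes=notes, result=full)
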