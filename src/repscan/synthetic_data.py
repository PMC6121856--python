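"""Synthetic multi-pair genomic landscapes with planted shared structure.

The generator is phenomenological: it draws per-window differentiation
fields directly rather than simulating coalescent histories, because the
downstream analyses consume window statistics.  A latent "constraint"
field L — a planted linear combination of smooth genomic features (gene
count +, GC −, centromere +, central position +) — stands in for the
conserved landscape that linked selection acts on:

* pair ``p``'s F_ST field on the logit scale is
  ``s_p * w * L + sqrt(1 - w^2) * eps_p``; the shared weight ``w`` sets how
  much of the landscape is common, and the divergence stage ``s_p in (0,1]``
  modulates how strongly an individual pair expresses it, so cross-pair
  F_ST correlations grow along the speciation continuum;
* the d_XY field is ``baseline * (1 - d_w * max(L, 0)) + noise``, identical
  in expectation across pairs and independent of stage, so low-d_XY
  outliers co-locate in all pairs regardless of how far along they are —
  absolute divergence carries the imprint of recurrent ancestral processes
  rather than of the current episode of divergence.

An optional Balding–Nichols site layer turns window F_ST targets into
per-site allele counts for estimator tests, and a metadata generator maps
stages onto continuum proxies (hybrid-zone width 600 km at stage 0 down to
0 km at stage 1, percent hybrids 70% down to 0%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter1d

from .features_glm import centromere_flag, position_index, size_class_series
from .io_core import GenomeLayout, RepscanError, ValidationError

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_layout_features",
    "simulate_pair_landscapes",
    "simulate_site_counts",
    "simulate_continuum_metadata",
    "simulate_all",
]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic landscape generator.

    Defaults emulate the study conditions of an eight-pair comparative
    songbird scan: 100-kb windows on a mix of macro- (50–150 Mb) and
    micro- (5–19 Mb) chromosomes, genome-wide F_ST baseline around 0.1,
    d_XY around 0.01 per site, stages spread along the speciation
    continuum, and continuum proxies spanning 0–600 km hybrid-zone width
    and 0–70% hybrids.
    """

    seed: int = 0
    n_pairs: int = 8
    n_macro: int = 3
    n_micro: int = 5
    macro_len_range: tuple = (50_000_000, 150_000_000)
    micro_len_range: tuple = (5_000_000, 19_000_000)
    window_size: int = 100_000
    autocorr_scale: float = 10.0    # windows; 0 -> white-noise features
    micro_gc_offset: float = 0.03   # microchromosomes are more GC-rich
    gc_ds_corr: float = 0.5         # d_s tracks GC (both follow recombination)
    mean_gene_count: float = 2.0    # genes per 100-kb window
    shared_weight: float = 0.6      # w in [0, 1]
    stages: tuple | None = None     # defaults to linspace(0.2, 1, n_pairs)
    baseline_fst: float = 0.1
    fst_logit_scale: float = 0.6
    dxy_baseline: float = 0.01
    dxy_weight: float = 0.5         # d_w in [0, 1]
    dxy_noise_sd: float = 0.002
    feature_coefs: Mapping = field(default_factory=lambda: {
        "gene_count": 1.0, "gc": -1.0, "centromere": 0.8, "position": 0.6,
    })
    no_dxy_pair: str | None = None  # emulate a pair lacking d_XY coverage
    n_callable: int = 50_000        # callable sites reported per window
    # Balding–Nichols site layer
    snps_per_window: int = 200
    n_alleles: int = 50             # sampled allele copies per population
    sample_size: int = 25           # individuals (drives the depth filter)
    # continuum proxies
    width_max_km: float = 600.0
    pct_hybrids_max: float = 70.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_weight <= 1.0:
            raise ValidationError("shared_weight must lie in [0, 1]")
        if not 0.0 <= self.dxy_weight <= 1.0:
            raise ValidationError("dxy_weight must lie in [0, 1]")
        for s in self.stage_vector():
            if not 0.0 < s <= 1.0:
                raise ValidationError("stages must lie in (0, 1]")

    def stage_vector(self) -> np.ndarray:
        if self.stages is not None:
            return np.asarray(self.stages, dtype=float)
        return np.linspace(0.2, 1.0, self.n_pairs)

    def pair_names(self) -> list[str]:
        return [f"pair{i + 1:02d}" for i in range(self.n_pairs)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("stages", "macro_len_range", "micro_len_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimTruth:
    """Ground truth stored alongside simulated outputs for recovery tests."""

    latent: pd.Series                 # constraint field L per window
    feature_coefs: dict
    stages: dict                      # pair -> stage
    shared_weight: float
    fst_target: pd.DataFrame          # noise-free logit-scale shared component
    dxy_shared: pd.Series             # shared d_XY component


# ---------------------------------------------------------------------------
# layout + features
# ---------------------------------------------------------------------------

def _smooth_field(n: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian field with autocorrelation length ``scale``."""
    raw = rng.standard_normal(n)
    if scale <= 0 or n < 3:
        return raw
    sm = gaussian_filter1d(raw, sigma=scale, mode="nearest")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def simulate_layout_features(config: SimConfig,
                             rng: np.random.Generator | None = None
                             ) -> tuple[GenomeLayout, pd.DataFrame]:
    """Draw a genome layout and smooth per-window genomic features.

    Macro chromosomes get one centromeric interval each; microchromosomes
    are more GC-rich by ``micro_gc_offset``; d_s is positively correlated
    with GC (both track recombination in birds).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = []
    for i in range(config.n_macro):
        length = int(rng.integers(*config.macro_len_range))
        chroms.append((f"chr{i + 1}", length))
    for i in range(config.n_micro):
        length = int(rng.integers(*config.micro_len_range))
        chroms.append((f"chr{config.n_macro + i + 1}", length))
    layout = GenomeLayout(tuple(chroms), config.window_size)

    cent_rows = []
    gc_parts, gene_parts, ds_parts, ld_parts = [], [], [], []
    for chrom, length in layout.chromosomes:
        W = layout.n_windows(chrom)
        f_gc = _smooth_field(W, config.autocorr_scale, rng)
        f_gene = _smooth_field(W, config.autocorr_scale, rng)
        f_ld = _smooth_field(W, config.autocorr_scale, rng)
        is_micro = length < 20_000_000
        gc = 0.42 + (config.micro_gc_offset if is_micro else 0.0) + 0.04 * f_gc
        gc_parts.append(np.clip(gc, 0.2, 0.8))
        lam = config.mean_gene_count * np.exp(0.5 * f_gene)
        gene_parts.append(rng.poisson(lam))
        ds_noise = rng.standard_normal(W)
        ds = 0.05 * np.exp(0.3 * (config.gc_ds_corr * f_gc
                                  + np.sqrt(max(0.0, 1 - config.gc_ds_corr**2))
                                  * ds_noise))
        ds_parts.append(ds)
        ld_parts.append(np.clip(0.25 + 0.08 * f_ld, 0.01, 0.99))
        if length > 40_000_000:
            mid = length // 2
            half_w = int(rng.integers(5, 16)) * config.window_size
            cent_rows.append({"chrom": chrom,
                              "start": max(0, mid - half_w),
                              "end": min(length, mid + half_w)})
    centromeres = pd.DataFrame(cent_rows, columns=["chrom", "start", "end"])

    idx = layout.window_index()
    feats = pd.DataFrame({
        "gc": np.concatenate(gc_parts),
        "gene_count": np.concatenate(gene_parts),
        "ds": np.concatenate(ds_parts),
        "ld": np.concatenate(ld_parts),
    }, index=idx)
    feats["position"] = position_index(layout)
    feats["size_class"] = size_class_series(layout)
    feats["centromere"] = centromere_flag(layout, centromeres)
    feats.attrs["centromeres"] = centromeres
    return layout, feats


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def simulate_pair_landscapes(layout: GenomeLayout, features: pd.DataFrame,
                             config: SimConfig,
                             rng: np.random.Generator | None = None
                             ) -> tuple[dict, SimTruth]:
    """Per-pair window F_ST / d_XY tables with planted shared structure.

    Returns ``(tables, truth)`` where ``tables`` maps pair name to a
    window table (chrom, start, end, fst, dxy, n_callable) and ``truth``
    records the latent field, coefficients and stages.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    w = config.shared_weight
    stages = config.stage_vector()
    names = config.pair_names()

    def z(col):
        x = features[col].to_numpy(dtype=float)
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    L = np.zeros(len(features))
    for feat, coef in config.feature_coefs.items():
        if feat == "centromere":
            L += coef * features[feat].to_numpy(dtype=float)
        else:
            L += coef * z(feat)
    sd = L.std()
    if sd > 0:
        L = (L - L.mean()) / sd
    latent = pd.Series(L, index=features.index, name="latent")

    n_win = len(L)
    base_logit = _logit(config.baseline_fst)
    Lpos = np.clip(L, 0.0, None)
    dxy_shared = config.dxy_baseline * (1.0 - config.dxy_weight * Lpos)

    tables: dict[str, pd.DataFrame] = {}
    target = {}
    win = layout.windows()
    for name, s in zip(names, stages):
        eps = rng.standard_normal(n_win)
        zfield = s * w * L + np.sqrt(1.0 - w**2) * eps
        fst = 1.0 / (1.0 + np.exp(-(base_logit + config.fst_logit_scale * zfield)))
        dxy = np.clip(dxy_shared + config.dxy_noise_sd * rng.standard_normal(n_win),
                      0.0, None)
        tbl = win.copy()
        tbl["fst"] = fst
        tbl["dxy"] = dxy
        tbl["n_callable"] = config.n_callable
        if config.no_dxy_pair == name:
            tbl["dxy"] = np.nan
        tables[name] = tbl
        target[name] = s * w * L
    truth = SimTruth(latent=latent, feature_coefs=dict(config.feature_coefs),
                     stages=dict(zip(names, stages)), shared_weight=w,
                     fst_target=pd.DataFrame(target, index=features.index),
                     dxy_shared=pd.Series(dxy_shared, index=features.index))
    return tables, truth


# ---------------------------------------------------------------------------
# Balding–Nichols site layer
# ---------------------------------------------------------------------------

def simulate_site_counts(fst_targets: pd.Series, layout: GenomeLayout,
                         config: SimConfig,
                         rng: np.random.Generator | None = None,
                         dense_depth: bool = False
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site allele counts under the Balding–Nichols model.

    For each window with target differentiation F, SNP ancestral
    frequencies are Uniform(0.05, 0.95); each population's frequency is
    Beta(p(1-F)/F, (1-p)(1-F)/F) (mean p, variance F p(1-p)), and counts
    are Binomial draws of ``n_alleles`` copies.  The depth table is a
    uniform field passing the callable filter, emitted at SNP positions
    (or at every base with ``dense_depth``, for small layouts only).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if (fst_targets >= 1.0).any() or (fst_targets < 0.0).any():
        raise ValidationError("window F_ST targets must lie in [0, 1)")
    n = config.n_alleles
    rows = []
    for (chrom, start), F in fst_targets.items():
        end = min(start + layout.window_size, layout.length(chrom))
        m = min(config.snps_per_window, end - start)
        pos = np.sort(rng.choice(np.arange(start + 1, end + 1), size=m,
                                 replace=False))
        p_anc = rng.uniform(0.05, 0.95, size=m)
        if F > 1e-12:
            shape = (1.0 - F) / F
            p1 = rng.beta(p_anc * shape, (1 - p_anc) * shape)
            p2 = rng.beta(p_anc * shape, (1 - p_anc) * shape)
        else:
            p1 = p2 = p_anc
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "ac1": rng.binomial(n, p1), "n1": n,
            "ac2": rng.binomial(n, p2), "n2": n,
        }))
    sites = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["chrom", "pos", "ac1", "n1", "ac2", "n2"]))
    # depth uniform in a band that passes both callable bounds
    lo = 3 * config.sample_size
    if dense_depth:
        dep_rows = []
        for chrom, length in layout.chromosomes:
            pos = np.arange(1, length + 1)
            dep_rows.append(pd.DataFrame({
                "chrom": chrom, "pos": pos,
                "depth": rng.integers(lo, lo + 10, size=length),
            }))
        depth = pd.concat(dep_rows, ignore_index=True)
    else:
        depth = sites[["chrom", "pos"]].copy()
        depth["depth"] = rng.integers(lo, lo + 10, size=len(sites))
    return sites, depth


# ---------------------------------------------------------------------------
# continuum metadata
# ---------------------------------------------------------------------------

def _random_ultrametric(labels: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Random ultrametric-style distance matrix via random pair coalescence."""
    clusters = [[i] for i in range(len(labels))]
    height = 0.0
    D = np.zeros((len(labels), len(labels)))
    while len(clusters) > 1:
        height += float(rng.exponential(1.0))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                D[a, b] = D[b, a] = 2.0 * height
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return pd.DataFrame(D, index=labels, columns=labels)


def simulate_continuum_metadata(config: SimConfig,
                                rng: np.random.Generator | None = None
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Continuum proxies per pair plus a random phylogenetic control matrix.

    Hybrid-zone width shrinks linearly from ``width_max_km`` at stage 0 to
    0 at stage 1; percent hybrids likewise from ``pct_hybrids_max``;
    genetic distances (cytochrome-b p-distance, autosomal tree distance)
    grow linearly with stage.  The control matrix mimics patristic
    distances among the focal taxa and is independent of stage.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    stages = config.stage_vector()
    names = config.pair_names()
    meta = pd.DataFrame({
        "pair": names,
        "stage": stages,
        "width_km": config.width_max_km * (1.0 - stages),
        "pct_hybrids": config.pct_hybrids_max * (1.0 - stages),
        "cytb_pdist": 0.01 + 0.09 * stages,
        "auto_dist": 0.02 + 0.18 * stages,
    }).set_index("pair")
    control = _random_ultrametric(names, rng)
    return meta, control


def simulate_all(config: SimConfig) -> dict:
    """One-call convenience: layout, features, landscapes, metadata, truth."""
    rng = np.random.default_rng(config.seed)
    layout, features = simulate_layout_features(config, rng)
    tables, truth = simulate_pair_landscapes(layout, features, config, rng)
    meta, control = simulate_continuum_metadata(config, rng)
    return {"layout": layout, "features": features, "tables": tables,
            "truth": truth, "metadata": meta, "control": control}
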