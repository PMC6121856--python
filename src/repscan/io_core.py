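"""Shared I/O, coordinate conventions and window arithmetic.

Conventions used throughout the package:

* input site positions are 1-based (VCF convention);
* windows are stored 0-based, half-open ``[start, start + window_size)``
  (BED convention), keyed by ``(chrom, start)``;
* missing statistics are serialized as ``"NA"`` and held as NaN in memory;
* chromosome order is the order of the layout file, never lexicographic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("repscan")

__all__ = [
    "RepscanError",
    "ParseError",
    "ValidationError",
    "GenomeLayout",
    "SiteAlleleCounts",
    "read_site_counts",
    "read_depth_table",
    "read_r2_table",
    "read_feature_table",
    "read_centromeres",
    "read_window_table",
    "write_window_table",
    "read_pair_matrix",
    "write_pair_matrix",
    "load_config",
]


class RepscanError(Exception):
    """Base class for package errors."""


class ParseError(RepscanError):
    """A file could not be parsed; carries the offending line number."""


class ValidationError(RepscanError):
    """Parsed values violate a domain invariant."""


@dataclass(frozen=True)
class SiteAlleleCounts:
    """Allele counts at one biallelic site for a pair of populations.

    ``ac1``/``ac2`` count the alternate allele out of ``n1``/``n2`` sampled
    allele copies.  Frequencies are exposed as ``p1`` and ``p2``.
    """

    chrom: str
    pos: int  # 1-based
    ac1: int
    n1: int
    ac2: int
    n2: int
    depth: int | None = None

    def __post_init__(self) -> None:
        for ac, n, label in ((self.ac1, self.n1, "1"), (self.ac2, self.n2, "2")):
            if n <= 0:
                raise ValidationError(
                    f"{self.chrom}:{self.pos}: sample size n{label}={n} must be > 0"
                )
            if not 0 <= ac <= n:
                raise ValidationError(
                    f"{self.chrom}:{self.pos}: allele count ac{label}={ac} "
                    f"outside [0, {n}]"
                )

    @property
    def p1(self) -> float:
        return self.ac1 / self.n1

    @property
    def p2(self) -> float:
        return self.ac2 / self.n2


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths, partitioned into fixed-size windows.

    The last window of a chromosome may be shorter than ``window_size``.
    """

    chromosomes: tuple[tuple[str, int], ...]
    window_size: int = 100_000
    _lengths: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValidationError("window_size must be positive")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length")
        object.__setattr__(self, "_lengths", dict(self.chromosomes))

    # -- basic accessors -------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def n_windows(self, chrom: str) -> int:
        return -(-self.length(chrom) // self.window_size)  # ceil division

    def chrom_rank(self, chrom: str) -> int:
        return self.names.index(chrom)

    # -- window arithmetic -----------------------------------------------

    def assign_window(self, chrom: str, pos: int) -> tuple[str, int]:
        """Window ``(chrom, start)`` containing 1-based position ``pos``."""
        length = self.length(chrom)
        if not 1 <= pos <= length:
            raise ValidationError(
                f"position {chrom}:{pos} outside chromosome (length {length})"
            )
        start = ((pos - 1) // self.window_size) * self.window_size
        return (chrom, start)

    def assign_starts(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Vectorized window starts for an array of 1-based positions."""
        pos = np.asarray(pos)
        length = self.length(chrom)
        if pos.size and (pos.min() < 1 or pos.max() > length):
            bad = pos[(pos < 1) | (pos > length)][0]
            raise ValidationError(
                f"position {chrom}:{bad} outside chromosome (length {length})"
            )
        return ((pos - 1) // self.window_size) * self.window_size

    def windows(self) -> pd.DataFrame:
        """All windows as a DataFrame with columns chrom, start, end."""
        rows = []
        for chrom, length in self.chromosomes:
            starts = np.arange(0, length, self.window_size)
            ends = np.minimum(starts + self.window_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def window_index(self) -> pd.MultiIndex:
        win = self.windows()
        return pd.MultiIndex.from_arrays([win["chrom"], win["start"]],
                                         names=["chrom", "start"])

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path, window_size: int = 100_000) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                         comment="#", dtype={"chrom": str})
        return cls(tuple(zip(df["chrom"], df["length"].astype(int))), window_size)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.chromosomes).to_csv(path, sep="\t", header=False,
                                              index=False)


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------

_SITE_COLS = ["chrom", "pos", "ac1", "n1", "ac2", "n2"]


def read_site_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-site allele-count TSV.

    Expected header: ``chrom pos ac1 n1 ac2 n2`` with an optional ``depth``
    column.  Records are validated (``0 <= ac <= n``, ``n > 0``, positions
    strictly increasing within each chromosome); violations raise
    :class:`ValidationError` with a line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty site-count file")
        return pd.DataFrame(columns=_SITE_COLS)
    missing = [c for c in _SITE_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in _SITE_COLS[1:]:
        if not pd.api.types.is_integer_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = (bad[0] + 2) if len(bad) else "?"
            raise ParseError(f"{path}:{line}: non-integer value in column {col}")
    if df.empty:
        warnings.warn(f"{path}: empty site-count file")
        return df
    bad = (df["n1"] <= 0) | (df["n2"] <= 0)
    if bad.any():
        raise ValidationError(f"{path}:{df.index[bad][0] + 2}: sample size <= 0")
    bad = (df["ac1"] < 0) | (df["ac1"] > df["n1"]) | (df["ac2"] < 0) | (df["ac2"] > df["n2"])
    if bad.any():
        raise ValidationError(
            f"{path}:{df.index[bad][0] + 2}: allele count outside [0, n]"
        )
    for chrom, sub in df.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
            raise ValidationError(
                f"{path}: positions not strictly increasing on {chrom}"
            )
    return df.reset_index(drop=True)


def read_depth_table(path: str | Path) -> pd.DataFrame:
    """Read a per-site depth TSV with header ``chrom pos depth``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos", "depth"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col}")
    return df


def read_r2_table(path: str | Path) -> pd.DataFrame:
    """Read a SNP-pair LD table with header ``chrom pos1 pos2 r2``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos1", "pos2", "r2"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col}")
    return df


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a per-window feature TSV keyed by (chrom, start)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    for col in ("chrom", "start"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col}")
    return df.set_index(["chrom", "start"])


def read_centromeres(path: str | Path) -> pd.DataFrame:
    """Read centromeric intervals from a 3-column BED file (no header)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end"], dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return df


# ---------------------------------------------------------------------------
# window tables (BED-like TSV)
# ---------------------------------------------------------------------------

def write_window_table(stats: pd.DataFrame, path: str | Path,
                       layout: GenomeLayout | None = None) -> None:
    """Write a per-window statistics table as BED-like TSV.

    Columns ``chrom``, ``start``, ``end`` come first; remaining columns are
    written in their existing order.  NaN is serialized as ``NA``.  When a
    layout is given, rows are sorted by (layout chromosome order, start).
    """
    df = stats.copy()
    if isinstance(df.index, pd.MultiIndex):
        df = df.reset_index()
    lead = ["chrom", "start", "end"] if "end" in df.columns else ["chrom", "start"]
    df = df[lead + [c for c in df.columns if c not in lead]]
    if layout is not None:
        df = df.assign(_rank=df["chrom"].map(layout.chrom_rank))
        df = df.sort_values(["_rank", "start"]).drop(columns="_rank")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_window_table(path: str | Path) -> pd.DataFrame:
    """Read a window table written by :func:`write_window_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    for col in ("chrom", "start"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col}")
    return df


def window_key(df: pd.DataFrame) -> pd.MultiIndex:
    """(chrom, start) MultiIndex for a window table."""
    return pd.MultiIndex.from_arrays([df["chrom"], df["start"]],
                                     names=["chrom", "start"])


# ---------------------------------------------------------------------------
# pair matrices
# ---------------------------------------------------------------------------

def write_pair_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def read_pair_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    return df


def load_config(path: str | Path) -> dict:
    """Load a key: value configuration file (YAML subset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ParseError(f"{path}: config must be a mapping of key: value pairs")
    return dict(cfg)
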