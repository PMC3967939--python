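"""Readers/writers and in-memory containers for chromatin signal data.

All coordinates are 0-based half-open, as in BED/bedGraph.  The canonical
interchange format for a multi-factor signal or call matrix is a plain TSV
with a ``chrom  start  end  <factor...>`` header; per-factor binary calls are
additionally exported as one BED file per factor.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates the declared dialect."""


Bin = tuple[str, int, int]


def _check_bins(bins: Sequence[Bin]) -> None:
    for i, (chrom, start, end) in enumerate(bins):
        if not (start < end):
            raise FormatError(f"bin {i} ({chrom}:{start}-{end}): start >= end")


def _check_factors(factors: Sequence[str]) -> None:
    if len(set(factors)) != len(factors):
        dupes = sorted({f for f in factors if list(factors).count(f) > 1})
        raise FormatError(f"duplicated factor names: {dupes}")


@dataclass
class SignalMatrix:
    """Continuous per-bin signal for a set of chromatin factors.

    Parameters
    ----------
    bins
        Genomic bins as ``(chrom, start, end)`` with 0-based half-open
        coordinates.
    factors
        Unique factor (track) names, one per column.
    values
        Array of shape ``(n_bins, n_factors)``; NaN marks missing signal.
    coverage
        Fraction in [0, 1] of each bin covered by underlying measurements
        (probes/reads); bins below the coverage cutoff are withheld during
        binarization.
    """

    bins: list[Bin]
    factors: list[str]
    values: np.ndarray
    coverage: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (bins x factors)")
        if self.values.shape != (len(self.bins), len(self.factors)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.bins)} bins x {len(self.factors)} factors"
            )
        _check_bins(self.bins)
        _check_factors(self.factors)
        if self.coverage is None:
            self.coverage = np.ones(len(self.bins))
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.coverage.shape != (len(self.bins),):
            raise ValueError("coverage must be one value per bin")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_factors(self) -> int:
        return len(self.factors)


@dataclass
class ChromatinCodeMatrix:
    """Binary occupancy calls (the "chromatin code") per bin and factor.

    ``calls`` must be strictly 0/1 with no missing entries; binarization is
    responsible for resolving missingness before constructing this type.
    """

    bins: list[Bin]
    factors: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.bins), len(self.factors)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.bins)} bins x {len(self.factors)} factors"
            )
        if np.isnan(self.calls.astype(float)).any():
            raise ValueError("calls may not contain missing entries")
        uniq = np.unique(self.calls)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError(f"calls must be binary, found values {uniq}")
        self.calls = self.calls.astype(np.int8)
        _check_bins(self.bins)
        _check_factors(self.factors)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def column(self, factor: str) -> np.ndarray:
        return self.calls[:, self.factors.index(factor)]

    def drop_factor(self, factor: str) -> "ChromatinCodeMatrix":
        j = self.factors.index(factor)
        keep = [i for i in range(self.n_factors) if i != j]
        return ChromatinCodeMatrix(
            bins=list(self.bins),
            factors=[self.factors[i] for i in keep],
            calls=self.calls[:, keep],
        )


@dataclass
class EvaluationStandard:
    """Curated set of experimentally supported factor pairs (positives)."""

    pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair not allowed: {a}")
            canon.add((min(a, b), max(a, b)))
        self.pairs = canon

    def restrict(self, factors: Iterable[str]) -> "EvaluationStandard":
        universe = set(factors)
        return EvaluationStandard(
            {p for p in self.pairs if p[0] in universe and p[1] in universe}
        )


# ---------------------------------------------------------------------------
# signal matrix TSV
# ---------------------------------------------------------------------------

_COORD_COLS = ["chrom", "start", "end"]


def read_signal_matrix(
    path: str | Path,
    dialect: str = "tsv",
    bins: Sequence[Bin] | None = None,
) -> SignalMatrix:
    """Read a continuous signal matrix.

    ``tsv`` dialect: a single file with header ``chrom start end <factor...>``
    and optionally a ``coverage`` column.  ``bedgraph-set`` dialect: ``path``
    is a directory of ``<factor>.bedgraph`` tracks that are averaged onto the
    user-supplied ``bins`` grid (coverage = covered fraction of each bin).
    """
    if dialect == "tsv":
        return _read_signal_tsv(Path(path))
    if dialect == "bedgraph-set":
        if bins is None:
            raise ValueError("bedgraph-set dialect requires an explicit bin grid")
        return _read_bedgraph_set(Path(path), list(bins))
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_signal_tsv(path: Path) -> SignalMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_factors([c for c in header if c not in _COORD_COLS + ["coverage"]])
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in _COORD_COLS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    has_cov = "coverage" in df.columns
    factor_cols = [c for c in df.columns if c not in _COORD_COLS + ["coverage"]]
    _check_factors(factor_cols)
    try:
        starts = df["start"].astype(int)
        ends = df["end"].astype(int)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer coordinates ({exc})") from exc
    bad = np.nonzero((starts >= ends).to_numpy())[0]
    if bad.size:
        # +2: header line plus 1-based numbering
        raise FormatError(f"{path}: start >= end on line {bad[0] + 2}")
    for c in factor_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise FormatError(f"{path}: non-numeric value in column {c!r}")
    df = df.assign(_start=starts, _end=ends).sort_values(["chrom", "_start"])
    bins = list(zip(df["chrom"], df["_start"], df["_end"]))
    if len(set(bins)) != len(bins):
        raise FormatError(f"{path}: duplicated bins")
    cov = df["coverage"].to_numpy(float) if has_cov else None
    return SignalMatrix(
        bins=bins,
        factors=factor_cols,
        values=df[factor_cols].to_numpy(float),
        coverage=cov,
    )


def write_signal_matrix(matrix: SignalMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.bins, columns=_COORD_COLS)
    for j, f in enumerate(matrix.factors):
        df[f] = matrix.values[:, j]
    df["coverage"] = matrix.coverage
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _read_bedgraph_set(directory: Path, bins: list[Bin]) -> SignalMatrix:
    tracks = sorted(directory.glob("*.bedgraph"))
    if not tracks:
        raise FormatError(f"{directory}: no .bedgraph tracks found")
    _check_bins(bins)
    factors = [t.stem for t in tracks]
    _check_factors(factors)
    values = np.full((len(bins), len(tracks)), np.nan)
    coverage = np.zeros(len(bins))
    order = sorted(range(len(bins)), key=lambda i: bins[i][:2])
    for j, track in enumerate(tracks):
        df = pd.read_csv(
            track, sep="\t", header=None,
            names=["chrom", "start", "end", "value"], dtype={"chrom": str},
        )
        cov_bp = np.zeros(len(bins))
        wsum = np.zeros(len(bins))
        by_chrom = {c: g for c, g in df.groupby("chrom")}
        for i in order:
            chrom, bstart, bend = bins[i]
            g = by_chrom.get(chrom)
            if g is None:
                continue
            s = g["start"].to_numpy()
            e = g["end"].to_numpy()
            v = g["value"].to_numpy(float)
            overlap = np.minimum(e, bend) - np.maximum(s, bstart)
            m = overlap > 0
            cov_bp[i] = overlap[m].sum()
            wsum[i] = (overlap[m] * v[m]).sum()
        with np.errstate(invalid="ignore"):
            values[:, j] = np.where(cov_bp > 0, wsum / np.maximum(cov_bp, 1), np.nan)
        coverage = np.maximum(coverage, cov_bp / np.array([b[2] - b[1] for b in bins]))
    return SignalMatrix(bins=bins, factors=factors, values=values, coverage=coverage)


# ---------------------------------------------------------------------------
# binary calls: combined TSV + per-factor BED
# ---------------------------------------------------------------------------

def write_binary_calls(matrix: ChromatinCodeMatrix, path: str | Path) -> None:
    """Write calls as a combined TSV at ``path`` plus per-factor BED files.

    BED files are named ``<stem>.<factor>.bed`` next to the TSV and contain
    one record per bin with call = 1 (empty file when a factor has none).
    """
    path = Path(path)
    df = pd.DataFrame(matrix.bins, columns=_COORD_COLS)
    for j, f in enumerate(matrix.factors):
        df[f] = matrix.calls[:, j]
    df.to_csv(path, sep="\t", index=False)
    stem = path.with_suffix("")
    for j, f in enumerate(matrix.factors):
        safe = f.replace(os.sep, "_")
        with open(f"{stem}.{safe}.bed", "w") as fh:
            for (chrom, start, end), call in zip(matrix.bins, matrix.calls[:, j]):
                if call:
                    fh.write(f"{chrom}\t{start}\t{end}\n")


def read_binary_calls(path: str | Path) -> ChromatinCodeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    factor_cols = [c for c in df.columns if c not in _COORD_COLS]
    return ChromatinCodeMatrix(
        bins=list(zip(df["chrom"], df["start"].astype(int), df["end"].astype(int))),
        factors=factor_cols,
        calls=df[factor_cols].to_numpy(),
    )


# ---------------------------------------------------------------------------
# evaluation standard TSV (two columns of factor names)
# ---------------------------------------------------------------------------

def read_standard(path: str | Path) -> EvaluationStandard:
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], comment="#")
    return EvaluationStandard(set(zip(df["a"].astype(str), df["b"].astype(str))))


def write_standard(standard: EvaluationStandard, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(standard.pairs):
            fh.write(f"{a}\t{b}\n")
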