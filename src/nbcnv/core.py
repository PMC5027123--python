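"""Domain containers and tabular I/O for binned read-count data.

All genomic coordinates are 0-based, half-open (BED convention), both in
memory and on disk.  Count tracks are tab-separated text with the header
``chrom  start  end  gc  count``; CNV segments are written either as BED
(name field ``gain:CN`` / ``loss:CN``, score field = number of member bins)
or as a headered TSV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class NbcnvError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(NbcnvError):
    """Input data violates a documented invariant."""


class ParseError(ValidationError):
    """A text file could not be parsed; the message names the offending line."""


class SolverDivergenceError(NbcnvError):
    """The ADMM iteration produced non-finite residuals."""

    def __init__(self, iteration: int, message: str | None = None):
        self.iteration = iteration
        super().__init__(
            message or f"solver diverged (non-finite residual) at iteration {iteration}"
        )


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BinSet:
    """An ordered grid of genomic bins.

    Parameters
    ----------
    chrom : array of str, one per bin.
    start, end : int arrays, 0-based half-open coordinates.
    gc : float array, GC fraction per bin in [0, 1]; NaN where unknown.
    mappable_positions : optional int array, number of uniquely mappable
        positions per bin (filled by variable-size binning).
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray | None = None
    mappable_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.gc is not None:
            self.gc = np.asarray(self.gc, dtype=float)
        if self.mappable_positions is not None:
            self.mappable_positions = np.asarray(self.mappable_positions, dtype=np.int64)
        self.validate()

    def __len__(self) -> int:
        return len(self.start)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    def validate(self) -> None:
        n = len(self.start)
        if not (len(self.chrom) == len(self.end) == n):
            raise ValidationError("chrom/start/end arrays have unequal lengths")
        bad = np.nonzero(self.end <= self.start)[0]
        if bad.size:
            raise ValidationError(
                f"bin end <= start at row {bad[0] + 1} "
                f"({self.chrom[bad[0]]}:{self.start[bad[0]]}-{self.end[bad[0]]})"
            )
        # sorted by (chrom, start) with chromosomes in contiguous blocks,
        # non-overlapping within a chromosome
        for i in range(1, n):
            if self.chrom[i] == self.chrom[i - 1]:
                if self.start[i] < self.start[i - 1]:
                    raise ValidationError(f"bins not sorted by start at row {i + 1}")
                if self.start[i] < self.end[i - 1]:
                    raise ValidationError(
                        f"overlapping bins at rows {i} and {i + 1} on {self.chrom[i]}"
                    )
        seen: dict = {}
        for i, c in enumerate(self.chrom):
            if c in seen and self.chrom[i - 1] != c:
                raise ValidationError(f"chromosome {c} appears in non-contiguous blocks")
            seen[c] = True
        if self.gc is not None:
            g = self.gc[~np.isnan(self.gc)]
            if g.size and (g.min() < 0 or g.max() > 1):
                raise ValidationError("gc fraction outside [0, 1]")
        if self.mappable_positions is not None and (self.mappable_positions < 0).any():
            raise ValidationError("negative mappable_positions")

    @property
    def has_gc(self) -> bool:
        return self.gc is not None and not np.all(np.isnan(self.gc))

    @classmethod
    def uniform(cls, chrom_lengths: dict[str, int], bin_size: int,
                merge_tail: bool = True) -> "BinSet":
        """Tile each chromosome with fixed-size bins.

        With ``merge_tail`` a trailing remainder shorter than ``bin_size`` is
        merged into the last bin instead of forming its own short bin.
        """
        chroms, starts, ends = [], [], []
        for name, length in chrom_lengths.items():
            edges = list(range(0, length, bin_size)) + [length]
            if merge_tail and len(edges) > 2 and edges[-1] - edges[-2] < bin_size:
                del edges[-2]
            for a, b in zip(edges[:-1], edges[1:]):
                chroms.append(name)
                starts.append(a)
                ends.append(b)
        return cls(np.array(chroms, dtype=object), np.array(starts), np.array(ends))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end})
        df["gc"] = self.gc if self.gc is not None else np.nan
        if self.mappable_positions is not None:
            df["mappable_positions"] = self.mappable_positions
        return df


@dataclass
class CountTrack:
    """Per-bin read counts and (optionally) the derived read-depth signal.

    ``counts`` are nonnegative; they are integer-valued as read from an
    aligner but become real-valued after GC normalization.  ``rd`` is the
    relative read depth, counts / mean(counts), and has mean 1 by
    construction.
    """

    bins: BinSet
    counts: np.ndarray
    rd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.bins):
            raise ValidationError(
                f"{len(self.counts)} counts for {len(self.bins)} bins"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("non-finite counts")
        if (self.counts < 0).any():
            raise ValidationError("negative counts")
        if self.rd is not None:
            self.rd = np.asarray(self.rd, dtype=float)
            if len(self.rd) != len(self.bins):
                raise ValidationError("rd length does not match bins")
            if (self.rd < 0).any():
                raise ValidationError("negative rd values")

    def __len__(self) -> int:
        return len(self.counts)

    def to_dataframe(self) -> pd.DataFrame:
        df = self.bins.to_dataframe()[["chrom", "start", "end", "gc"]]
        df["count"] = self.counts
        if self.rd is not None:
            df["rd"] = self.rd
        return df


@dataclass
class NBParams:
    """Fitted NB2 parameters: mean mu > 0, dispersion alpha > 0.

    Variance is mu + mu**2 / dispersion; dispersion -> infinity recovers the
    Poisson model.
    """

    mean: float
    dispersion: float
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValidationError("NB mean must be positive")
        if not self.dispersion > 0:
            raise ValidationError("NB dispersion must be positive")

    @property
    def variance(self) -> float:
        return self.mean + self.mean**2 / self.dispersion


FIDELITIES = ("negative_binomial", "poisson")


@dataclass
class SolverConfig:
    """Configuration of the penalized-likelihood ADMM solver.

    lambda1 weighs the total-variation (smoothness) penalty and lambda2 the
    L1 penalty centered at the baseline ``baseline_c``; both are expressed
    per unit of relative read depth (see solver module docs).  ``dispersion``
    is the NB over-dispersion alpha, held fixed during the solve.
    ``admm_penalty`` is the quadratic coupling weight of the augmented
    Lagrangian.
    """

    lambda1: float = 1.0
    lambda2: float = 1.0
    baseline_c: float | None = None
    dispersion: float = 9.5
    admm_penalty: float = 1.0
    max_iter: int = 2000
    tol: float = 1e-6
    fidelity: str = "negative_binomial"
    signal_scale: float | None = None

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValidationError("lambda1/lambda2 must be nonnegative")
        if self.baseline_c is not None and not self.baseline_c > 0:
            raise ValidationError("baseline_c must be positive")
        if not self.dispersion > 0:
            raise ValidationError("dispersion must be positive")
        if not self.admm_penalty > 0:
            raise ValidationError("admm_penalty must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValidationError("tol must be positive")
        if self.fidelity not in FIDELITIES:
            raise ValidationError(f"fidelity must be one of {FIDELITIES}")
        if self.signal_scale is not None and not self.signal_scale > 0:
            raise ValidationError("signal_scale must be positive")

    def replace(self, **kw) -> "SolverConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class CNProfile:
    """Per-bin fitted signal and its integer copy-number translation."""

    bins: BinSet
    fitted: np.ndarray
    cn: np.ndarray
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.fitted = np.asarray(self.fitted, dtype=float)
        self.cn = np.asarray(self.cn, dtype=np.int64)
        if len(self.fitted) != len(self.bins) or len(self.cn) != len(self.bins):
            raise ValidationError("profile length does not match bins")
        if not np.all(self.fitted > 0):
            raise ValidationError("fitted signal must be positive")
        if (self.cn < 0).any():
            raise ValidationError("negative copy number")
        if self.ploidy < 1:
            raise ValidationError("ploidy must be >= 1")

    def __len__(self) -> int:
        return len(self.cn)

    def to_dataframe(self) -> pd.DataFrame:
        df = self.bins.to_dataframe()[["chrom", "start", "end"]]
        df["fitted"] = self.fitted
        df["cn"] = self.cn
        return df


@dataclass(frozen=True)
class CNVSegment:
    """A merged run of bins sharing a non-baseline copy number.

    Coordinates are the union of the member-bin intervals, 0-based half-open.
    """

    chrom: str
    start: int
    end: int
    cn: int
    kind: str  # "gain" or "loss"
    n_bins: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("segment end must exceed start")
        if self.kind not in ("gain", "loss"):
            raise ValidationError("segment kind must be 'gain' or 'loss'")
        if self.n_bins < 1:
            raise ValidationError("segment must contain at least one bin")


@dataclass
class ConfusionCounts:
    """Bin-level confusion counts for variant-vs-normal calls."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0:
                raise ValidationError("negative confusion count")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def _ratio(self, num: int, den: int) -> float:
        return num / den if den else float("nan")

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.total)

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    def metrics(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TRACK_COLUMNS = ["chrom", "start", "end", "gc", "count"]


def _read_table(path, names: list[str], header: bool) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#",
            header=0 if header else None,
            dtype=str, skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names)
    if header:
        missing = [c for c in names if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing column(s) {missing}")
        df = df[names]
    else:
        if df.shape[1] < len(names):
            raise ParseError(
                f"{path}: expected {len(names)} columns, found {df.shape[1]}"
            )
        df = df.iloc[:, : len(names)]
        df.columns = names
    return df


def _to_numeric(df: pd.DataFrame, col: str, path, kind=float) -> np.ndarray:
    converted = pd.to_numeric(df[col], errors="coerce")
    na_in = df[col].isna() | df[col].astype(str).str.upper().isin(["NA", "NAN", "."])
    bad = converted.isna() & ~na_in
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ParseError(
            f"{path}: malformed value {df[col].iloc[row]!r} in column "
            f"'{col}' at data row {row + 1}"
        )
    arr = converted.to_numpy(dtype=float)
    if kind is int:
        if np.any(np.isnan(arr)):
            row = int(np.nonzero(np.isnan(arr))[0][0])
            raise ParseError(f"{path}: missing integer in column '{col}' at data row {row + 1}")
        return arr.astype(np.int64)
    return arr


def read_count_track(path, format: str = "tsv") -> CountTrack:
    """Read a per-bin count track.

    ``tsv`` expects a header line ``chrom start end gc count``; ``bed``
    accepts the same five columns without a header (BED5-like).  The GC
    column may be NA when normalization will be skipped.
    """
    if format not in ("tsv", "bed"):
        raise ValidationError(f"unknown count-track format {format!r}")
    df = _read_table(path, _TRACK_COLUMNS, header=(format == "tsv"))
    start = _to_numeric(df, "start", path, int)
    end = _to_numeric(df, "end", path, int)
    gc = _to_numeric(df, "gc", path, float)
    counts = _to_numeric(df, "count", path, float)
    bins = BinSet(df["chrom"].to_numpy(dtype=object), start, end, gc)
    return CountTrack(bins, counts)


def write_count_track(track: CountTrack, path, format: str = "tsv") -> None:
    """Write a count track; lossless round-trip with :func:`read_count_track`."""
    if format not in ("tsv", "bed"):
        raise ValidationError(f"unknown count-track format {format!r}")
    df = track.to_dataframe()[_TRACK_COLUMNS].copy()
    # keep integer counts integer on disk
    if np.allclose(df["count"], np.round(df["count"])):
        df["count"] = df["count"].astype(np.int64)
    df.to_csv(path, sep="\t", index=False, header=(format == "tsv"),
              float_format="%.10g", na_rep="NA")


def write_bins(bins: BinSet, path) -> None:
    bins.to_dataframe().to_csv(path, sep="\t", index=False,
                               float_format="%.10g", na_rep="NA")


def read_bins(path) -> BinSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column '{col}'")
    gc = df["gc"].to_numpy(dtype=float) if "gc" in df.columns else None
    mp = (df["mappable_positions"].to_numpy(dtype=np.int64)
          if "mappable_positions" in df.columns else None)
    return BinSet(df["chrom"].to_numpy(dtype=object),
                  df["start"].to_numpy(dtype=np.int64),
                  df["end"].to_numpy(dtype=np.int64), gc, mp)


_SEG_HEADER = "#chrom\tstart\tend\tname\tn_bins"


def write_segments(segments: Sequence[CNVSegment], path, format: str = "bed") -> None:
    """Write CNV segments as BED (name = ``gain:CN``/``loss:CN``, score =
    n_bins) or as a headered TSV."""
    if format not in ("bed", "tsv"):
        raise ValidationError(f"unknown segment format {format!r}")
    path = Path(path)
    with open(path, "w") as fh:
        if format == "bed":
            fh.write(_SEG_HEADER + "\n")
            for s in segments:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.kind}:{s.cn}\t{s.n_bins}\n")
        else:
            fh.write("chrom\tstart\tend\tcn\tkind\tn_bins\n")
            for s in segments:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.cn}\t{s.kind}\t{s.n_bins}\n")


def read_segments(path, format: str = "bed") -> list[CNVSegment]:
    """Inverse of :func:`write_segments` for either format."""
    if format not in ("bed", "tsv"):
        raise ValidationError(f"unknown segment format {format!r}")
    out: list[CNVSegment] = []
    path = Path(path)
    if format == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError(f"{path}: too few fields on line {lineno}")
                try:
                    kind, cn = parts[3].split(":")
                    n_bins = int(parts[4]) if len(parts) > 4 else 1
                    out.append(CNVSegment(parts[0], int(parts[1]), int(parts[2]),
                                          int(cn), kind, n_bins))
                except (ValueError, ValidationError) as exc:
                    raise ParseError(f"{path}: malformed segment on line {lineno}: {exc}")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        for _, r in df.iterrows():
            out.append(CNVSegment(str(r["chrom"]), int(r["start"]), int(r["end"]),
                                  int(r["cn"]), str(r["kind"]), int(r["n_bins"])))
    return out
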