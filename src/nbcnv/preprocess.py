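"""Binning, counting, GC normalization and data-quality metrics.

Single-cell read-depth analysis trades resolution (many bins) against
per-bin signal quality.  This module provides the pieces of that trade:
variable-size bins that equalize uniquely mappable positions, read counting
into bins, LOWESS-based GC-bias correction, the MAPD noise metric, the
histogram overlap ratio measuring how well a noise model fits the observed
counts, and a score that selects a bin count balancing the two.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import BinSet, CountTrack, NBParams, ValidationError
from .distributions import fit_gaussian_mle, fit_nb_mle, fit_poisson_mle


# ---------------------------------------------------------------------------
# variable-size binning
# ---------------------------------------------------------------------------


def _load_sequences(genome) -> dict[str, str]:
    if isinstance(genome, (str, Path)):
        from Bio import SeqIO

        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(genome), "fasta")}
    return {name: seq.upper() for name, seq in genome.items()}


def _gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def build_variable_bins(genome, read_length: int, n_bins: int) -> BinSet:
    """Divide a genome into bins of equal numbers of uniquely mappable positions.

    A position is uniquely mappable iff its length-k substring (k =
    ``read_length``) occurs exactly once in the whole genome, an exact-k-mer
    surrogate for aligner-based mappability.  Each chromosome contributes
    L - k + 1 candidate positions.  Within a chromosome every bin except the
    last holds the same number of mappable positions; the last absorbs the
    remainder.  For multiple chromosomes ``n_bins`` is apportioned by each
    chromosome's share of mappable positions (at least one bin each).
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    seqs = _load_sequences(genome)
    if not seqs:
        raise ValidationError("no sequences supplied")
    k = int(read_length)
    for name, seq in seqs.items():
        if len(seq) < k:
            raise ValidationError(f"sequence {name} shorter than read length {k}")
    kmer_counts: Counter = Counter()
    for seq in seqs.values():
        for i in range(len(seq) - k + 1):
            kmer_counts[seq[i:i + k]] += 1
    mappable: dict[str, np.ndarray] = {}
    for name, seq in seqs.items():
        pos = [i for i in range(len(seq) - k + 1)
               if kmer_counts[seq[i:i + k]] == 1]
        mappable[name] = np.asarray(pos, dtype=np.int64)
    total = sum(len(p) for p in mappable.values())
    if total == 0:
        raise ValidationError("genome has no uniquely mappable positions")
    if n_bins > total:
        raise ValidationError(
            f"n_bins={n_bins} exceeds the {total} uniquely mappable positions"
        )
    # apportion bins by mappable share (largest remainder, >= 1 per chrom)
    names = list(seqs)
    shares = np.array([len(mappable[c]) for c in names], dtype=float) / total
    alloc = np.maximum(np.floor(shares * n_bins).astype(int), 1)
    while alloc.sum() < n_bins:
        alloc[np.argmax(shares * n_bins - alloc)] += 1
    while alloc.sum() > n_bins:
        cand = np.nonzero(alloc > 1)[0]
        alloc[cand[np.argmin((shares * n_bins - alloc)[cand])]] -= 1

    chroms, starts, ends, gcs, mps = [], [], [], [], []
    for name, n_c in zip(names, alloc):
        mp = mappable[name]
        if len(mp) < n_c:
            raise ValidationError(
                f"chromosome {name}: {len(mp)} mappable positions < {n_c} bins"
            )
        q = len(mp) // n_c
        L = len(seqs[name])
        prev_end = 0
        for j in range(n_c):
            last = j == n_c - 1
            members = mp[j * q:] if last else mp[j * q:(j + 1) * q]
            start = prev_end
            end = L if last else int(mp[(j + 1) * q - 1]) + 1
            prev_end = end
            chroms.append(name)
            starts.append(start)
            ends.append(end)
            gcs.append(_gc_fraction(seqs[name][start:end]))
            mps.append(len(members))
    return BinSet(np.array(chroms, dtype=object), np.array(starts),
                  np.array(ends), np.array(gcs), np.array(mps))


def count_reads_in_bins(alignments, bins: BinSet, min_mapq: int = 0) -> CountTrack:
    """Count aligned reads per bin by leftmost mapped position.

    Accepts SAM/BAM/CRAM.  The file is streamed sequentially, so no index is
    required.  Unmapped, secondary, supplementary and sub-``min_mapq`` reads
    are excluded; strand is ignored.  Reads on contigs absent from ``bins``
    or falling outside every bin are dropped.
    """
    import pysam

    counts = np.zeros(len(bins), dtype=np.int64)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    chrom_arr = bins.chrom
    for name in np.unique(chrom_arr.astype(str)):
        idx = np.nonzero(chrom_arr.astype(str) == name)[0]
        by_chrom[name] = (bins.start[idx], bins.end[idx], idx)
    with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            entry = by_chrom.get(read.reference_name)
            if entry is None:
                continue
            starts, ends, idx = entry
            pos = read.reference_start
            j = np.searchsorted(starts, pos, side="right") - 1
            if j >= 0 and pos < ends[j]:
                counts[idx[j]] += 1
    return CountTrack(bins=bins, counts=counts)


# ---------------------------------------------------------------------------
# normalization and read depth
# ---------------------------------------------------------------------------


def _interp_with_extrapolation(x, xp, fp):
    y = np.interp(x, xp, fp)
    if len(xp) >= 2:
        lo = x < xp[0]
        hi = x > xp[-1]
        y = np.asarray(y, dtype=float)
        y[lo] = fp[0] + (x[lo] - xp[0]) * (fp[1] - fp[0]) / (xp[1] - xp[0])
        y[hi] = fp[-1] + (x[hi] - xp[-1]) * (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
    return y


def gc_normalize(track: CountTrack, frac: float = 0.3,
                 interpolation: str = "linear") -> CountTrack:
    """Remove GC-content bias with a LOWESS fit and linear interpolation.

    Counts are rescaled by median(count) / fitted(gc), where fitted(.) is a
    LOWESS regression of count on GC fraction evaluated by linear
    interpolation (and extrapolation beyond the fitted range, from the two
    nearest fitted points).  Fitted values are floored at 1e-6 x median.
    """
    if interpolation != "linear":
        raise ValidationError("only linear interpolation is supported")
    if not track.bins.has_gc:
        raise ValidationError("track has no GC values; cannot GC-normalize "
                              "(supply gc per bin or skip normalization)")
    if len(track) < 10:
        raise ValidationError("need at least 10 bins to fit the GC trend")
    counts = track.counts
    if np.all(counts == 0):
        raise ValidationError("all counts are zero")
    gc = track.bins.gc
    ok = ~np.isnan(gc)
    if ok.sum() < 10:
        raise ValidationError("fewer than 10 bins with known GC")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fit = lowess(counts[ok], gc[ok], frac=frac, return_sorted=True)
    xp, fp = fit[:, 0], fit[:, 1]
    # collapse duplicate GC values for interpolation
    xp_u, inv = np.unique(xp, return_inverse=True)
    fp_u = np.bincount(inv, weights=fp) / np.bincount(inv)
    med = float(np.median(counts))
    fitted = _interp_with_extrapolation(gc, xp_u, fp_u)
    fitted = np.where(np.isnan(gc), med, fitted)
    fitted = np.maximum(fitted, 1e-6 * med)
    normalized = counts * (med / fitted)
    return CountTrack(bins=track.bins, counts=normalized)


def compute_rd(track: CountTrack) -> CountTrack:
    """Fill the relative read-depth signal rd = count / mean(count)."""
    if len(track) == 0:
        raise ValidationError("empty track")
    m = float(np.mean(track.counts))
    if not m > 0:
        raise ValidationError("mean count is zero")
    return CountTrack(bins=track.bins, counts=track.counts,
                      rd=track.counts / m)


# ---------------------------------------------------------------------------
# quality metrics
# ---------------------------------------------------------------------------


def mapd(signal, pseudocount: float = 0.0) -> float:
    """Median absolute pairwise difference of successive log2 values.

    A robust noise measure for read-depth signals: larger values mean
    noisier data.  Invariant under global positive scaling.  All values
    (after adding ``pseudocount``) must be positive.
    """
    x = np.asarray(signal, dtype=float) + pseudocount
    if x.size < 2:
        raise ValidationError("need at least 2 values")
    if np.any(x <= 0):
        raise ValidationError(
            "nonpositive values; pass pseudocount=0.5 to handle zero counts"
        )
    return float(np.median(np.abs(np.diff(np.log2(x)))))


def histogram_overlap(a, b) -> float:
    """Intersection-over-union of two aligned frequency histograms.

    sum(min(A, B)) / sum(max(A, B)); 1 iff the histograms are identical,
    0 for disjoint support.  Symmetric in A and B.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("histograms must be aligned (equal length)")
    if np.any(a < 0) or np.any(b < 0):
        raise ValidationError("histogram frequencies must be nonnegative")
    denom = float(np.maximum(a, b).sum())
    if denom == 0:
        raise ValidationError("both histograms are empty")
    return float(np.minimum(a, b).sum()) / denom


def overlap_ratio(observed, model: str, params, tail_sigmas: float = 5.0) -> float:
    """Overlap ratio between observed counts and a fitted noise model.

    The empirical frequency histogram A of the observed integer counts and
    the model-expected histogram B = n * pmf are built on the integer
    support 0 .. max(observed) + ``tail_sigmas`` model standard deviations,
    and their intersection-over-union returned.  ``model`` is one of
    ``nb`` (params: NBParams or (mean, dispersion)), ``poisson`` (mean) or
    ``gaussian`` ((mean, sd), integrated over unit-width cells).
    """
    y = np.asarray(observed)
    if y.size == 0:
        raise ValidationError("observed counts are empty")
    if np.any(y < 0):
        raise ValidationError("counts must be nonnegative")
    yi = np.round(y).astype(np.int64)
    if model == "nb":
        if isinstance(params, NBParams):
            mean, disp = params.mean, params.dispersion
        else:
            mean, disp = params
        if not (mean > 0 and disp > 0):
            raise ValidationError("invalid NB parameters")
        sigma = np.sqrt(mean + mean * mean / disp)
        dist = stats.nbinom(disp, disp / (mean + disp))
    elif model == "poisson":
        mean = float(params if np.isscalar(params) else params[0])
        if not mean > 0:
            raise ValidationError("invalid Poisson mean")
        sigma = np.sqrt(mean)
        dist = stats.poisson(mean)
    elif model == "gaussian":
        mean, sd = params
        if not sd > 0:
            raise ValidationError("invalid Gaussian sd")
        sigma = sd
        dist = None
    else:
        raise ValidationError(f"unknown model {model!r}")
    hi = int(yi.max()) + int(np.ceil(tail_sigmas * sigma)) + 1
    support = np.arange(hi + 1)
    A = np.bincount(yi, minlength=hi + 1).astype(float)
    if dist is not None:
        B = yi.size * dist.pmf(support)
    else:  # Gaussian probability of the unit-width cell around each integer
        B = yi.size * (stats.norm.cdf(support + 0.5, mean, sd)
                       - stats.norm.cdf(support - 0.5, mean, sd))
    return histogram_overlap(A, B)


# ---------------------------------------------------------------------------
# bin-count selection
# ---------------------------------------------------------------------------


@dataclass
class BinCountAssessment:
    """Quality metrics of one candidate bin count."""

    bin_count: int
    mapd: float
    overlap_nb: float
    overlap_poisson: float = float("nan")
    overlap_gaussian: float = float("nan")

    def __post_init__(self) -> None:
        if self.mapd < 0:
            raise ValidationError("mapd must be nonnegative")
        for v in (self.overlap_nb, self.overlap_poisson, self.overlap_gaussian):
            if not np.isnan(v) and not 0 <= v <= 1:
                raise ValidationError("overlap ratios must lie in [0, 1]")


def assess_track(track: CountTrack, bin_count: int | None = None,
                 pseudocount: float = 0.5) -> BinCountAssessment:
    """Fit the three noise models to a track and compute its quality metrics.

    MAPD is computed on the relative read depth (scale-invariant, so
    identical on raw counts); zero counts are handled with the pseudocount.
    """
    y = track.counts
    nb = fit_nb_mle(y)
    lam = fit_poisson_mle(y)
    mu, sd = fit_gaussian_mle(y)
    return BinCountAssessment(
        bin_count=bin_count if bin_count is not None else len(track),
        mapd=mapd(y, pseudocount=pseudocount if np.any(y == 0) else 0.0),
        overlap_nb=overlap_ratio(y, "nb", nb),
        overlap_poisson=overlap_ratio(y, "poisson", lam),
        overlap_gaussian=overlap_ratio(y, "gaussian", (mu, sd)),
    )


def select_bin_count(assessments: Sequence[BinCountAssessment],
                     tradeoff_weight: float = 0.208,
                     mapd_cap: float = 0.45,
                     poly_degree: int = 3,
                     orientation: str = "quality") -> int:
    """Pick the bin count balancing resolution, noise and model fit.

    A polynomial g-hat of degree ``poly_degree`` is fitted to the
    MAPD-versus-bin-count curve; candidates with MAPD above ``mapd_cap``
    are excluded and the score

        S(x) = (1 - w) * overlap_nb(x) - w * g-hat(x)

    is maximized over the remainder (w = ``tradeoff_weight``, between 0.20
    and 0.30).  ``orientation='flipped'`` swaps the two terms' roles,
    maximizing (1 - w) * g-hat(x) - w * overlap_nb(x) instead.
    """
    if len(assessments) < 3:
        raise ValidationError("need at least 3 candidate assessments")
    if not 0.20 <= tradeoff_weight <= 0.30:
        raise ValidationError("tradeoff_weight must lie in [0.20, 0.30]")
    if orientation not in ("quality", "flipped"):
        raise ValidationError("orientation must be 'quality' or 'flipped'")
    xs = np.array([a.bin_count for a in assessments], dtype=float)
    ms = np.array([a.mapd for a in assessments])
    ks = np.array([a.overlap_nb for a in assessments])
    deg = min(poly_degree, len(assessments) - 1)
    ghat = np.polyval(np.polyfit(xs, ms, deg), xs)
    ok = ms <= mapd_cap
    if not ok.any():
        raise ValidationError(
            f"no candidate has MAPD <= {mapd_cap}; consider a larger cap"
        )
    w = tradeoff_weight
    if orientation == "quality":
        score = (1 - w) * ks - w * ghat
    else:
        score = (1 - w) * ghat - w * ks
    score = np.where(ok, score, -np.inf)
    return int(xs[int(np.argmax(score))])
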