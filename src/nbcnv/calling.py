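"""Translation of the fitted signal into integer copy numbers, segment
merging, and benchmarking of calls against a known truth."""

from __future__ import annotations

import numpy as np

from .core import BinSet, CNProfile, CNVSegment, ConfusionCounts, ValidationError


def profile_from_fit(fitted, baseline_c: float, ploidy: int = 2,
                     bins: BinSet | None = None) -> CNProfile:
    """Round the fitted signal to integer copy numbers.

    cn_t = round(ploidy * fitted_t / baseline_c), clipped at 0.  Halves round
    up (deterministically), so fitted = 1.25 * c at ploidy 2 gives CN 3.
    """
    fitted = np.asarray(fitted, dtype=float)
    if not np.all(fitted > 0):
        raise ValidationError("fitted signal must be positive")
    if not baseline_c > 0:
        raise ValidationError("baseline_c must be positive")
    if ploidy < 1:
        raise ValidationError("ploidy must be >= 1")
    cn = np.floor(ploidy * fitted / baseline_c + 0.5).astype(np.int64)
    cn = np.maximum(cn, 0)
    if bins is None:
        n = len(fitted)
        bins = BinSet(np.array(["chrUn"] * n, dtype=object),
                      np.arange(n, dtype=np.int64),
                      np.arange(1, n + 1, dtype=np.int64))
    return CNProfile(bins=bins, fitted=fitted, cn=cn, ploidy=ploidy)


def _runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal values as (start, end, value), end exclusive."""
    out = []
    i = 0
    n = len(values)
    while i < n:
        j = i
        while j < n and values[j] == values[i]:
            j += 1
        out.append((i, j, int(values[i])))
        i = j
    return out


def regularize_cn(cn, ploidy: int, min_seg_bins: int,
                  bridge_gaps: bool = True) -> np.ndarray:
    """Absorb runs shorter than ``min_seg_bins`` into their flanks.

    Variant runs (cn != ploidy) shorter than the minimum take the copy
    number of their longer flanking run (left flank on ties or at array
    boundaries).  With ``bridge_gaps`` (the default) short *normal* runs
    lying strictly between two variant runs are absorbed the same way, so a
    single event fragmented by a brief dip back to baseline is reported as
    one call rather than two — the usual merge rule of segmentation-based
    callers.  The pass repeats until no short run remains.
    """
    cn = np.asarray(cn, dtype=np.int64).copy()
    changed = True
    while changed:
        changed = False
        runs = _runs(cn)
        for idx, (a, b, value) in enumerate(runs):
            if b - a >= min_seg_bins:
                continue
            left = runs[idx - 1] if idx > 0 else None
            right = runs[idx + 1] if idx + 1 < len(runs) else None
            if value == ploidy:
                # only bridge interior gaps flanked by variants on both sides
                if not bridge_gaps or left is None or right is None:
                    continue
            if left is None and right is None:
                continue  # whole array is one short run; leave it
            if right is None or (left is not None
                                 and (left[1] - left[0]) >= (right[1] - right[0])):
                cn[a:b] = left[2]
            else:
                cn[a:b] = right[2]
            changed = True
            break  # recompute runs after each absorption
    return cn


def segment_profile(profile: CNProfile, min_seg_bins: int = 3) -> list[CNVSegment]:
    """Merge equal-CN runs of a profile into gain/loss segments.

    Variant runs (cn != ploidy) shorter than ``min_seg_bins`` are absorbed
    into the flanking majority state and not reported.  Segment coordinates
    are the union of the member-bin intervals.  Runs never span chromosome
    boundaries.
    """
    if min_seg_bins < 1:
        raise ValidationError("min_seg_bins must be >= 1")
    bins = profile.bins
    segments: list[CNVSegment] = []
    # process each chromosome block independently
    chroms = bins.chrom
    block_start = 0
    n = len(profile)
    for i in range(1, n + 1):
        if i == n or chroms[i] != chroms[block_start]:
            cn_block = regularize_cn(profile.cn[block_start:i], profile.ploidy,
                                     min_seg_bins)
            for a, b, value in _runs(cn_block):
                if value == profile.ploidy or b - a < min_seg_bins:
                    continue
                ga, gb = block_start + a, block_start + b
                segments.append(CNVSegment(
                    chrom=str(chroms[block_start]),
                    start=int(bins.start[ga]),
                    end=int(bins.end[gb - 1]),
                    cn=value,
                    kind="gain" if value > profile.ploidy else "loss",
                    n_bins=b - a,
                ))
            block_start = i
    return segments


def evaluate_calls(truth, called, ploidy: int = 2,
                   strict: bool = False) -> tuple[ConfusionCounts, dict[str, float]]:
    """Bin-level confusion counts and the four benchmark metrics.

    A bin is positive when its true copy number differs from the ploidy.  By
    default a true positive only requires variant-vs-normal agreement (a
    called gain over a true loss still counts as detected); ``strict=True``
    additionally requires the exact copy number to match.
    """
    truth = np.asarray(truth, dtype=np.int64)
    called = np.asarray(called, dtype=np.int64)
    if truth.shape != called.shape:
        raise ValidationError("truth and called have different lengths")
    t_var = truth != ploidy
    c_var = called != ploidy
    if strict:
        tp = int(np.sum(t_var & c_var & (truth == called)))
        fn = int(np.sum(t_var) - tp)
    else:
        tp = int(np.sum(t_var & c_var))
        fn = int(np.sum(t_var & ~c_var))
    fp = int(np.sum(~t_var & c_var))
    tn = int(np.sum(~t_var & ~c_var))
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return counts, counts.metrics()
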