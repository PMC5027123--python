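"""Count-level simulation of single-cell CNV data and benchmark harness.

The generator emulates a chromosome-21-scale experiment: a 35,106,692-bp
diploid template tiled with 50-kb bins (702 bins, the last absorbing the
remainder), a background of ~228 reads per bin (160,452 reads at 0.22x
coverage), and NB over-dispersion alpha = 9.5 matching single-cell
whole-genome-amplification noise.  Ten non-overlapping CNVs of 300 kb to
2 Mb (6-40 bins) with copy number 1 or 3 are implanted per replicate, and
per-bin counts are drawn from NB(mean * cn/2, alpha).  These defaults are
the package's study conditions; scale them down only via the explicit
keyword arguments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (BinSet, CountTrack, NbcnvError, SolverConfig,
                   ValidationError)
from .calling import evaluate_calls, profile_from_fit, regularize_cn
from .distributions import fit_nb_mle
from .solver import admm_fit

CHR21_TEMPLATE_BP = 35_106_692
DEFAULT_BIN_SIZE = 50_000
DEFAULT_N_BINS = CHR21_TEMPLATE_BP // DEFAULT_BIN_SIZE  # 702
DEFAULT_MEAN_COUNT = 228.0                              # 160452 reads / 702 bins
DEFAULT_DISPERSION = 9.5
_SEED_MOD = 2**31


def _rng(seed: int, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((int(seed) + salt) % _SEED_MOD)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated replicate."""

    n_bins: int
    cn: np.ndarray
    events: list[tuple[int, int, int]]  # (start_bin, end_bin, cn), half-open
    seed: int
    mean_count: float = DEFAULT_MEAN_COUNT
    dispersion: float = DEFAULT_DISPERSION

    def __post_init__(self) -> None:
        self.cn = np.asarray(self.cn, dtype=np.int64)
        if len(self.cn) != self.n_bins:
            raise ValidationError("cn length does not match n_bins")
        ends = sorted(self.events)
        for (a1, b1, _), (a2, _, _) in zip(ends, ends[1:]):
            if a2 < b1:
                raise ValidationError("overlapping events")
        for a, b, c in self.events:
            if not np.all(self.cn[a:b] == c):
                raise ValidationError("cn array inconsistent with events")

    def to_dataframe(self, bins: BinSet | None = None) -> pd.DataFrame:
        if bins is None:
            bins = chr21_template_bins(self.n_bins)
        df = bins.to_dataframe()[["chrom", "start", "end"]]
        df["cn"] = self.cn
        return df


def chr21_template_bins(n_bins: int = DEFAULT_N_BINS,
                        template_bp: int = CHR21_TEMPLATE_BP) -> BinSet:
    """Uniform bin grid over the chromosome-21-sized template.

    The last bin absorbs the remainder so exactly ``n_bins`` bins tile the
    template.
    """
    width = template_bp // n_bins
    starts = np.arange(n_bins, dtype=np.int64) * width
    ends = np.append(starts[1:], template_bp)
    return BinSet(np.array(["chr21"] * n_bins, dtype=object), starts, ends)


def implant_cnvs(n_bins: int = DEFAULT_N_BINS, n_events: int = 10,
                 size_range_bins: tuple[int, int] = (6, 40),
                 states: tuple[int, ...] = (1, 3), seed: int = 0,
                 mean_count: float = DEFAULT_MEAN_COUNT,
                 dispersion: float = DEFAULT_DISPERSION,
                 max_rejections: int = 10_000) -> SimulationTruth:
    """Place non-overlapping CNV events uniformly at random.

    Events keep at least one normal bin between them (rejection sampling).
    Copy-number states are split evenly over ``states`` and assigned in a
    random order.  Reproducible for a fixed seed.
    """
    lo, hi = size_range_bins
    if lo < 1 or hi < lo:
        raise ValidationError("invalid size range")
    if n_events * hi > n_bins:
        raise ValidationError("events cannot fit into the template")
    rng = _rng(seed)
    cn = np.full(n_bins, 2, dtype=np.int64)
    # even split of states, leftovers assigned at random
    reps = [s for i, s in enumerate(sorted(states)) for _ in
            range(n_events // len(states) + (1 if i < n_events % len(states) else 0))]
    state_assignment = rng.permutation(np.array(reps, dtype=np.int64))
    events: list[tuple[int, int, int]] = []
    occupied = np.zeros(n_bins, dtype=bool)
    rejections = 0
    for k in range(n_events):
        size = int(rng.integers(lo, hi + 1))
        while True:
            start = int(rng.integers(0, n_bins - size + 1))
            pad_lo = max(start - 1, 0)
            pad_hi = min(start + size + 1, n_bins)
            if not occupied[pad_lo:pad_hi].any():
                break
            rejections += 1
            if rejections > max_rejections:
                raise NbcnvError(
                    f"could not place event {k + 1}/{n_events} after "
                    f"{max_rejections} rejections; template too crowded"
                )
        occupied[start:start + size] = True
        state = int(state_assignment[k])
        cn[start:start + size] = state
        events.append((start, start + size, state))
    events.sort()
    return SimulationTruth(n_bins=n_bins, cn=cn, events=events, seed=int(seed),
                           mean_count=mean_count, dispersion=dispersion)


def simulate_counts(truth: SimulationTruth, seed: int | None = None,
                    bins: BinSet | None = None) -> CountTrack:
    """Draw per-bin counts y_t ~ NB(mean_count * cn_t / 2, dispersion).

    The default stream is derived from ``truth.seed`` (offset so it is
    independent of the placement draws); identical inputs give identical
    tracks.
    """
    if not truth.mean_count > 0 or not truth.dispersion > 0:
        raise ValidationError("mean_count and dispersion must be positive")
    rng = _rng(truth.seed if seed is None else seed, salt=10_007)
    means = truth.mean_count * truth.cn / 2.0
    a = truth.dispersion
    counts = np.zeros(truth.n_bins, dtype=np.int64)
    pos = means > 0
    counts[pos] = rng.negative_binomial(a, a / (a + means[pos]))
    if bins is None:
        bins = chr21_template_bins(truth.n_bins)
    return CountTrack(bins=bins, counts=counts)


def simulate_toy_genome(length: int, alphabet: str = "ACGT", seed: int = 0,
                        repeat_block: tuple[int, int, int] | None = None
                        ) -> dict[str, str]:
    """Random toy genome (single chromosome) for exercising the binning code.

    ``repeat_block = (src, dest, size)`` copies ``size`` bases from position
    ``src`` to ``dest``, creating duplicated k-mers and hence non-uniquely-
    mappable positions.
    """
    rng = _rng(seed)
    seq = rng.choice(list(alphabet), size=length)
    if repeat_block is not None:
        src, dest, size = repeat_block
        if src + size > length or dest + size > length:
            raise ValidationError("repeat block outside sequence")
        seq[dest:dest + size] = seq[src:src + size]
    return {"chr1": "".join(seq)}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# lambda-grid pruning
# ---------------------------------------------------------------------------


def tune_lambdas(clean_track: CountTrack, grid1, grid2, seed: int = 0,
                 dispersion: float | None = None, n_events: int = 10,
                 size_range_bins: tuple[int, int] = (6, 40),
                 solver_kwargs: dict | None = None
                 ) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Grid search for the penalty weights on a copy-neutral track.

    +/-1-CN events are implanted into the clean track's expected signal and
    re-noised with the NB model; the solver runs per (lambda1, lambda2) and
    the Euclidean distance between the fitted signal and the true signal
    (both on the copy-number scale) is recorded.  Solver failures mark the
    cell NaN.

    Returns the distance matrix (rows = lambda1, columns = lambda2) and the
    argmin pair.
    """
    grid1 = list(grid1)
    grid2 = list(grid2)
    if not grid1 or not grid2:
        raise ValidationError("grids must be nonempty")
    m = float(np.mean(clean_track.counts))
    if dispersion is None:
        dispersion = fit_nb_mle(clean_track.counts).dispersion
    n = len(clean_track)
    truth = implant_cnvs(n_bins=n, n_events=n_events,
                         size_range_bins=size_range_bins, states=(1, 3),
                         seed=seed, mean_count=m, dispersion=dispersion)
    track = simulate_counts(truth, bins=clean_track.bins)
    y = track.counts
    c = float(np.mean(y))
    mat = np.full((len(grid1), len(grid2)), np.nan)
    for i, l1 in enumerate(grid1):
        for j, l2 in enumerate(grid2):
            cfg = SolverConfig(lambda1=float(l1), lambda2=float(l2),
                               dispersion=float(dispersion),
                               **(solver_kwargs or {}))
            try:
                x, _ = admm_fit(y, cfg)
            except NbcnvError as exc:  # pragma: no cover - defensive
                warnings.warn(f"solver failed at lambda=({l1}, {l2}): {exc}")
                continue
            fitted_cn = 2.0 * x / c
            mat[i, j] = float(np.linalg.norm(fitted_cn - truth.cn))
    df = pd.DataFrame(mat, index=pd.Index(grid1, name="lambda1"),
                      columns=pd.Index(grid2, name="lambda2"))
    if np.all(np.isnan(mat)):
        raise NbcnvError("solver failed on every grid cell")
    i, j = np.unravel_index(np.nanargmin(mat), mat.shape)
    return df, (float(grid1[i]), float(grid2[j]))


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------


def run_benchmark(n_replicates: int,
                  solver_cfgs: dict[str, SolverConfig] | None = None,
                  seed: int = 0, n_bins: int = DEFAULT_N_BINS,
                  n_events: int = 10,
                  size_range_bins: tuple[int, int] = (6, 40),
                  mean_count: float = DEFAULT_MEAN_COUNT,
                  dispersion: float = DEFAULT_DISPERSION,
                  min_seg_bins: int = 3,
                  return_replicates: bool = False):
    """Repeated simulate-call-score experiment.

    Per replicate: implant CNVs, draw NB counts, run each configured solver,
    translate to integer CN, regularize short runs, and score the bin-level
    confusion against the truth.  Replicate seeds are master seed + index.

    Returns a DataFrame of mean and standard deviation of the four metrics
    per method (and, with ``return_replicates``, the per-replicate table).
    """
    if n_replicates < 2:
        raise ValidationError("need at least 2 replicates")
    if solver_cfgs is None:
        solver_cfgs = {
            "nbCNV": SolverConfig(fidelity="negative_binomial",
                                  dispersion=dispersion),
            "poiCNV": SolverConfig(fidelity="poisson", dispersion=dispersion),
        }
    rows = []
    for r in range(n_replicates):
        rep_seed = (seed + r) % _SEED_MOD
        truth = implant_cnvs(n_bins=n_bins, n_events=n_events,
                             size_range_bins=size_range_bins, states=(1, 3),
                             seed=rep_seed, mean_count=mean_count,
                             dispersion=dispersion)
        track = simulate_counts(truth)
        y = track.counts
        c = float(np.mean(y))
        try:
            rep_rows = []
            for name, cfg in solver_cfgs.items():
                x, state = admm_fit(y, cfg)
                profile = profile_from_fit(x, baseline_c=c, ploidy=2,
                                           bins=track.bins)
                called = regularize_cn(profile.cn, 2, min_seg_bins)
                _, metrics = evaluate_calls(truth.cn, called, ploidy=2)
                rep_rows.append({"method": name, "replicate": r, **metrics})
        except NbcnvError as exc:
            warnings.warn(f"replicate {r} excluded (solver failure: {exc})")
            continue
        rows.extend(rep_rows)
    per_rep = pd.DataFrame(rows)
    if per_rep.empty:
        raise NbcnvError("all replicates failed")
    metrics = ["accuracy", "precision", "sensitivity", "specificity"]
    summary = per_rep.groupby("method")[metrics].agg(["mean", "std"])
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    if return_replicates:
        return summary, per_rep
    return summary
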