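"""statsmodels-style front end: a model bound to one count track whose
``fit`` runs the penalized-likelihood solver and returns a results object
with the copy-number profile, segments, diagnostics and a summary table.

Example
-------
>>> from nbcnv import CNVModel
>>> from nbcnv.simulate import implant_cnvs, simulate_counts
>>> track = simulate_counts(implant_cnvs(seed=1))
>>> res = CNVModel(track, dispersion=9.5).fit(lambda1=1.0, lambda2=1.0)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .calling import evaluate_calls, profile_from_fit, regularize_cn, segment_profile
from .core import (CNProfile, CountTrack, SolverConfig, ValidationError)
from .distributions import fit_nb_mle
from .preprocess import compute_rd, gc_normalize
from .solver import ADMMState, admm_fit


class CNVModel:
    """Copy-number model for one binned read-count track.

    The per-bin counts are treated as negative-binomially distributed around
    a piecewise-constant copy-number signal, which is recovered by ADMM as
    the minimizer of the NB negative log-likelihood plus a total-variation
    (smoothness) and a baseline-centered L1 (sparsity) penalty.

    Parameters
    ----------
    track : CountTrack
        Bins and raw counts for a single cell.
    dispersion : float, optional
        NB over-dispersion alpha.  Best estimated on a known copy-neutral
        track (:func:`nbcnv.distributions.fit_nb_mle`); when omitted it is
        estimated from this track itself, which inflates alpha when real
        CNVs are present (a warning is emitted).
    ploidy : int
        Baseline copy number of the cell (2 for diploid).
    fidelity : {"negative_binomial", "poisson"}
        Likelihood of the fidelity term; "poisson" reproduces the earlier
        Poisson-model caller used as a baseline.
    gc_correction : {"auto", True, False}
        LOWESS GC normalization before solving; "auto" applies it whenever
        the bins carry GC values.
    baseline : float, optional
        Copy-neutral count level c.  Defaults to the mean of the (possibly
        normalized) counts.
    """

    def __init__(self, track: CountTrack, dispersion: float | None = None,
                 ploidy: int = 2, fidelity: str = "negative_binomial",
                 gc_correction="auto", baseline: float | None = None,
                 lowess_frac: float = 0.3):
        if ploidy < 1:
            raise ValidationError("ploidy must be >= 1")
        self.track = track
        self.dispersion = dispersion
        self.ploidy = int(ploidy)
        self.fidelity = fidelity
        self.baseline = baseline
        use_gc = track.bins.has_gc if gc_correction == "auto" else bool(gc_correction)
        if use_gc:
            self.normalized = gc_normalize(track, frac=lowess_frac)
        else:
            self.normalized = track
        self.normalized = compute_rd(self.normalized)
        self.gc_corrected = use_gc

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CNVModel":
        """Build a model from a DataFrame with columns
        chrom, start, end, count and optionally gc."""
        from .core import BinSet

        for col in ("chrom", "start", "end", "count"):
            if col not in df.columns:
                raise ValidationError(f"missing column '{col}'")
        gc = df["gc"].to_numpy(dtype=float) if "gc" in df.columns else None
        bins = BinSet(df["chrom"].to_numpy(dtype=object),
                      df["start"].to_numpy(dtype=np.int64),
                      df["end"].to_numpy(dtype=np.int64), gc)
        return cls(CountTrack(bins, df["count"].to_numpy(dtype=float)), **kwargs)

    def fit(self, lambda1: float = 1.0, lambda2: float = 1.0,
            admm_penalty: float = 1.0, max_iter: int = 2000,
            tol: float = 1e-6, min_seg_bins: int = 3) -> "CNVResults":
        """Run the ADMM solver and translate the fit into CN calls.

        lambda1/lambda2 weigh smoothness and sparsity per unit of relative
        read depth; 1.0 is the pruned default for both.
        """
        y = self.normalized.counts
        alpha = self.dispersion
        if alpha is None:
            alpha = fit_nb_mle(y).dispersion
            warnings.warn(
                "dispersion estimated from the analyzed track itself; "
                "prefer a copy-neutral reference track"
            )
        cfg = SolverConfig(lambda1=lambda1, lambda2=lambda2,
                           baseline_c=self.baseline, dispersion=float(alpha),
                           admm_penalty=admm_penalty, max_iter=max_iter,
                           tol=tol, fidelity=self.fidelity)
        x, state = admm_fit(y, cfg)
        return CNVResults(self, cfg, x, state, min_seg_bins)


class CNVResults:
    """Fit results: fitted signal, CN profile, segments and diagnostics."""

    def __init__(self, model: CNVModel, config: SolverConfig,
                 fitted: np.ndarray, state: ADMMState, min_seg_bins: int):
        self.model = model
        self.config = config
        self.fitted = fitted
        self.state = state
        self.min_seg_bins = int(min_seg_bins)
        y = model.normalized.counts
        self.baseline_ = (config.baseline_c if config.baseline_c is not None
                          else float(np.mean(y)))
        raw_profile = profile_from_fit(fitted, self.baseline_, model.ploidy,
                                       bins=model.track.bins)
        cn = regularize_cn(raw_profile.cn, model.ploidy, self.min_seg_bins)
        self.profile = CNProfile(bins=model.track.bins, fitted=fitted,
                                 cn=cn, ploidy=model.ploidy)
        self.segments = segment_profile(self.profile, self.min_seg_bins)

    # -- accessors ----------------------------------------------------------

    @property
    def fitted_cn(self) -> np.ndarray:
        """Continuous copy-number signal ploidy * fitted / baseline."""
        return self.model.ploidy * self.fitted / self.baseline_

    @property
    def cn(self) -> np.ndarray:
        return self.profile.cn

    @property
    def n_iter(self) -> int:
        return self.state.n_iter

    def evaluate(self, truth_cn, strict: bool = False):
        """Bin-level confusion counts and metrics against a known truth."""
        return evaluate_calls(truth_cn, self.profile.cn,
                              ploidy=self.model.ploidy, strict=strict)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        n = len(m.track)
        gains = [s for s in self.segments if s.kind == "gain"]
        losses = [s for s in self.segments if s.kind == "loss"]
        var_bins = int(np.sum(self.profile.cn != m.ploidy))
        rows = [
            ("No. bins", f"{n}"),
            ("Fidelity", m.fidelity),
            ("GC corrected", str(m.gc_corrected)),
            ("Dispersion (alpha)", f"{self.config.dispersion:.4g}"),
            ("lambda1 (smoothness)", f"{self.config.lambda1:.4g}"),
            ("lambda2 (sparsity)", f"{self.config.lambda2:.4g}"),
            ("Baseline c", f"{self.baseline_:.4g}"),
            ("Ploidy", f"{m.ploidy}"),
            ("ADMM iterations", f"{self.state.n_iter}"
             + ("" if self.state.converged else " (not converged)")),
            ("Primal residual", f"{self.state.primal_residual:.3e}"),
            ("Dual residual", f"{self.state.dual_residual:.3e}"),
            ("Variant bins", f"{var_bins} / {n}"),
            ("Gain segments", f"{len(gains)}"),
            ("Loss segments", f"{len(losses)}"),
        ]
        width = max(len(k) for k, _ in rows) + 2
        lines = ["Copy-number fit (penalized NB likelihood, ADMM)",
                 "=" * 48]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        if self.segments:
            lines.append("-" * 48)
            lines.append(f"{'segment':<28}{'kind':<7}{'CN':>3}{'bins':>6}")
            for s in self.segments:
                loc = f"{s.chrom}:{s.start}-{s.end}"
                lines.append(f"{loc:<28}{s.kind:<7}{s.cn:>3}{s.n_bins:>6}")
        return "\n".join(lines)

    def segments_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "chrom": s.chrom, "start": s.start, "end": s.end,
            "cn": s.cn, "kind": s.kind, "n_bins": s.n_bins,
        } for s in self.segments])

    def plot(self, ax=None):
        """Plot normalized counts, the fitted signal and integer CN calls."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3.5))
        y = self.model.normalized.counts
        scale = self.model.ploidy / self.baseline_
        ax.plot(np.arange(len(y)), y * scale, ".", ms=2, color="0.6",
                label="observed RD (CN units)")
        ax.plot(self.fitted_cn, color="C0", lw=1.5, label="fitted signal")
        ax.step(np.arange(len(y)), self.profile.cn, where="mid", color="C3",
                lw=1.0, label="called CN")
        ax.set_xlabel("bin")
        ax.set_ylabel("copy number")
        ax.legend(loc="upper right", fontsize=8)
        return ax
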