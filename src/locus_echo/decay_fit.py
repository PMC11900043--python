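"""Fit a correlation-vs-distance decay curve per locus.

Neighbor co-expression falls off with genomic separation; the working model is
an exponential with offset,

    pcc(d) = c + a * exp(-|d| / lambda),

with amplitude ``a``, decay length ``lambda`` (bp) and baseline ``c``.  A
power-law alternative ``c + a * (|d|/1kb)^-alpha`` is available behind the
``model`` flag.  Fits use multistart nonlinear least squares; when the
amplitude is statistically indistinguishable from zero the locus is reported
as flat (a = 0, c = mean PCC).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

#: multistart initial decay lengths, bp
LAMBDA_STARTS = (1_000.0, 5_000.0, 25_000.0)
LAMBDA_BOUNDS = (100.0, 1e7)


class DecayFitError(RuntimeError):
    """Raised when a fit cannot be performed; may carry a partial fit."""

    def __init__(self, message: str, partial: "DecayFit | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass
class DecayFit:
    """Fitted decay parameters for one locus."""

    a: float  # amplitude, unitless
    lam: float  # decay length, bp (NaN when flat)
    c: float  # baseline offset
    rss: float
    n_points: int
    flat_flag: bool
    model: str = "exponential"

    def predict(self, distances: Sequence[float]) -> np.ndarray:
        d = np.abs(np.asarray(distances, dtype=float))
        if self.flat_flag or not np.isfinite(self.lam):
            return np.full_like(d, self.c)
        if self.model == "exponential":
            return self.c + self.a * np.exp(-d / self.lam)
        return self.c + self.a * np.power(np.maximum(d, 1.0) / 1_000.0, -self.lam)


def _exp_model(d, a, lam, c):
    return c + a * np.exp(-d / lam)


def _pow_model(d, a, alpha, c):
    return c + a * np.power(np.maximum(d, 1.0) / 1_000.0, -alpha)


def fit_decay(
    points: Sequence[tuple[float, float]],
    model: str = "exponential",
    flat_alpha: float = 0.05,
) -> DecayFit:
    """Least-squares fit of PCC versus |genomic distance|.

    Parameters
    ----------
    points
        Iterable of ``(distance_bp, pcc)``; distances may be signed, only the
        magnitude is used.  Requires >= 4 points with >= 3 distinct |d|.
    model
        ``"exponential"`` (default) or ``"power"``.
    flat_alpha
        Two-sided level for the amplitude's flatness check: when the
        amplitude confidence interval covers zero the flat model is returned.
    """
    pts = [(abs(float(d)), float(r)) for d, r in points if np.isfinite(r)]
    if len(pts) < 4:
        raise DecayFitError(f"need >= 4 finite points, got {len(pts)}")
    d = np.array([p[0] for p in pts])
    r = np.array([p[1] for p in pts])
    if len(np.unique(d)) < 3:
        raise DecayFitError("need >= 3 distinct |distance| values")

    n = len(pts)
    c_flat = float(r.mean())
    rss_flat = float(((r - c_flat) ** 2).sum())

    def flat_fit() -> DecayFit:
        return DecayFit(a=0.0, lam=float("nan"), c=c_flat, rss=rss_flat,
                        n_points=n, flat_flag=True, model=model)

    if np.ptp(r) == 0:  # constant input: no decay estimable
        return flat_fit()

    func = _exp_model if model == "exponential" else _pow_model
    lam_bounds = LAMBDA_BOUNDS if model == "exponential" else (0.01, 10.0)
    lam_starts = LAMBDA_STARTS if model == "exponential" else (0.5, 1.0, 2.0)
    a_init = float(r.max() - r.min())
    c_init = float(r.min())

    best = None
    for lam0 in lam_starts:
        try:
            popt, pcov = curve_fit(
                func,
                d,
                r,
                p0=[a_init, lam0, c_init],
                bounds=([-2.0, lam_bounds[0], -1.0], [2.0, lam_bounds[1], 1.0]),
                maxfev=20_000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(((r - func(d, *popt)) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise DecayFitError("no start converged", partial=flat_fit())

    rss, (a, lam, c), pcov = best
    # flatness: amplitude CI covering 0, or no improvement over the flat model
    dof = max(n - 3, 1)
    with np.errstate(invalid="ignore"):
        se_a = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    from scipy import stats as _st

    tcrit = _st.t.ppf(1 - flat_alpha / 2, dof)
    if rss > rss_flat or (se_a == np.inf) or abs(a) <= tcrit * se_a:
        return flat_fit()
    return DecayFit(a=float(a), lam=float(lam), c=float(c), rss=rss,
                    n_points=n, flat_flag=False, model=model)


def write_fits(fits: dict[str, DecayFit], path: str | Path) -> None:
    """Export per-locus fits as TSV (locus, a, lambda, c, rss, n, flat_flag)."""
    import pandas as pd

    rows = [
        {
            "locus": locus,
            "a": f.a,
            "lambda_bp": f.lam,
            "c": f.c,
            "rss": f.rss,
            "n_points": f.n_points,
            "flat_flag": f.flat_flag,
            "model": f.model,
        }
        for locus, f in fits.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plot_fit(
    points: Sequence[tuple[float, float]], fit: DecayFit, path: str | Path,
    title: str = "",
) -> None:
    """Scatter the (|d|, pcc) points with the fitted curve overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = np.abs(np.array([p[0] for p in points], dtype=float))
    r = np.array([p[1] for p in points], dtype=float)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(d / 1_000.0, r, "o", label="neighbor PCC")
    grid = np.linspace(0, max(d.max(), 1.0), 200)
    ax.plot(grid / 1_000.0, fit.predict(grid), "-", label="fitted decay")
    ax.set_xlabel("genomic distance (kb)")
    ax.set_ylabel("PCC")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
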