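"""Relative expression from qPCR cycle thresholds by the 2^-ddCt method.

For each strain, dCt = mean Ct(target) - mean Ct(reference gene, ACT1 by
default); ddCt subtracts the calibrator strain's dCt, and the fold change is
2^-ddCt, assuming a doubling per cycle.  Reactions failing the melt-curve
check (multiple amplicons) are excluded before any averaging.  Statistics are
computed on log2 folds, where Gaussian Ct noise is additive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_REFERENCE = "ACT1"
LN2 = np.log(2.0)


class QpcrError(ValueError):
    """Invalid Ct table input."""


@dataclass
class ExpressionEstimate:
    strain: str
    gene: str
    dct: float  # cycles
    ddct: float  # cycles
    fold: float  # 2^-ddct
    sem: float  # fold units, delta-method from replicate Ct variability
    n: int  # replicates retained after melt filtering
    replicate_log2_folds: np.ndarray  # per-replicate log2 folds (for testing)


def _mean_ct(sub: pd.DataFrame, strain: str, gene: str) -> tuple[float, np.ndarray]:
    rows = sub[(sub["strain"] == strain) & (sub["gene"] == gene)]
    if rows.empty:
        raise QpcrError(f"no usable {gene} reactions for strain {strain!r}")
    ct = rows["Ct"].to_numpy(dtype=float)
    if np.any(ct <= 0):
        raise QpcrError(f"non-positive Ct for {strain}/{gene}")
    return float(ct.mean()), ct


def ddct(
    table: pd.DataFrame,
    target: str,
    reference: str = DEFAULT_REFERENCE,
    calibrator: str = "WT",
    *,
    efficiency: float = 2.0,
) -> dict[str, ExpressionEstimate]:
    """Per-strain relative expression of ``target`` vs ``reference``.

    ``table`` needs columns (strain, gene, replicate, Ct, melt_ok).  Rows with
    ``melt_ok == False`` are dropped first; a strain whose every replicate is
    filtered is dropped with a warning; a strain missing the reference gene is
    an error.  ``efficiency`` generalizes the classic assumption of perfect
    doubling (fold = E^-ddCt).
    """
    required = {"strain", "gene", "replicate", "Ct", "melt_ok"}
    missing = required - set(table.columns)
    if missing:
        raise QpcrError(f"Ct table missing columns: {sorted(missing)}")
    usable = table[table["melt_ok"].astype(bool)]
    strains = list(dict.fromkeys(table["strain"]))
    if calibrator not in strains:
        raise QpcrError(f"calibrator strain {calibrator!r} absent from table")

    kept = []
    for strain in strains:
        sub = usable[usable["strain"] == strain]
        if sub[sub["gene"] == target].shape[0] < 2:
            if table[(table["strain"] == strain) & (table["gene"] == target)].shape[0]:
                warnings.warn(
                    f"strain {strain!r}: <2 usable {target} replicates after "
                    "melt filtering; dropped"
                )
                continue
            raise QpcrError(f"no {target} reactions for strain {strain!r}")
        if sub[sub["gene"] == reference].empty:
            raise QpcrError(f"missing reference gene {reference!r} for {strain!r}")
        kept.append(strain)
    if calibrator not in kept:
        raise QpcrError(f"calibrator {calibrator!r} lost to melt filtering")

    log2e = np.log2(efficiency)

    def dct_of(strain: str) -> tuple[float, np.ndarray, np.ndarray]:
        mean_t, ct_t = _mean_ct(usable, strain, target)
        mean_r, ct_r = _mean_ct(usable, strain, reference)
        return mean_t - mean_r, ct_t, ct_r

    cal_dct, _, _ = dct_of(calibrator)
    out: dict[str, ExpressionEstimate] = {}
    for strain in kept:
        dct_val, ct_t, ct_r = dct_of(strain)
        ddct_val = dct_val - cal_dct
        fold = float(efficiency ** (-ddct_val))
        # delta method: var(dCt) from replicate scatter of both genes
        var_dct = ct_t.var(ddof=1) / len(ct_t) + ct_r.var(ddof=1) / len(ct_r)
        sem_fold = fold * LN2 * log2e * float(np.sqrt(var_dct))
        # per-replicate folds: pair target and reference Cts replicate-wise so
        # reference scatter enters each replicate's fold; subtracting the mean
        # reference instead would shift all of a strain's folds together and
        # hide reference noise from between-strain tests
        sub = usable[usable["strain"] == strain]
        paired = pd.merge(
            sub[sub["gene"] == target][["replicate", "Ct"]],
            sub[sub["gene"] == reference][["replicate", "Ct"]],
            on="replicate",
            suffixes=("_t", "_r"),
        )
        if len(paired) >= 2:
            rep_dct = paired["Ct_t"].to_numpy(float) - paired["Ct_r"].to_numpy(float)
        else:  # unpaired plates: fall back to the strain's mean reference Ct
            rep_dct = ct_t - ct_r.mean()
        rep_log2 = -(rep_dct - cal_dct) * log2e
        out[strain] = ExpressionEstimate(
            strain=strain,
            gene=target,
            dct=float(dct_val),
            ddct=float(ddct_val),
            fold=fold,
            sem=float(sem_fold),
            n=len(ct_t),
            replicate_log2_folds=rep_log2,
        )
    return out


@dataclass
class ExpressionComparison:
    strain_a: str
    strain_b: str
    t_stat: float
    p_value: float
    log2_fold_diff: float
    significant: bool


def compare_expression(
    a: ExpressionEstimate, b: ExpressionEstimate, alpha: float = 0.05
) -> ExpressionComparison:
    """Two-sided t-test of two strains' replicate-level log2 folds."""
    xa, xb = a.replicate_log2_folds, b.replicate_log2_folds
    if len(xa) < 2 or len(xb) < 2:
        raise QpcrError("need >= 2 replicate folds per strain")
    if np.array_equal(xa, xb):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(xa, xb, equal_var=True)
        if np.isnan(p):
            t, p = 0.0, 1.0
    return ExpressionComparison(
        strain_a=a.strain,
        strain_b=b.strain,
        t_stat=float(t),
        p_value=float(p),
        log2_fold_diff=float(xa.mean() - xb.mean()),
        significant=bool(p < alpha),
    )


def estimates_to_frame(estimates: dict[str, ExpressionEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain": e.strain,
                "gene": e.gene,
                "dCt": e.dct,
                "ddCt": e.ddct,
                "fold": e.fold,
                "sem": e.sem,
                "n": e.n,
            }
            for e in estimates.values()
        ]
    )


def plot_folds(estimates: dict[str, ExpressionEstimate], path, title: str = "") -> None:
    """Bar plot of per-strain fold changes with SEM error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strains = list(estimates)
    folds = [estimates[s].fold for s in strains]
    sems = [estimates[s].sem for s in strains]
    fig, ax = plt.subplots(figsize=(1 + 0.8 * len(strains), 3.2))
    ax.bar(strains, folds, yerr=sems, capsize=3, color="#4477aa")
    ax.axhline(1.0, ls="--", c="grey", lw=0.8)
    ax.set_ylabel("relative expression (2^-ddCt)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
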