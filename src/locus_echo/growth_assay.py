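"""Spotting-assay quantification: growth indices, stress/control ratios,
mutant-vs-wild-type testing and the locus heatmap.

A spotting assay plates 5-fold serial dilutions of each culture; each spot is
scored in [0, 1] (0 = no growth, 1 = confluent).  The growth index of a grid
is the sum of its per-dilution scores, so a strain growing out to deeper
dilutions scores higher; relative growth is the mean stressed index over the
mean control index.  Mutants are compared to the wild type with a two-sided
Student's t-test (pooled variance) at alpha = 0.05, with Welch's test
available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


class GrowthInputError(ValueError):
    """Invalid spotting-score input."""


@dataclass
class GrowthGrid:
    """One replicate's dilution series for one strain under one condition."""

    strain: str
    condition: str
    replicate: str | int
    scores: Sequence[float]  # ordered by dilution step

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        if arr.size == 0:
            raise GrowthInputError("empty score list")
        if np.any((arr < 0) | (arr > 1)):
            raise GrowthInputError(
                f"scores outside [0, 1] for {self.strain}/{self.condition}"
            )
        self.scores = arr


def grids_from_frame(df: pd.DataFrame) -> list[GrowthGrid]:
    """Build grids from a long table (strain, condition, replicate, dilution, score).

    ``bio_rep``/``tech_rep`` columns, when present, are combined into one
    replicate id; dilution steps are sorted within each grid.
    """
    df = df.copy()
    if "replicate" not in df.columns:
        if {"bio_rep", "tech_rep"} <= set(df.columns):
            df["replicate"] = (
                df["bio_rep"].astype(str) + "." + df["tech_rep"].astype(str)
            )
        else:
            raise GrowthInputError("need a replicate (or bio_rep/tech_rep) column")
    grids = []
    for (strain, cond, rep), sub in df.groupby(
        ["strain", "condition", "replicate"], sort=True
    ):
        sub = sub.sort_values("dilution")
        grids.append(
            GrowthGrid(strain=strain, condition=cond, replicate=rep,
                       scores=sub["score"].to_list())
        )
    return grids


def growth_index(grid: GrowthGrid) -> float:
    """Sum of per-dilution scores; ranges from 0 to the number of steps."""
    return float(np.sum(grid.scores))


def relative_growth(
    stress: Sequence[GrowthGrid], control: Sequence[GrowthGrid]
) -> float:
    """Mean stressed growth index divided by mean control growth index.

    Returns NaN (undefined, never 0) when the control shows no growth.
    """
    if not stress or not control:
        raise GrowthInputError("need at least one grid per condition")
    strains = {g.strain for g in stress} | {g.strain for g in control}
    if len(strains) > 1:
        raise GrowthInputError(f"grids mix strains: {sorted(strains)}")
    control_mean = float(np.mean([growth_index(g) for g in control]))
    stress_mean = float(np.mean([growth_index(g) for g in stress]))
    if control_mean == 0:
        return float("nan")
    return stress_mean / control_mean


@dataclass
class GrowthResult:
    strain: str
    condition: str
    growth_index: float
    relative_growth: float
    n: int
    n_wt: int
    sem: float
    sem_wt: float
    t_stat: float
    p_vs_wt: float
    significant: bool


def compare_to_wt(
    mutant: Sequence[float],
    wt: Sequence[float],
    *,
    strain: str = "mutant",
    condition: str = "",
    equal_var: bool = True,
    alpha: float = ALPHA,
) -> GrowthResult:
    """Two-sample t-test of per-replicate mutant values against wild type.

    ``mutant`` and ``wt`` are per-biological-replicate summaries (technical
    replicates should be averaged first to avoid pseudo-replication).  The
    default is Student's pooled-variance t; ``equal_var=False`` gives Welch.
    """
    m = np.asarray(mutant, dtype=float)
    w = np.asarray(wt, dtype=float)
    if m.size < 2 or w.size < 2:
        raise GrowthInputError("need >= 2 replicates per group")
    t, p = stats.ttest_ind(m, w, equal_var=equal_var)
    if math.isnan(p):  # both groups constant and equal
        t, p = 0.0, 1.0
    wt_mean = float(w.mean())
    return GrowthResult(
        strain=strain,
        condition=condition,
        growth_index=float(m.mean()),
        relative_growth=float(m.mean() / wt_mean) if wt_mean != 0 else float("nan"),
        n=m.size,
        n_wt=w.size,
        sem=float(stats.sem(m)),
        sem_wt=float(stats.sem(w)),
        t_stat=float(t),
        p_vs_wt=float(p),
        significant=bool(p < alpha),
    )


def average_technical_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical replicates to one growth index per biological replicate.

    Expects columns (strain, condition, bio_rep, tech_rep, dilution, score);
    returns (strain, condition, bio_rep, growth_index).
    """
    idx = (
        df.groupby(["strain", "condition", "bio_rep", "tech_rep"])["score"]
        .sum()
        .reset_index(name="growth_index")
    )
    return (
        idx.groupby(["strain", "condition", "bio_rep"])["growth_index"]
        .mean()
        .reset_index()
    )


#: sentinel carried in heatmap cells whose deletion strain cannot exist
UNAVAILABLE = "essential"

POSITIONS = ("-1", "FT", "+1")


def locus_growth_heatmap(
    results: Mapping[str, Mapping[str, float | str]],
    locus_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the locus x position matrix of relative growth.

    ``results`` maps each focal (freeze-thaw) gene to a mapping over positions
    ``"-1"`` (centromeric flank), ``"FT"`` and ``"+1"`` (telomeric flank);
    values are relative-growth numbers or the string :data:`UNAVAILABLE` for
    essential-gene flanks whose deletion strain does not exist.  Unavailable
    cells stay marked, never coerced to 0.
    """
    loci = list(locus_order) if locus_order is not None else list(results)
    mat = pd.DataFrame(index=loci, columns=list(POSITIONS), dtype=object)
    for locus in loci:
        for pos in POSITIONS:
            val = results.get(locus, {}).get(pos, np.nan)
            mat.loc[locus, pos] = val
    return mat


def plot_growth_heatmap(matrix: pd.DataFrame, path) -> None:
    """Render the locus heatmap; unavailable cells are hatched with a label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    numeric = matrix.map(lambda v: np.nan if isinstance(v, str) else float(v))
    fig, ax = plt.subplots(figsize=(4, 0.6 * len(matrix) + 1.5))
    im = ax.imshow(numeric.to_numpy(dtype=float), cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    for i, locus in enumerate(matrix.index):
        for j, pos in enumerate(matrix.columns):
            if isinstance(matrix.loc[locus, pos], str):
                ax.text(j, i, "ess.", ha="center", va="center", color="red")
    fig.colorbar(im, ax=ax, label="relative growth (stress / control)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
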