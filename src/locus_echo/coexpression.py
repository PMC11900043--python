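"""Focal-vs-neighbor Pearson correlation across condition blocks.

A "block" is one stressor time series (e.g. a 30->37 degC heat shock) or the
synchronized cell-cycle course; correlations are always computed within a
block, because pooling across stressors with different mean responses
manufactures spurious correlation.  Undefined correlations (too few complete
pairs, zero variance) propagate as missing values, never as zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .genome_map import NeighborhoodMap

logger = logging.getLogger(__name__)

#: minimum complete observation pairs for a reported correlation
MIN_PAIRS = 3

#: |PCC| above this marks a strong transcriptional relationship
STRONG_PCC = 0.5


class ExpressionError(ValueError):
    """Inconsistent expression matrix / manifest input."""


@dataclass
class ExpressionMatrix:
    """Gene x sample log-ratio values plus a sample -> block manifest."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    block_manifest: pd.Series  # index: sample ids, values: block names

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.block_manifest.index]
        if missing:
            raise ExpressionError(f"samples absent from manifest: {missing}")
        if self.values.index.duplicated().any():
            raise ExpressionError("duplicate gene ids in expression matrix")
        self.values.index.name = "gene_id"
        counts = self.block_manifest.loc[list(self.values.columns)].value_counts()
        logger.info("samples per block: %s", counts.to_dict())

    def blocks(self) -> list[str]:
        return list(dict.fromkeys(self.block_manifest.loc[list(self.values.columns)]))

    def block_samples(self, block: str) -> list[str]:
        return [s for s in self.values.columns if self.block_manifest[s] == block]

    def gene(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.values.index:
            raise KeyError(gene_id)
        return self.values.loc[gene_id].to_numpy(dtype=float)

    def to_files(self, matrix_path: str | Path, manifest_path: str | Path) -> None:
        self.values.rename_axis("gene_id").to_csv(matrix_path, sep="\t")
        self.block_manifest.rename_axis("sample_id").rename("block_name").to_csv(
            manifest_path, sep="\t"
        )


def load_expression(matrix_path: str | Path, manifest_path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited gene x sample table and its block manifest."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    manifest = pd.read_csv(manifest_path, sep="\t", index_col=0)["block_name"]
    return ExpressionMatrix(values=values, block_manifest=manifest)


def pcc(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Pearson product-moment correlation on pairwise-complete observations.

    Returns ``(r, n_pairs)``.  ``r`` is NaN (an undefined-correlation signal)
    when fewer than :data:`MIN_PAIRS` complete pairs remain or either series
    has zero variance.  Identical complete-pair series return exactly 1.0
    (self-comparison guarantee).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[mask], y[mask]
    n = int(mask.sum())
    if n < MIN_PAIRS:
        return float("nan"), n
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan"), n
    if np.array_equal(xs, ys):
        return 1.0, n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = stats.pearsonr(xs, ys).statistic
    return float(np.clip(r, -1.0, 1.0)), n


@dataclass(frozen=True)
class ProfileEntry:
    neighbor: str
    signed_distance: float
    pcc: float  # NaN when undefined
    n_pairs: int


@dataclass
class CorrelationProfile:
    """Per-locus focal-vs-neighbor correlations within one condition block."""

    focal: str
    block: str
    entries: list[ProfileEntry] = field(default_factory=list)

    def defined(self) -> list[ProfileEntry]:
        return [e for e in self.entries if not np.isnan(e.pcc)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "focal": self.focal,
                    "block": self.block,
                    "neighbor": e.neighbor,
                    "distance_bp": e.signed_distance,
                    "pcc": e.pcc,
                    "n_pairs": e.n_pairs,
                }
                for e in self.entries
            ]
        )


def locus_profile(
    expr: ExpressionMatrix, nbhd: NeighborhoodMap, block: str
) -> CorrelationProfile:
    """Correlate the focal gene with each neighbor over one block's samples."""
    if nbhd.focal not in expr.values.index:
        raise ExpressionError(f"focal gene {nbhd.focal!r} absent from matrix")
    samples = expr.block_samples(block)
    if not samples:
        raise ExpressionError(f"block {block!r} has no samples")
    focal_vals = expr.values.loc[nbhd.focal, samples].to_numpy(dtype=float)
    entries = []
    skipped = []
    for nb in nbhd.neighbors:
        if nb.gene_id not in expr.values.index:
            skipped.append(nb.gene_id)
            continue
        nb_vals = expr.values.loc[nb.gene_id, samples].to_numpy(dtype=float)
        r, n = pcc(focal_vals, nb_vals)
        entries.append(
            ProfileEntry(
                neighbor=nb.gene_id, signed_distance=nb.signed_distance, pcc=r, n_pairs=n
            )
        )
    if skipped:
        logger.info("neighbors absent from matrix, skipped: %s", skipped)
    return CorrelationProfile(focal=nbhd.focal, block=block, entries=entries)


def locus_average_pcc(profile: CorrelationProfile, method: str = "mean") -> float:
    """Average focal-vs-neighbor PCC over a locus (one block).

    ``method='mean'`` is the plain arithmetic mean over defined entries;
    ``method='fisher'`` averages on the Fisher z scale and transforms back.
    Returns NaN when no entry is defined.
    """
    vals = np.array([e.pcc for e in profile.defined()], dtype=float)
    if vals.size == 0:
        return float("nan")
    if method == "mean":
        return float(vals.mean())
    if method == "fisher":
        z = np.arctanh(np.clip(vals, -0.999999, 0.999999))
        return float(np.tanh(z.mean()))
    raise ValueError(f"unknown averaging method {method!r}")


@dataclass
class CorrelationHeatmap:
    """Locus heatmap: rows in genomic order, condition columns clustered."""

    focal: str
    values: pd.DataFrame  # rows: window genes (genomic order), cols: blocks
    strong_mask: pd.DataFrame  # True where |pcc| > STRONG_PCC
    linkage: np.ndarray | None

    def to_tsv(self, path: str | Path) -> None:
        self.values.rename_axis("gene").to_csv(path, sep="\t")


def condition_heatmap(
    profiles: Mapping[str, CorrelationProfile],
    nbhd: NeighborhoodMap,
) -> CorrelationHeatmap:
    """Assemble per-block profiles into a clustered locus heatmap.

    Rows are the locus window genes in genomic order with the focal row fixed
    at PCC = 1 (self-comparison); columns (condition blocks) are reordered by
    average-linkage agglomerative clustering on Euclidean distance, computed
    on a deterministic (alphabetical) column ordering so the result does not
    depend on the input ordering.  Blocks whose profile is entirely undefined
    are dropped with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 condition blocks to cluster")
    window = nbhd.ordered_window()
    cols = {}
    for block in sorted(profiles):
        prof = profiles[block]
        col = {e.neighbor: e.pcc for e in prof.entries}
        col[prof.focal] = 1.0
        series = pd.Series([col.get(g, np.nan) for g in window], index=window)
        if series.drop(prof.focal).isna().all():
            warnings.warn(f"block {block!r} has no defined correlations; dropped")
            continue
        cols[block] = series
    if len(cols) < 2:
        raise ValueError("fewer than 2 usable blocks after dropping undefined ones")
    mat = pd.DataFrame(cols)  # columns already in sorted(block) order

    # cluster condition columns; impute NaNs with column means for distance only
    filled = mat.to_numpy(dtype=float).T.copy()
    col_means = np.nanmean(filled, axis=1, keepdims=True)
    inds = np.where(np.isnan(filled))
    filled[inds] = np.take(col_means[:, 0], inds[0])
    if filled.shape[0] > 2:
        link = hierarchy.linkage(pdist(filled), method="average")
        order = hierarchy.leaves_list(link)
    else:
        link = None
        order = np.arange(filled.shape[0])
    ordered = mat.iloc[:, list(order)]
    return CorrelationHeatmap(
        focal=nbhd.focal,
        values=ordered,
        strong_mask=ordered.abs() > STRONG_PCC,
        linkage=link,
    )


def plot_heatmap(heatmap: CorrelationHeatmap, path: str | Path) -> None:
    """Render the locus heatmap to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.5 * heatmap.values.shape[1], 4))
    im = ax.imshow(heatmap.values.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_yticks(range(len(heatmap.values.index)), heatmap.values.index)
    ax.set_xticks(range(len(heatmap.values.columns)), heatmap.values.columns,
                  rotation=90)
    ax.set_title(f"{heatmap.focal} locus")
    fig.colorbar(im, ax=ax, label="PCC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
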