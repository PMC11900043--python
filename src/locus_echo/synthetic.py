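"""Synthetic genomes, expression compendia, qPCR plates and spotting grids.

Every generator takes an explicit seed and is bit-reproducible, so the whole
analysis pipeline can be exercised and validated against known ground truth
without any external download.  The expression generator plants a
distance-decaying correlation kernel

    corr(g_i, g_j) = c0 + a0 * exp(-d_ij / lambda0),   d_ij = |midpoint distance|

between genes on the same chromosome (genes on different chromosomes are
independent), which is exactly the family of curves the decay-fitting stage
estimates — parameter recovery is therefore a well-posed end-to-end check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_map import AnnotationTable, FEATURE_COLUMNS, GENE_COLUMNS

logger = logging.getLogger(__name__)

#: condition blocks mirroring an environmental-stress compendium plus a
#: synchronized cell-cycle course
DEFAULT_BLOCKS = (
    "cell_cycle",
    "HS25.37",
    "HS29.33",
    "HS30.37",
    "H2O2",
    "HC_menadione",
    "LC_menadione",
    "diamide",
    "DTT",
    "hyperosmotic",
    "hypoosmotic",
)


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the synthetic study.

    Attributes
    ----------
    decay_amplitude, decay_length, baseline_corr
        The planted correlation kernel ``c0 + a0*exp(-d/lambda0)``;
        ``decay_length`` is in base pairs.
    noise_sd
        Per-gene expression standard deviation (overall scale, log-ratio
        units); it does not dilute the planted correlations.
    """

    n_chromosomes: int = 2
    genes_per_chromosome: int = 18
    mean_gene_length: int = 1500
    mean_intergenic_gap: int = 1500
    decay_amplitude: float = 0.6  # a0
    decay_length: float = 10_000.0  # lambda0, bp
    baseline_corr: float = 0.05  # c0
    n_blocks: int = 4
    samples_per_block: int = 25
    noise_sd: float = 1.0
    seed: int = 0
    block_names: tuple[str, ...] = field(default=DEFAULT_BLOCKS)

    def __post_init__(self) -> None:
        if self.decay_amplitude + self.baseline_corr > 1 + 1e-12:
            raise ValueError("decay_amplitude + baseline_corr must be <= 1")
        if not (0 <= self.decay_amplitude <= 1):
            raise ValueError("decay_amplitude must lie in [0, 1]")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        for name in (
            "n_chromosomes",
            "genes_per_chromosome",
            "mean_gene_length",
            "mean_intergenic_gap",
            "n_blocks",
            "samples_per_block",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def blocks(self) -> list[str]:
        return list(self.block_names[: self.n_blocks])


def simulate_genome(config: SimulationConfig) -> AnnotationTable:
    """Draw an ordered, non-overlapping gene map with one centromere per chromosome."""
    rng = np.random.default_rng(config.seed)
    gene_rows, feature_rows = [], []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = int(rng.integers(1_000, 5_000))
        starts_ends = []
        for g in range(config.genes_per_chromosome):
            length = max(int(rng.gamma(10.0, config.mean_gene_length / 10.0)), 50)
            gene_rows.append(
                {
                    "gene_id": f"g{c + 1}_{g + 1:03d}",
                    "chromosome": chrom,
                    "start": pos,
                    "end": pos + length,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "is_essential": False,
                }
            )
            starts_ends.append((pos, pos + length))
            gap = max(int(rng.exponential(config.mean_intergenic_gap)), 1)
            pos += length + gap
        # centromere in the middle intergenic gap
        mid = len(starts_ends) // 2
        if len(starts_ends) > 1:
            left_end = starts_ends[mid - 1][1]
            right_start = starts_ends[mid][0]
            cen_mid = (left_end + right_start) // 2
        else:
            cen_mid = starts_ends[0][1] + 500
        feature_rows.append(
            {
                "feature_type": "centromere",
                "chromosome": chrom,
                "start": max(cen_mid - 60, 0),
                "end": cen_mid + 60,
            }
        )
    return AnnotationTable(
        pd.DataFrame(gene_rows, columns=GENE_COLUMNS),
        pd.DataFrame(feature_rows, columns=FEATURE_COLUMNS),
    )


def correlation_kernel(
    distances: np.ndarray, a0: float, lambda0: float, c0: float
) -> np.ndarray:
    """Planted gene-pair correlation as a function of |distance| in bp."""
    return c0 + a0 * np.exp(-np.abs(distances) / lambda0)


def nearest_psd(matrix: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping."""
    sym = (matrix + matrix.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps:
        return sym
    clipped = (vecs * np.maximum(vals, eps)) @ vecs.T
    # restore unit diagonal so the result stays a correlation matrix
    d = np.sqrt(np.diag(clipped))
    return clipped / np.outer(d, d)


def simulate_expression(annotation: AnnotationTable, config: SimulationConfig):
    """Sample a gene x sample log-ratio matrix with the planted decay kernel.

    Returns an :class:`~locus_echo.coexpression.ExpressionMatrix`.  Within each
    condition block a block-specific mean shift is added per gene (constant
    across the block's samples, so within-block correlations keep the kernel);
    genes on different chromosomes are uncorrelated.
    """
    from .coexpression import ExpressionMatrix  # local import: avoid cycle

    if annotation.genes.empty:
        raise ValueError("annotation must contain at least one gene")
    rng = np.random.default_rng(config.seed + 1)
    blocks = config.blocks
    n_samples = config.n_blocks * config.samples_per_block
    sample_ids = []
    manifest = {}
    for b in blocks:
        for i in range(config.samples_per_block):
            sid = f"{b}_{i + 1:02d}"
            sample_ids.append(sid)
            manifest[sid] = b

    gene_order: list[str] = []
    values = np.empty((0, n_samples))
    for chrom in annotation.chromosomes():
        genes = annotation.chromosome_genes(chrom)
        mids = ((genes["start"] + genes["end"]) / 2.0).to_numpy()
        dist = np.abs(mids[:, None] - mids[None, :])
        corr = correlation_kernel(dist, config.decay_amplitude,
                                  config.decay_length, config.baseline_corr)
        np.fill_diagonal(corr, 1.0)
        vals = np.linalg.eigvalsh((corr + corr.T) / 2.0)
        if vals.min() < 1e-10:
            logger.info(
                "covariance for %s not PSD (min eigenvalue %.3g); applying "
                "nearest-PSD repair", chrom, vals.min(),
            )
            corr = nearest_psd(corr)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
        z = chol @ rng.standard_normal((len(genes), n_samples))
        x = config.noise_sd * z
        # block mean shifts, constant within a block
        col = 0
        for _ in blocks:
            shift = rng.normal(0.0, 0.5, size=(len(genes), 1))
            x[:, col : col + config.samples_per_block] += shift
            col += config.samples_per_block
        values = np.vstack([values, x])
        gene_order += list(genes["gene_id"])

    frame = pd.DataFrame(values, index=gene_order, columns=sample_ids)
    return ExpressionMatrix(values=frame, block_manifest=pd.Series(manifest))


def simulate_qpcr(
    true_fold_changes: dict[str, float],
    n_replicates: int = 4,
    seed: int = 0,
    *,
    target_gene: str = "YCP4",
    reference_gene: str = "ACT1",
    calibrator: str = "WT",
    noise_sd: float = 0.1,
    reference_ct: float = 15.0,
    target_ct: float = 25.0,
) -> pd.DataFrame:
    """Generate a Ct table whose expected 2^-ddCt equals the requested folds.

    ``true_fold_changes`` maps strain -> fold relative to the calibrator; the
    calibrator itself is added with fold 1 if absent.  Gaussian noise of
    ``noise_sd`` cycles is added to every reaction.
    """
    if any(f <= 0 for f in true_fold_changes.values()):
        raise ValueError("fold changes must be positive")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    folds = dict(true_fold_changes)
    folds.setdefault(calibrator, 1.0)
    rows = []
    for strain, fold in folds.items():
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample": f"{strain}_r{rep}",
                    "strain": strain,
                    "gene": reference_gene,
                    "replicate": rep,
                    "Ct": reference_ct + rng.normal(0.0, noise_sd),
                    "melt_ok": True,
                }
            )
            rows.append(
                {
                    "sample": f"{strain}_r{rep}",
                    "strain": strain,
                    "gene": target_gene,
                    "replicate": rep,
                    # a fold-change f lowers the target Ct by log2(f) cycles
                    "Ct": target_ct - np.log2(fold) + rng.normal(0.0, noise_sd),
                    "melt_ok": True,
                }
            )
    return pd.DataFrame(rows)


def simulate_growth(
    relative_fitness: dict[str, float],
    n_dilutions: int = 6,
    n_replicates: int = 3,
    seed: int = 0,
    *,
    control_condition: str = "30C",
    stress_condition: str = "40C",
    control_capacity: float | None = None,
    noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate paired control / stressed spotting-score grids.

    Growth on a dilution series is modelled through a latent per-strain
    capacity ``G`` (in dilution-step units): the expected score at step ``d``
    is ``clip(G - d, 0, 1)``, so the growth index (sum of scores) has
    expectation ``G`` whenever ``0 <= G <= n_dilutions``.  The stressed grid
    uses capacity ``ratio * G``, making the expected stress/control growth
    ratio equal to the requested relative fitness.

    Returns ``(control, stressed)`` DataFrames with columns
    ``strain, condition, replicate, dilution, score``.
    """
    if any(r < 0 for r in relative_fitness.values()):
        raise ValueError("relative fitness must be >= 0")
    if n_dilutions < 3:
        raise ValueError("need at least 3 dilution steps")
    rng = np.random.default_rng(seed)
    if control_capacity is None:
        control_capacity = 0.75 * n_dilutions

    def grid_rows(strain: str, condition: str, capacity: float) -> list[dict]:
        rows = []
        for rep in range(1, n_replicates + 1):
            for d in range(n_dilutions):
                expected = float(np.clip(capacity - d, 0.0, 1.0))
                if capacity == 0.0:
                    score = 0.0
                else:
                    score = float(np.clip(expected + rng.normal(0.0, noise_sd), 0.0, 1.0))
                rows.append(
                    {
                        "strain": strain,
                        "condition": condition,
                        "replicate": rep,
                        "dilution": d,
                        "score": score,
                    }
                )
        return rows

    control_rows, stress_rows = [], []
    for strain, ratio in relative_fitness.items():
        control_rows += grid_rows(strain, control_condition, control_capacity)
        stress_rows += grid_rows(strain, stress_condition, ratio * control_capacity)
    return pd.DataFrame(control_rows), pd.DataFrame(stress_rows)
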