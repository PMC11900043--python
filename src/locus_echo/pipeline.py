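"""End-to-end orchestration: simulate-or-load, map, correlate, fit, quantify.

Every stage writes flat TSV plus images under the output directory, and a
``manifest.json`` records package/library versions, the seed and input file
hashes so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import coexpression, datasets, decay_fit, genome_map, growth_assay, qpcr, synteny
from .synthetic import (
    SimulationConfig,
    simulate_expression,
    simulate_growth,
    simulate_qpcr,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run."""

    out_dir: str = "locus_echo_out"
    seed: int = 0
    focal_genes: Sequence[str] = field(default_factory=lambda: list(datasets.FREEZE_THAW_GENES))
    k: int = 3
    decay_model: str = "exponential"
    averaging: str = "mean"  # locus-average PCC: "mean" or "fisher"
    equal_var: bool = True  # Student's t (pooled); False -> Welch
    alpha: float = 0.05
    # inputs; None -> packaged map / simulated data
    annotation_path: str | None = None
    expression_path: str | None = None
    expression_manifest_path: str | None = None
    growth_scores_path: str | None = None
    ct_table_path: str | None = None
    synteny_dir: str | None = None
    # simulation knobs (used when the corresponding input path is None)
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns a summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"focal_genes": list(config.focal_genes)}
    input_hashes = {}

    # ---- stage: genome map ------------------------------------------------
    try:
        if config.annotation_path:
            annotation = genome_map.load_annotation(config.annotation_path)
            input_hashes["annotation"] = _sha256(Path(config.annotation_path))
        else:
            annotation = datasets.freeze_thaw_annotation()
        neighborhoods = {
            g: genome_map.neighborhood(annotation, g, config.k)
            for g in config.focal_genes
        }
        genome_map.write_neighborhoods(
            neighborhoods.values(), out / "neighborhoods.tsv"
        )
        logger.info("genome_map: %d loci mapped", len(neighborhoods))
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"genome_map stage failed: {exc}") from exc

    # ---- stage: expression ------------------------------------------------
    try:
        if config.expression_path:
            expr = coexpression.load_expression(
                config.expression_path, config.expression_manifest_path
            )
            input_hashes["expression"] = _sha256(Path(config.expression_path))
        else:
            sim_cfg = SimulationConfig(seed=config.seed, **config.sim)
            expr = simulate_expression(annotation, sim_cfg)
            expr.to_files(out / "expression.tsv", out / "expression_manifest.tsv")
        blocks = expr.blocks()
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"expression stage failed: {exc}") from exc

    # ---- stage: coexpression + decay fits ---------------------------------
    try:
        n_pairs = 0
        fits: dict[str, decay_fit.DecayFit] = {}
        locus_avg: dict[str, float] = {}
        for focal, nbhd in neighborhoods.items():
            profiles = {
                b: coexpression.locus_profile(expr, nbhd, b) for b in blocks
            }
            frames = [p.to_frame() for p in profiles.values()]
            pd.concat(frames, ignore_index=True).to_csv(
                out / f"{focal}_profiles.tsv", sep="\t", index=False
            )
            n_pairs += sum(len(p.entries) for p in profiles.values())
            heat = coexpression.condition_heatmap(profiles, nbhd)
            heat.to_tsv(out / f"{focal}_heatmap.tsv")
            coexpression.plot_heatmap(heat, out / f"{focal}_heatmap.png")
            first = blocks[0]
            locus_avg[focal] = coexpression.locus_average_pcc(
                profiles[first], method=config.averaging
            )
            points = [
                (e.signed_distance, e.pcc)
                for p in profiles.values()
                for e in p.defined()
            ]
            fit = decay_fit.fit_decay(points, model=config.decay_model)
            fits[focal] = fit
            decay_fit.plot_fit(points, fit, out / f"{focal}_decay.png",
                               title=f"{focal} locus")
        decay_fit.write_fits(fits, out / "decay_fits.tsv")
        pd.Series(locus_avg, name="locus_average_pcc").rename_axis("focal").to_csv(
            out / "locus_average_pcc.tsv", sep="\t"
        )
        summary["pairs_correlated"] = n_pairs
        summary["fits_converged"] = sum(not f.flat_flag for f in fits.values())
        summary["locus_average_pcc"] = locus_avg
        logger.info("coexpression: %d pairs, %d non-flat fits", n_pairs,
                    summary["fits_converged"])
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"coexpression/decay stage failed: {exc}") from exc

    # ---- stage: growth assay ----------------------------------------------
    try:
        growth_summary = _growth_stage(config, annotation, neighborhoods, out)
        summary["growth"] = growth_summary
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"growth stage failed: {exc}") from exc

    # ---- stage: qPCR ------------------------------------------------------
    try:
        summary["qpcr"] = _qpcr_stage(config, out)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"qpcr stage failed: {exc}") from exc

    # ---- stage: synteny ---------------------------------------------------
    try:
        summary["synteny"] = _synteny_stage(config, out)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"synteny stage failed: {exc}") from exc

    manifest = {
        "locus_echo": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "input_sha256": input_hashes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def _deletion_strains(
    neighborhoods: Mapping[str, genome_map.NeighborhoodMap],
) -> dict[str, tuple[str, str]]:
    """All (focal, position) deletion strains for the locus screen.

    Returns strain name -> (locus, position in {-1, FT, +1}); essential
    flanks are excluded (their deletion strains cannot exist).
    """
    strains = {}
    for focal, nbhd in neighborhoods.items():
        strains[f"{focal.lower()}d"] = (focal, "FT")
        for n in nbhd.neighbors:
            if abs(n.offset) != 1 or n.is_essential:
                continue
            pos = "+1" if n.direction in ("telomeric", "right") else "-1"
            strains[f"{n.gene_id.lower()}d"] = (focal, pos)
    return strains


def _growth_stage(config, annotation, neighborhoods, out: Path) -> dict:
    strain_map = _deletion_strains(neighborhoods)
    if config.growth_scores_path:
        df = pd.read_csv(config.growth_scores_path)
        control = df[df["condition"] == "30C"]
        stress = df[df["condition"] == "40C"]
        input_note = config.growth_scores_path
    else:
        rng = np.random.default_rng(config.seed + 11)
        fitness = {"WT": 0.5}
        for strain in strain_map:
            fitness[strain] = float(np.round(rng.uniform(0.4, 0.9), 3))
        control, stress = simulate_growth(
            fitness, n_dilutions=6, n_replicates=6, seed=config.seed + 12
        )
        control.to_csv(out / "growth_control.csv", index=False)
        stress.to_csv(out / "growth_stress.csv", index=False)
        input_note = "simulated"

    control_grids = growth_assay.grids_from_frame(control)
    stress_grids = growth_assay.grids_from_frame(stress)

    def strain_grids(grids, strain):
        return [g for g in grids if g.strain == strain]

    strains = sorted({g.strain for g in control_grids})
    rel = {
        s: growth_assay.relative_growth(
            strain_grids(stress_grids, s), strain_grids(control_grids, s)
        )
        for s in strains
    }
    wt_vals = [growth_assay.growth_index(g) for g in strain_grids(stress_grids, "WT")]
    rows = []
    for s in strains:
        if s == "WT":
            continue
        vals = [growth_assay.growth_index(g) for g in strain_grids(stress_grids, s)]
        res = growth_assay.compare_to_wt(
            vals, wt_vals, strain=s, condition="40C",
            equal_var=config.equal_var, alpha=config.alpha,
        )
        rows.append(
            {
                "strain": s,
                "relative_growth": rel[s],
                "growth_index_40C": res.growth_index,
                "sem": res.sem,
                "t": res.t_stat,
                "p_vs_wt": res.p_vs_wt,
                "significant": res.significant,
            }
        )
    pd.DataFrame(rows).to_csv(out / "growth_results.tsv", sep="\t", index=False)

    # locus x position heatmap; essential flanks stay marked unavailable
    heat_input: dict[str, dict[str, object]] = {
        f: {} for f in neighborhoods
    }
    for strain, (locus, pos) in strain_map.items():
        if strain in rel:
            heat_input[locus][pos] = rel[strain]
    for focal, nbhd in neighborhoods.items():
        for n in nbhd.neighbors:
            if abs(n.offset) == 1 and n.is_essential:
                pos = "+1" if n.direction in ("telomeric", "right") else "-1"
                heat_input[focal][pos] = growth_assay.UNAVAILABLE
    matrix = growth_assay.locus_growth_heatmap(heat_input,
                                               locus_order=list(neighborhoods))
    matrix.rename_axis("locus").to_csv(out / "growth_heatmap.tsv", sep="\t")
    growth_assay.plot_growth_heatmap(matrix, out / "growth_heatmap.png")
    return {
        "input": input_note,
        "n_strains": len(strains),
        "n_significant": int(sum(r["significant"] for r in rows)),
    }


def _qpcr_stage(config, out: Path) -> dict:
    if config.ct_table_path:
        table = pd.read_csv(config.ct_table_path)
        input_note = config.ct_table_path
        target = [g for g in table["gene"].unique() if g != qpcr.DEFAULT_REFERENCE][0]
    else:
        # the marker-integration scenario at the YCP4 locus: flank deletions
        # leave YCP4 expression unchanged (fold 1) in expectation
        table = simulate_qpcr(
            {"mrpl32d": 1.0, "cit2d": 1.0},
            n_replicates=4,
            seed=config.seed + 21,
            target_gene="YCP4",
        )
        table.to_csv(out / "ct_table.csv", index=False)
        input_note = "simulated"
        target = "YCP4"
    estimates = qpcr.ddct(table, target=target, calibrator="WT")
    qpcr.estimates_to_frame(estimates).to_csv(out / "qpcr_folds.tsv", sep="\t",
                                              index=False)
    qpcr.plot_folds(estimates, out / "qpcr_folds.png", title=f"{target} / ACT1")
    comparisons = {
        s: qpcr.compare_expression(estimates[s], estimates["WT"], alpha=config.alpha)
        for s in estimates
        if s != "WT"
    }
    return {
        "input": input_note,
        "target": target,
        "folds": {s: e.fold for s, e in estimates.items()},
        "p_vs_wt": {s: c.p_value for s, c in comparisons.items()},
    }


def _synteny_stage(config, out: Path) -> dict:
    if config.synteny_dir:
        tables = {
            p.stem: synteny.load_gene_order(p)
            for p in sorted(Path(config.synteny_dir).glob("*.tsv"))
        }
        input_note = config.synteny_dir
    else:
        tables = datasets.ycp4_synteny_panel()
        input_note = "packaged toy panel"
    table = synteny.align_orders(tables, anchor="YCP4")
    table.to_tsv(out / "synteny_alignment.tsv")
    summary = synteny.conservation_summary(table)
    summary.to_csv(out / "synteny_summary.tsv", sep="\t")
    synteny.plot_alignment(table, out / "synteny_alignment.png")
    return {
        "input": input_note,
        "n_species": len(table.species),
        "losses_per_column": summary["n_lost"].to_dict(),
    }
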