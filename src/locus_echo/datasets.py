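"""Packaged reference fixtures and loaders for user-supplied compendia.

The shipped gene-order map covers the six S. cerevisiae freeze-thaw tolerance
loci (AQY1, ATH1, CAR1, POG1, PUT1, YCP4) with three flanking genes per side;
its gene order, chromosome arms and essential-gene flags follow the public
annotation while coordinates are synthetic approximations (see the file
header).  Real expression compendia are not shipped: users export the GEO
series matrices themselves and load them with
:func:`load_external_cell_cycle` / :func:`locus_echo.coexpression.load_expression`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .coexpression import ExpressionMatrix
from .genome_map import AnnotationTable, load_annotation

#: the six genes whose deletion increases freeze-thaw survival
FREEZE_THAW_GENES = ("AQY1", "ATH1", "CAR1", "POG1", "PUT1", "YCP4")

#: immediate flanks of each freeze-thaw gene: (telomeric +1, centromeric -1)
FLANKING_GENES = {
    "AQY1": ("HPA1", "QCR2"),
    "ATH1": ("YPR027C", "CCL1"),
    "CAR1": ("PEX25", "GDE1"),
    "POG1": ("SIM1", "QDR2"),
    "PUT1": ("DPH6", "RRN5"),
    "YCP4": ("CIT2", "MRPL32"),
}

#: flanking genes that are essential (their deletion strains do not exist)
ESSENTIAL_FLANKS = ("RRN5", "CCL1")


def freeze_thaw_annotation() -> AnnotationTable:
    """The packaged gene-order map of the six freeze-thaw loci."""
    ref = resources.files("locus_echo.data") / "freeze_thaw_loci_synthetic.gff3"
    with resources.as_file(ref) as path:
        return load_annotation(path)


def ycp4_synteny_panel() -> dict[str, pd.DataFrame]:
    """A toy cross-species gene-order panel anchored on YCP4.

    Encodes the qualitative conservation picture at this locus: the YCP4
    pillar is retained throughout the Saccharomyces clade and the
    reconstructed ancestor but lost in exactly two divergent lineages
    (T. blattae and E. gossypii), while the telomeric flank CIT2 is retained
    in every species; insertions appear between pillars as divergence grows.
    """

    def table(genes: list[tuple[str, str]]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_rank": range(1, len(genes) + 1),
                "gene_id": [g for g, _ in genes],
                "family_id": [f for _, f in genes],
            }
        )

    core = ["YCR001W", "CDC10", "MRPL32", "YCP4", "CIT2", "YCR006C", "YCR007C"]
    ident = [(g, g) for g in core]
    return {
        "S. cerevisiae": table(ident),
        "S. paradoxus": table([(f"Spar_{g}", g) for g in core]),
        "S. mikatae": table([(f"Smik_{g}", g) for g in core]),
        "S. kudriavzevii": table(
            [(f"Skud_{g}", g) for g in core if g != "YCR006C"]
        ),
        # YCP4 pillar lost; an unrelated gene inserted next to MRPL32
        "E. gossypii": table(
            [
                ("Egos_CDC10", "CDC10"),
                ("Egos_MRPL32", "MRPL32"),
                ("Egos_novel1", "EGOS_FAM1"),
                ("Egos_CIT2", "CIT2"),
                ("Egos_YCR007C", "YCR007C"),
            ]
        ),
        # YCP4 pillar lost; two inserted genes interrupt the locus
        "T. blattae": table(
            [
                ("Tbla_YCR001W", "YCR001W"),
                ("Tbla_MRPL32", "MRPL32"),
                ("Tbla_novel1", "TBLA_FAM1"),
                ("Tbla_novel2", "TBLA_FAM2"),
                ("Tbla_CIT2", "CIT2"),
                ("Tbla_YCR006C", "YCR006C"),
            ]
        ),
        "ancestor": table([(f"Anc_{g}", g) for g in core]),
    }


def load_external_cell_cycle(matrix_path: str | Path) -> ExpressionMatrix:
    """Load a user-exported alpha-factor cell-cycle series matrix.

    ``matrix_path`` is a tab-delimited gene x sample table (gene ids in the
    first column) exported from the synchronized cell-cycle compendium; all
    samples are assigned to the single block ``"cell_cycle"``.  Raises
    FileNotFoundError with download guidance when the file is absent.
    """
    path = Path(matrix_path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found. Export the alpha-factor cell-cycle series "
            "matrix (GEO series GSE22) as a tab-delimited gene x sample table "
            "and place it at this path; no downloading is built in."
        )
    values = pd.read_csv(path, sep="\t", index_col=0)
    manifest = pd.Series("cell_cycle", index=values.columns)
    return ExpressionMatrix(values=values, block_manifest=manifest)
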