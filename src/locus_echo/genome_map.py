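"""Ordered per-chromosome gene maps and flanking-gene neighborhoods.

The container here is deliberately simple: an ordered gene table plus optional
non-ORF feature intervals (centromeres, telomeric repeats).  Neighborhoods are
defined by gene *rank* along the chromosome, not by base-pair windows, because
position effects of marker integration act on adjacent transcription units
regardless of their size.  Coordinates are stored 0-based half-open; GFF3 I/O
converts at the boundary.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "is_essential"]
FEATURE_COLUMNS = ["feature_type", "chromosome", "start", "end"]

#: feature types treated as non-ORF landmarks rather than genes
LANDMARK_TYPES = {"centromere", "telomeric_repeat", "telomere"}


class AnnotationError(ValueError):
    """Malformed annotation input (bad coordinates, duplicate ids...)."""


class UnknownGeneError(KeyError):
    """A focal gene id is absent from the annotation."""


@dataclass
class AnnotationTable:
    """Ordered gene coordinates per chromosome with optional landmark features.

    Parameters
    ----------
    genes
        DataFrame with columns ``gene_id, chromosome, start, end, strand,
        is_essential``; coordinates 0-based half-open.
    features
        DataFrame with columns ``feature_type, chromosome, start, end`` for
        centromere / telomeric-repeat intervals.  May be empty.
    """

    genes: pd.DataFrame
    features: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=FEATURE_COLUMNS)
    )

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        if self.genes["gene_id"].duplicated().any():
            dups = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"]
            raise AnnotationError(f"duplicate gene ids: {sorted(set(dups))}")
        bad = self.genes["end"] < self.genes["start"]
        if bad.any():
            raise AnnotationError(
                f"end < start for genes: {list(self.genes.loc[bad, 'gene_id'])}"
            )
        cen = self.features[self.features["feature_type"] == "centromere"]
        if cen["chromosome"].duplicated().any():
            raise AnnotationError("more than one centromere on a chromosome")
        # canonical order: by chromosome, then start
        self.genes = self.genes.sort_values(
            ["chromosome", "start"], kind="stable"
        ).reset_index(drop=True)

    # -- lookups ----------------------------------------------------------

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.genes["chromosome"]))

    def chromosome_genes(self, chromosome: str) -> pd.DataFrame:
        """Genes of one chromosome in start order (rank order)."""
        sub = self.genes[self.genes["chromosome"] == chromosome]
        return sub.reset_index(drop=True)

    def gene(self, gene_id: str) -> pd.Series:
        hits = self.genes[self.genes["gene_id"] == gene_id]
        if hits.empty:
            raise UnknownGeneError(gene_id)
        return hits.iloc[0]

    def centromere(self, chromosome: str) -> pd.Series | None:
        cen = self.features[
            (self.features["feature_type"] == "centromere")
            & (self.features["chromosome"] == chromosome)
        ]
        if cen.empty:
            return None
        return cen.iloc[0]

    @staticmethod
    def midpoint(rec: pd.Series) -> float:
        return (rec["start"] + rec["end"]) / 2.0

    # -- I/O --------------------------------------------------------------

    def to_gff3(self, path: str | Path) -> None:
        """Write genes and landmark features as GFF3 (1-based inclusive)."""
        lines = ["##gff-version 3"]
        for _, f in self.features.iterrows():
            lines.append(
                "\t".join(
                    [
                        f["chromosome"],
                        "locus_echo",
                        f["feature_type"],
                        str(int(f["start"]) + 1),
                        str(int(f["end"])),
                        ".",
                        ".",
                        ".",
                        f"ID={f['feature_type']}_{f['chromosome']}",
                    ]
                )
            )
        for _, g in self.genes.iterrows():
            attrs = f"ID={g['gene_id']};Name={g['gene_id']}"
            if bool(g["is_essential"]):
                attrs += ";essential=true"
            lines.append(
                "\t".join(
                    [
                        g["chromosome"],
                        "locus_echo",
                        "gene",
                        str(int(g["start"]) + 1),
                        str(int(g["end"])),
                        ".",
                        g["strand"],
                        ".",
                        attrs,
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")


def load_annotation(path: str | Path) -> AnnotationTable:
    """Read a GFF3 file (or a plain TSV gene table) into an :class:`AnnotationTable`.

    GFF3 ``gene`` rows become gene records; centromere / telomeric-repeat rows
    become landmark features; any other feature type is ignored (count logged).
    A TSV fallback expects the columns ``gene_id, chromosome, start, end,
    strand`` (0-based half-open) and an optional ``is_essential``.

    Raises
    ------
    AnnotationError
        If a record has ``end < start`` (the offending lines are named).
    """
    path = Path(path)
    text = path.read_text()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    if not (first.startswith("##gff") or path.suffix.lower() in {".gff", ".gff3"}):
        return _load_gene_table(path)

    # validate coordinates up front so errors can name source lines;
    # gffutils itself would choke on end < start without a line number
    bad_lines = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 5:
            try:
                if int(parts[4]) < int(parts[3]):
                    bad_lines.append(lineno)
            except ValueError:
                bad_lines.append(lineno)
    if bad_lines:
        raise AnnotationError(f"end < start (or unparsable) at lines: {bad_lines}")

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    gene_rows, feature_rows = [], []
    ignored: dict[str, int] = {}
    for feat in db.all_features():
        if feat.featuretype == "gene":
            gid = feat.attributes.get("ID", [feat.id])[0]
            essential = feat.attributes.get("essential", ["false"])[0].lower() == "true"
            gene_rows.append(
                {
                    "gene_id": gid,
                    "chromosome": feat.seqid,
                    "start": feat.start - 1,  # to 0-based half-open
                    "end": feat.end,
                    "strand": feat.strand if feat.strand in "+-" else "+",
                    "is_essential": essential,
                }
            )
        elif feat.featuretype in LANDMARK_TYPES:
            feature_rows.append(
                {
                    "feature_type": feat.featuretype,
                    "chromosome": feat.seqid,
                    "start": feat.start - 1,
                    "end": feat.end,
                }
            )
        else:
            ignored[feat.featuretype] = ignored.get(feat.featuretype, 0) + 1
    if ignored:
        logger.info("ignored feature types: %s", ignored)
    return AnnotationTable(
        pd.DataFrame(gene_rows, columns=GENE_COLUMNS),
        pd.DataFrame(feature_rows, columns=FEATURE_COLUMNS),
    )


def _load_gene_table(path: Path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chromosome", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"gene table missing columns: {sorted(missing)}")
    if "is_essential" not in df.columns:
        df["is_essential"] = False
    return AnnotationTable(df[GENE_COLUMNS])


@dataclass(frozen=True)
class Neighbor:
    gene_id: str
    offset: int  # signed gene rank relative to the focal gene
    signed_distance: float  # neighbor midpoint - focal midpoint, bp
    direction: str  # telomeric | centromeric | left | right
    is_essential: bool = False


@dataclass
class NeighborhoodMap:
    """Ordered flanking genes around a focal gene, with signed distances."""

    focal: str
    neighbors: list[Neighbor]
    k: int

    def __post_init__(self) -> None:
        offsets = [n.offset for n in self.neighbors]
        if offsets != sorted(offsets):
            raise ValueError("neighbor offsets must be strictly ordered")
        if any(abs(o) > self.k or o == 0 for o in offsets):
            raise ValueError("offsets must be nonzero with |offset| <= k")

    def gene_ids(self) -> list[str]:
        return [n.gene_id for n in self.neighbors]

    def ordered_window(self) -> list[str]:
        """Gene ids in genomic order with the focal gene in place."""
        out = [n.gene_id for n in self.neighbors if n.offset < 0]
        out.append(self.focal)
        out += [n.gene_id for n in self.neighbors if n.offset > 0]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "focal": self.focal,
                    "neighbor": n.gene_id,
                    "offset": n.offset,
                    "distance_bp": n.signed_distance,
                    "direction": n.direction,
                    "is_essential": n.is_essential,
                }
                for n in self.neighbors
            ]
        )


def neighborhood(annotation: AnnotationTable, focal: str, k: int = 3) -> NeighborhoodMap:
    """Extract up to ``k`` flanking genes on each side of ``focal``.

    Neighbors are taken in gene-rank order along the chromosome (strand is
    irrelevant).  ``signed_distance`` is neighbor midpoint minus focal
    midpoint.  When the chromosome carries a centromere feature, each neighbor
    is labelled ``telomeric`` or ``centromeric`` according to which side of
    the focal gene it lies on relative to the centromere; without one, labels
    fall back to coordinate ``left`` / ``right``.

    Fewer than ``k`` neighbors are returned without error at chromosome ends;
    a single-gene chromosome yields an empty neighbor list.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    focal_rec = annotation.gene(focal)
    chrom = focal_rec["chromosome"]
    genes = annotation.chromosome_genes(chrom)
    rank = genes.index[genes["gene_id"] == focal][0]
    focal_mid = AnnotationTable.midpoint(focal_rec)

    cen = annotation.centromere(chrom)
    if cen is not None:
        cen_mid = (cen["start"] + cen["end"]) / 2.0
        # on the right arm (focal beyond the centromere) increasing coordinate
        # moves away from the centromere, i.e. telomeric; mirrored on the left
        telomeric_sign = 1.0 if focal_mid >= cen_mid else -1.0
    else:
        telomeric_sign = None

    neighbors = []
    for offset in range(-k, k + 1):
        if offset == 0:
            continue
        idx = rank + offset
        if idx < 0 or idx >= len(genes):
            continue
        rec = genes.iloc[idx]
        dist = AnnotationTable.midpoint(rec) - focal_mid
        if telomeric_sign is None:
            direction = "right" if dist > 0 else "left"
        else:
            direction = "telomeric" if dist * telomeric_sign > 0 else "centromeric"
        neighbors.append(
            Neighbor(
                gene_id=rec["gene_id"],
                offset=offset,
                signed_distance=dist,
                direction=direction,
                is_essential=bool(rec["is_essential"]),
            )
        )
    return NeighborhoodMap(focal=focal, neighbors=neighbors, k=k)


def write_neighborhoods(maps: Iterable[NeighborhoodMap], path: str | Path) -> None:
    """Export neighborhoods as TSV (focal, neighbor, offset, distance, direction)."""
    frames = [m.to_frame() for m in maps]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.to_csv(path, sep="\t", index=False)
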