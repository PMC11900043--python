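"""Anchored gene-order (synteny) alignment across species.

Each species is an ordered gene list with homology-family labels (the shape of
gene-order-browser "pillar" exports).  Columns are fixed by a reference
species' window around an anchor gene; every other species' genes are matched
to those columns by homology family under an order-consistency constraint
(longest increasing chain, orientation-agnostic).  Unmatched columns are
losses; species genes falling between two matched columns without a column
family are insertions.  A reconstructed ancestral gene order participates as
just another species row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PRESENT = "present"
LOST = "lost"


class SyntenyError(ValueError):
    """Invalid synteny input (e.g. anchor absent from the reference)."""


def load_gene_order(path: str | Path) -> pd.DataFrame:
    """Read a per-species TSV of (position_rank, gene_id, family_id)."""
    df = pd.read_csv(path, sep="\t")
    required = {"position_rank", "gene_id", "family_id"}
    missing = required - set(df.columns)
    if missing:
        raise SyntenyError(f"gene-order table missing columns: {sorted(missing)}")
    return df.sort_values("position_rank").reset_index(drop=True)


@dataclass
class SyntenyTable:
    """Alignment of species gene orders against a reference locus window."""

    anchor: str
    reference: str
    columns: list[str]  # reference gene ids, in genomic order
    species: list[str]
    cells: pd.DataFrame  # species x columns of PRESENT / LOST
    insertions: pd.DataFrame  # species x (n_columns - 1) gap counts
    matched_ids: dict[str, dict[str, str]] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        out = self.cells.copy()
        out.index.name = "species"
        out.to_csv(path, sep="\t")


def _family_of(table: pd.DataFrame, gene_id: str) -> str:
    hits = table[table["gene_id"] == gene_id]
    if hits.empty:
        raise SyntenyError(f"gene {gene_id!r} absent from table")
    return hits.iloc[0]["family_id"]


def _best_chain(candidates: list[list[int]]) -> list[int | None]:
    """Pick at most one position per column so positions strictly increase.

    ``candidates[j]`` are the species positions carrying column j's family.
    Returns, per column, the chosen position or None, maximizing the number
    of matched columns (ties broken toward earlier positions).
    """
    # DP over flattened (column, position) states
    states = [(j, p) for j, ps in enumerate(candidates) for p in sorted(ps)]
    n = len(states)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        ji, pi = states[i]
        for h in range(i):
            jh, ph = states[h]
            if jh < ji and ph < pi and best_len[h] + 1 > best_len[i]:
                best_len[i] = best_len[h] + 1
                prev[i] = h
    choice: list[int | None] = [None] * len(candidates)
    if not states:
        return choice
    end = int(np.argmax(best_len))
    while end != -1:
        j, p = states[end]
        choice[j] = p
        end = prev[end]
    return choice


def align_orders(
    tables: Mapping[str, pd.DataFrame],
    anchor: str,
    window: int | None = None,
    reference: str | None = None,
) -> SyntenyTable:
    """Align species gene orders around ``anchor``.

    Parameters
    ----------
    tables
        Mapping species -> ordered gene table with columns
        (position_rank, gene_id, family_id).  The first key is the reference
        unless ``reference`` names another species.
    anchor
        Gene id in the reference species; its column anchors the alignment.
    window
        Reference genes retained on each side of the anchor (None keeps the
        whole table).  Species matches must fall within ``2 * n_columns``
        positions of the species' own anchor homolog when it exists.
    """
    if not tables:
        raise SyntenyError("no species tables supplied")
    reference = reference or next(iter(tables))
    ref = tables[reference].reset_index(drop=True)
    if anchor not in set(ref["gene_id"]):
        raise SyntenyError(f"anchor {anchor!r} absent from reference {reference!r}")
    anchor_idx = ref.index[ref["gene_id"] == anchor][0]
    if window is None:
        lo, hi = 0, len(ref)
    else:
        lo, hi = max(anchor_idx - window, 0), min(anchor_idx + window + 1, len(ref))
    ref_window = ref.iloc[lo:hi]
    columns = list(ref_window["gene_id"])
    col_families = list(ref_window["family_id"])
    anchor_family = _family_of(ref, anchor)

    species = list(tables)
    cells = pd.DataFrame(LOST, index=species, columns=columns, dtype=object)
    gap_labels = [f"{a}|{b}" for a, b in zip(columns[:-1], columns[1:])]
    insertions = pd.DataFrame(0, index=species, columns=gap_labels, dtype=int)
    matched_ids: dict[str, dict[str, str]] = {}

    for sp in species:
        table = tables[sp].reset_index(drop=True)
        order = list(table["family_id"])
        genes = list(table["gene_id"])
        fwd = _align_one(order, col_families, anchor_family, len(columns))
        rev = _align_one(order[::-1], col_families, anchor_family, len(columns))
        n_fwd = sum(p is not None for p in fwd)
        n_rev = sum(p is not None for p in rev)
        if n_rev > n_fwd:  # orientation-agnostic: take the better strand
            chain = [None if p is None else len(order) - 1 - p for p in rev]
        else:
            chain = fwd
        matched_ids[sp] = {}
        for col, pos in zip(columns, chain):
            if pos is not None:
                cells.loc[sp, col] = PRESENT
                matched_ids[sp][col] = genes[pos]
        # insertion counts between consecutive matched columns
        pos_by_col = {j: p for j, p in enumerate(chain) if p is not None}
        matched_cols = sorted(pos_by_col)
        for a, b in zip(matched_cols[:-1], matched_cols[1:]):
            pa, pb = sorted((pos_by_col[a], pos_by_col[b]))
            between = abs(pb - pa) - 1
            # species genes between the two matches that are not homologs of
            # any intervening (lost) column count as inserted
            inter_families = set(col_families[a + 1 : b])
            extra = sum(
                1
                for p in range(pa + 1, pb)
                if order[p] not in inter_families
            )
            if extra > 0:
                # attribute the block to the gap nearest its position; with
                # reference gaps a..b collapse onto gap label between cols a,b
                insertions.loc[sp, f"{columns[a]}|{columns[a + 1]}"] += extra
            _ = between
    return SyntenyTable(
        anchor=anchor,
        reference=reference,
        columns=columns,
        species=species,
        cells=cells,
        insertions=insertions,
        matched_ids=matched_ids,
    )


def _align_one(
    order: list[str],
    col_families: list[str],
    anchor_family: str,
    n_columns: int,
) -> list[int | None]:
    """Chain columns into one species' family order, windowed on its anchor."""
    anchor_positions = [i for i, fam in enumerate(order) if fam == anchor_family]
    if anchor_positions:
        center = anchor_positions[0]
        span = 2 * n_columns
        lo, hi = center - span, center + span
    else:
        lo, hi = -np.inf, np.inf
    candidates = [
        [i for i, fam in enumerate(order) if fam == cf and lo <= i <= hi]
        for cf in col_families
    ]
    return _best_chain(candidates)


def conservation_summary(table: SyntenyTable) -> pd.DataFrame:
    """Per-column counts of present / lost species and adjacent insertions.

    ``n_inserted_adjacent`` counts species with at least one inserted gene in
    a gap flanking the column.  ``n_present + n_lost`` equals the number of
    species for every column.
    """
    if not table.columns:
        raise SyntenyError("empty synteny table")
    rows = []
    for j, col in enumerate(table.columns):
        present = int((table.cells[col] == PRESENT).sum())
        gaps = []
        if j > 0:
            gaps.append(f"{table.columns[j - 1]}|{col}")
        if j < len(table.columns) - 1:
            gaps.append(f"{col}|{table.columns[j + 1]}")
        if gaps:
            adjacent = int((table.insertions[gaps].sum(axis=1) > 0).sum())
        else:
            adjacent = 0
        rows.append(
            {
                "column": col,
                "n_present": present,
                "n_lost": len(table.species) - present,
                "n_inserted_adjacent": adjacent,
            }
        )
    return pd.DataFrame(rows).set_index("column")


def cross_species_profiles(
    expr_by_species: Mapping[str, "object"],
    nbhd,
    ortholog_maps: Mapping[str, Mapping[str, str]] | None = None,
    blocks: Mapping[str, Sequence[str]] | None = None,
):
    """Per-species locus correlation profiles with gene order maintained.

    ``ortholog_maps[species]`` translates reference gene ids to that species'
    matrix ids (identity when omitted); neighbors without an ortholog in a
    species are simply absent from its profile.  Returns
    ``{species: {block: CorrelationProfile}}``.
    """
    from .coexpression import locus_profile
    from .genome_map import Neighbor, NeighborhoodMap

    out: dict[str, dict[str, object]] = {}
    for sp, expr in expr_by_species.items():
        mapping = dict(ortholog_maps.get(sp, {})) if ortholog_maps else {}

        def translate(gid: str) -> str:
            return mapping.get(gid, gid)

        neighbors = [
            Neighbor(
                gene_id=translate(n.gene_id),
                offset=n.offset,
                signed_distance=n.signed_distance,
                direction=n.direction,
                is_essential=n.is_essential,
            )
            for n in nbhd.neighbors
            if translate(n.gene_id) in expr.values.index
        ]
        sp_nbhd = NeighborhoodMap(focal=translate(nbhd.focal), neighbors=neighbors,
                                  k=nbhd.k)
        block_names = blocks.get(sp) if blocks else expr.blocks()
        out[sp] = {b: locus_profile(expr, sp_nbhd, b) for b in block_names}
    return out


def plot_alignment(table: SyntenyTable, path) -> None:
    """Render the anchored alignment: arrows for present genes, gaps for losses."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1 + 0.9 * len(table.columns), 0.5 * len(table.species) + 1)
    )
    for i, sp in enumerate(table.species):
        y = len(table.species) - 1 - i
        for j, col in enumerate(table.columns):
            if table.cells.loc[sp, col] == PRESENT:
                color = "#1f4e8c" if col == table.anchor else "#7ea6d9"
                if sp == "ancestor":
                    color = "#7d5ba6"
                ax.arrow(j, y, 0.6, 0, width=0.12, head_width=0.25,
                         head_length=0.15, length_includes_head=True,
                         color=color)
        ax.text(-0.4, y, sp, ha="right", va="center", fontsize=8)
    for j, col in enumerate(table.columns):
        ax.text(j + 0.3, len(table.species) - 0.4, col, rotation=60,
                ha="left", va="bottom", fontsize=7)
    ax.set_xlim(-3, len(table.columns) + 1)
    ax.set_ylim(-0.8, len(table.species) + 0.8)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
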