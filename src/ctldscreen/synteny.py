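"""Micro-synteny block detection between two genomes.

Conservation of synteny — preservation of local gene order between
chromosomes of different species — is used as additional evidence for
candidate receptor genes. Because the target genome may derive from a
whole-genome duplication (the tetraploid carp carries roughly two copies of
each zebrafish gene), the ortholog map is one-to-one-or-two and each target
copy participates in chaining independently, so one reference region can
yield parallel blocks on two target scaffolds.

Formalization: *anchors* are ortholog pairs co-resident on one (reference
chromosome, target chromosome) combination; *blocks* are maximal chains of
anchors whose order indices are strictly monotone on both genomes (both
orientations tried) with at most ``max_gap`` intervening non-anchor genes
between consecutive anchors on each genome. The gap is measured in genes,
not base pairs, which is robust to assembly-scale differences between a
chromosome-level reference and a fragmented scaffold assembly. All maximal
chains are reported; no chain-conflict resolution is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Set

import pandas as pd

ORIENT_SAME = "same"
ORIENT_INVERTED = "inverted"


@dataclass(frozen=True)
class SyntenyBlock:
    """A chained run of ortholog anchors linking two chromosome segments."""

    ref_chrom: str
    target_chrom: str
    anchors: tuple[tuple[str, str], ...]  # (ref gene, target gene), ref order
    orientation: str
    ref_span: tuple[int, int]  # order-index range, inclusive
    target_span: tuple[int, int]

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def _order_lookup(gene_map: pd.DataFrame) -> tuple[dict[str, tuple[str, int]], dict[str, list[str]]]:
    """gene -> (chrom, order index); chrom -> genes in order."""
    loc: dict[str, tuple[str, int]] = {}
    by_chrom: dict[str, list[str]] = {}
    for chrom, sub in gene_map.groupby("chrom"):
        ordered = sub.sort_values("order")["gene_id"].tolist()
        by_chrom[chrom] = ordered
        for idx, gene in enumerate(ordered):
            loc[gene] = (chrom, idx)
    return loc, by_chrom


def find_blocks(
    ref_map: pd.DataFrame,
    target_map: pd.DataFrame,
    orthologs: Mapping[str, Set[str]],
    min_anchors: int = 3,
    max_gap: int = 5,
) -> list[SyntenyBlock]:
    """All maximal micro-synteny blocks between the two gene maps.

    ``ref_map``/``target_map`` follow :func:`ctldscreen.io_formats.read_gene_map`
    (columns gene_id, chrom, start_bp, order). ``orthologs`` maps each
    reference gene to its 1 or 2 target copies.
    """
    if min_anchors < 2:
        raise ValueError(f"min_anchors must be >= 2, got {min_anchors}")
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    if ref_map.empty or target_map.empty:
        raise ValueError("gene maps must be non-empty")

    ref_loc, _ = _order_lookup(ref_map)
    tgt_loc, _ = _order_lookup(target_map)

    # anchors per (ref chrom, target chrom)
    grouped: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for ref_gene in sorted(orthologs):
        if ref_gene not in ref_loc:
            continue
        rchrom, ri = ref_loc[ref_gene]
        for tgt_gene in sorted(orthologs[ref_gene]):
            if tgt_gene not in tgt_loc:
                continue
            tchrom, ti = tgt_loc[tgt_gene]
            grouped.setdefault((rchrom, tchrom), []).append((ri, ti, ref_gene, tgt_gene))

    blocks: list[SyntenyBlock] = []
    for (rchrom, tchrom), anchors in sorted(grouped.items()):
        anchors = sorted(anchors)
        ref_anchor_idx = {a[0] for a in anchors}
        tgt_anchor_idx = {a[1] for a in anchors}

        def gap_ok(i_lo: int, i_hi: int, anchor_idx: set[int]) -> bool:
            between = range(min(i_lo, i_hi) + 1, max(i_lo, i_hi))
            non_anchor = sum(1 for x in between if x not in anchor_idx)
            return non_anchor <= max_gap

        for orientation in (ORIENT_SAME, ORIENT_INVERTED):
            chains = _maximal_chains(anchors, orientation, ref_anchor_idx, tgt_anchor_idx, gap_ok)
            for chain in chains:
                if len(chain) < min_anchors:
                    continue
                ris = [a[0] for a in chain]
                tis = [a[1] for a in chain]
                # a 2-anchor chain matches both orientations; report it once
                if orientation == ORIENT_INVERTED and len(chain) == 2:
                    if tis[1] > tis[0]:
                        continue
                blocks.append(
                    SyntenyBlock(
                        ref_chrom=rchrom,
                        target_chrom=tchrom,
                        anchors=tuple((a[2], a[3]) for a in chain),
                        orientation=orientation,
                        ref_span=(min(ris), max(ris)),
                        target_span=(min(tis), max(tis)),
                    )
                )
    # drop chains whose anchor set is contained in another block's (same chrom pair)
    keep: list[SyntenyBlock] = []
    for blk in blocks:
        mine = set(blk.anchors)
        subsumed = any(
            other is not blk
            and other.ref_chrom == blk.ref_chrom
            and other.target_chrom == blk.target_chrom
            and mine < set(other.anchors)
            for other in blocks
        )
        if not subsumed and blk not in keep:
            keep.append(blk)
    return keep


def _maximal_chains(anchors, orientation, ref_idx, tgt_idx, gap_ok):
    """Enumerate extension-maximal monotone chains via DFS over the
    compatible-successor DAG (anchors pre-sorted by ref order)."""
    n = len(anchors)

    def compatible(a, b) -> bool:  # can b follow a directly?
        if b[0] <= a[0]:
            return False
        if orientation == ORIENT_SAME and b[1] <= a[1]:
            return False
        if orientation == ORIENT_INVERTED and b[1] >= a[1]:
            return False
        return gap_ok(a[0], b[0], ref_idx) and gap_ok(a[1], b[1], tgt_idx)

    successors = {i: [j for j in range(i + 1, n) if compatible(anchors[i], anchors[j])] for i in range(n)}
    has_pred = set()
    for i, succ in successors.items():
        has_pred.update(succ)

    chains: list[list] = []

    def dfs(path: list[int]) -> None:
        succ = successors[path[-1]]
        if not succ:
            chains.append([anchors[i] for i in path])
            return
        for j in succ:
            dfs(path + [j])

    for i in range(n):
        if i not in has_pred:
            dfs([i])
    return chains


def genes_in_blocks(
    blocks: Sequence[SyntenyBlock],
    target_map: pd.DataFrame,
    gene_classes: Mapping[str, bool],
) -> list[tuple[str, SyntenyBlock]]:
    """Target-genome genes of the flagged class (e.g. CTLD-encoding) whose
    order index falls inside a block's target span.

    Residents count, not just anchors — a conserved neighbourhood can
    harbour a receptor gene that is itself not an ortholog anchor.
    """
    tgt_loc, _ = _order_lookup(target_map)
    out: list[tuple[str, SyntenyBlock]] = []
    for blk in blocks:
        lo, hi = blk.target_span
        for gene, (chrom, idx) in tgt_loc.items():
            if chrom == blk.target_chrom and lo <= idx <= hi and gene_classes.get(gene, False):
                out.append((gene, blk))
    out.sort(key=lambda x: (x[0], x[1].ref_chrom, x[1].target_chrom))
    return out


def blocks_to_frame(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    rows = [
        (
            b.ref_chrom,
            b.target_chrom,
            b.orientation,
            b.n_anchors,
            b.ref_span[0],
            b.ref_span[1],
            b.target_span[0],
            b.target_span[1],
            ";".join(f"{r}|{t}" for r, t in b.anchors),
        )
        for b in blocks
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "ref_chrom", "target_chrom", "orientation", "n_anchors",
            "ref_span_lo", "ref_span_hi", "target_span_lo", "target_span_hi", "anchors",
        ],
    )
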