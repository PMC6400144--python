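from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from ctldscreen.synteny import find_blocks, genes_in_blocks
from ctldscreen.synthetic_data import SimConfig, generate_gene_maps


def gene_map(order_by_chrom):
    rows = []
    for chrom, genes in order_by_chrom.items():
        for k, g in enumerate(genes):
            rows.append((g, chrom, 10 * (k + 1)))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start_bp"])
    df["order"] = df.groupby("chrom")["start_bp"].rank(method="first").astype(int) - 1
    return df


# ---------------------------------------------------------------------------
# brute-force oracle: every monotone anchor subset respecting the gap bound
# ---------------------------------------------------------------------------


def brute_force_blocks(ref_map, tgt_map, orthologs, min_anchors, max_gap):
    ref_loc = {r.gene_id: (r.chrom, r.order) for r in ref_map.itertuples(index=False)}
    tgt_loc = {r.gene_id: (r.chrom, r.order) for r in tgt_map.itertuples(index=False)}
    grouped = {}
    for rg in orthologs:
        if rg not in ref_loc:
            continue
        for tg in orthologs[rg]:
            if tg not in tgt_loc:
                continue
            key = (ref_loc[rg][0], tgt_loc[tg][0])
            grouped.setdefault(key, []).append((ref_loc[rg][1], tgt_loc[tg][1], rg, tg))

    result = set()
    for (rc, tc), anchors in grouped.items():
        anchors = sorted(anchors)
        ref_idx = {a[0] for a in anchors}
        tgt_idx = {a[1] for a in anchors}

        def gap_ok(x, y, idx):
            return sum(1 for z in range(min(x, y) + 1, max(x, y)) if z not in idx) <= max_gap

        def valid(chain):
            ris = [a[0] for a in chain]
            tis = [a[1] for a in chain]
            if any(b <= a for a, b in zip(ris, ris[1:])):
                return False
            inc = all(b > a for a, b in zip(tis, tis[1:]))
            dec = all(b < a for a, b in zip(tis, tis[1:]))
            if not (inc or dec):
                return False
            for a, b in zip(chain, chain[1:]):
                if not gap_ok(a[0], b[0], ref_idx) or not gap_ok(a[1], b[1], tgt_idx):
                    return False
            return True

        chains = []
        for size in range(min_anchors, len(anchors) + 1):
            for combo in combinations(anchors, size):
                if valid(list(combo)):
                    chains.append(frozenset((a[2], a[3]) for a in combo))
        maximal = {
            c for c in chains if not any(c < other for other in chains)
        }
        result |= {(rc, tc, c) for c in maximal}
    return result


class TestFindBlocks:
    def test_hand_chaining_with_one_intervening_gene(self):
        ref = gene_map({"chr1": ["g1", "g2", "g3", "g4", "g5"]})
        tgt = gene_map({"chrX": ["h1", "h2", "h9", "h3", "h4"]})
        orth = {f"g{i}": {f"h{i}"} for i in range(1, 6)}
        (block,) = find_blocks(ref, tgt, orth, min_anchors=3, max_gap=1)
        assert block.anchors == (("g1", "h1"), ("g2", "h2"), ("g3", "h3"), ("g4", "h4"))
        assert block.orientation == "same"

    def test_reversed_target_order_is_inverted(self):
        ref = gene_map({"chr1": ["g1", "g2", "g3", "g4", "g5"]})
        tgt = gene_map({"chrX": ["h4", "h3", "h2", "h1"]})
        orth = {f"g{i}": {f"h{i}"} for i in range(1, 6)}
        (block,) = find_blocks(ref, tgt, orth, min_anchors=3, max_gap=1)
        assert block.orientation == "inverted"
        assert {a for a in block.anchors} == {(f"g{i}", f"h{i}") for i in range(1, 5)}

    def test_too_few_anchors_yield_no_block(self):
        ref = gene_map({"chr1": ["g1", "g2"]})
        tgt = gene_map({"chrX": ["h1", "h2"]})
        orth = {"g1": {"h1"}, "g2": {"h2"}}
        assert find_blocks(ref, tgt, orth, min_anchors=3, max_gap=1) == []

    def test_gap_bound_enforced_on_both_genomes(self):
        ref = gene_map({"chr1": ["g1", "r1", "r2", "g2", "g3"]})
        tgt = gene_map({"chrX": ["h1", "h2", "h3"]})
        orth = {"g1": {"h1"}, "g2": {"h2"}, "g3": {"h3"}}
        # two non-anchor genes between g1 and g2 on the reference
        assert find_blocks(ref, tgt, orth, min_anchors=3, max_gap=1) == []
        (block,) = find_blocks(ref, tgt, orth, min_anchors=3, max_gap=2)
        assert block.n_anchors == 3

    def test_duplicated_orthologs_yield_parallel_blocks(self):
        ref = gene_map({"chr1": ["g1", "g2", "g3"]})
        tgt = gene_map(
            {"scfA": ["a1", "a2", "a3"], "scfB": ["b1", "b2", "b3"]}
        )
        orth = {"g1": {"a1", "b1"}, "g2": {"a2", "b2"}, "g3": {"a3", "b3"}}
        blocks = find_blocks(ref, tgt, orth, min_anchors=3, max_gap=1)
        assert {b.target_chrom for b in blocks} == {"scfA", "scfB"}

    def test_min_anchors_below_two_rejected(self):
        ref = gene_map({"chr1": ["g1"]})
        with pytest.raises(ValueError, match="min_anchors"):
            find_blocks(ref, ref, {"g1": {"g1"}}, min_anchors=1)

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(23)
        for trial in range(30):
            n_ref = int(rng.integers(6, 14))
            ref_genes = [f"g{i}" for i in range(n_ref)]
            tgt_genes = [f"h{i}" for i in range(n_ref)] + [f"f{i}" for i in range(4)]
            rng.shuffle(tgt_genes)
            ref = gene_map({"chr1": ref_genes})
            tgt = gene_map({"chrX": tgt_genes})
            orth = {f"g{i}": {f"h{i}"} for i in range(n_ref) if rng.random() < 0.8}
            min_anchors = int(rng.integers(2, 4))
            max_gap = int(rng.integers(0, 4))
            got = {
                (b.ref_chrom, b.target_chrom, frozenset(b.anchors))
                for b in find_blocks(ref, tgt, orth, min_anchors, max_gap)
            }
            expected = brute_force_blocks(ref, tgt, orth, min_anchors, max_gap)
            assert got == expected, (trial, min_anchors, max_gap)

    def test_ref_target_symmetry(self):
        rng = np.random.default_rng(29)
        ref_genes = [f"g{i}" for i in range(10)]
        tgt_genes = [f"h{i}" for i in range(10)]
        rng.shuffle(tgt_genes)
        ref = gene_map({"chr1": ref_genes})
        tgt = gene_map({"chrX": tgt_genes})
        orth = {f"g{i}": {f"h{i}"} for i in range(10)}
        inverted = {}
        for rg, ts in orth.items():
            for t in ts:
                inverted.setdefault(t, set()).add(rg)
        fwd = {frozenset(b.anchors) for b in find_blocks(ref, tgt, orth, 3, 2)}
        rev = {
            frozenset((b_gene, a_gene) for a_gene, b_gene in b.anchors)
            for b in find_blocks(tgt, ref, inverted, 3, 2)
        }
        assert fwd == rev


class TestGenesInBlocks:
    def test_resident_ctld_gene_inside_span_reported(self):
        ref = gene_map({"chr1": ["g1", "g2", "g3"]})
        tgt = gene_map({"chrX": ["h1", "ctld1", "h2", "h3"]})
        orth = {"g1": {"h1"}, "g2": {"h2"}, "g3": {"h3"}}
        blocks = find_blocks(ref, tgt, orth, min_anchors=3, max_gap=1)
        found = genes_in_blocks(blocks, tgt, {"ctld1": True, "h9": True})
        assert [g for g, _ in found] == ["ctld1"]

    def test_ctld_gene_outside_blocks_not_reported(self):
        ref = gene_map({"chr1": ["g1", "g2", "g3"]})
        tgt = gene_map({"chrX": ["h1", "h2", "h3"], "scfY": ["lonely_ctld"]})
        orth = {"g1": {"h1"}, "g2": {"h2"}, "g3": {"h3"}}
        blocks = find_blocks(ref, tgt, orth, min_anchors=3, max_gap=1)
        assert genes_in_blocks(blocks, tgt, {"lonely_ctld": True}) == []

    def test_duplicated_scaffolds_report_both_paralogues(self):
        ref = gene_map({"chr1": ["g1", "g2", "g3"]})
        tgt = gene_map(
            {"scfA": ["a1", "ctldA", "a2", "a3"], "scfB": ["b1", "ctldB", "b2", "b3"]}
        )
        orth = {"g1": {"a1", "b1"}, "g2": {"a2", "b2"}, "g3": {"a3", "b3"}}
        blocks = find_blocks(ref, tgt, orth, min_anchors=3, max_gap=1)
        found = {g for g, _ in genes_in_blocks(blocks, tgt, {"ctldA": True, "ctldB": True})}
        assert found == {"ctldA", "ctldB"}


class TestPlantedRecovery:
    def test_planted_blocks_recovered_exactly(self):
        config = SimConfig(seed=3, block_spec=((4, 1), (5, 2), (3, 0)), n_chrom=3)
        map_a, map_b, orth, truth = generate_gene_maps(config)
        blocks = find_blocks(map_a, map_b, orth, min_anchors=3, max_gap=2)
        found = {frozenset(b.anchors) for b in blocks}
        planted = {frozenset(b) for b in truth.planted_blocks}
        assert planted == found

    def test_duplication_factor_two_doubles_targets(self):
        config = SimConfig(seed=3, duplication_factor=2)
        _, _, orth, _ = generate_gene_maps(config)
        assert all(len(ts) == 2 for ts in orth.values())

    def test_planted_residents_found_inside_blocks(self):
        config = SimConfig(seed=5)
        map_a, map_b, orth, truth = generate_gene_maps(config)
        blocks = find_blocks(map_a, map_b, orth, min_anchors=3, max_gap=2)
        classes = {g: True for g in truth.planted_block_residents}
        found = {g for g, _ in genes_in_blocks(blocks, map_b, classes)}
        assert found == set(truth.planted_block_residents)
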