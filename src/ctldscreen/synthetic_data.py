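"""Synthetic data with known ground truth for every pipeline stage.

Generates (a) proteomes with planted CTLD intervals, signature motifs at
known locations and poly-hydrophobic transmembrane stretches; (b) paired
negative-binomial count matrices with planted up/down-regulated genes per
stimulus; (c) two-genome gene orders with planted conserved blocks and
tetraploid-style 2-copy duplication; (d) random term maps.

Everything is driven by one :class:`SimConfig`. A single master seed fans
out to fixed per-generator child seeds (proteome +1, counts +2, gene maps
+3, term map +4), so each data type can be regenerated independently and
identical configs give byte-identical outputs.

The ground truth (:class:`TruthManifest`) lists what was *planted*, not
everything that is detectable: background residues are i.i.d. uniform over
the 20-residue alphabet, so the motif scanner and the hydropathy caller may
legitimately find additional background hits. Recovery tests must therefore
check that planted items are found, not that found items equal planted ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CONTROL, CountMatrix, DomainAnnotation, ProteinRecord, SampleDesign
from .motif_architecture import BUILTIN_MOTIFS, LocationClass, MotifSpec

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: residues used to instantiate wildcard positions and spacers: avoids the
#: motif literals (W, H, Y, L, I) and the strongly hydrophobic TM residues,
#: so planted items stay where they were put.
_FILLER = "ACDEGNPQST"
_TM_RESIDUES = "ILVF"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data generator.

    Defaults mirror the emulated experiment where it states them: two
    β-glucan stimuli against paired unstimulated controls, a ≥2-fold
    planted effect size on 50 of 1000 genes, and duplication factor 2 for
    the tetraploid target genome. ``n_pairs`` defaults to 6 (the power-study
    design); the emulated study's own layout (3 cultures per stimulus, 5
    unstimulated samples for the expression criterion) is reachable with
    ``n_pairs=3, n_extra_controls=2``.
    """

    seed: int = 0
    # --- proteome ---
    n_proteins: int = 60
    ctld_fraction: float = 0.5
    motif_plant_rates: Mapping[str, float] = field(
        default_factory=lambda: {"WxH": 0.6, "WxHx{1,4}Y": 0.3, "WxHx{5}Y": 0.25, "ITAM": 0.5}
    )
    motif_locations: Mapping[str, str] = field(
        default_factory=lambda: {
            "WxH": "IN_DOMAIN",
            "WxHx{1,4}Y": "IN_DOMAIN",
            "WxHx{5}Y": "NEAR_BOUNDARY",
            "ITAM": "OUTSIDE",
        }
    )
    tm_rate: float = 0.4
    protein_length_range: tuple[int, int] = (250, 400)
    ctld_length: int = 110
    boundary_margin: int = 10
    tm_length: int = 21
    # --- counts ---
    n_genes: int = 1000
    n_pairs: int = 6
    n_extra_controls: int = 0
    stimuli: tuple[str, ...] = ("curdlan", "macrogard")
    n_de: int = 50
    lfc_mean: float = 2.0
    nb_dispersion: float = 0.1
    libsize_range: tuple[int, int] = (800_000, 1_200_000)
    base_mean_range: tuple[float, float] = (20.0, 500.0)
    gene_length_range: tuple[int, int] = (500, 5000)
    # --- gene maps ---
    n_chrom: int = 2
    genes_per_chrom: int = 30
    block_spec: tuple[tuple[int, int], ...] = ((4, 1), (5, 2))
    duplication_factor: int = 2

    def __post_init__(self) -> None:
        if self.n_proteins < 0 or self.n_genes < 0 or self.n_de < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.ctld_fraction <= 1.0):
            raise ValueError("ctld_fraction must be in [0, 1]")
        for name, rate in self.motif_plant_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"plant rate for '{name}' must be in [0, 1]")
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.duplication_factor not in (1, 2):
            raise ValueError("duplication_factor must be 1 or 2")
        if self.n_de > 0 and self.n_genes <= self.n_de:
            raise ValueError("n_genes must exceed n_de")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")


@dataclass
class TruthManifest:
    """Everything the generator planted, for downstream recovery tests."""

    planted_motifs: list[tuple[str, str, int, int, str]] = field(default_factory=list)
    # (protein_id, motif_name, start, end, location_class)
    planted_de: list[tuple[str, str, str, float]] = field(default_factory=list)
    # (gene_id, stimulus, direction, true lfc)
    planted_blocks: list[list[tuple[str, str]]] = field(default_factory=list)
    planted_tm: list[tuple[str, int, int]] = field(default_factory=list)
    planted_block_residents: list[str] = field(default_factory=list)
    # CTLD-class target genes placed inside planted block spans

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        raw = json.loads(text)
        return cls(
            planted_motifs=[tuple(x) for x in raw["planted_motifs"]],
            planted_de=[tuple(x) for x in raw["planted_de"]],
            planted_blocks=[[tuple(p) for p in blk] for blk in raw["planted_blocks"]],
            planted_tm=[tuple(x) for x in raw["planted_tm"]],
            planted_block_residents=list(raw.get("planted_block_residents", [])),
        )


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------


def _instantiate_motif(spec: MotifSpec, rng: np.random.Generator) -> str:
    out: list[str] = []
    for tok in spec.tokens:
        if tok.residues is not None:
            out.append(rng.choice(sorted(tok.residues)))
        else:
            run = int(rng.integers(tok.min_len, tok.max_len + 1))
            out.extend(rng.choice(list(_FILLER), size=run))
    return "".join(out)


def _free_slot(
    rng: np.random.Generator, lo: int, hi: int, length: int, occupied: list[tuple[int, int]]
) -> int | None:
    """A 0-based start in [lo, hi] whose [start, start+length) avoids
    occupied intervals; None after bounded retries."""
    if hi < lo:
        return None
    for _ in range(30):
        start = int(rng.integers(lo, hi + 1))
        span = (start, start + length - 1)
        if all(span[1] < s or span[0] > e for s, e in occupied):
            return start
    return None


def generate_proteome(
    config: SimConfig,
) -> tuple[list[ProteinRecord], list[DomainAnnotation], TruthManifest]:
    """Proteins with planted CTLDs, signature motifs and TM stretches.

    Each CTLD-bearing protein carries one CTLD interval of fixed length;
    motifs are planted per ``motif_plant_rates`` at the location class named
    in ``motif_locations`` (inside the CTLD / just outside within the
    boundary margin / well outside). TM stretches are poly-hydrophobic runs
    long enough to be certain calls for the hydropathy caller.
    """
    rng = np.random.default_rng(config.seed + 1)
    specs = {name: MotifSpec(name, pat) for name, pat in BUILTIN_MOTIFS.items()}
    for name in config.motif_plant_rates:
        if name not in specs:
            raise ValueError(f"unknown motif '{name}' (no builtin pattern)")
        if specs[name].max_length > config.ctld_length:
            raise ValueError(
                f"motif '{name}' (up to {specs[name].max_length} residues) is longer "
                f"than the host CTLD interval ({config.ctld_length} residues)"
            )

    proteins: list[ProteinRecord] = []
    domains: list[DomainAnnotation] = []
    manifest = TruthManifest()
    lo_len, hi_len = config.protein_length_range
    margin = config.boundary_margin

    for idx in range(config.n_proteins):
        pid = f"prot{idx + 1:04d}"
        length = int(rng.integers(lo_len, hi_len + 1))
        seq = list(rng.choice(list(_AA20), size=length))
        has_ctld = rng.random() < config.ctld_fraction
        occupied: list[tuple[int, int]] = []  # 0-based inclusive intervals

        dom: DomainAnnotation | None = None
        if has_ctld:
            dom_start0 = int(rng.integers(20, 61))
            dom = DomainAnnotation(pid, "CTLD", dom_start0 + 1, dom_start0 + config.ctld_length)
            domains.append(dom)

        for name in sorted(config.motif_plant_rates):
            rate = config.motif_plant_rates[name]
            if dom is None or rng.random() >= rate:
                continue
            spec = specs[name]
            text = _instantiate_motif(spec, rng)
            want = LocationClass(config.motif_locations.get(name, "IN_DOMAIN"))
            dom0_start, dom0_end = dom.start - 1, dom.end - 1
            if want == LocationClass.IN_DOMAIN:
                start0 = _free_slot(
                    rng, dom0_start, dom0_end - len(text) + 1, len(text), occupied
                )
            elif want == LocationClass.NEAR_BOUNDARY:
                # entirely outside the CTLD, within `margin` residues of its end
                lo = dom0_end + 1
                hi = min(dom0_end + 1 + margin, length - len(text))
                start0 = _free_slot(rng, lo, hi, len(text), occupied)
            else:  # OUTSIDE: more than `margin` residues past the CTLD end
                lo = dom0_end + margin + 5
                hi = length - len(text)
                start0 = _free_slot(rng, lo, hi, len(text), occupied)
            if start0 is None:
                continue  # no room this time; planting is best-effort, truth stays exact
            seq[start0 : start0 + len(text)] = list(text)
            occupied.append((start0, start0 + len(text) - 1))
            manifest.planted_motifs.append(
                (pid, name, start0 + 1, start0 + len(text), want.value)
            )

        if rng.random() < config.tm_rate:
            tm_text = "".join(rng.choice(list(_TM_RESIDUES), size=config.tm_length))
            if dom is not None:
                # keep the TM clear of the CTLD and its classification margin
                lo = dom.end + margin + 5
            else:
                lo = 10
            start0 = _free_slot(rng, lo, length - config.tm_length, config.tm_length, occupied)
            if start0 is not None:
                seq[start0 : start0 + config.tm_length] = list(tm_text)
                occupied.append((start0, start0 + config.tm_length - 1))
                manifest.planted_tm.append((pid, start0 + 1, start0 + config.tm_length))

        proteins.append(ProteinRecord(pid, "".join(seq)))
    return proteins, domains, manifest


# ---------------------------------------------------------------------------
# paired counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2 (Poisson limit at
    dispersion -> 0)."""
    if dispersion < 1e-8:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate_counts(
    config: SimConfig,
) -> tuple[CountMatrix, SampleDesign, TruthManifest]:
    """Paired negative-binomial counts with planted fold changes.

    Each of ``n_pairs`` fish contributes one control sample plus one sample
    per stimulus; ``n_extra_controls`` adds unpaired unstimulated samples
    (they widen the expression-criterion control set only). Planted DE genes
    get a multiplicative ``2**lfc`` applied in the stimulated samples of
    every pair, with sign chosen per gene.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    lo_bm, hi_bm = config.base_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo_bm), np.log(hi_bm), size=config.n_genes))
    gene_lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=config.n_genes
    )

    samples: list[tuple[str, str, str]] = []
    for i in range(1, config.n_pairs + 1):
        samples.append((f"f{i}_{CONTROL}", f"f{i}", CONTROL))
        for stim in config.stimuli:
            samples.append((f"f{i}_{stim}", f"f{i}", stim))
    for j in range(1, config.n_extra_controls + 1):
        samples.append((f"x{j}_{CONTROL}", f"x{j}", CONTROL))
    design = SampleDesign(samples=tuple(samples))

    lo_ls, hi_ls = config.libsize_range
    libsizes = np.exp(rng.uniform(np.log(lo_ls), np.log(hi_ls), size=len(samples)))

    manifest = TruthManifest()
    lfc = {}  # (gene_index, stimulus) -> signed log2 fold change
    for stim in config.stimuli:
        if config.n_de == 0:
            continue
        chosen = rng.choice(config.n_genes, size=config.n_de, replace=False)
        for gi in sorted(chosen):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            value = sign * config.lfc_mean
            lfc[(gi, stim)] = value
            manifest.planted_de.append(
                (genes[gi], stim, "up" if sign > 0 else "down", value)
            )

    # scale base means so column sums land near the drawn library sizes
    scale = 1.0 / base_mean.sum()
    counts = np.zeros((config.n_genes, len(samples)), dtype=np.int64)
    for s_idx, (sid, _, cond) in enumerate(samples):
        mu = base_mean * scale * libsizes[s_idx]
        if cond != CONTROL:
            fold = np.ones(config.n_genes)
            for (gi, stim), value in lfc.items():
                if stim == cond:
                    fold[gi] = 2.0 ** value
            mu = mu * fold
        counts[:, s_idx] = _nb_draw(rng, mu, config.nb_dispersion)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=[s[0] for s in samples]),
        gene_lengths=pd.Series(gene_lengths, index=genes, name="length"),
    )
    return matrix, design, manifest


# ---------------------------------------------------------------------------
# gene maps
# ---------------------------------------------------------------------------


def generate_gene_maps(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, set[str]], TruthManifest]:
    """Two-genome gene orders with planted micro-synteny blocks.

    Genome A (reference) has ``n_chrom`` chromosomes of ``genes_per_chrom``
    ordered genes. Every A gene has ``duplication_factor`` copies in genome
    B. Planted blocks occupy a consecutive run of A genes; each B copy of
    the run is laid out co-ordered on its own scaffold with at most the
    block's ``max_gap`` unmapped filler genes between consecutive anchors
    (one filler per block is a CTLD-class resident gene, mirroring a
    receptor gene sitting inside a conserved neighbourhood). All remaining B
    copies land on singleton scaffolds, emulating a fragmented assembly.
    """
    rng = np.random.default_rng(config.seed + 3)
    chroms = [f"chrA{i + 1}" for i in range(config.n_chrom)]
    a_rows = []
    a_genes_by_chrom: dict[str, list[str]] = {}
    for chrom in chroms:
        ids = [f"a_{chrom}_{k + 1:03d}" for k in range(config.genes_per_chrom)]
        a_genes_by_chrom[chrom] = ids
        for k, gid in enumerate(ids):
            a_rows.append((gid, chrom, 10_000 * (k + 1)))
    map_a = pd.DataFrame(a_rows, columns=["gene_id", "chrom", "start_bp"])

    orthologs: dict[str, set[str]] = {}
    for chrom in chroms:
        for gid in a_genes_by_chrom[chrom]:
            orthologs[gid] = {
                f"b_{gid}_c{c + 1}" for c in range(config.duplication_factor)
            }

    manifest = TruthManifest()
    b_rows: list[tuple[str, str, int]] = []
    used_offset: dict[str, int] = {c: 0 for c in chroms}
    placed_on_blocks: set[str] = set()

    for blk_idx, (n_anchors, max_gap) in enumerate(config.block_spec):
        chrom = chroms[blk_idx % len(chroms)]
        offset = used_offset[chrom]
        if offset + n_anchors > config.genes_per_chrom:
            raise ValueError(
                f"chromosome '{chrom}' is over-full: block of {n_anchors} anchors "
                f"does not fit past offset {offset} ({config.genes_per_chrom} genes)"
            )
        anchors_a = a_genes_by_chrom[chrom][offset : offset + n_anchors]
        used_offset[chrom] = offset + n_anchors + 2  # leave slack between blocks

        # gap pattern shared across copies so every copy satisfies the bound
        gaps = [int(rng.integers(0, max_gap + 1)) for _ in range(n_anchors - 1)]
        if max_gap >= 1 and gaps and all(g == 0 for g in gaps):
            gaps[0] = 1  # keep room for the resident CTLD gene
        resident_slot = next((i for i, g in enumerate(gaps) if g > 0), None)

        for copy in range(config.duplication_factor):
            scaffold = f"scf_block{blk_idx + 1}_c{copy + 1}"
            pos = 0
            pairs: list[tuple[str, str]] = []
            for i, a_gene in enumerate(anchors_a):
                b_gene = f"b_{a_gene}_c{copy + 1}"
                b_rows.append((b_gene, scaffold, 1_000 * (pos + 1)))
                placed_on_blocks.add(b_gene)
                pairs.append((a_gene, b_gene))
                pos += 1
                if i < n_anchors - 1:
                    for j in range(gaps[i]):
                        if i == resident_slot and j == 0:
                            fid = f"b_ctld_block{blk_idx + 1}_c{copy + 1}"
                            manifest.planted_block_residents.append(fid)
                        else:
                            fid = f"b_fill_block{blk_idx + 1}_c{copy + 1}_{i}_{j}"
                        b_rows.append((fid, scaffold, 1_000 * (pos + 1)))
                        pos += 1
            manifest.planted_blocks.append(pairs)

    for chrom in chroms:
        for gid in a_genes_by_chrom[chrom]:
            for copy in range(config.duplication_factor):
                b_gene = f"b_{gid}_c{copy + 1}"
                if b_gene not in placed_on_blocks:
                    b_rows.append((b_gene, f"scf_{gid}_c{copy + 1}", 1_000))

    map_b = pd.DataFrame(b_rows, columns=["gene_id", "chrom", "start_bp"])
    for df in (map_a, map_b):
        df["order"] = df.groupby("chrom")["start_bp"].rank(method="first").astype("int64") - 1
    return map_a, map_b, orthologs, manifest


# ---------------------------------------------------------------------------
# term maps
# ---------------------------------------------------------------------------


def generate_term_map(
    config: SimConfig, genes: Sequence[str], n_terms: int = 20
) -> dict[str, set[str]]:
    """Random term -> gene-set annotations over the given gene universe."""
    rng = np.random.default_rng(config.seed + 4)
    genes = list(genes)
    out: dict[str, set[str]] = {}
    for t in range(n_terms):
        size = int(rng.integers(10, max(11, len(genes) // 20)))
        size = min(size, len(genes))
        members = rng.choice(len(genes), size=size, replace=False)
        out[f"T{t + 1:03d}"] = {genes[i] for i in members}
    return out
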