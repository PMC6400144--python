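"""Readers and writers for every on-disk format the screening pipeline touches.

Conventions (enforced, not just documented):

* All residue coordinates are **1-based inclusive**, the style used by
  Pfam/EMBOSS reports; a ``start`` of 0 is always rejected.
* Tabular files are tab-separated, ``#`` starts a comment line, and a header
  row is required.
* Protein sequences use the 20 canonical residues plus ``X`` (unknown);
  ``*`` (translation stop) is stripped with a warning, since conceptual
  translations frequently end in a stop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = AMINO_ACIDS | {"X"}
GAP = "-"
CONTROL = "control"


class FormatError(ValueError):
    """Raised for any malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# protein records and FASTA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: unique identifier plus upper-case amino-acid sequence."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def _parse_fasta_text(
    lines: Iterable[str], *, allow_gaps: bool = False, source: str = "<fasta>"
) -> list[ProteinRecord]:
    allowed = ALPHABET | ({GAP} if allow_gaps else set())
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    stripped_stop = False

    def flush() -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{source}: record '{header}' has an empty sequence")
        records.append(ProteinRecord(id=header, sequence=seq))
        header, chunks = None, []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].split()[0] if line[1:].split() else ""
            if not header:
                raise FormatError(f"{source}:{lineno}: empty FASTA identifier")
            if header in seen:
                raise FormatError(f"{source}:{lineno}: duplicate identifier '{header}'")
            seen.add(header)
            continue
        if header is None:
            raise FormatError(f"{source}:{lineno}: sequence data before any '>' header")
        piece = "".join(line.split()).upper()
        if "*" in piece:
            piece = piece.replace("*", "")
            stripped_stop = True
        for ch in piece:
            if ch not in allowed:
                raise FormatError(
                    f"{source}:{lineno}: illegal character '{ch}' in sequence of '{header}'"
                )
        chunks.append(piece)
    flush()
    if stripped_stop:
        warnings.warn(f"{source}: stop codons ('*') stripped from sequences", stacklevel=3)
    if not records:
        raise FormatError(f"{source}: no FASTA records found")
    return records


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read plain (ungapped) protein FASTA; records are kept in file order."""
    path = Path(path)
    with open(path) as fh:
        return _parse_fasta_text(fh, allow_gaps=False, source=str(path))


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# alignments (aligned FASTA)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """Ordered (id, aligned sequence) pairs of equal length; gap char ``-``."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise FormatError("alignment ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("alignment contains duplicate ids")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise FormatError(f"aligned sequences have unequal lengths: {sorted(lengths)}")


def read_alignment(path: str | Path) -> Alignment:
    path = Path(path)
    with open(path) as fh:
        records = _parse_fasta_text(fh, allow_gaps=True, source=str(path))
    return Alignment(
        ids=tuple(r.id for r in records), sequences=tuple(r.sequence for r in records)
    )


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    write_fasta(
        [ProteinRecord(i, s) for i, s in zip(alignment.ids, alignment.sequences)], path
    )


# ---------------------------------------------------------------------------
# domain annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainAnnotation:
    """A labelled residue interval (1-based inclusive) on a protein."""

    protein_id: str
    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"invalid interval [{self.start}, {self.end}] for '{self.protein_id}': "
                "coordinates are 1-based inclusive with start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_domain_table(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[DomainAnnotation]:
    """Read a domain-interval table and validate it against protein lengths."""
    lengths = {p.id: p.length for p in proteins}
    df = _read_tsv(path, ["protein_id", "label", "start", "end"])
    out: list[DomainAnnotation] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        pid = str(row.protein_id)
        if pid not in lengths:
            raise FormatError(f"{path} row {row_no}: unknown protein_id '{pid}'")
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path} row {row_no}: non-integer coordinates") from exc
        if start < 1:
            raise FormatError(
                f"{path} row {row_no}: start {start} invalid (coordinates are 1-based)"
            )
        if end > lengths[pid]:
            raise FormatError(
                f"{path} row {row_no}: end {end} exceeds length {lengths[pid]} of '{pid}'"
            )
        out.append(DomainAnnotation(pid, str(row.label), start, end))
    return out


def write_domain_table(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(d.protein_id, d.label, d.start, d.end) for d in domains],
        columns=["protein_id", "label", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# paired sample design and count matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """Paired layout: each pair (fish/culture) has exactly one control sample.

    ``condition`` is either :data:`CONTROL` or a stimulus label (e.g.
    ``curdlan``, ``macrogard``).
    """

    samples: tuple[tuple[str, str, str], ...]  # (sample_id, pair_id, condition)

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample_id in design")
        controls: dict[str, int] = {}
        pairs_with_stim: set[str] = set()
        for _, pair, cond in self.samples:
            if cond == CONTROL:
                controls[pair] = controls.get(pair, 0) + 1
            else:
                pairs_with_stim.add(pair)
        for pair, n in controls.items():
            if n != 1:
                raise FormatError(f"pair '{pair}' has {n} control samples (expected 1)")
        for pair in sorted(pairs_with_stim):
            if pair not in controls:
                raise FormatError(f"stimulated sample of pair '{pair}' has no control partner")

    @property
    def sample_ids(self) -> list[str]:
        return [s[0] for s in self.samples]

    def condition_of(self, sample_id: str) -> str:
        for sid, _, cond in self.samples:
            if sid == sample_id:
                return cond
        raise KeyError(sample_id)

    def control_samples(self) -> list[str]:
        return [s for s, _, c in self.samples if c == CONTROL]

    def stimuli(self) -> list[str]:
        seen: list[str] = []
        for _, _, cond in self.samples:
            if cond != CONTROL and cond not in seen:
                seen.append(cond)
        return seen

    def pairs_for(self, stimulus: str) -> list[tuple[str, str, str]]:
        """Complete (pair_id, control_sample, stimulated_sample) triples."""
        ctrl = {p: s for s, p, c in self.samples if c == CONTROL}
        out = []
        for sid, pair, cond in self.samples:
            if cond == stimulus and pair in ctrl:
                out.append((pair, ctrl[pair], sid))
        return out


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-gene transcript lengths."""

    counts: pd.DataFrame  # genes x samples, int64
    gene_lengths: pd.Series  # bp, indexed like counts

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique or not self.counts.columns.is_unique:
            raise FormatError("count matrix gene/sample ids must be unique")
        if (self.counts.values < 0).any():
            raise FormatError("count matrix contains negative values")
        if not self.gene_lengths.index.equals(self.counts.index):
            raise FormatError("gene_lengths index does not match count matrix genes")
        if (self.gene_lengths <= 0).any():
            bad = self.gene_lengths.index[self.gene_lengths <= 0][0]
            raise FormatError(f"non-positive gene length for '{bad}'")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def read_counts(
    path_counts: str | Path, path_design: str | Path
) -> tuple[CountMatrix, SampleDesign]:
    """Read a count table (gene_id, length, one column per sample) + design."""
    df = _read_tsv(path_counts, ["gene_id", "length"])
    df = df.set_index("gene_id")
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path_counts}: duplicate gene_id '{dup}'")
    lengths = pd.to_numeric(df.pop("length"), errors="coerce")
    if lengths.isna().any():
        bad = lengths.index[lengths.isna()][0]
        raise FormatError(f"{path_counts}: non-numeric length for gene '{bad}'")
    counts = pd.DataFrame(index=df.index)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            gene = vals.index[vals.isna()][0]
            raise FormatError(f"{path_counts}: non-numeric count at (gene '{gene}', sample '{col}')")
        if ((vals % 1) != 0).any():
            gene = vals.index[(vals % 1) != 0][0]
            raise FormatError(
                f"{path_counts}: non-integer count at (gene '{gene}', sample '{col}')"
            )
        if (vals < 0).any():
            gene = vals.index[vals < 0][0]
            raise FormatError(f"{path_counts}: negative count at (gene '{gene}', sample '{col}')")
        counts[col] = vals.astype("int64")

    ddf = _read_tsv(path_design, ["sample_id", "pair_id", "condition"])
    design = SampleDesign(
        samples=tuple(
            (str(r.sample_id), str(r.pair_id), str(r.condition))
            for r in ddf.itertuples(index=False)
        )
    )
    if set(design.sample_ids) != set(counts.columns):
        raise FormatError(
            f"{path_design}: design samples {sorted(design.sample_ids)} do not match "
            f"count columns {sorted(counts.columns)}"
        )
    matrix = CountMatrix(counts=counts[design.sample_ids], gene_lengths=lengths.astype("int64"))
    return matrix, design


def write_counts(matrix: CountMatrix, design: SampleDesign, path_counts, path_design) -> None:
    out = matrix.counts.copy()
    out.insert(0, "length", matrix.gene_lengths)
    out.index.name = "gene_id"
    out.to_csv(path_counts, sep="\t")
    pd.DataFrame(list(design.samples), columns=["sample_id", "pair_id", "condition"]).to_csv(
        path_design, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene maps, ortholog maps and term maps
# ---------------------------------------------------------------------------


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """Gene location table (gene_id, chrom, start_bp) with derived order index.

    The order index of a gene is the rank of its start coordinate within its
    chromosome (0-based).
    """
    df = _read_tsv(path, ["gene_id", "chrom", "start_bp"])
    df = df.assign(start_bp=pd.to_numeric(df["start_bp"], errors="raise").astype("int64"))
    if df.duplicated(subset=["chrom", "gene_id"]).any():
        bad = df[df.duplicated(subset=["chrom", "gene_id"])].iloc[0]
        raise FormatError(f"{path}: duplicate (chrom, gene_id) ({bad.chrom}, {bad.gene_id})")
    df["order"] = df.groupby("chrom")["start_bp"].rank(method="first").astype("int64") - 1
    return df.reset_index(drop=True)


def write_gene_map(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene_id", "chrom", "start_bp"]].to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | Path) -> dict[str, set[str]]:
    df = _read_tsv(path, ["ref_id", "target_id"])
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.ref_id), set()).add(str(r.target_id))
    return out


def write_ortholog_map(orthologs: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [(ref, tgt) for ref in sorted(orthologs) for tgt in sorted(orthologs[ref])]
    pd.DataFrame(rows, columns=["ref_id", "target_id"]).to_csv(path, sep="\t", index=False)


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """term_id -> gene id set, one (term_id, gene_id) pair per row."""
    df = _read_tsv(path, ["term_id", "gene_id"])
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.term_id), set()).add(str(r.gene_id))
    return out


def write_term_map(terms: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [(t, g) for t in sorted(terms) for g in sorted(terms[t])]
    pd.DataFrame(rows, columns=["term_id", "gene_id"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick trees (dendropy containers, internal-node support labels)
# ---------------------------------------------------------------------------


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick, keeping branch lengths and support labels."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)
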