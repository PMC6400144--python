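"""Signature-motif scanning and domain-architecture classification.

Implements the receptor-screening side of the pipeline that operates on
protein sequence alone:

* a small PROSITE-flavoured pattern matcher (literals, ``x`` wildcards,
  ``[AB]`` alternation, ``x{m,n}`` bounded wildcard repetition) used for the
  glucan-binding signatures ``WxH``, ``WxHx{1,4}Y`` and ``WxHx{5}Y`` and the
  ITAM signature ``Yxx[LI]``;
* classification of hits relative to annotated C-type lectin-like domain
  (CTLD) intervals (inside / near a boundary / outside);
* a Kyte-Doolittle sliding-window transmembrane-segment caller;
* a per-protein architecture summary with a Dectin-1-likeness flag.

All coordinates are 1-based inclusive. Matching is case-insensitive and an
``X`` (unknown residue) in the sequence satisfies wildcard positions but
never a literal position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping, Sequence

from .io_formats import AMINO_ACIDS, DomainAnnotation, ProteinRecord

CTLD_LABEL = "CTLD"

#: Signature patterns used throughout the screen. ``WxH`` is the minimal
#: glucan-binding signature of Dectin-1; the ``...Y`` variants add the
#: tyrosine that shapes the binding cleft (1-4 or exactly 5 spacer residues);
#: ``ITAM`` is the single-occurrence YxxL/I activation-motif signature.
BUILTIN_MOTIFS: dict[str, str] = {
    "WxH": "WxH",
    "WxHx{1,4}Y": "WxHx{1,4}Y",
    "WxHx{5}Y": "WxHx{5}Y",
    "ITAM": "Yxx[LI]",
}


class PatternError(ValueError):
    """Malformed motif pattern; message carries the offending position."""


class LocationClass(str, Enum):
    IN_DOMAIN = "IN_DOMAIN"
    NEAR_BOUNDARY = "NEAR_BOUNDARY"
    OUTSIDE = "OUTSIDE"


@dataclass(frozen=True)
class _Token:
    """One pattern element: a residue set (literal/alternation) or a bounded
    wildcard run. ``residues=None`` marks a wildcard."""

    residues: frozenset[str] | None
    min_len: int
    max_len: int


@dataclass(frozen=True)
class MotifSpec:
    """A named signature pattern in the mini-grammar.

    Grammar: a literal residue letter; ``x`` for any residue; ``[AB]`` for
    alternation over the bracketed residues; ``x{m,n}`` (or ``x{m}``) for a
    bounded wildcard run with 1 <= m <= n <= 9.
    """

    name: str
    pattern: str

    def __post_init__(self) -> None:
        tokens = _parse_pattern(self.pattern)
        if all(t.residues is None for t in tokens):
            raise PatternError(f"pattern '{self.pattern}' has no literal position")

    @property
    def tokens(self) -> tuple[_Token, ...]:
        return _parse_pattern(self.pattern)

    @property
    def min_length(self) -> int:
        return sum(t.min_len for t in self.tokens)

    @property
    def max_length(self) -> int:
        return sum(t.max_len for t in self.tokens)


def _parse_pattern(pattern: str) -> tuple[_Token, ...]:
    tokens: list[_Token] = []
    i = 0
    n = len(pattern)
    while i < n:
        ch = pattern[i]
        if ch == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise PatternError(f"position {i}: unterminated '[' in '{pattern}'")
            members = pattern[i + 1 : j].upper()
            if not members or any(m not in AMINO_ACIDS for m in members):
                raise PatternError(f"position {i}: bad alternation '[{members}]'")
            tokens.append(_Token(frozenset(members), 1, 1))
            i = j + 1
        elif ch in ("x", "X"):
            i += 1
            if i < n and pattern[i] == "{":
                j = pattern.find("}", i)
                if j < 0:
                    raise PatternError(f"position {i}: unterminated '{{' in '{pattern}'")
                body = pattern[i + 1 : j]
                parts = body.split(",")
                try:
                    if len(parts) == 1:
                        m_rep = n_rep = int(parts[0])
                    elif len(parts) == 2:
                        m_rep, n_rep = int(parts[0]), int(parts[1])
                    else:
                        raise ValueError
                except ValueError:
                    raise PatternError(
                        f"position {i}: bad repetition '{{{body}}}'"
                    ) from None
                if not (1 <= m_rep <= n_rep <= 9):
                    raise PatternError(
                        f"position {i}: repetition bounds must satisfy 1 <= m <= n <= 9"
                    )
                tokens.append(_Token(None, m_rep, n_rep))
                i = j + 1
            else:
                tokens.append(_Token(None, 1, 1))
        elif ch.upper() in AMINO_ACIDS:
            tokens.append(_Token(frozenset(ch.upper()), 1, 1))
            i += 1
        else:
            raise PatternError(f"position {i}: unexpected character '{ch}' in '{pattern}'")
    if not tokens:
        raise PatternError("empty pattern")
    return tuple(tokens)


@dataclass(frozen=True)
class MotifHit:
    """One signature match; ``location_class`` is set by locate_in_domains."""

    protein_id: str
    motif_name: str
    start: int  # 1-based inclusive
    end: int
    matched_text: str
    location_class: LocationClass | None = None
    domain_ref: DomainAnnotation | None = None


def find_motifs(protein: ProteinRecord, spec: MotifSpec) -> list[MotifHit]:
    """Report *all* matches of ``spec`` in the protein, overlaps included.

    For bounded wildcard repetition every distinct (start, end) pair that
    satisfies the pattern is a separate hit.
    """
    seq = protein.sequence.upper()
    tokens = spec.tokens
    n = len(seq)
    hits: list[MotifHit] = []

    def extend(pos: int, tok_idx: int, start: int) -> None:
        if tok_idx == len(tokens):
            hits.append(
                MotifHit(
                    protein_id=protein.id,
                    motif_name=spec.name,
                    start=start + 1,
                    end=pos,
                    matched_text=seq[start:pos],
                )
            )
            return
        tok = tokens[tok_idx]
        if tok.residues is not None:
            if pos < n and seq[pos] in tok.residues:  # 'X' never equals a literal
                extend(pos + 1, tok_idx + 1, start)
        else:
            for run in range(tok.min_len, tok.max_len + 1):
                if pos + run > n:
                    break
                extend(pos + run, tok_idx + 1, start)

    for start in range(n):
        extend(start, 0, start)
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def scan_proteins(
    proteins: Sequence[ProteinRecord],
    specs: Sequence[MotifSpec] | None = None,
) -> dict[str, list[MotifHit]]:
    """Scan every protein with every spec; hits keyed by motif name."""
    if specs is None:
        specs = [MotifSpec(name, pat) for name, pat in BUILTIN_MOTIFS.items()]
    out: dict[str, list[MotifHit]] = {s.name: [] for s in specs}
    for prot in proteins:
        for spec in specs:
            out[spec.name].extend(find_motifs(prot, spec))
    return out


# ---------------------------------------------------------------------------
# hit location relative to CTLD intervals
# ---------------------------------------------------------------------------


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Residues strictly between two intervals; 0 when they touch/overlap."""
    if a_end < b_start:
        return b_start - a_end - 1
    if b_end < a_start:
        return a_start - b_end - 1
    return 0


def locate_in_domains(
    hits: Sequence[MotifHit],
    domains: Sequence[DomainAnnotation],
    margin: int = 10,
    domain_label: str = CTLD_LABEL,
) -> list[MotifHit]:
    """Classify each hit relative to the protein's CTLD intervals.

    IN_DOMAIN when the hit lies fully inside some CTLD; NEAR_BOUNDARY when it
    overlaps a CTLD partially or lies within ``margin`` residues of a CTLD
    boundary; OTHERWISE OUTSIDE. ``domain_ref`` is the classifying domain
    (nearest on tie).
    """
    if margin < 0:
        raise ValueError(f"margin must be non-negative, got {margin}")
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for dom in domains:
        if dom.label == domain_label:
            by_protein.setdefault(dom.protein_id, []).append(dom)

    located: list[MotifHit] = []
    for hit in hits:
        doms = by_protein.get(hit.protein_id, [])
        best: tuple[int, int, DomainAnnotation] | None = None  # (class-rank, gap, dom)
        for dom in doms:
            if dom.start <= hit.start and hit.end <= dom.end:
                cand = (0, 0, dom)
            else:
                gap = _interval_gap(hit.start, hit.end, dom.start, dom.end)
                if gap <= margin:
                    cand = (1, gap, dom)
                else:
                    continue
            if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                best = cand
        if best is None:
            located.append(replace(hit, location_class=LocationClass.OUTSIDE, domain_ref=None))
        elif best[0] == 0:
            located.append(
                replace(hit, location_class=LocationClass.IN_DOMAIN, domain_ref=best[2])
            )
        else:
            located.append(
                replace(hit, location_class=LocationClass.NEAR_BOUNDARY, domain_ref=best[2])
            )
    return located


# ---------------------------------------------------------------------------
# transmembrane segments by hydropathy
# ---------------------------------------------------------------------------

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


@dataclass(frozen=True)
class TMSegment:
    protein_id: str
    start: int  # 1-based inclusive
    end: int


def predict_tm(
    protein: ProteinRecord, window: int = 19, threshold: float = 1.6
) -> list[TMSegment]:
    """Sliding-window Kyte-Doolittle transmembrane caller.

    A window is TM-positive when its mean hydropathy exceeds ``threshold``;
    overlapping positive windows merge into maximal segments. Sequences
    shorter than the window yield no segments. Defaults (window 19,
    threshold 1.6) are the classic values for membrane-spanning helices.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 5, got {window}")
    seq = protein.sequence.upper()
    n = len(seq)
    if n < window:
        return []
    scores = [KYTE_DOOLITTLE[ch] for ch in seq]
    acc = sum(scores[:window])
    positive: list[tuple[int, int]] = []  # 0-based [start, end) windows
    for i in range(n - window + 1):
        if i > 0:
            acc += scores[i + window - 1] - scores[i - 1]
        if acc / window > threshold:
            positive.append((i, i + window))
    segments: list[TMSegment] = []
    for s, e in positive:
        if segments and s < _last_end(segments[-1]):
            prev = segments[-1]
            segments[-1] = TMSegment(protein.id, prev.start, e)  # extend overlap
        else:
            segments.append(TMSegment(protein.id, s + 1, e))
    return segments


def _last_end(seg: TMSegment) -> int:
    return seg.end  # seg.end is exclusive 0-based == inclusive 1-based


# ---------------------------------------------------------------------------
# architecture summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchitectureSummary:
    """Per-protein domain-architecture bookkeeping (CTLD / ITAM / TM counts).

    ``dectin1_like`` captures the "complete" Dectin-1 architecture: at least
    one CTLD carrying a WxH signature, a transmembrane segment, and one or
    two ITAMs (Dectin-1 itself signals through a single hemITAM; proteins
    with many YxxL/I occurrences are not considered Dectin-1-like).
    """

    protein_id: str
    n_ctld: int
    n_itam: int
    n_tm: int
    wxh_in_ctld: bool
    wxhxny_hits: tuple[MotifHit, ...]
    dectin1_like: bool


def is_dectin1_like(n_ctld: int, n_itam: int, n_tm: int, wxh_in_ctld: bool) -> bool:
    return n_ctld >= 1 and n_tm >= 1 and 1 <= n_itam <= 2 and wxh_in_ctld


def summarize_architecture(
    protein: ProteinRecord,
    domains: Sequence[DomainAnnotation],
    located_hits: Mapping[str, Sequence[MotifHit]],
    tm_segments: Sequence[TMSegment],
) -> ArchitectureSummary:
    """Combine domain, motif and TM evidence for one protein.

    ``located_hits`` maps motif name -> located hits (any protein; filtered
    here). Every YxxL/I occurrence counts as one ITAM.
    """
    pid = protein.id
    n_ctld = sum(1 for d in domains if d.protein_id == pid and d.label == CTLD_LABEL)
    itam_hits = [h for h in located_hits.get("ITAM", []) if h.protein_id == pid]
    wxh_hits = [h for h in located_hits.get("WxH", []) if h.protein_id == pid]
    wxhxny = tuple(
        h
        for name, hits in located_hits.items()
        if name.startswith("WxHx")
        for h in hits
        if h.protein_id == pid
    )
    n_tm = sum(1 for t in tm_segments if t.protein_id == pid)
    wxh_in = any(h.location_class == LocationClass.IN_DOMAIN for h in wxh_hits)
    return ArchitectureSummary(
        protein_id=pid,
        n_ctld=n_ctld,
        n_itam=len(itam_hits),
        n_tm=n_tm,
        wxh_in_ctld=wxh_in,
        wxhxny_hits=wxhxny,
        dectin1_like=is_dectin1_like(n_ctld, len(itam_hits), n_tm, wxh_in),
    )
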