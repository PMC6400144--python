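"""Hypergeometric over-representation analysis of term annotations.

A target gene list (for example the consensus DEGs of one stimulus) is
tested term-by-term against a background universe (for example every
annotated gene): with ``N`` background genes of which ``K`` carry the term,
and ``n`` target genes of which ``k`` carry it, the enrichment p-value is
the hypergeometric upper tail ``P[X >= k]``. Adjustment is selectable
between Benjamini-Hochberg and Benjamini-Yekutieli; a term is enriched when
its adjusted p-value is at or below ``alpha`` (default 0.05).

Genes without any term annotation still count in ``N``/``n`` — the
background is the full universe, not the annotated subset. Ontology-graph
propagation is out of scope; term maps are taken as explicit.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Set

import pandas as pd
from scipy import stats


def hypergeom_upper_tail(k: int, n_target: int, big_k: int, big_n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N=big_n, K=big_k, n=n_target)."""
    if not (0 <= k <= min(n_target, big_k)):
        raise ValueError(f"impossible overlap k={k} for n={n_target}, K={big_k}, N={big_n}")
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n_target))


def collapse_to_reference(
    genes: Iterable[str], ortholog_map: Mapping[str, Set[str]]
) -> set[str]:
    """Collapse duplicated (e.g. tetraploid paralogue) gene ids to unique
    reference ids via an inverted ref -> targets ortholog map; ids with no
    mapping are kept as-is."""
    inverse: dict[str, str] = {}
    for ref, targets in ortholog_map.items():
        for t in targets:
            inverse[t] = ref
    return {inverse.get(g, g) for g in genes}


def enrich_terms(
    target: Set[str],
    background: Set[str],
    term_map: Mapping[str, Set[str]],
    adjust: str = "bh",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of each term in ``target`` versus ``background``.

    Returns one row per term (term_id, k, n, K, N, p, q, enriched), sorted by
    (q, p, term_id). Raises when the target is not a subset of the background
    or when the term map is empty.
    """
    from .expression_de import bh_adjust, by_adjust

    offenders = sorted(target - background)
    if offenders:
        raise ValueError(f"target genes missing from background: {offenders}")
    if not term_map:
        raise ValueError("term map is empty")
    if adjust not in ("bh", "by"):
        raise ValueError(f"adjust must be 'bh' or 'by', got '{adjust}'")

    big_n = len(background)
    n_target = len(target)
    rows = []
    for term_id in sorted(term_map):
        annotated = term_map[term_id] & background
        big_k = len(annotated)
        k = len(annotated & target)
        p = hypergeom_upper_tail(k, n_target, big_k, big_n)
        rows.append((term_id, k, n_target, big_k, big_n, p))
    df = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p"])
    adjuster = bh_adjust if adjust == "bh" else by_adjust
    df["q"] = adjuster(df["p"].values)
    df["enriched"] = df["q"] <= alpha
    return df.sort_values(["q", "p", "term_id"], kind="stable").reset_index(drop=True)
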