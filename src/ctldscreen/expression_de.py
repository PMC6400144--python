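"""Expression level filtering and paired differential expression.

The screening pipeline needs two expression criteria:

* a constitutive-expression criterion — mean RPKM across unstimulated
  (control) macrophage samples at or above a threshold (default 50);
* a differential-regulation criterion — a gene is called regulated by a
  stimulus only when **two independent paired tests agree** (the dual-method
  consensus): method A is a moderated paired t-test with BH adjustment
  (adjusted p <= alpha), method B is an exact sign-flip permutation test with
  an edgeR-style double rule (raw p <= alpha AND BH-adjusted p <= alpha).

The two methods are deliberate, transparent stand-ins preserving what the
original two-package analysis contributes structurally — the paired
contrast, two independent tests, dual thresholds and their intersection —
without re-implementing negative-binomial GLM machinery.

Note on small designs: the exact sign-flip test has a two-sided p-value
floor of ``2 / 2**n_pairs`` (0.25 at n=3), and with many genes the BH
adjustment of those discrete p-values is floor-limited as well; see the
methods note for the practical consequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, SampleDesign

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NONE = "none"  # sentinel for all-zero genes


# ---------------------------------------------------------------------------
# RPKM and the expression criterion
# ---------------------------------------------------------------------------


def compute_rpkm(matrix: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``rpkm(g, s) = counts(g, s) * 1e9 / (libsize(s) * length(g))`` with
    ``libsize`` the column sum of the count matrix.
    """
    libsize = matrix.counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"sample '{zero.index[0]}' has zero library size")
    return (
        matrix.counts * 1e9
    ).div(libsize, axis=1).div(matrix.gene_lengths.astype(float), axis=0)


@dataclass(frozen=True)
class ExpressionFilterResult:
    passing: frozenset[str]
    mean_control_rpkm: pd.Series
    reference_fraction: pd.Series | None  # expression as fraction of e.g. actb


def expression_filter(
    rpkm: pd.DataFrame,
    control_samples: Sequence[str],
    threshold: float = 50.0,
    reference_gene: str | None = "actb",
) -> ExpressionFilterResult:
    """Genes whose mean control RPKM is >= threshold (inclusive).

    When the named reference gene (default ``actb``, the housekeeping
    beta-actin) is present, each gene's mean control expression is also
    reported as a fraction of the reference gene's.
    """
    if not list(control_samples):
        raise ValueError("no control samples given")
    means = rpkm[list(control_samples)].mean(axis=1)
    passing = frozenset(means.index[means >= threshold])
    fraction = None
    if reference_gene is not None and reference_gene in means.index:
        ref = means.loc[reference_gene]
        if ref > 0:
            fraction = means / ref
    return ExpressionFilterResult(
        passing=passing, mean_control_rpkm=means, reference_fraction=fraction
    )


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped to 1.

    Ties are handled by a stable sort plus the standard cumulative minimum,
    so tied p-values receive identical q-values.
    """
    p = _check_p(p)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def by_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli adjustment: BH scaled by the harmonic sum c(m)."""
    p = _check_p(p)
    m = p.size
    if m == 0:
        return p
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# paired differential expression
# ---------------------------------------------------------------------------


def paired_log2_differences(
    matrix: CountMatrix,
    design: SampleDesign,
    stimulus: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-pair log2 fold changes on library-size-normalized counts.

    For pair *i*: ``d_i = log2((stim_i + pc) / sf_stim) - log2((ctrl_i + pc)
    / sf_ctrl)`` where the size factor of a sample is its library size
    divided by the mean library size. Columns are pair ids.
    """
    pairs = design.pairs_for(stimulus)
    if len(pairs) < 2:
        raise ValueError(
            f"stimulus '{stimulus}' has {len(pairs)} complete pair(s); need >= 2"
        )
    libsize = matrix.counts.sum(axis=0).astype(float)
    sf = libsize / libsize.mean()
    cols = {}
    for pair_id, ctrl, stim in pairs:
        norm_stim = (matrix.counts[stim] + pseudocount) / sf[stim]
        norm_ctrl = (matrix.counts[ctrl] + pseudocount) / sf[ctrl]
        cols[pair_id] = np.log2(norm_stim) - np.log2(norm_ctrl)
    return pd.DataFrame(cols, index=matrix.counts.index)


def moderated_paired_t(d: np.ndarray, prior_df: float = 4.0) -> np.ndarray:
    """One-sample moderated t on per-pair differences (genes x pairs).

    Gene variances are shrunk toward the median gene variance with
    ``prior_df`` pseudo-degrees of freedom; p-values are two-sided with
    ``n - 1 + prior_df`` degrees of freedom.
    """
    from scipy import stats

    d = np.asarray(d, dtype=float)
    n = d.shape[1]
    mean = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    s2_prior = float(np.median(s2))
    s2_shrunk = (prior_df * s2_prior + (n - 1) * s2) / (prior_df + n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2_shrunk / n)
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1 + prior_df)
    return np.minimum(p, 1.0)


def sign_flip_p(d: np.ndarray, max_exact_pairs: int = 12, rng=None, n_mc: int = 10000) -> np.ndarray:
    """Exact two-sided sign-flip permutation p-values for each gene.

    The statistic is the mean of the per-pair differences. With ``n <=
    max_exact_pairs`` all ``2**n`` sign assignments are enumerated; p is the
    fraction of assignments whose \\|mean\\| is at least the observed \\|mean\\|
    (the identity assignment is always counted, so p is never 0). For larger
    designs a seeded Monte-Carlo sample of sign vectors is used.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[1]
    obs = np.abs(d.mean(axis=1))
    if n <= max_exact_pairs:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))  # (2^n, n)
    else:
        rng = np.random.default_rng(rng)
        signs = rng.choice((1.0, -1.0), size=(n_mc, n))
        signs[0] = 1.0  # keep the identity so p > 0
    perm_means = np.abs(d @ signs.T) / n  # genes x flips
    tol = 1e-12
    ge = perm_means >= (obs[:, None] - tol)
    return ge.sum(axis=1) / signs.shape[0]


def paired_de(
    matrix: CountMatrix,
    design: SampleDesign,
    stimulus: str,
    alpha_a: float = 0.05,
    alpha_b: float = 0.05,
    pseudocount: float = 0.5,
    prior_df: float = 4.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Dual-method paired differential expression for one stimulus.

    Returns one row per gene: ``mean_paired_log2fc``, method-A and method-B
    raw and BH-adjusted p-values, direction, per-method significance and the
    consensus call (significant under both methods). All-zero genes get
    p = 1 for both methods and direction 'none'.
    """
    d_frame = paired_log2_differences(matrix, design, stimulus, pseudocount)
    d = d_frame.values
    genes = d_frame.index

    pairs = design.pairs_for(stimulus)
    used_samples = [s for pr in pairs for s in (pr[1], pr[2])]
    all_zero = (matrix.counts[used_samples].sum(axis=1) == 0).values

    mean_lfc = d.mean(axis=1)
    p_a = moderated_paired_t(d, prior_df=prior_df)
    p_b = sign_flip_p(d, rng=seed)
    p_a[all_zero] = 1.0
    p_b[all_zero] = 1.0
    mean_lfc[all_zero] = 0.0
    q_a = bh_adjust(p_a)
    q_b = bh_adjust(p_b)

    direction = np.where(mean_lfc > 0, DIRECTION_UP, DIRECTION_DOWN)
    direction = np.where(all_zero, DIRECTION_NONE, direction)

    sig_a = (q_a <= alpha_a) & ~all_zero
    # edgeR-style double rule: raw p and FDR both at or below alpha_b
    sig_b = (p_b <= alpha_b) & (q_b <= alpha_b) & ~all_zero

    return pd.DataFrame(
        {
            "gene_id": genes,
            "stimulus": stimulus,
            "mean_paired_log2fc": mean_lfc,
            "p_method_a": p_a,
            "q_method_a": q_a,
            "p_method_b": p_b,
            "q_method_b": q_b,
            "direction": direction,
            "significant_a": sig_a,
            "significant_b": sig_b,
            "consensus": sig_a & sig_b,
        }
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# cross-stimulus concordance (Venn classification)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceReport:
    """Venn comparison of the consensus DEG sets of two stimuli."""

    n_a_only: int
    n_b_only: int
    n_shared: int
    n_concordant: int
    n_discordant: int
    labels: Mapping[str, str]  # gene -> {a_only, b_only, concordant, discordant}

    @property
    def venn_counts(self) -> dict[str, int]:
        return {"a_only": self.n_a_only, "b_only": self.n_b_only, "shared": self.n_shared}


def concordance(results_a: pd.DataFrame, results_b: pd.DataFrame) -> ConcordanceReport:
    """Classify consensus DEGs of two stimuli as shared-concordant,
    shared-discordant, or private to either stimulus."""
    deg_a = {g: results_a.loc[g, "direction"] for g in results_a.index[results_a["consensus"]]}
    deg_b = {g: results_b.loc[g, "direction"] for g in results_b.index[results_b["consensus"]]}
    labels: dict[str, str] = {}
    conc = disc = 0
    for g in sorted(set(deg_a) | set(deg_b)):
        if g in deg_a and g in deg_b:
            if deg_a[g] == deg_b[g]:
                labels[g] = "concordant"
                conc += 1
            else:
                labels[g] = "discordant"
                disc += 1
        elif g in deg_a:
            labels[g] = "a_only"
        else:
            labels[g] = "b_only"
    n_shared = conc + disc
    return ConcordanceReport(
        n_a_only=len(deg_a) - n_shared,
        n_b_only=len(deg_b) - n_shared,
        n_shared=n_shared,
        n_concordant=conc,
        n_discordant=disc,
        labels=labels,
    )
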