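"""Conditional false discovery rate (cFDR) estimation from paired GWAS p-values.

Given, for each SNP, a p-value for a primary trait and one for a genetically
correlated secondary trait, the conditional FDR is the posterior probability
that the SNP is null for the primary trait given that both p-values are at
least as extreme as observed::

    cFDR(i|j) = Pr(H0(i) | p_i <= P_i, p_j <= P_j)
              = p_i / Pr(p_i <= P_i | p_j <= P_j)

The denominator is estimated empirically over all SNPs in the (LD-pruned)
table: the fraction of SNPs whose secondary p-value is at most the observed
P_j that also have primary p-value at most the observed P_i.  The
conjunctional cFDR (ccFDR), declaring association with *both* traits, is the
larger of the two directional cFDRs.

Conventions: the index SNP is included in both counts (so every estimate lies
in (0, 1] and no division by zero can occur), comparisons are non-strict on
the stored values with no jittering, and cFDR ratios are capped at 1.  No
kernel smoothing, monotone regression, or sample-overlap correction is
applied: the estimator is the raw empirical conditional proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "conditional_exceedance",
    "conditional_exceedance_reference",
    "cfdr",
    "ccfdr",
    "cfdr_table",
    "classify",
    "ClassificationCounts",
    "SIG_CLASSES",
]

SIG_CLASSES = ("none", "primary_only", "secondary_only", "pleiotropic")


def _validate_pair(p_i: np.ndarray, p_j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    if p_i.ndim != 1 or p_j.ndim != 1:
        raise ValueError("p-value inputs must be one-dimensional vectors")
    if p_i.size == 0:
        raise ValueError("empty p-value vectors")
    if p_i.shape != p_j.shape:
        raise ValueError(f"length mismatch: {p_i.size} vs {p_j.size}")
    for name, v in (("p_i", p_i), ("p_j", p_j)):
        if not np.all((v > 0) & (v <= 1)):
            raise ValueError(f"{name} contains values outside (0, 1]; clamp upstream")
    return p_i, p_j


def conditional_exceedance_reference(p_i, p_j) -> np.ndarray:
    """O(n^2) reference estimator of Pr(p_i <= P_i | p_j <= P_j) per SNP.

    Direct dominance counting from the definition; serves as the independent
    cross-check for :func:`conditional_exceedance`.
    """
    p_i, p_j = _validate_pair(p_i, p_j)
    # at n=2000 the n^2 boolean matrices are ~4e6 entries: fine in memory
    le_i = p_i[None, :] <= p_i[:, None]  # [k, l]: p_i[l] <= p_i[k]
    le_j = p_j[None, :] <= p_j[:, None]
    num = (le_i & le_j).sum(axis=1)
    den = le_j.sum(axis=1)
    return num / den


class _Bit:
    """Fenwick tree over counts, 1-based."""

    def __init__(self, n: int):
        self.n = n
        self.t = [0] * (n + 1)

    def add(self, i: int) -> None:
        while i <= self.n:
            self.t[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:
        s = 0
        while i > 0:
            s += self.t[i]
            i -= i & (-i)
        return s


def conditional_exceedance(p_i, p_j) -> np.ndarray:
    """Estimate Pr(p_i <= P_i | p_j <= P_j) for every SNP.

    For SNP k the estimate is
    ``#{l : p_i[l] <= p_i[k] and p_j[l] <= p_j[k]} / #{l : p_j[l] <= p_j[k]}``
    counting over all n SNPs including k itself, so every value lies in
    (0, 1].  O(n log n): SNPs are swept in order of the secondary p-value and
    dominance counts accumulated in a Fenwick tree over the rank-compressed
    primary p-values; ties on either axis are handled inclusively (non-strict
    comparisons), matching the reference implementation exactly.
    """
    p_i, p_j = _validate_pair(p_i, p_j)
    n = p_i.size

    # rank-compress p_i with ties sharing a rank; queries use the max rank
    order_i = np.sort(p_i)
    rank_i = np.searchsorted(order_i, p_i, side="right")  # in 1..n

    # denominator: number of p_j values <= p_j[k] (max rank under ties)
    order_j = np.sort(p_j)
    den = np.searchsorted(order_j, p_j, side="right")

    num = np.empty(n, dtype=np.int64)
    bit = _Bit(n)
    sweep = np.argsort(p_j, kind="stable")
    start = 0
    while start < n:
        # group of tied p_j values: insert the whole group before querying it,
        # since tied SNPs fall inside each other's conditioning sets
        stop = start
        while stop < n and p_j[sweep[stop]] == p_j[sweep[start]]:
            stop += 1
        for idx in sweep[start:stop]:
            bit.add(int(rank_i[idx]))
        for idx in sweep[start:stop]:
            num[idx] = bit.prefix(int(rank_i[idx]))
        start = stop

    return num / den


def cfdr(p_i, p_j, *, reference: bool = False) -> np.ndarray:
    """Per-SNP conditional FDR for the primary trait given the secondary.

    ``cfdr[k] = min(1, p_i[k] / Pr_hat(p_i <= P_i | p_j <= P_j))``; always
    at least ``p_i[k]`` since the denominator is a probability.

    Parameters
    ----------
    reference
        Use the O(n^2) reference estimator for the denominator instead of the
        fast sweep (identical output; for cross-checking).
    """
    est = conditional_exceedance_reference if reference else conditional_exceedance
    denom = est(p_i, p_j)
    return np.minimum(1.0, np.asarray(p_i, dtype=float) / denom)


def ccfdr(cfdr_12, cfdr_21) -> np.ndarray:
    """Conjunctional cFDR: elementwise maximum of the two directional cFDRs."""
    a = np.asarray(cfdr_12, dtype=float)
    b = np.asarray(cfdr_21, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return np.maximum(a, b)


@dataclass(frozen=True)
class ClassificationCounts:
    n_primary: int
    n_secondary: int
    n_total: int
    n_pleiotropic: int


def classify(table: pd.DataFrame, alpha: float = 0.01) -> tuple[pd.Series, ClassificationCounts]:
    """Assign a significance class per SNP at threshold ``alpha``.

    ``pleiotropic`` iff ccfdr <= alpha; ``primary_only`` iff the
    primary-given-secondary cFDR <= alpha and not pleiotropic; analogously
    ``secondary_only``; else ``none``.  The counts ``n_primary`` and
    ``n_secondary`` tally every SNP significant for that trait (pleiotropic
    SNPs count for both); ``n_total`` counts SNPs significant for at least
    one trait.
    """
    c12 = table["cfdr_primary_given_secondary"].to_numpy(dtype=float)
    c21 = table["cfdr_secondary_given_primary"].to_numpy(dtype=float)
    cc = table["ccfdr"].to_numpy(dtype=float)

    sig_p = c12 <= alpha
    sig_s = c21 <= alpha
    pleio = cc <= alpha

    labels = np.full(len(table), "none", dtype=object)
    labels[sig_p & ~pleio] = "primary_only"
    labels[sig_s & ~pleio] = "secondary_only"
    labels[pleio] = "pleiotropic"
    counts = ClassificationCounts(
        n_primary=int(sig_p.sum()),
        n_secondary=int(sig_s.sum()),
        n_total=int((sig_p | sig_s).sum()),
        n_pleiotropic=int(pleio.sum()),
    )
    return pd.Series(labels, index=table.index, name="sig_class"), counts


def cfdr_table(harmonised: pd.DataFrame, alpha: float = 0.01, *, reference: bool = False) -> pd.DataFrame:
    """Full cFDR table from a harmonised per-SNP p-value table.

    Expects columns ``rsid, p_primary, p_secondary``; returns those plus
    ``cfdr_primary_given_secondary``, ``cfdr_secondary_given_primary``,
    ``ccfdr`` and ``sig_class``.
    """
    p1 = harmonised["p_primary"].to_numpy(dtype=float)
    p2 = harmonised["p_secondary"].to_numpy(dtype=float)
    out = harmonised[["rsid", "p_primary", "p_secondary"]].copy()
    out["cfdr_primary_given_secondary"] = cfdr(p1, p2, reference=reference)
    out["cfdr_secondary_given_primary"] = cfdr(p2, p1, reference=reference)
    out["ccfdr"] = ccfdr(
        out["cfdr_primary_given_secondary"], out["cfdr_secondary_given_primary"]
    )
    out["sig_class"], _ = classify(out, alpha=alpha)
    return out
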