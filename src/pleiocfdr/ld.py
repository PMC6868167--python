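"""Windowed greedy LD pruning of a genotype dosage panel.

Mirrors the classic indep-pairwise procedure: within each window of 50
consecutive retained SNPs on a chromosome, while any pair has squared
dosage correlation r² above the threshold (0.2), one member of the pair is
removed; the window then slides along 5 SNPs and the pruning repeats.
Windows are counted in SNPs over currently retained variants, per
chromosome.  Which member of an offending pair is removed is made fully
deterministic: the SNP with higher missingness goes first, then the one with
lower minor-allele frequency, then the later (chrom, pos).

Dosages are additive allele counts in {0, 1, 2} with NaN for missing; r² is
the squared Pearson correlation over pairwise-complete samples.  A pair
involving a monomorphic (zero-variance) SNP has undefined r² and is treated
as not prunable (r² = 0); ``drop_monomorphic`` removes MAF = 0 SNPs up
front instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "pairwise_r2", "indep_pairwise", "subset_to_pruned", "PruneResult"]


@dataclass
class GenotypeMatrix:
    """Sample x SNP dosage matrix with ordered SNP metadata.

    ``dosages`` is float with entries in {0, 1, 2, NaN}; ``snps`` has columns
    ``rsid, chrom, pos`` and must be sorted by (chrom, pos) with unique rsids.
    """

    dosages: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D sample x SNP matrix")
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but {len(self.snps)} SNP records"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage entries must be 0, 1, 2 or NaN")
        if self.snps["rsid"].duplicated().any():
            raise ValueError("duplicate rsid in SNP metadata")
        self.snps = self.snps.reset_index(drop=True)
        chroms = self.snps["chrom"].astype(str).to_numpy()
        pos = self.snps["pos"].to_numpy()
        seen: set[str] = set()
        prev = None
        for c, p in zip(chroms, pos):
            if c != prev:
                if c in seen:
                    raise ValueError("SNP metadata must group chromosomes contiguously")
                seen.add(c)
                prev = c
            elif p < last_pos:
                raise ValueError("SNP positions must be non-decreasing within a chromosome")
            last_pos = p

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            f = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)


def pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete (both non-missing) samples.  Returns 0.0
    when fewer than two complete pairs remain or either vector has zero
    variance — such pairs cannot drive pruning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    x, y = a[ok], b[ok]
    if x.size < 2:
        return 0.0
    xc = x - x.mean()
    yc = y - y.mean()
    sx = xc @ xc
    sy = yc @ yc
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r2 = (xc @ yc) ** 2 / (sx * sy)
    return float(min(r2, 1.0))


@dataclass
class PruneResult:
    retained: list[str]
    pruned: list[str]
    report: dict = field(default_factory=dict)


def indep_pairwise(
    G: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2max: float = 0.2,
    *,
    drop_monomorphic: bool = False,
) -> PruneResult:
    """Greedy windowed LD pruning; returns retained and pruned rsid lists.

    Per chromosome: take the window of ``window`` consecutive currently
    retained SNPs starting at offset 0; while any pair inside has
    r² > ``r2max`` remove one member (tie-break: higher missingness, then
    lower MAF, then later position); slide the window ``step`` retained SNPs
    along and repeat until the window start passes the last SNP.  After the
    scan no two retained SNPs that ever shared a window have r² > ``r2max``.
    """
    if step < 1 or window <= step:
        raise ValueError(f"need window > step >= 1, got window={window} step={step}")
    if not 0.0 < r2max < 1.0:
        raise ValueError(f"r2max must be in (0, 1), got {r2max}")

    maf = G.maf()
    miss = G.missingness()
    retained_mask = np.ones(G.n_snps, dtype=bool)
    n_monomorphic = int((maf == 0).sum())
    if drop_monomorphic:
        retained_mask[maf == 0] = False

    cache: dict[tuple[int, int], float] = {}

    def r2(i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        if key not in cache:
            cache[key] = pairwise_r2(G.dosages[:, key[0]], G.dosages[:, key[1]])
        return cache[key]

    def remove_choice(i: int, j: int) -> int:
        # higher missingness, then lower MAF, then later (chrom, pos) order
        if miss[i] != miss[j]:
            return i if miss[i] > miss[j] else j
        if maf[i] != maf[j]:
            return i if maf[i] < maf[j] else j
        return max(i, j)  # metadata is position-sorted

    chroms = G.snps["chrom"].astype(str).to_numpy()
    for chrom in pd.unique(chroms):
        chrom_idx = np.flatnonzero((chroms == chrom) & retained_mask)
        alive = list(chrom_idx)
        start = 0
        while start < len(alive):
            # prune the current window to a fixpoint, rescanning after removal
            changed = True
            while changed:
                changed = False
                win = alive[start : start + window]
                for a in range(len(win)):
                    for b in range(a + 1, len(win)):
                        if r2(win[a], win[b]) > r2max:
                            victim = remove_choice(win[a], win[b])
                            retained_mask[victim] = False
                            alive.remove(victim)
                            changed = True
                            break
                    if changed:
                        break
            start += step

    rsids = G.snps["rsid"].to_numpy()
    retained = [str(r) for r in rsids[retained_mask]]
    pruned = [str(r) for r in rsids[~retained_mask]]
    return PruneResult(
        retained=retained,
        pruned=pruned,
        report={
            "n_snps": G.n_snps,
            "n_retained": len(retained),
            "n_pruned": len(pruned),
            "n_monomorphic": n_monomorphic,
            "window": window,
            "step": step,
            "r2max": r2max,
        },
    )


def subset_to_pruned(table: pd.DataFrame, retained: list[str]) -> tuple[pd.DataFrame, dict]:
    """Restrict a harmonised table to the retained rsids, order preserved.

    Retained rsids absent from the table are ignored and counted in the
    returned report.
    """
    keep = set(retained)
    out = table[table["rsid"].isin(keep)].reset_index(drop=True)
    report = {
        "n_retained_input": len(retained),
        "n_rows_kept": len(out),
        "n_retained_absent": len(keep - set(table["rsid"])),
    }
    return out, report
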