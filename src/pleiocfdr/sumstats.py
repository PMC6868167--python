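"""Reading, validation and cross-trait harmonisation of GWAS summary statistics.

Input files are header-bearing, tab- or whitespace-delimited tables with one
row per SNP.  A :class:`Dialect` maps the file's column names onto the fields
the pipeline needs (rsID, chromosome, position, effect/other allele, effect
size, p-value) and records whether the effect column is a signed beta or an
odds ratio — the distinction matters when an allele flip requires the effect
to be negated (beta) or inverted (OR).

Validation policy: p-values <= 0 are clamped to the smallest positive double
(extreme hits are kept, not dropped) and p > 1, bad positions or degenerate
allele pairs invalidate the row; dropped rows are counted in the returned
report.  Harmonisation joins the two tables on shared variants, reconciles
alleles (accepting an effect/other swap with the corresponding effect flip)
and drops genuinely mismatched allele pairs.  Strand-ambiguous (A/T, C/G)
SNPs are retained and matched literally by default; ``drop_ambiguous=True``
excludes them.  Duplicate rsIDs keep the first occurrence, deterministically
in input order.  Positions are 1-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Dialect",
    "ReadReport",
    "HarmoniseReport",
    "read_sumstats",
    "harmonise",
    "write_harmonised",
    "HARMONISED_COLUMNS",
]

_TINY = np.nextafter(0.0, 1.0)
_VALID_CHROMS = {str(c) for c in range(1, 23)} | {"X"}
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

HARMONISED_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "effect_primary",
    "p_primary",
    "effect_secondary",
    "p_secondary",
    "flipped",
]


@dataclass(frozen=True)
class Dialect:
    """Column mapping for one summary-statistic file."""

    rsid: str = "rsid"
    chrom: str = "chrom"
    pos: str = "pos"
    effect_allele: str = "effect_allele"
    other_allele: str = "other_allele"
    effect: str = "effect"
    pvalue: str = "pvalue"
    effect_is_or: bool = False  # odds ratio (flip by inversion) vs beta (negation)

    @classmethod
    def from_dict(cls, d: dict) -> "Dialect":
        return cls(**d)

    def required_columns(self) -> list[str]:
        return [
            self.rsid,
            self.chrom,
            self.pos,
            self.effect_allele,
            self.other_allele,
            self.effect,
            self.pvalue,
        ]


@dataclass
class ReadReport:
    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    n_clamped_p: int = 0
    dropped_reasons: dict = field(default_factory=dict)

    def _drop(self, reason: str, n: int) -> None:
        if n:
            self.n_dropped += n
            self.dropped_reasons[reason] = self.dropped_reasons.get(reason, 0) + n


def read_sumstats(path, dialect: Dialect | dict | None = None) -> tuple[pd.DataFrame, ReadReport]:
    """Read and validate one summary-statistic file.

    Returns a DataFrame with the standard columns
    ``rsid, chrom, pos, effect_allele, other_allele, effect, pvalue`` (rows
    failing validation dropped) and a :class:`ReadReport` accounting for every
    input row.  A missing mandatory column is a hard error naming the column.
    """
    if dialect is None:
        dialect = Dialect()
    elif isinstance(dialect, dict):
        dialect = Dialect.from_dict(dialect)

    raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    for col in dialect.required_columns():
        if col not in raw.columns:
            raise ValueError(f"summary-statistic file {path} is missing mandatory column {col!r}")

    df = pd.DataFrame(
        {
            "rsid": raw[dialect.rsid].astype(str),
            "chrom": raw[dialect.chrom].astype(str).str.removeprefix("chr"),
            "pos": pd.to_numeric(raw[dialect.pos], errors="coerce"),
            "effect_allele": raw[dialect.effect_allele].astype(str).str.upper(),
            "other_allele": raw[dialect.other_allele].astype(str).str.upper(),
            "effect": pd.to_numeric(raw[dialect.effect], errors="coerce"),
            "pvalue": pd.to_numeric(raw[dialect.pvalue], errors="coerce"),
        }
    )
    report = ReadReport(n_read=len(df))

    bad_p = df["pvalue"].isna() | (df["pvalue"] > 1)
    report._drop("unparseable_or_invalid_pvalue", int(bad_p.sum()))
    df = df[~bad_p]

    clamp = df["pvalue"] <= 0
    report.n_clamped_p = int(clamp.sum())
    df.loc[clamp, "pvalue"] = _TINY

    bad_pos = df["pos"].isna() | (df["pos"] < 1) | (df["pos"] % 1 != 0)
    report._drop("invalid_position", int(bad_pos.sum()))
    df = df[~bad_pos]

    bad_chrom = ~df["chrom"].isin(_VALID_CHROMS)
    report._drop("invalid_chromosome", int(bad_chrom.sum()))
    df = df[~bad_chrom]

    bad_alleles = (
        (df["effect_allele"] == df["other_allele"])
        | (df["effect_allele"] == "")
        | (df["other_allele"] == "")
        | (df["effect_allele"] == "NAN")
        | (df["other_allele"] == "NAN")
    )
    report._drop("invalid_alleles", int(bad_alleles.sum()))
    df = df[~bad_alleles]

    bad_effect = df["effect"].isna()
    report._drop("unparseable_effect", int(bad_effect.sum()))
    df = df[~bad_effect]

    df = df.astype({"pos": np.int64}).reset_index(drop=True)
    report.n_kept = len(df)
    return df, report


@dataclass
class HarmoniseReport:
    n_primary: int = 0
    n_secondary: int = 0
    n_intersection: int = 0
    n_matched: int = 0
    n_flipped: int = 0
    n_allele_mismatch_dropped: int = 0
    n_ambiguous_dropped: int = 0
    n_duplicates_primary: int = 0
    n_duplicates_secondary: int = 0


def _is_ambiguous(ea: pd.Series, oa: pd.Series) -> pd.Series:
    pair = [frozenset((a, b)) for a, b in zip(ea, oa)]
    return pd.Series([p in _AMBIGUOUS_PAIRS for p in pair], index=ea.index)


def harmonise(
    primary: pd.DataFrame,
    secondary: pd.DataFrame,
    join_key: str = "rsid",
    *,
    secondary_effect_is_or: bool = False,
    drop_ambiguous: bool = False,
) -> tuple[pd.DataFrame, HarmoniseReport]:
    """Merge two validated summary-statistic tables into one per-SNP table.

    The output holds exactly the variants shared under ``join_key`` (either
    ``"rsid"`` or ``"rsid+pos"``) whose allele pairs reconcile.  Coordinates
    and the effect/other allele orientation come from the primary table; a
    secondary record stated for the swapped orientation is aligned by
    negating its beta (or inverting its OR) and flagged ``flipped``.
    """
    if join_key not in ("rsid", "rsid+pos"):
        raise ValueError(f"unsupported join key {join_key!r}")
    keys = ["rsid"] if join_key == "rsid" else ["rsid", "pos"]

    report = HarmoniseReport(n_primary=len(primary), n_secondary=len(secondary))
    p = primary.drop_duplicates(subset=keys, keep="first")
    s = secondary.drop_duplicates(subset=keys, keep="first")
    report.n_duplicates_primary = len(primary) - len(p)
    report.n_duplicates_secondary = len(secondary) - len(s)

    m = p.merge(s, on=keys, how="inner", suffixes=("_p", "_s"))
    report.n_intersection = len(m)
    if len(m) == 0:
        empty = pd.DataFrame(columns=HARMONISED_COLUMNS)
        return empty, report

    same = (m["effect_allele_p"] == m["effect_allele_s"]) & (
        m["other_allele_p"] == m["other_allele_s"]
    )
    swapped = (m["effect_allele_p"] == m["other_allele_s"]) & (
        m["other_allele_p"] == m["effect_allele_s"]
    )
    keep = same | swapped
    if drop_ambiguous:
        amb = _is_ambiguous(m["effect_allele_p"], m["other_allele_p"])
        report.n_ambiguous_dropped = int((keep & amb).sum())
        keep &= ~amb
    report.n_allele_mismatch_dropped = int((~(same | swapped)).sum())

    m = m[keep].copy()
    swapped = swapped[keep]
    effect_s = m["effect_s"].to_numpy(dtype=float)
    if secondary_effect_is_or:
        aligned = np.where(swapped, 1.0 / effect_s, effect_s)
    else:
        aligned = np.where(swapped, -effect_s, effect_s)

    chrom_col = "chrom_p" if "chrom_p" in m.columns else "chrom"
    pos_col = "pos" if "pos" in m.columns else "pos_p"
    out = pd.DataFrame(
        {
            "rsid": m["rsid"],
            "chrom": m[chrom_col],
            "pos": m[pos_col] if pos_col in m.columns else m["pos_p"],
            "effect_allele": m["effect_allele_p"],
            "other_allele": m["other_allele_p"],
            "effect_primary": m["effect_p"].to_numpy(dtype=float),
            "p_primary": m["pvalue_p"].to_numpy(dtype=float),
            "effect_secondary": aligned,
            "p_secondary": m["pvalue_s"].to_numpy(dtype=float),
            "flipped": swapped.to_numpy(dtype=bool),
        }
    ).reset_index(drop=True)
    report.n_matched = len(out)
    report.n_flipped = int(out["flipped"].sum())
    return out, report


def write_harmonised(table: pd.DataFrame, path) -> None:
    """Write a harmonised table as TSV with the fixed standard header."""
    table[HARMONISED_COLUMNS].to_csv(path, sep="\t", index=False)
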