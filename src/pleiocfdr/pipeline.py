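"""End-to-end orchestration: read → harmonise → prune → cFDR → classify → annotate.

A :class:`RunConfig` holds the file paths and the analysis parameters; its
defaults are the study parameters (prune at r² > 0.2 in a 50-SNP window
sliding by 5; significance at cFDR and ccFDR ≤ 0.01; ±0.5 Mbp gene window).
Every run writes the resolved configuration next to its outputs so the run
can be reproduced exactly, and a machine-readable JSON report with per-stage
counts.  Pruning and annotation are optional stages: if no genotype panel or
gene table is given they are skipped with a loud warning in the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as annot
from . import ld, sumstats
from .cfdr import cfdr_table, classify

logger = logging.getLogger("pleiocfdr")

__all__ = ["RunConfig", "run_pipeline", "load_genotype_panel", "top_hits"]


@dataclass
class RunConfig:
    sumstats_primary: str = ""
    sumstats_secondary: str = ""
    dialect_primary: dict = field(default_factory=dict)
    dialect_secondary: dict = field(default_factory=dict)
    secondary_effect_is_or: bool = False
    join_key: str = "rsid"
    drop_ambiguous: bool = False
    genotypes: str | None = None  # dosage TSV; pruning skipped if None
    genotype_snps: str | None = None  # SNP metadata TSV (rsid, chrom, pos)
    prune_window: int = 50
    prune_step: int = 5
    prune_r2max: float = 0.2
    alpha: float = 0.01
    genes: str | None = None  # gene table TSV; annotation skipped if None
    gene_window: int = 500_000
    out_dir: str = "pleiocfdr_out"
    seed: int = 0
    top_n: int = 50

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def load_genotype_panel(dosage_path, snp_meta_path) -> ld.GenotypeMatrix:
    """Load a dosage TSV (rows = samples, header = rsids) plus SNP metadata.

    Also accepts PLINK .raw additive exports: the FID/IID/PAT/MAT/SEX/
    PHENOTYPE leader columns are dropped and ``rsid_A``-style headers
    stripped of the allele suffix.
    """
    df = pd.read_csv(dosage_path, sep=r"\s+")
    leader = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    df = df.drop(columns=leader)
    df.columns = [c.rsplit("_", 1)[0] if c.startswith("rs") and "_" in c else c for c in df.columns]
    meta = pd.read_csv(snp_meta_path, sep="\t", dtype={"chrom": str})
    missing = [r for r in meta["rsid"] if r not in df.columns]
    if missing:
        raise ValueError(f"{len(missing)} metadata SNPs absent from the dosage table, e.g. {missing[:3]}")
    dosages = df[meta["rsid"].tolist()].to_numpy(dtype=float)
    return ld.GenotypeMatrix(dosages=dosages, snps=meta[["rsid", "chrom", "pos"]])


def top_hits(cfdr_table: pd.DataFrame, n: int = 50, by: str = "cfdr_primary_given_secondary") -> pd.DataFrame:
    """Top-n lookup table ordered by a cFDR column ascending, stable on ties."""
    return cfdr_table.sort_values(by, kind="stable").head(n).reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and return the machine-readable report.

    Outputs written under ``config.out_dir``: resolved_config.yaml,
    harmonised.tsv, retained.txt/pruned.txt (if pruning ran), cfdr.tsv,
    top_hits.tsv, annotation.tsv (if a gene table was given), report.json
    and report.txt.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    report: dict = {"stages": {}, "parameters": dataclasses.asdict(config)}

    prim, rep1 = sumstats.read_sumstats(config.sumstats_primary, config.dialect_primary or None)
    sec, rep2 = sumstats.read_sumstats(config.sumstats_secondary, config.dialect_secondary or None)
    report["stages"]["read"] = {
        "primary": dataclasses.asdict(rep1),
        "secondary": dataclasses.asdict(rep2),
    }

    harm, hrep = sumstats.harmonise(
        prim,
        sec,
        join_key=config.join_key,
        secondary_effect_is_or=config.secondary_effect_is_or,
        drop_ambiguous=config.drop_ambiguous,
    )
    sumstats.write_harmonised(harm, out / "harmonised.tsv")
    report["stages"]["harmonise"] = dataclasses.asdict(hrep)
    logger.info("harmonised %d SNPs (%d flipped)", hrep.n_matched, hrep.n_flipped)

    if config.genotypes:
        G = load_genotype_panel(config.genotypes, config.genotype_snps)
        panel_rsids = set(G.snps["rsid"])
        n_absent = int((~harm["rsid"].isin(panel_rsids)).sum())
        prune = ld.indep_pairwise(
            G, window=config.prune_window, step=config.prune_step, r2max=config.prune_r2max
        )
        (out / "retained.txt").write_text("\n".join(prune.retained) + "\n")
        (out / "pruned.txt").write_text("\n".join(prune.pruned) + ("\n" if prune.pruned else ""))
        harm, srep = ld.subset_to_pruned(harm, prune.retained)
        report["stages"]["prune"] = {
            **prune.report,
            **srep,
            "n_harmonised_absent_from_panel": n_absent,
        }
        logger.info("pruning kept %d of %d panel SNPs", prune.report["n_retained"], G.n_snps)
    else:
        logger.warning("no genotype panel configured: LD pruning SKIPPED")
        report["stages"]["prune"] = {"skipped": True}

    table = cfdr_table(harm, alpha=config.alpha)
    _, counts = classify(table, alpha=config.alpha)
    table.to_csv(out / "cfdr.tsv", sep="\t", index=False)
    top_hits(table, n=config.top_n).to_csv(out / "top_hits.tsv", sep="\t", index=False)
    report["stages"]["cfdr"] = {
        "n_snps": len(table),
        "alpha": config.alpha,
        **dataclasses.asdict(counts),
    }
    logger.info(
        "cFDR at alpha=%g: %d primary, %d secondary, %d total, %d pleiotropic",
        config.alpha, counts.n_primary, counts.n_secondary, counts.n_total, counts.n_pleiotropic,
    )

    if config.genes:
        genes = annot.read_gene_table(config.genes)
        sig = table[table["sig_class"] != "none"].merge(
            harm[["rsid", "chrom", "pos"]], on="rsid"
        )
        ann = annot.annotate_table(sig, genes, window=config.gene_window)
        ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
        report["stages"]["annotate"] = {"n_snps": int(sig["rsid"].nunique()), "n_rows": len(ann)}
    else:
        report["stages"]["annotate"] = {"skipped": True}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    (out / "report.txt").write_text(_human_report(report))
    return report


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _human_report(report: dict) -> str:
    lines = ["pleiocfdr run report", "===================="]
    for stage, info in report["stages"].items():
        lines.append(f"\n[{stage}]")
        for k, v in info.items():
            lines.append(f"  {k}: {v}")
    return "\n".join(lines) + "\n"
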