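"""End-to-end orchestration: filtered SNPs -> per-gene statistics -> scans.

Every stage output is a pure function of (inputs, config, seed); the
manifest records a hash of the configuration and of each written file so
reruns can be checked for bit-identity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classtests import run_class_scan, scan_to_frame
from .formats import read_fasta, write_vcf
from .genes import classify_region, coding_effect, read_gff, region_rate_table
from .molevol import CalibrationError, calibrate_tails, synonymous_site_count
from .workflows import contig_faywu, gene_dnds
from .popgen import (
    empirical_hw_density,
    hwe_locus_filter,
    mean_observed_het,
    ridge_vs_hw_curve,
)
from .variants import (
    extract_diallelic_snps,
    filter_genotypes,
    filter_sites,
    read_vcf,
    ts_tv_ratio,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    vcf: str
    gff: str
    fasta: str
    outdir: str
    ingroup: list[str]
    outgroup: str
    annotations: str | None = None  # gene -> Pfam accession TSV
    exclude: list[str] = field(default_factory=list)
    min_substitutions: int = 6
    replicates: int = 10
    truncation_window: tuple[float, float] = (-5.0, 1.0)
    alpha: float = 0.05
    min_class_size: int = 5
    hwe_grid: int = 201
    min_calibration_n: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outgroup in self.ingroup:
            raise ValueError("the outgroup individual cannot be in the ingroup")
        overlap = set(self.exclude) & set(self.ingroup)
        if overlap:
            raise ValueError(f"excluded individuals listed in the ingroup: {overlap}")
        if self.replicates < 1 or self.min_substitutions < 0:
            raise ValueError("thresholds out of domain")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "truncation_window" in raw:
            raw["truncation_window"] = tuple(raw["truncation_window"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run filter -> classify -> dN/dS, H, heterozygosity, HWE -> scans.

    Returns the manifest dict (also written to ``manifest.json``); stage
    outputs land in ``config.outdir`` as TSV files.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, samples = read_vcf(config.vcf)
    missing = {config.outgroup, *config.ingroup} - set(samples)
    if missing:
        raise ValueError(f"individuals absent from the VCF: {sorted(missing)}")
    ingroup_idx = [samples.index(s) for s in config.ingroup]
    outgroup_idx = samples.index(config.outgroup)

    surviving = filter_sites(records, n_individuals=len(samples))
    surviving = [filter_genotypes(r) for r in surviving]
    snps = extract_diallelic_snps(surviving, samples)

    contigs = read_fasta(config.fasta)
    models_by_contig = read_gff(config.gff)
    models = [m for ms in models_by_contig.values() for m in ms]
    lengths = {name: len(seq) for name, seq in contigs.items()}

    write_vcf(outdir / "filtered.vcf", surviving, samples, lengths)

    snps_by_contig: dict[str, list] = {}
    for s in snps:
        snps_by_contig.setdefault(s.contig, []).append(s)

    # --- coding effects and region classes ---------------------------------
    effect_rows = []
    for contig, loci in snps_by_contig.items():
        for model in models_by_contig.get(contig, ()):
            seq = contigs[contig]
            positions = {l.pos - 1 for l in loci}
            for locus in loci:
                region = classify_region(locus.pos - 1, model)
                eff = (
                    coding_effect(locus, model, seq, positions)
                    if region.endswith("codon")
                    else "."
                )
                effect_rows.append(
                    {
                        "contig": contig,
                        "pos": locus.pos,
                        "gene": model.gene_id,
                        "region": region,
                        "effect": eff,
                    }
                )
    effects = pd.DataFrame(effect_rows)
    effects.to_csv(outdir / "effects.tsv", sep="\t", index=False)

    # --- per-gene dN/dS ----------------------------------------------------
    dnds_rows = []
    for model in models:
        summary, n_qual = gene_dnds(
            model,
            contigs[model.contig],
            snps_by_contig.get(model.contig, []),
            ingroup_idx,
            outgroup_idx,
            min_substitutions=config.min_substitutions,
        )
        dnds_rows.append(
            {
                "gene": model.gene_id,
                "contig": model.contig,
                "n_qualifying": n_qual,
                "dnds": np.nan if summary is None else summary,
            }
        )
    dnds = pd.DataFrame(dnds_rows)
    calibration = None
    try:
        calibration = calibrate_tails(
            dnds["dnds"].dropna().tolist(),
            window=config.truncation_window,
            min_in_window=config.min_calibration_n,
        )
        dnds["tail_p"] = [
            calibration.upper_tail_prob(v) if np.isfinite(v) else np.nan
            for v in dnds["dnds"]
        ]
    except CalibrationError:
        dnds["tail_p"] = np.nan
    dnds.to_csv(outdir / "dnds.tsv", sep="\t", index=False)

    # --- Fay & Wu's H per gene-containing contig ---------------------------
    h_rows = []
    gene_contigs = sorted({m.contig for m in models})
    for ci, contig in enumerate(gene_contigs):
        loci = snps_by_contig.get(contig, [])
        rng = np.random.default_rng([config.seed % (2**31), 2, ci])
        med = contig_faywu(
            loci, ingroup_idx, outgroup_idx, rng, replicates=config.replicates
        )
        for model in models_by_contig.get(contig, ()):
            h_rows.append(
                {
                    "gene": model.gene_id,
                    "contig": contig,
                    "n_loci": len(loci),
                    "median_H": np.nan if med is None else med,
                }
            )
    faywu = pd.DataFrame(h_rows)
    faywu.to_csv(outdir / "faywu.tsv", sep="\t", index=False)

    # --- heterozygosity ----------------------------------------------------
    het_rows = []
    for model in models:
        loci = [
            l
            for l in snps_by_contig.get(model.contig, [])
            if classify_region(l.pos - 1, model) != "other"
        ]
        ho = mean_observed_het(loci, ingroup_idx, outgroup_idx)
        het_rows.append(
            {
                "gene": model.gene_id,
                "n_loci": len(loci),
                "H_O": np.nan if ho is None else ho,
            }
        )
    pd.DataFrame(het_rows).to_csv(outdir / "het.tsv", sep="\t", index=False)

    # --- Hardy-Weinberg density -------------------------------------------
    hw_loci = hwe_locus_filter(snps, ingroup_idx)
    ridge_mean = np.nan
    if hw_loci:
        grid = empirical_hw_density(hw_loci, ingroup_idx, resolution=config.hwe_grid)
        ridge = ridge_vs_hw_curve(grid)
        ridge_mean = float(np.mean([d for _, d in ridge]))
        pd.DataFrame(
            {
                "r": grid.points[:, 0],
                "h": grid.points[:, 1],
                "v": grid.points[:, 2],
                "log_density": grid.log_density,
            }
        ).to_csv(outdir / "hw_density.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"r": p[0], "h": p[1], "v": p[2], "distance": d}
                for p, d in ridge
            ]
        ).to_csv(outdir / "hw_ridge.tsv", sep="\t", index=False)

    # --- class scans -------------------------------------------------------
    annotations: dict[str, set[str]] = {}
    if config.annotations:
        ann = pd.read_csv(config.annotations, sep="\t")
        for _, row in ann.iterrows():
            annotations.setdefault(str(row["gene"]), set()).add(str(row["accession"]))
    for stat_name, frame, column in (
        ("dnds", dnds, "dnds"),
        ("faywu", faywu, "median_H"),
    ):
        if not annotations:
            break
        stats_map = {
            str(r["gene"]): float(r[column])
            for _, r in frame.iterrows()
            if np.isfinite(r[column])
        }
        results = run_class_scan(
            stats_map, annotations, min_class_size=config.min_class_size
        )
        scan_to_frame(results).to_csv(
            outdir / f"class_scan_{stat_name}.tsv", sep="\t", index=False
        )

    # --- summary -----------------------------------------------------------
    rates = region_rate_table(snps, models_by_contig, lengths)
    rates.to_csv(outdir / "region_rates.tsv", sep="\t", index=False)
    syn_pi_num = 0.0
    syn_sites = 0.0
    eff_by_pos = {
        (r["contig"], r["pos"]): r["effect"] for r in effect_rows
    }
    for model in models:
        syn_sites += synonymous_site_count(model.cds_sequence(contigs[model.contig]))
    for locus in snps:
        if eff_by_pos.get((locus.contig, locus.pos)) != "synonymous":
            continue
        n_ref, n_var = locus.allele_counts(ingroup_idx)
        n_l = n_ref + n_var
        if n_l >= 2 and 0 < n_var < n_l:
            syn_pi_num += 2.0 * n_var * (n_ref) / (n_l * (n_l - 1))
    summary = {
        "n_sites_input": len(records),
        "n_sites_filtered": len(surviving),
        "n_diallelic_snps": len(snps),
        "ts_tv": ts_tv_ratio(snps) if snps else np.nan,
        "pi_S": syn_pi_num / syn_sites if syn_sites else np.nan,
        "mean_ridge_distance": ridge_mean,
        "dnds_median": float(dnds["dnds"].median()),
        "calibration_mu": calibration.mu if calibration else np.nan,
        "calibration_sigma": calibration.sigma if calibration else np.nan,
        "dnds_alpha_threshold": calibration.threshold(config.alpha)
        if calibration
        else np.nan,
    }
    pd.DataFrame([summary]).to_csv(outdir / "summary.tsv", sep="\t", index=False)

    cfg = asdict(config)
    cfg["truncation_window"] = list(config.truncation_window)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {},
        "summary": {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in summary.items()},
    }
    for path in sorted(outdir.glob("*.tsv")) + [outdir / "filtered.vcf"]:
        manifest["outputs"][path.name] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
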