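"""End-to-end driver: simulate -> frequencies -> PHS -> phase -> ASE -> report.

A single master seed deterministically derives independent per-stage seeds,
so rerunning the same configuration reproduces every output byte for byte.
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

from . import ase as ase_mod
from . import genotypes as gio
from . import phasing, phs, synthetic

logger = logging.getLogger(__name__)

DEFAULT_SCHEMES = ("DLY", "LYD", "YDL")
_STAGES = ("frequencies", "purebreds", "family", "genes", "counts", "extra")


@dataclass
class PipelineConfig:
    """All knobs of the simulated-study pipeline."""

    out_dir: str = "crossase_run"
    seed: int = 0
    # breed divergence model
    n_loci: int = 100_000
    fst_duroc: float = 0.30
    fst_ly_split: float = 0.05
    fst_ly_ancestor: float = 0.05
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    # panel and family sizes
    n_per_breed: dict[str, int] = field(
        default_factory=lambda: dict(synthetic.DEFAULT_N_PER_BREED)
    )
    n_offspring: int = 6
    # expression simulation
    n_genes: int = 200
    rna_depth_mean: float = 100.0
    rna_dispersion: float = 10.0
    ase_fraction: float = 0.2
    ase_rho: float = 0.8
    tissues: tuple[str, ...] = ("adipose", "heart", "liver", "muscle")
    # analysis thresholds
    schemes: tuple[str, ...] = DEFAULT_SCHEMES
    tail_fraction: float = 0.01
    phs_threshold: float = 0.9
    min_count: int = ase_mod.DEFAULT_MIN_TOTAL
    alpha: float = ase_mod.DEFAULT_ALPHA
    min_ase_samples: int = ase_mod.DEFAULT_MIN_ASE_SAMPLES

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must be in [0, 0.5)")
        if not 0 <= self.phs_threshold <= 1:
            raise ValueError("phs_threshold must be in [0, 1]")
        if self.min_count < 1 or self.min_ase_samples < 1:
            raise ValueError("min_count and min_ase_samples must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory in simulate mode")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("ancestral_freq_range", "tissues", "schemes"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(_STAGES, children)
        }


def simulate_fixtures(config: PipelineConfig, out_dir: Path) -> dict[str, object]:
    """Generate and write all synthetic inputs; returns the in-memory objects."""
    seeds = config.stage_seeds()
    model = synthetic.BreedModel(
        n_loci=config.n_loci,
        ancestral_freq_range=config.ancestral_freq_range,
        fst_duroc=config.fst_duroc,
        fst_ly_split=config.fst_ly_split,
        fst_ly_ancestor=config.fst_ly_ancestor,
        seed=seeds["frequencies"],
    )
    freqs = synthetic.simulate_breed_frequencies(model)
    purebreds = synthetic.simulate_purebred_genotypes(
        freqs, config.n_per_breed, seed=seeds["purebreds"]
    )
    family = synthetic.simulate_dly_family(
        freqs, config.n_offspring, seed=seeds["family"]
    )
    exons = synthetic.simulate_gene_model(freqs, config.n_genes, seed=seeds["genes"])
    ase_truth = synthetic.simulate_allelic_counts(
        family,
        exons,
        synthetic.ASEParams(
            ase_fraction=config.ase_fraction, rho=config.ase_rho, tissues=config.tissues
        ),
        depth_mean=config.rna_depth_mean,
        dispersion=config.rna_dispersion,
        seed=seeds["counts"],
    )

    fixtures = out_dir / "fixtures"
    fixtures.mkdir(parents=True, exist_ok=True)
    gio.write_vcf(purebreds, fixtures / "purebreds.vcf")
    pd.DataFrame(
        {"sample": purebreds.samples, "breed": [purebreds.breeds[s] for s in purebreds.samples]}
    ).to_csv(fixtures / "breeds.tsv", sep="\t", index=False)
    gio.write_vcf(family.matrix, fixtures / "family.vcf")
    family.pedigree.to_csv(fixtures / "pedigree.tsv", sep="\t", index=False)
    exons.to_csv(fixtures / "exons.bed", sep="\t", index=False, header=False)
    ase_truth.counts.to_csv(fixtures / "counts.tsv", sep="\t", index=False)
    ase_truth.truth.to_csv(fixtures / "truth.tsv", sep="\t", index=False)
    return {
        "freqs": freqs,
        "purebreds": purebreds,
        "family": family,
        "exons": exons,
        "ase_truth": ase_truth,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full simulated study and write all stage outputs.

    Returns the run report (also written as ``report.json``): exclusion and
    filter counts per stage, PHS bin tables and scheme correlations, phased
    fractions, and the per-tissue ASE summaries.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config)}

    sim = simulate_fixtures(config, out_dir)
    fixtures = out_dir / "fixtures"

    # --- purebred genotypes: read back, depth filter, breed frequencies ---
    breeds_df = pd.read_csv(fixtures / "breeds.tsv", sep="\t")
    breed_map = dict(zip(breeds_df["sample"], breeds_df["breed"]))
    purebreds = gio.read_vcf_genotypes(fixtures / "purebreds.vcf", breed_map)
    filtered, depth_report = gio.depth_tail_filter(purebreds, config.tail_fraction)
    freqs_long = gio.genotype_frequencies(filtered)
    freqs_long.to_csv(out_dir / "frequencies.tsv", sep="\t", index=False)
    freq_table = gio.to_allele_frequencies(freqs_long)
    report["snp_filter"] = {"exclusions": purebreds.exclusions, **depth_report}

    # --- PHS per scheme ---
    tables, binnings = {}, {}
    phs_frames, marker_frames = [], []
    for code in config.schemes:
        scheme = phs.CrossScheme.from_code(code)
        table = phs.phs_for_scheme(scheme, freq_table)
        tables[code] = table
        binnings[code] = phs.bin_phs_counts(table)
        frame = table.table.copy()
        frame.insert(2, "scheme", code)
        phs_frames.append(frame)
        markers = phs.high_phs_markers(table, config.phs_threshold)
        markers.insert(0, "scheme", code)
        marker_frames.append(markers)
    pd.concat(phs_frames, ignore_index=True).to_csv(out_dir / "phs.tsv", sep="\t", index=False)
    bins_out = pd.concat(
        [b.assign(scheme=code) for code, b in binnings.items()], ignore_index=True
    )
    bins_out.to_csv(out_dir / "bins.tsv", sep="\t", index=False)
    pd.concat(marker_frames, ignore_index=True).to_csv(
        out_dir / "markers.tsv", sep="\t", index=False
    )
    comparison = phs.scheme_pairwise_correlation(binnings)
    comparison.r.to_csv(out_dir / "comparison.tsv", sep="\t")
    primary = config.schemes[0]
    report["phs"] = {
        "n_loci": {code: len(t.table) for code, t in tables.items()},
        "high_phs_counts": {
            code: int((t.phs > config.phs_threshold).sum()) for code, t in tables.items()
        },
        "mean_r_primary": comparison.mean_r(primary),
        "pairwise_r": comparison.r.to_dict(),
    }

    # --- family: Mendelian checks, heterozygosity, phasing, PHS validation ---
    family_matrix = gio.read_vcf_genotypes(fixtures / "family.vcf")
    pedigree = phasing.read_pedigree(fixtures / "pedigree.tsv")
    het = gio.per_individual_heterozygosity(family_matrix)
    het.to_csv(out_dir / "heterozygosity.tsv", sep="\t", index=False)
    mendel = {}
    for row in pedigree.itertuples(index=False):
        if pd.isna(row.sire) or pd.isna(row.dam):
            continue
        res = gio.mendelian_consistency(
            family_matrix.vector(row.sire),
            family_matrix.vector(row.dam),
            family_matrix.vector(row.id),
        )
        mendel[row.id] = {"n_complete": res.n_complete, "n_errors": res.n_errors,
                          "error_rate": res.error_rate}
    phased = phasing.phase_family(family_matrix, pedigree)
    phased.summary.to_csv(out_dir / "phasing_summary.tsv", sep="\t", index=False)
    phasing.write_phased_vcf(phased, family_matrix, out_dir / "phased.vcf")
    report["family"] = {
        "mendelian": mendel,
        "heterozygosity": het.set_index("sample")["n_het"].to_dict(),
        "phased_fraction": phased.summary.set_index("sample")["phased_fraction"].to_dict(),
    }

    # observed-vs-simulated heterozygosity by PHS bin for every family member
    primary_table = tables[primary]
    aligned = primary_table.table[["chrom", "pos"]].merge(
        family_matrix.loci.reset_index()[["chrom", "pos", "index"]],
        on=["chrom", "pos"],
        how="left",
    )
    idx = aligned["index"].to_numpy()
    ok = ~pd.isna(idx)
    fits = {}
    for sample in family_matrix.samples:
        geno = np.full(len(primary_table.table), gio.MISSING, dtype=np.int8)
        geno[ok] = family_matrix.vector(sample)[idx[ok].astype(int)]
        fits[sample] = phs.observed_het_by_bin(geno, primary_table).r
    report["phs_validation_r"] = fits

    # --- ASE calling ---
    exons = ase_mod.read_exons_bed(fixtures / "exons.bed")
    counts = pd.read_csv(fixtures / "counts.tsv", sep="\t", dtype={"chrom": str})
    snp_map, n_non_exonic = ase_mod.map_snps_to_gene_exons(family_matrix.loci, exons)
    phase_tbl = phased.phase_table()
    gene_counts, n_unphased = ase_mod.gene_allelic_counts(counts, phase_tbl, snp_map)
    # universe: gene x offspring x tissue combinations with a phased exonic het SNP
    het_phase = phase_tbl.merge(snp_map[["chrom", "pos", "gene_id"]], on=["chrom", "pos"])
    offspring = [s for s in phased.offspring if s in set(counts["sample"])]
    universe = (
        het_phase[het_phase["sample"].isin(offspring)][["gene_id", "sample"]]
        .drop_duplicates()
        .merge(pd.DataFrame({"tissue": list(config.tissues)}), how="cross")
    )
    records = ase_mod.classify_genes(
        gene_counts, universe, min_total=config.min_count, alpha=config.alpha
    )
    records.to_csv(out_dir / "gene_ase.tsv", sep="\t", index=False)
    high_conf = ase_mod.call_high_confidence_ase(records, config.min_ase_samples)
    high_conf.to_csv(out_dir / "high_confidence.tsv", sep="\t", index=False)
    callsets = {
        t: set(high_conf.loc[high_conf["tissue"] == t, "gene_id"]) for t in config.tissues
    }
    overlap, specific_fraction = ase_mod.tissue_specificity(callsets)
    overlap.to_csv(out_dir / "tissue_overlap.tsv", sep="\t", index=False)
    report["ase"] = {
        "n_non_exonic_snps": n_non_exonic,
        "n_unphased_rows_dropped": n_unphased,
        "n_high_confidence": {t: len(callsets[t]) for t in config.tissues},
        "n_union": len(set().union(*callsets.values())),
        "tissue_specific_fraction": specific_fraction,
        "median_allelic_ratio": {
            t: float(high_conf.loc[high_conf["tissue"] == t, "median_allelic_ratio"].median())
            if (high_conf["tissue"] == t).any()
            else float("nan")
            for t in config.tissues
        },
    }

    # recovery against the planted truth
    truth = sim["ase_truth"].truth
    planted = truth[truth["true_ratio"] != 0.5]
    recovered = high_conf.merge(planted, on=["gene_id", "tissue"])
    report["ase"]["n_planted"] = int(len(planted))
    report["ase"]["n_recovered"] = int(len(recovered))

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    logger.info("pipeline finished: %s", out_dir / "report.json")
    return report
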