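"""Gene-level allele-specific expression (ASE) calling from phased SNP counts.

Per gene, sample and tissue, reads covering phased exonic heterozygous SNPs
are oriented to the paternal/maternal haplotype and summed. Genes with at
least ``min_total`` informative reads are tested for deviation from the 1:1
allelic expectation with a two-sided exact binomial test; p-values are
Bonferroni-adjusted within each sample x tissue family, and each gene is
classified ASE (adjusted p < alpha), NA, or NO_HET_SNP. High-confidence ASE
genes per tissue are those called ASE in at least ``min_ase_samples``
individuals.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

ASE = "ASE"
NA = "NA"
NO_HET_SNP = "NO_HET_SNP"

DEFAULT_MIN_TOTAL = 10
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_ASE_SAMPLES = 2


def read_exons_bed(path: str) -> pd.DataFrame:
    """Read a BED file of exon intervals (0-based half-open) with the gene
    identifier in the name column."""
    exons = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "gene_id": str},
        comment="#",
    )
    return exons


def map_snps_to_gene_exons(
    loci: pd.DataFrame, exons: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Assign SNPs (1-based positions) to genes by exon overlap.

    Returns ``(snp_map, n_dropped)`` where ``snp_map`` has one row per
    (chrom, pos, gene_id) with an ``ambiguous`` flag for SNPs inside exons of
    more than one gene, and ``n_dropped`` counts non-exonic SNPs.
    """
    if (exons["end"] <= exons["start"]).any() or (exons["start"] < 0).any():
        raise ValueError("exon intervals must be 0-based half-open with end > start")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in exons.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"], sub["gene_id"])
        )
    rows = []
    n_dropped = 0
    for chrom, pos in zip(loci["chrom"], loci["pos"]):
        tree = trees.get(chrom)
        genes = sorted({iv.data for iv in tree.at(pos - 1)}) if tree is not None else []
        if not genes:
            n_dropped += 1
            continue
        for gene in genes:
            rows.append((chrom, pos, gene, len(genes) > 1))
    snp_map = pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "ambiguous"])
    return snp_map, n_dropped


def resolve_multi_snp_reads(
    read_level: pd.DataFrame, loci: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Collapse read-level SNP overlaps so each read is counted once.

    ``read_level`` rows are ``(read_id, sample, tissue, chrom, pos, allele)``;
    a read covering several SNPs contributes only at its lowest-(chrom, pos)
    SNP. Reads whose base matches neither the REF nor the ALT allele there
    are discarded and counted. Returns the aggregated table with
    ``ref_count``/``alt_count`` per (sample, tissue, chrom, pos).
    """
    required = {"read_id", "sample", "tissue", "chrom", "pos", "allele"}
    if not required.issubset(read_level.columns):
        raise ValueError(f"read-level table must have columns {sorted(required)}")
    df = read_level.sort_values(["chrom", "pos"], kind="stable")
    first = df.drop_duplicates(subset=["sample", "tissue", "read_id"], keep="first")
    alleles = loci[["chrom", "pos", "ref", "alt"]].drop_duplicates()
    merged = first.merge(alleles, on=["chrom", "pos"], how="left", validate="many_to_one")
    is_ref = merged["allele"] == merged["ref"]
    is_alt = merged["allele"] == merged["alt"]
    n_discarded = int((~(is_ref | is_alt)).sum())
    kept = merged[is_ref | is_alt].copy()
    kept["ref_count"] = (kept["allele"] == kept["ref"]).astype(int)
    kept["alt_count"] = (kept["allele"] == kept["alt"]).astype(int)
    agg = (
        kept.groupby(["sample", "tissue", "chrom", "pos", "ref", "alt"], as_index=False)[
            ["ref_count", "alt_count"]
        ]
        .sum()
        .sort_values(["sample", "tissue", "chrom", "pos"], ignore_index=True)
    )
    return agg, n_discarded


def gene_allelic_counts(
    counts: pd.DataFrame, phase_table: pd.DataFrame, snp_map: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Sum haplotype-resolved read counts per gene x sample x tissue.

    ``counts`` holds per-SNP ``ref_count``/``alt_count`` rows; ``phase_table``
    gives the paternal allele (0 = ref, 1 = alt) per (sample, chrom, pos).
    Rows at SNPs without a phase for their sample are dropped and counted.
    Returns ``(gene_counts, n_unphased_dropped)``.
    """
    # the exon map is authoritative for gene assignment
    mapped = counts.drop(columns=["gene_id"], errors="ignore").merge(
        snp_map[["chrom", "pos", "gene_id"]], on=["chrom", "pos"]
    )
    merged = mapped.merge(
        phase_table[["sample", "chrom", "pos", "paternal_allele"]],
        on=["sample", "chrom", "pos"],
        how="left",
    )
    unphased = merged["paternal_allele"].isna()
    n_dropped = int(merged.loc[unphased, ["chrom", "pos", "sample", "tissue"]]
                    .drop_duplicates().shape[0])
    merged = merged[~unphased].copy()
    pat_is_ref = merged["paternal_allele"] == 0
    merged["pat_count"] = np.where(pat_is_ref, merged["ref_count"], merged["alt_count"])
    merged["mat_count"] = np.where(pat_is_ref, merged["alt_count"], merged["ref_count"])
    gene_counts = (
        merged.groupby(["gene_id", "sample", "tissue"], as_index=False)
        .agg(pat_count=("pat_count", "sum"), mat_count=("mat_count", "sum"),
             n_snps=("pos", "nunique"))
        .sort_values(["tissue", "sample", "gene_id"], ignore_index=True)
    )
    return gene_counts, n_dropped


def binomial_ase_test(
    pat: np.ndarray | int, mat: np.ndarray | int, min_total: int = DEFAULT_MIN_TOTAL
) -> np.ndarray | float:
    """Two-sided exact binomial p-value against a 1:1 allelic ratio.

    For totals below ``min_total`` the gene is not tested (NaN). With
    n = pat + mat and k the smaller of the two counts, the two-sided tail
    probability under Binomial(n, 1/2) is ``min(1, 2 * P(X <= k))``, exact by
    symmetry of the null.
    """
    pat_arr = np.atleast_1d(np.asarray(pat, dtype=np.int64))
    mat_arr = np.atleast_1d(np.asarray(mat, dtype=np.int64))
    if (pat_arr < 0).any() or (mat_arr < 0).any():
        raise ValueError("allele counts must be non-negative")
    n = pat_arr + mat_arr
    lo = np.minimum(pat_arr, mat_arr)
    with np.errstate(invalid="ignore"):
        p = np.clip(2.0 * stats.binom.cdf(lo, np.maximum(n, 1), 0.5), 0.0, 1.0)
    p = np.where(n >= min_total, p, np.nan)
    return float(p[0]) if np.isscalar(pat) or np.ndim(pat) == 0 else p


def bonferroni_adjust(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni family-wise adjustment: ``min(1, m * p)`` with ``m`` the
    family size (defaults to the number of p-values)."""
    p = np.asarray(p_values, dtype=float)
    finite = p[~np.isnan(p)]
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(p * m, 1.0)


def classify_genes(
    gene_counts: pd.DataFrame,
    gene_universe: pd.DataFrame | None = None,
    min_total: int = DEFAULT_MIN_TOTAL,
    alpha: float = DEFAULT_ALPHA,
    family: str = "per_sample",
) -> pd.DataFrame:
    """Test, adjust and classify every gene x sample x tissue record.

    ``gene_universe`` (columns ``gene_id, sample, tissue``) lists the
    combinations that have at least one phased exonic heterozygous SNP;
    combinations absent from ``gene_counts`` are classified NO_HET_SNP.
    ``family`` selects the Bonferroni family: tested genes within each
    sample x tissue (default) or ``"global"`` for all tested records.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    records = gene_counts.copy()
    if gene_universe is not None:
        records = gene_universe.merge(
            records, on=["gene_id", "sample", "tissue"], how="outer"
        )
        for col in ("pat_count", "mat_count"):
            records[col] = records[col].fillna(0).astype(np.int64)
        records["n_snps"] = records["n_snps"].fillna(0).astype(np.int64)
    total = records["pat_count"] + records["mat_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        records["allelic_ratio"] = np.where(
            total > 0, np.maximum(records["pat_count"], records["mat_count"]) / total, np.nan
        )
        # signed counterpart of the ratio: fraction carried by the paternal allele
        records["paternal_fraction"] = np.where(
            total > 0, records["pat_count"] / total, np.nan
        )
    records["p_value"] = binomial_ase_test(
        records["pat_count"].to_numpy(), records["mat_count"].to_numpy(), min_total
    )
    records["adjusted_p"] = np.nan
    tested = records["p_value"].notna()
    if family == "per_sample":
        for _, idx in records[tested].groupby(["sample", "tissue"]).groups.items():
            records.loc[idx, "adjusted_p"] = bonferroni_adjust(
                records.loc[idx, "p_value"].to_numpy()
            )
    elif family == "global":
        records.loc[tested, "adjusted_p"] = bonferroni_adjust(
            records.loc[tested, "p_value"].to_numpy()
        )
    else:
        raise ValueError("family must be 'per_sample' or 'global'")
    no_het = records["n_snps"] == 0
    records["classification"] = np.select(
        [no_het, tested & (records["adjusted_p"] < alpha)], [NO_HET_SNP, ASE], default=NA
    )
    return records


def call_high_confidence_ase(
    records: pd.DataFrame, min_ase_samples: int = DEFAULT_MIN_ASE_SAMPLES
) -> pd.DataFrame:
    """Per-tissue high-confidence ASE genes: classified ASE in at least
    ``min_ase_samples`` individuals of that tissue. The per-gene allelic
    ratio is the median over its ASE-classified samples."""
    ase = records[records["classification"] == ASE]
    if ase.empty:
        return pd.DataFrame(
            columns=["tissue", "gene_id", "n_ase_samples", "median_allelic_ratio"]
        )
    grouped = (
        ase.groupby(["tissue", "gene_id"], as_index=False)
        .agg(n_ase_samples=("sample", "nunique"), median_allelic_ratio=("allelic_ratio", "median"))
    )
    out = grouped[grouped["n_ase_samples"] >= min_ase_samples].reset_index(drop=True)
    return out.sort_values(["tissue", "gene_id"], ignore_index=True)


def tissue_specificity(callsets: dict[str, set[str]]) -> tuple[pd.DataFrame, float]:
    """Venn-style overlap of per-tissue high-confidence gene sets.

    Returns per-combination counts over the union of genes and the fraction
    of genes detected in exactly one tissue.
    """
    if len(callsets) < 2:
        raise ValueError("tissue specificity needs at least two tissues")
    tissues = sorted(callsets)
    union = sorted(set().union(*callsets.values()))
    membership = {
        g: frozenset(t for t in tissues if g in callsets[t]) for g in union
    }
    rows = []
    for r in range(1, len(tissues) + 1):
        for combo in combinations(tissues, r):
            n = sum(1 for g in union if membership[g] == frozenset(combo))
            rows.append({"tissues": "+".join(combo), "n_tissues": r, "n_genes": n})
    overlap = pd.DataFrame(rows)
    n_specific = sum(1 for g in union if len(membership[g]) == 1)
    fraction = n_specific / len(union) if union else np.nan
    return overlap, fraction
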