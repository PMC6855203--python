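"""Genotype matrices, VCF input and per-breed genotype frequency summaries.

Genotypes are coded by alternate-allele dosage: 0 = homozygous reference,
1 = heterozygous, 2 = homozygous alternate, -1 = missing. Only biallelic
autosomal SNVs are kept; positions are 1-based as in VCF. The transmitted
(reference) allele frequency of a population at a locus is

    f = p_homref + p_het / 2,

which equals the reference-allele count divided by twice the number of
called genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1
GENOTYPE_CODES = (0, 1, 2)
LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt"]
_SEX_CHROMOSOMES = {"X", "Y"}
_BASES = {"A", "C", "G", "T"}

#: cyvcf2 ``gt_types`` (HOM_REF, HET, UNKNOWN, HOM_ALT) -> dosage codes
_CYVCF2_CODE = np.array([0, 1, MISSING, 2], dtype=np.int8)


def is_sex_chromosome(chrom: str) -> bool:
    return chrom.removeprefix("chr").upper() in _SEX_CHROMOSOMES


@dataclass
class GenotypeMatrix:
    """Samples x loci dosage matrix with per-locus total read depth.

    Parameters
    ----------
    loci
        DataFrame with columns ``chrom, pos, ref, alt, depth``, unique and
        sorted by ``(chrom, pos)`` (lexicographic chromosome order).
    samples
        Ordered sample identifiers, one per matrix row.
    genotypes
        ``int8`` array of shape ``(n_samples, n_loci)`` with codes in
        ``{-1, 0, 1, 2}``.
    breeds
        Optional sample -> breed label map.
    exclusions
        Record counts dropped while reading (multiallelic, non-SNV, sex
        chromosome records).
    """

    loci: pd.DataFrame
    samples: list[str]
    genotypes: np.ndarray
    breeds: dict[str, str] | None = None
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        missing_cols = [c for c in LOCUS_COLUMNS + ["depth"] if c not in self.loci.columns]
        if missing_cols:
            raise ValueError(f"loci frame lacks columns {missing_cols}")
        bad = ~np.isin(self.genotypes, (MISSING,) + GENOTYPE_CODES)
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        keys = list(zip(self.loci["chrom"], self.loci["pos"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos) locus keys")
        if keys != sorted(keys):
            raise ValueError("loci must be sorted by (chrom, pos)")
        if (self.loci["depth"].to_numpy() < 0).any():
            raise ValueError("per-locus depth must be non-negative")
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def vector(self, sample: str) -> np.ndarray:
        """Genotype vector of one sample across all loci."""
        return self.genotypes[self.sample_index(sample)]

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            loci=self.loci.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            genotypes=self.genotypes[:, mask],
            breeds=self.breeds,
            exclusions=dict(self.exclusions),
        )


def read_vcf_genotypes(path: str, breed_map: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records, non-SNV records and sex-chromosome records are
    skipped and counted in ``exclusions``; missing genotypes are preserved.
    Per-locus depth is taken from INFO/DP, falling back to the sum of
    per-sample FORMAT depths.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if breed_map is not None:
        unknown = [s for s in samples if s not in breed_map]
        if unknown:
            raise ValueError(f"samples missing from breed map: {unknown}")
    excl = {"multiallelic": 0, "non_snv": 0, "sex_chromosome": 0}
    rows, codes, depths = [], [], []
    for v in vcf:
        if is_sex_chromosome(v.CHROM):
            excl["sex_chromosome"] += 1
            continue
        if len(v.ALT) != 1:
            excl["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or v.REF not in _BASES or v.ALT[0] not in _BASES:
            excl["non_snv"] += 1
            continue
        dp = v.INFO.get("DP")
        if dp is None:
            dp = int(np.clip(v.gt_depths, 0, None).sum()) if samples else 0
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        codes.append(_CYVCF2_CODE[v.gt_types])
        depths.append(int(dp))
    for key, n in excl.items():
        if n:
            logger.info("read_vcf_genotypes: skipped %d %s records", n, key)
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    loci["depth"] = depths
    geno = (
        np.asarray(codes, dtype=np.int8).T
        if codes
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
    loci = loci.iloc[order].reset_index(drop=True)
    geno = geno[:, order]
    breeds = {s: breed_map[s] for s in samples} if breed_map is not None else None
    return GenotypeMatrix(loci=loci, samples=samples, genotypes=geno, breeds=breeds, exclusions=excl)


def depth_tail_filter(
    matrix: GenotypeMatrix, tail_fraction: float = 0.01
) -> tuple[GenotypeMatrix, dict[str, float]]:
    """Drop loci in the extreme tails of the per-locus depth distribution.

    Loci with depth strictly below the ``tail_fraction`` empirical quantile
    or strictly above the ``1 - tail_fraction`` quantile are removed; the
    default of 1% per tail removes about 2% of loci in total. Returns the
    filtered matrix and a report of what was removed.
    """
    if not 0.0 <= tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in [0, 0.5)")
    depth = matrix.loci["depth"].to_numpy()
    if matrix.n_loci == 0:
        return matrix, {"n_input": 0, "n_removed": 0, "lower": np.nan, "upper": np.nan}
    lower = float(np.quantile(depth, tail_fraction))
    upper = float(np.quantile(depth, 1.0 - tail_fraction))
    keep = (depth >= lower) & (depth <= upper)
    report = {
        "n_input": int(matrix.n_loci),
        "n_removed": int((~keep).sum()),
        "n_removed_low": int((depth < lower).sum()),
        "n_removed_high": int((depth > upper).sum()),
        "lower": lower,
        "upper": upper,
    }
    return matrix.subset_loci(keep), report


def genotype_frequencies(
    matrix: GenotypeMatrix, breeds: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-locus per-breed genotype frequencies and transmitted-allele frequency.

    Returns a long-form frame with columns ``chrom, pos, ref, alt, breed,
    p_homref, p_het, p_homalt, n_called, f``. Missing genotypes are excluded
    from the denominators; loci with no called genotype in a breed carry NaN
    proportions (they are excluded from downstream PHS).
    """
    breeds = breeds if breeds is not None else matrix.breeds
    if breeds is None:
        raise ValueError("no breed assignment provided")
    unassigned = [s for s in matrix.samples if s not in breeds]
    if unassigned:
        raise ValueError(f"samples without breed assignment: {unassigned}")
    out = []
    sample_arr = np.array(matrix.samples)
    for breed in sorted(set(breeds[s] for s in matrix.samples)):
        rows = np.array([breeds[s] == breed for s in sample_arr])
        block = matrix.genotypes[rows]
        counts = np.stack([(block == g).sum(axis=0) for g in GENOTYPE_CODES], axis=1).astype(float)
        n_called = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = counts / n_called[:, None]
        df = matrix.loci[LOCUS_COLUMNS].copy()
        df["breed"] = breed
        df["p_homref"] = props[:, 0]
        df["p_het"] = props[:, 1]
        df["p_homalt"] = props[:, 2]
        df["n_called"] = n_called.astype(int)
        # algebraically p_homref + p_het/2, but computed from raw allele
        # counts so f equals ref-allele-count / (2 * n_called) exactly
        with np.errstate(invalid="ignore", divide="ignore"):
            df["f"] = (2.0 * counts[:, 0] + counts[:, 1]) / (2.0 * n_called)
        out.append(df)
    return pd.concat(out, ignore_index=True)


def to_allele_frequencies(freqs: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-form genotype frequencies to one transmitted-allele-frequency
    column per breed (NaN where a breed has no called genotype)."""
    wide = (
        freqs.pivot_table(index=LOCUS_COLUMNS, columns="breed", values="f", dropna=False)
        .reset_index()
        .rename_axis(columns=None)
    )
    order = np.lexsort((wide["pos"].to_numpy(), wide["chrom"].to_numpy()))
    return wide.iloc[order].reset_index(drop=True)


def per_individual_heterozygosity(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Heterozygous-genotype count and fraction (over non-missing loci) per sample."""
    n_het = (matrix.genotypes == 1).sum(axis=1)
    n_called = (matrix.genotypes != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_called > 0, n_het / n_called, np.nan)
    return pd.DataFrame(
        {
            "sample": matrix.samples,
            "n_het": n_het.astype(int),
            "n_called": n_called.astype(int),
            "het_fraction": frac,
        }
    )


@dataclass
class MendelianResult:
    """Per-locus Mendelian consistency flags for one trio."""

    inconsistent: np.ndarray  # True where the trio violates Mendelian transmission
    n_complete: int
    n_errors: int

    @property
    def error_rate(self) -> float:
        return self.n_errors / self.n_complete if self.n_complete else np.nan


def mendelian_consistency(
    g_sire: np.ndarray, g_dam: np.ndarray, g_offspring: np.ndarray
) -> MendelianResult:
    """Flag loci where the offspring genotype cannot be formed from one allele
    of each parent. Loci with any missing member are not counted."""
    gs, gd, go = (np.asarray(g, dtype=np.int8) for g in (g_sire, g_dam, g_offspring))
    if not gs.shape == gd.shape == go.shape:
        raise ValueError("trio genotype vectors must have equal length")
    complete = (gs != MISSING) & (gd != MISSING) & (go != MISSING)
    s_ref, s_alt = gs <= 1, gs >= 1  # parent can transmit ref / alt
    d_ref, d_alt = gd <= 1, gd >= 1
    possible = np.select(
        [go == 0, go == 1, go == 2],
        [s_ref & d_ref, (s_ref & d_alt) | (s_alt & d_ref), s_alt & d_alt],
        default=False,
    )
    inconsistent = complete & ~possible
    return MendelianResult(
        inconsistent=inconsistent,
        n_complete=int(complete.sum()),
        n_errors=int(inconsistent.sum()),
    )


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as VCF v4.2 with GT genotypes and INFO/DP depth."""
    code_to_gt = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    loci = matrix.loci
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in loci["chrom"].unique():
            length = int(loci.loc[loci["chrom"] == chrom, "pos"].max()) + 10_000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.samples) + "\n")
        geno = matrix.genotypes
        for j, (chrom, pos, ref, alt, depth) in enumerate(
            zip(loci["chrom"], loci["pos"], loci["ref"], loci["alt"], loci["depth"])
        ):
            gts = "\t".join(code_to_gt[int(g)] for g in geno[:, j])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tDP={int(depth)}\tGT\t{gts}\n")
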