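"""Synthetic study generator: purebred panels, a DLY family, allelic RNA counts.

Emulates the data layout of a three-breed pig crossbreeding study with
ground-truth labels for recovery tests:

* Three purebred populations (Duroc, Landrace, Yorkshire) whose per-locus
  allele frequencies follow a hierarchical Balding-Nichols model in which
  Landrace and Yorkshire share a recent common ancestor, making them
  mutually closer than either is to Duroc.
* A three-generation DLY family — Landrace grandsire x Yorkshire granddam
  producing an LY dam, mated to a Duroc sire — with every transmitted gamete
  recorded, so the parental origin of each offspring allele is known.
* Per-gene allelic RNA read counts for the crossbred offspring across
  tissues, with ASE effects planted at a stated paternal ratio in a subset
  of genes (tissue-specific by default) and a 1:1 ratio everywhere else.

Loci are independent (no linkage map); sex chromosomes are never simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ase as ase_mod
from .genotypes import GenotypeMatrix

DEFAULT_N_PER_BREED = {"D": 11, "L": 9, "Y": 10}
GRANDSIRE, GRANDDAM, SIRE, DAM = "L_GS", "Y_GD", "D_SIRE", "LY_DAM"
_BASES = np.array(list("ACGT"))


@dataclass
class BreedModel:
    """Hierarchical Balding-Nichols divergence model for the three breeds.

    The ancestral reference-allele frequency of each locus is drawn uniform
    on ``ancestral_freq_range``. Duroc frequencies drift from the ancestor
    with ``fst_duroc``; an unobserved Landrace/Yorkshire ancestor drifts with
    ``fst_ly_ancestor`` and Landrace and Yorkshire each drift from it with
    ``fst_ly_split``. With the defaults, L and Y are mutually closer than
    either is to D.
    """

    n_loci: int = 100_000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    fst_duroc: float = 0.30
    fst_ly_split: float = 0.05
    fst_ly_ancestor: float = 0.05
    n_chromosomes: int = 18
    locus_spacing: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must be ordered within (0, 1)")
        for name in ("fst_duroc", "fst_ly_split", "fst_ly_ancestor"):
            val = getattr(self, name)
            if not 0.0 <= val < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_chromosomes < 1 or self.locus_spacing < 1:
            raise ValueError("n_chromosomes and locus_spacing must be >= 1")


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    """Draw subpopulation frequencies around ancestral ``p`` at divergence
    ``fst`` (Beta with mean p and variance fst * p * (1 - p))."""
    if fst == 0.0:
        return p.copy()
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale)


def _locus_frame(n_loci: int, n_chromosomes: int, spacing: int, rng: np.random.Generator) -> pd.DataFrame:
    chroms = sorted(str(c) for c in range(1, n_chromosomes + 1))
    per = int(np.ceil(n_loci / len(chroms)))
    chrom_col = np.repeat(chroms, per)[:n_loci]
    pos = np.concatenate(
        [np.arange(1, (chrom_col == c).sum() + 1) * spacing for c in chroms]
    )
    ref_idx = rng.integers(0, 4, size=n_loci)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_loci)) % 4
    return pd.DataFrame(
        {"chrom": chrom_col, "pos": pos, "ref": _BASES[ref_idx], "alt": _BASES[alt_idx]}
    )


def simulate_breed_frequencies(model: BreedModel) -> pd.DataFrame:
    """Per-locus transmitted (reference) allele frequencies for D, L and Y.

    Returns a wide table with columns ``chrom, pos, ref, alt, ancestral,
    D, L, Y``; genotype frequencies of any breed are the Hardy-Weinberg
    expansion of its column. Deterministic given ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    loci = _locus_frame(model.n_loci, model.n_chromosomes, model.locus_spacing, rng)
    lo, hi = model.ancestral_freq_range
    p = rng.uniform(lo, hi, size=model.n_loci)
    ly_ancestor = _balding_nichols(rng, p, model.fst_ly_ancestor)
    freqs = loci.copy()
    freqs["ancestral"] = p
    freqs["D"] = np.clip(_balding_nichols(rng, p, model.fst_duroc), 0.0, 1.0)
    freqs["L"] = np.clip(_balding_nichols(rng, ly_ancestor, model.fst_ly_split), 0.0, 1.0)
    freqs["Y"] = np.clip(_balding_nichols(rng, ly_ancestor, model.fst_ly_split), 0.0, 1.0)
    return freqs


def _draw_depth(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """Negative-binomial per-locus total depth (overdispersed, so the depth
    distribution has tails for the tail filter to act on)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_purebred_genotypes(
    freqs: pd.DataFrame,
    n_per_breed: dict[str, int] | None = None,
    seed: int = 0,
    depth_mean_per_sample: float = 15.0,
    depth_dispersion: float = 8.0,
) -> GenotypeMatrix:
    """Draw purebred panel genotypes at Hardy-Weinberg equilibrium per breed.

    Sample names are ``<breed><index>``; per-locus total depth is drawn
    negative-binomial with mean ``depth_mean_per_sample * n_samples``.
    Breeds mapped to zero samples simply contribute no rows.
    """
    n_per_breed = dict(DEFAULT_N_PER_BREED) if n_per_breed is None else n_per_breed
    rng = np.random.default_rng(seed)
    samples: list[str] = []
    breeds: dict[str, str] = {}
    blocks = []
    n_loci = len(freqs)
    for breed in sorted(n_per_breed):
        n = n_per_breed[breed]
        if n < 0:
            raise ValueError("sample counts must be non-negative")
        if breed not in freqs.columns:
            raise KeyError(f"breed {breed!r} not present in frequency table")
        alt_freq = 1.0 - freqs[breed].to_numpy(dtype=float)
        blocks.append(rng.binomial(2, alt_freq, size=(n, n_loci)).astype(np.int8))
        for i in range(n):
            name = f"{breed}{i + 1:02d}"
            samples.append(name)
            breeds[name] = breed
    geno = np.vstack(blocks) if blocks else np.empty((0, n_loci), dtype=np.int8)
    loci = freqs[["chrom", "pos", "ref", "alt"]].copy()
    loci["depth"] = _draw_depth(
        rng, depth_mean_per_sample * max(len(samples), 1), depth_dispersion, n_loci
    )
    return GenotypeMatrix(loci=loci, samples=samples, genotypes=geno, breeds=breeds)


@dataclass
class FamilyTruth:
    """A simulated DLY family with fully tracked gamete transmission.

    ``paternal_allele``/``maternal_allele`` (n_offspring x n_loci, 0 = ref,
    1 = alt) are the ground-truth haplotype origins of each crossbred
    offspring; ``maternal_grandparent`` records whether the dam transmitted
    her Landrace-grandsire (0) or Yorkshire-granddam (1) allele.
    """

    matrix: GenotypeMatrix
    pedigree: pd.DataFrame
    offspring: list[str]
    paternal_allele: np.ndarray
    maternal_allele: np.ndarray
    maternal_grandparent: np.ndarray
    dam_paternal_allele: np.ndarray = field(repr=False, default=None)
    dam_maternal_allele: np.ndarray = field(repr=False, default=None)


def simulate_dly_family(
    freqs: pd.DataFrame,
    n_offspring: int = 6,
    seed: int = 0,
    depth_mean_per_sample: float = 38.5,
    depth_dispersion: float = 8.0,
) -> FamilyTruth:
    """Simulate the ten-member DLY family with recorded gamete transmissions.

    Grandparents are drawn at HWE from Landrace and Yorkshire, the LY dam
    receives one gamete from each, the Duroc sire is drawn at HWE from D,
    and each of ``n_offspring`` crossbred offspring receives one tracked
    gamete from the sire and one from the dam.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    rng = np.random.default_rng(seed)
    n_loci = len(freqs)

    def hwe_alleles(breed: str) -> np.ndarray:
        alt = 1.0 - freqs[breed].to_numpy(dtype=float)
        return rng.binomial(1, alt, size=(2, n_loci)).astype(np.int8)

    gs_alleles = hwe_alleles("L")  # Landrace grandsire
    gd_alleles = hwe_alleles("Y")  # Yorkshire granddam
    sire_alleles = hwe_alleles("D")  # Duroc terminal sire

    def gamete(alleles: np.ndarray) -> np.ndarray:
        pick = rng.integers(0, 2, size=n_loci)
        return alleles[pick, np.arange(n_loci)].astype(np.int8)

    dam_pat = gamete(gs_alleles)  # dam's paternal haplotype, from L grandsire
    dam_mat = gamete(gd_alleles)  # dam's maternal haplotype, from Y granddam
    dam_alleles = np.stack([dam_pat, dam_mat])

    offspring_names = [f"DLY_{i + 1:02d}" for i in range(n_offspring)]
    paternal = np.empty((n_offspring, n_loci), dtype=np.int8)
    maternal = np.empty((n_offspring, n_loci), dtype=np.int8)
    grandparent = np.empty((n_offspring, n_loci), dtype=np.int8)
    for i in range(n_offspring):
        paternal[i] = gamete(sire_alleles)
        pick = rng.integers(0, 2, size=n_loci)
        maternal[i] = dam_alleles[pick, np.arange(n_loci)]
        grandparent[i] = pick  # 0 -> allele traces to L grandsire, 1 -> Y granddam

    samples = [GRANDSIRE, GRANDDAM, SIRE, DAM] + offspring_names
    geno = np.vstack(
        [
            gs_alleles.sum(axis=0),
            gd_alleles.sum(axis=0),
            sire_alleles.sum(axis=0),
            dam_alleles.sum(axis=0),
            paternal + maternal,
        ]
    ).astype(np.int8)
    loci = freqs[["chrom", "pos", "ref", "alt"]].copy()
    loci["depth"] = _draw_depth(
        rng, depth_mean_per_sample * len(samples), depth_dispersion, n_loci
    )
    breeds = {GRANDSIRE: "L", GRANDDAM: "Y", SIRE: "D", DAM: "LY"}
    breeds.update({name: "DLY" for name in offspring_names})
    matrix = GenotypeMatrix(loci=loci, samples=samples, genotypes=geno, breeds=breeds)
    rows = [
        {"id": GRANDSIRE, "sire": "0", "dam": "0", "sex": "M", "generation": 0},
        {"id": GRANDDAM, "sire": "0", "dam": "0", "sex": "F", "generation": 0},
        {"id": SIRE, "sire": "0", "dam": "0", "sex": "M", "generation": 1},
        {"id": DAM, "sire": GRANDSIRE, "dam": GRANDDAM, "sex": "F", "generation": 1},
    ]
    sexes = ["M", "F"] * ((n_offspring + 1) // 2)
    rows += [
        {"id": name, "sire": SIRE, "dam": DAM, "sex": sexes[i], "generation": 2}
        for i, name in enumerate(offspring_names)
    ]
    return FamilyTruth(
        matrix=matrix,
        pedigree=pd.DataFrame(rows),
        offspring=offspring_names,
        paternal_allele=paternal,
        maternal_allele=maternal,
        maternal_grandparent=grandparent,
        dam_paternal_allele=dam_pat,
        dam_maternal_allele=dam_mat,
    )


def simulate_gene_model(
    freqs: pd.DataFrame,
    n_genes: int = 200,
    snps_per_gene: tuple[int, int] = (3, 8),
    intergenic_loci: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Lay genes along the simulated loci and return their exon intervals.

    Each gene claims a run of consecutive loci; every claimed locus gets a
    small exon interval around it, except that genes spanning three or more
    loci leave their middle locus uncovered (intronic). Returns a BED-like
    frame ``chrom, start, end, gene_id`` (0-based half-open).
    """
    lo, hi = snps_per_gene
    if not 1 <= lo <= hi:
        raise ValueError("snps_per_gene bounds must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    loci = freqs[["chrom", "pos"]].reset_index(drop=True)
    rows = []
    i, gene = 0, 0
    n_loci = len(loci)
    while gene < n_genes and i < n_loci:
        k = int(rng.integers(lo, hi + 1))
        chrom = loci.loc[i, "chrom"]
        run = loci.iloc[i : i + k]
        run = run[run["chrom"] == chrom]
        if len(run) == 0:
            i += 1
            continue
        gene_id = f"G{gene + 1:04d}"
        positions = run["pos"].to_list()
        intronic = positions[len(positions) // 2] if len(positions) >= 3 else None
        for pos in positions:
            if pos == intronic:
                continue
            rows.append({"chrom": chrom, "start": pos - 6, "end": pos + 5, "gene_id": gene_id})
        gene += 1
        i += len(run) + intergenic_loci
    if gene < n_genes:
        raise ValueError(f"only {gene} of {n_genes} genes fit on {n_loci} loci")
    return pd.DataFrame(rows)


@dataclass
class ASEParams:
    """Planted allele-specific expression effects.

    ``ase_fraction`` of genes receive a true paternal read ratio of ``rho``
    (all remaining genes are null at exactly 0.5); with ``tissue_specific``
    each effect is placed in a single random tissue.
    """

    ase_fraction: float = 0.2
    rho: float = 0.8
    tissues: tuple[str, ...] = ("adipose", "heart", "liver", "muscle")
    tissue_specific: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.ase_fraction <= 1.0:
            raise ValueError("ase_fraction must be in [0, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if not self.tissues:
            raise ValueError("at least one tissue is required")


@dataclass
class ASETruth:
    """Simulated allelic counts plus the generating truth."""

    counts: pd.DataFrame  # sample, tissue, chrom, pos, ref, alt, gene_id, ref_count, alt_count
    truth: pd.DataFrame  # gene_id, tissue, true_ratio
    ase_genes: list[str]
    skipped_genes: list[str]
    params: ASEParams


def simulate_gene_counts(
    n_genes: int,
    n_samples: int,
    rho: float | np.ndarray,
    depth_mean: float,
    dispersion: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Gene-level paternal/maternal totals: negative-binomial totals with the
    paternal share binomial at ratio ``rho``. Shapes (n_genes, n_samples)."""
    p_nb = dispersion / (dispersion + depth_mean)
    total = rng.negative_binomial(dispersion, p_nb, size=(n_genes, n_samples))
    rho_arr = np.broadcast_to(np.asarray(rho, dtype=float).reshape(-1, 1), total.shape)
    pat = rng.binomial(total, rho_arr)
    return pat, total - pat


def simulate_allelic_counts(
    family: FamilyTruth,
    exons: pd.DataFrame,
    ase_params: ASEParams | None = None,
    depth_mean: float = 100.0,
    dispersion: float = 10.0,
    seed: int = 0,
) -> ASETruth:
    """Simulate per-SNP allelic RNA counts for the crossbred offspring.

    Per gene x offspring x tissue, a negative-binomial total is split
    paternal/maternal at the gene's true tissue ratio and then distributed
    multinomially across the gene's exonic SNPs at which that offspring is
    heterozygous (samples emit counts only at their own het loci). Counts
    are reported as REF/ALT using the true phase. Genes with no exonic SNP
    among the family loci are flagged and skipped.
    """
    params = ase_params if ase_params is not None else ASEParams()
    rng = np.random.default_rng(seed)
    loci = family.matrix.loci
    snp_map, _ = ase_mod.map_snps_to_gene_exons(loci, exons)
    all_genes = sorted(exons["gene_id"].unique())
    covered = set(snp_map["gene_id"])
    skipped = [g for g in all_genes if g not in covered]
    genes = [g for g in all_genes if g in covered]

    n_ase = int(round(params.ase_fraction * len(genes)))
    ase_genes = sorted(rng.choice(genes, size=n_ase, replace=False)) if n_ase else []
    tissue_of = {
        g: (params.tissues[rng.integers(len(params.tissues))] if params.tissue_specific else None)
        for g in ase_genes
    }
    truth_rows = [
        {
            "gene_id": g,
            "tissue": t,
            "true_ratio": params.rho
            if g in tissue_of and tissue_of[g] in (None, t)
            else 0.5,
        }
        for g in genes
        for t in params.tissues
    ]
    truth = pd.DataFrame(truth_rows)
    ratio_lookup = {(r["gene_id"], r["tissue"]): r["true_ratio"] for r in truth_rows}

    pos_index = {(c, p): j for j, (c, p) in enumerate(zip(loci["chrom"], loci["pos"]))}
    gene_snps = {
        g: [pos_index[(c, p)] for c, p in zip(sub["chrom"], sub["pos"])]
        for g, sub in snp_map.groupby("gene_id")
    }
    locus_arr = loci[["chrom", "pos", "ref", "alt"]].to_numpy()
    p_nb = dispersion / (dispersion + depth_mean)

    rows = []
    for g in genes:
        snp_idx = np.array(gene_snps[g], dtype=int)
        for s, sample in enumerate(family.offspring):
            het = snp_idx[
                family.paternal_allele[s, snp_idx] != family.maternal_allele[s, snp_idx]
            ]
            if het.size == 0:
                continue
            share = np.full(het.size, 1.0 / het.size)
            for tissue in params.tissues:
                total = int(rng.negative_binomial(dispersion, p_nb))
                if total == 0:
                    continue
                pat_total = int(rng.binomial(total, ratio_lookup[(g, tissue)]))
                pat_snp = rng.multinomial(pat_total, share)
                mat_snp = rng.multinomial(total - pat_total, share)
                for j, snp in enumerate(het):
                    chrom, pos, ref, alt = locus_arr[snp]
                    pat_is_alt = family.paternal_allele[s, snp] == 1
                    ref_n = mat_snp[j] if pat_is_alt else pat_snp[j]
                    alt_n = pat_snp[j] if pat_is_alt else mat_snp[j]
                    if ref_n == 0 and alt_n == 0:
                        continue
                    rows.append(
                        (sample, tissue, chrom, pos, ref, alt, g, int(ref_n), int(alt_n))
                    )
    counts = pd.DataFrame(
        rows,
        columns=[
            "sample", "tissue", "chrom", "pos", "ref", "alt",
            "gene_id", "ref_count", "alt_count",
        ],
    )
    return ASETruth(
        counts=counts, truth=truth, ase_genes=list(ase_genes),
        skipped_genes=skipped, params=params,
    )


def true_phase_table(family: FamilyTruth) -> pd.DataFrame:
    """Ground-truth phase of every offspring het locus, in the same layout as
    :meth:`crossase.phasing.PhasedFamily.phase_table` (for oracle tests)."""
    frames = []
    loci = family.matrix.loci
    for i, sample in enumerate(family.offspring):
        het = family.paternal_allele[i] != family.maternal_allele[i]
        frames.append(
            pd.DataFrame(
                {
                    "sample": sample,
                    "chrom": loci.loc[het, "chrom"].to_numpy(),
                    "pos": loci.loc[het, "pos"].to_numpy(),
                    "paternal_allele": family.paternal_allele[i, het],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
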