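"""Mendelian trio phasing of offspring heterozygous SNPs.

Given a heterozygous offspring and its parents' genotypes at a biallelic
locus, there are nine ordered (sire, dam) genotype pairs; seven of them
are compatible with Mendelian transmission. Two (parents homozygous for
opposite alleles) and four (one parent homozygous, the other heterozygous)
determine which parent contributed each allele; the remaining compatible
pair (both parents heterozygous) cannot be phased from the trio alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

UNPHASED = -1  # allele placeholder where no phase was assigned


class TrioClass(IntEnum):
    """Classification of one (sire, dam, offspring) genotype configuration."""

    NOT_HET_OFFSPRING = 0
    PHASABLE_BOTH_HOM = 1
    PHASABLE_ONE_HET = 2
    UNPHASABLE_BOTH_HET = 3
    MENDELIAN_ERROR = 4
    INCOMPLETE = 5


PHASABLE_CLASSES = (TrioClass.PHASABLE_BOTH_HOM, TrioClass.PHASABLE_ONE_HET)


def classify_trios(
    g_sire: np.ndarray, g_dam: np.ndarray, g_offspring: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised trio classification.

    Returns ``(classes, paternal, maternal)``: the :class:`TrioClass` code per
    locus and, for phasable loci, the paternal and maternal allele (0 = ref,
    1 = alt); non-phasable loci carry :data:`UNPHASED`.
    """
    gs = np.asarray(g_sire, dtype=np.int8)
    gd = np.asarray(g_dam, dtype=np.int8)
    go = np.asarray(g_offspring, dtype=np.int8)
    if not gs.shape == gd.shape == go.shape:
        raise ValueError("trio genotype vectors must have equal length")

    incomplete = (gs == MISSING) | (gd == MISSING) | (go == MISSING)
    het = ~incomplete & (go == 1)
    # a het offspring needs one parent able to transmit ref, the other alt
    consistent = ((gs <= 1) & (gd >= 1)) | ((gs >= 1) & (gd <= 1))
    sire_hom = (gs == 0) | (gs == 2)
    dam_hom = (gd == 0) | (gd == 2)

    classes = np.full(gs.shape, TrioClass.NOT_HET_OFFSPRING, dtype=np.int8)
    classes[incomplete] = TrioClass.INCOMPLETE
    classes[het & ~consistent] = TrioClass.MENDELIAN_ERROR
    classes[het & consistent & (gs == 1) & (gd == 1)] = TrioClass.UNPHASABLE_BOTH_HET
    both_hom = het & consistent & sire_hom & dam_hom
    classes[both_hom] = TrioClass.PHASABLE_BOTH_HOM
    one_het = het & consistent & (sire_hom ^ dam_hom)
    classes[one_het] = TrioClass.PHASABLE_ONE_HET

    paternal = np.full(gs.shape, UNPHASED, dtype=np.int8)
    maternal = np.full(gs.shape, UNPHASED, dtype=np.int8)
    # homozygous parent transmits its allele; the other parent the complement
    from_sire = (both_hom | one_het) & sire_hom
    paternal[from_sire] = gs[from_sire] // 2
    maternal[from_sire] = 1 - paternal[from_sire]
    from_dam = one_het & dam_hom
    maternal[from_dam] = gd[from_dam] // 2
    paternal[from_dam] = 1 - maternal[from_dam]
    return classes, paternal, maternal


def classify_trio_configuration(
    g_sire: int, g_dam: int, g_offspring: int
) -> tuple[TrioClass, int | None, int | None]:
    """Classify a single trio configuration; returns the class and, when
    phasable, the paternal and maternal allele (0 = ref, 1 = alt)."""
    cls, pat, mat = classify_trios(
        np.array([g_sire]), np.array([g_dam]), np.array([g_offspring])
    )
    phased = cls[0] in (TrioClass.PHASABLE_BOTH_HOM, TrioClass.PHASABLE_ONE_HET)
    return (
        TrioClass(int(cls[0])),
        int(pat[0]) if phased else None,
        int(mat[0]) if phased else None,
    )


@dataclass
class PhasedFamily:
    """Trio-phasing result for every offspring of a family.

    ``classes``, ``paternal`` and ``maternal`` have shape
    ``(n_offspring, n_loci)``; alleles are 0/1 for phased loci and
    :data:`UNPHASED` elsewhere. ``summary`` reports per-offspring phased
    fractions with the Mendelian-error loci both included in and excluded
    from the heterozygous-locus denominator.
    """

    offspring: list[str]
    loci: pd.DataFrame
    classes: np.ndarray
    paternal: np.ndarray
    maternal: np.ndarray
    summary: pd.DataFrame

    def phase_table(self) -> pd.DataFrame:
        """Long-form phased loci: ``sample, chrom, pos, paternal_allele``."""
        frames = []
        for i, sample in enumerate(self.offspring):
            mask = self.paternal[i] != UNPHASED
            frames.append(
                pd.DataFrame(
                    {
                        "sample": sample,
                        "chrom": self.loci.loc[mask, "chrom"].to_numpy(),
                        "pos": self.loci.loc[mask, "pos"].to_numpy(),
                        "paternal_allele": self.paternal[i, mask],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def read_pedigree(path: str) -> pd.DataFrame:
    """Read a pedigree TSV with columns ``id, sire, dam`` (extra columns such
    as sex/generation are kept); '0', '.' or empty mean unknown parent."""
    ped = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "sire", "dam"}
    if not required.issubset(ped.columns):
        raise ValueError(f"pedigree must have columns {sorted(required)}")
    for col in ("sire", "dam"):
        ped[col] = ped[col].replace({"0": None, ".": None, "": None})
    return ped


def phase_family(matrix: GenotypeMatrix, pedigree: pd.DataFrame) -> PhasedFamily:
    """Phase every genotyped individual whose sire and dam are both genotyped.

    Heterozygous offspring loci are classified per trio configuration;
    phasable loci receive paternal/maternal alleles. Mendelian-error and
    both-parents-het loci remain unphased.
    """
    known = set(matrix.samples)

    def declared(parent) -> bool:
        return pd.notna(parent) and parent not in ("0", ".", "")

    offspring = []
    for row in pedigree.itertuples(index=False):
        if row.id not in known or not (declared(row.sire) or declared(row.dam)):
            continue
        if not (declared(row.sire) and declared(row.dam)):
            raise ValueError(f"offspring {row.id}: pedigree names only one parent")
        if row.sire not in known or row.dam not in known:
            raise ValueError(f"offspring {row.id}: parents not both genotyped")
        offspring.append((row.id, row.sire, row.dam))
    if not offspring:
        raise ValueError("pedigree contains no genotyped trio")

    n = len(offspring)
    classes = np.empty((n, matrix.n_loci), dtype=np.int8)
    paternal = np.full((n, matrix.n_loci), UNPHASED, dtype=np.int8)
    maternal = np.full((n, matrix.n_loci), UNPHASED, dtype=np.int8)
    rows = []
    for i, (child, sire, dam) in enumerate(offspring):
        cls, pat, mat = classify_trios(
            matrix.vector(sire), matrix.vector(dam), matrix.vector(child)
        )
        classes[i], paternal[i], maternal[i] = cls, pat, mat
        counts = {c: int((cls == c).sum()) for c in TrioClass}
        n_phased = counts[TrioClass.PHASABLE_BOTH_HOM] + counts[TrioClass.PHASABLE_ONE_HET]
        n_het = n_phased + counts[TrioClass.UNPHASABLE_BOTH_HET] + counts[TrioClass.MENDELIAN_ERROR]
        n_het_excl = n_het - counts[TrioClass.MENDELIAN_ERROR]
        rows.append(
            {
                "sample": child,
                "sire": sire,
                "dam": dam,
                "n_het": n_het,
                "n_phased": n_phased,
                "n_unphasable": counts[TrioClass.UNPHASABLE_BOTH_HET],
                "n_mendelian_error": counts[TrioClass.MENDELIAN_ERROR],
                "n_incomplete": counts[TrioClass.INCOMPLETE],
                "phased_fraction": n_phased / n_het if n_het else np.nan,
                "phased_fraction_excl_me": n_phased / n_het_excl if n_het_excl else np.nan,
            }
        )
    return PhasedFamily(
        offspring=[o[0] for o in offspring],
        loci=matrix.loci,
        classes=classes,
        paternal=paternal,
        maternal=maternal,
        summary=pd.DataFrame(rows),
    )


def write_phased_vcf(family: PhasedFamily, matrix: GenotypeMatrix, path: str) -> None:
    """Write the family VCF with phased offspring genotypes.

    Phased offspring loci carry ``pat|mat`` genotypes; everything else stays
    unphased. A FORMAT field ``TC`` holds the trio-configuration class code
    for offspring samples ('.' for other family members).
    """
    unphased_gt = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    off_index = {s: i for i, s in enumerate(family.offspring)}
    loci = matrix.loci
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=TC,Number=1,Type=Integer,Description='
            '"Trio configuration class (0 not-het, 1 both-hom phasable, '
            '2 one-het phasable, 3 both-het unphasable, 4 mendelian error, 5 incomplete)">\n'
        )
        for chrom in loci["chrom"].unique():
            length = int(loci.loc[loci["chrom"] == chrom, "pos"].max()) + 10_000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.samples) + "\n")
        for j, (chrom, pos, ref, alt, depth) in enumerate(
            zip(loci["chrom"], loci["pos"], loci["ref"], loci["alt"], loci["depth"])
        ):
            fields = []
            for s, sample in enumerate(matrix.samples):
                g = int(matrix.genotypes[s, j])
                if sample in off_index:
                    i = off_index[sample]
                    if family.paternal[i, j] != UNPHASED:
                        gt = f"{family.paternal[i, j]}|{family.maternal[i, j]}"
                    else:
                        gt = unphased_gt[g]
                    fields.append(f"{gt}:{int(family.classes[i, j])}")
                else:
                    fields.append(f"{unphased_gt[g]}:.")
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tDP={int(depth)}\tGT:TC\t"
                + "\t".join(fields)
                + "\n"
            )
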