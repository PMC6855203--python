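"""Per-locus probability of heterozygosity (PHS) for crossbreeding schemes.

A crossbreeding scheme is a binary tree whose leaves are purebred
populations and whose internal nodes are matings (sire side x dam side),
e.g. the terminal three-way scheme DLY = Duroc x (Landrace x Yorkshire).
Under random mating and Mendelian transmission, the genotype distribution
of a cross depends on each side only through its transmitted
reference-allele frequency f:

    leaf:   f = p_homref + p_het / 2
    cross:  f = (f_sire + f_dam) / 2

and the offspring of the root cross with side frequencies ``f_s, f_d`` are

    P(hom-ref) = f_s f_d
    P(het)     = f_s (1 - f_d) + (1 - f_s) f_d      (= PHS)
    P(hom-alt) = (1 - f_s)(1 - f_d).

:func:`propagate_genotype_distribution` implements the slower route that
propagates full genotype distributions through every mating by enumerating
parental genotype pairs and gametes; it guards the closed form above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import LOCUS_COLUMNS, MISSING

N_BINS = 20
_BIN_WIDTH = 1.0 / N_BINS
# P(transmit reference allele | genotype code)
_GAMETE_REF = (1.0, 0.5, 0.0)


@dataclass(frozen=True)
class Cross:
    """A mating between two scheme subtrees (sire side, dam side)."""

    sire: "Cross | str"
    dam: "Cross | str"


@dataclass(frozen=True)
class CrossScheme:
    name: str
    root: Cross

    @classmethod
    def from_code(cls, code: str) -> "CrossScheme":
        """Build a scheme from a breed-letter code.

        A three-letter code ``ABC`` means the terminal cross A x (B x C);
        a two-letter code ``AB`` means the two-way cross A x B.
        """
        if len(code) == 3:
            root = Cross(code[0], Cross(code[1], code[2]))
        elif len(code) == 2:
            root = Cross(code[0], code[1])
        else:
            raise ValueError(f"scheme code must have 2 or 3 breed letters, got {code!r}")
        return cls(name=code, root=root)

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node) -> None:
            if isinstance(node, Cross):
                walk(node.sire)
                walk(node.dam)
            else:
                out.append(node)

        walk(self.root)
        return out


@dataclass
class PHSTable:
    """Per-locus offspring genotype distribution for one scheme.

    ``table`` has columns ``chrom, pos, ref, alt, pRR, pHet, pAA, phs``
    with ``phs == pHet``; loci with a missing frequency in any leaf breed
    are excluded and counted in ``n_excluded``.
    """

    scheme: str
    table: pd.DataFrame
    n_excluded: int

    @property
    def phs(self) -> np.ndarray:
        return self.table["phs"].to_numpy()


def transmitted_allele_frequency(node, freqs: pd.DataFrame) -> np.ndarray:
    """Per-locus probability that a random individual of this scheme node
    transmits the reference allele."""
    if isinstance(node, Cross):
        return 0.5 * (
            transmitted_allele_frequency(node.sire, freqs)
            + transmitted_allele_frequency(node.dam, freqs)
        )
    if node not in freqs.columns:
        raise KeyError(f"breed {node!r} not present in frequency table")
    return freqs[node].to_numpy(dtype=float)


def phs_for_scheme(scheme: CrossScheme, freqs: pd.DataFrame) -> PHSTable:
    """Compute the per-locus PHS table of a scheme from a wide frequency table
    (one transmitted-allele-frequency column per breed)."""
    if not isinstance(scheme.root, Cross):
        raise ValueError("a scheme must contain at least one cross")
    leaves = scheme.leaves()
    for leaf in leaves:
        if leaf not in freqs.columns:
            raise KeyError(f"breed {leaf!r} not present in frequency table")
    mask = freqs[leaves].notna().all(axis=1).to_numpy()
    sub = freqs.loc[mask].reset_index(drop=True)
    f_s = transmitted_allele_frequency(scheme.root.sire, sub)
    f_d = transmitted_allele_frequency(scheme.root.dam, sub)
    table = sub[LOCUS_COLUMNS].copy()
    table["pRR"] = f_s * f_d
    table["pHet"] = f_s * (1.0 - f_d) + (1.0 - f_s) * f_d
    table["pAA"] = (1.0 - f_s) * (1.0 - f_d)
    table["phs"] = table["pHet"]
    return PHSTable(scheme=scheme.name, table=table, n_excluded=int((~mask).sum()))


def propagate_genotype_distribution(node, genotype_freqs: dict[str, np.ndarray]) -> np.ndarray:
    """Reference route: propagate full genotype distributions through the tree.

    ``genotype_freqs`` maps breed -> array of shape (n_loci, 3) holding
    (p_homref, p_het, p_homalt). For a cross, every (sire genotype, dam
    genotype) pair is enumerated together with its gamete transmission
    probabilities. Returns the node's genotype distribution, shape (n_loci, 3).
    """
    if not isinstance(node, Cross):
        arr = np.asarray(genotype_freqs[node], dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("leaf genotype frequencies must have shape (n_loci, 3)")
        return arr
    ds = propagate_genotype_distribution(node.sire, genotype_freqs)
    dd = propagate_genotype_distribution(node.dam, genotype_freqs)
    out = np.zeros_like(ds)
    for gs in range(3):
        for gd in range(3):
            w = ds[:, gs] * dd[:, gd]
            ts, td = _GAMETE_REF[gs], _GAMETE_REF[gd]
            out[:, 0] += w * ts * td
            out[:, 1] += w * (ts * (1.0 - td) + (1.0 - ts) * td)
            out[:, 2] += w * (1.0 - ts) * (1.0 - td)
    return out


def bin_index(phs: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Bin index of PHS values over [0, 1]: half-open bins of width 1/n_bins,
    last bin closed. A small epsilon guards against values such as 0.35
    landing one float below a bin edge."""
    v = np.asarray(phs, dtype=float)
    idx = np.floor(v * n_bins + 1e-9).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def bin_phs_counts(table: PHSTable, n_bins: int = N_BINS) -> pd.DataFrame:
    """Count loci and mean PHS per bin. Columns: ``bin, left, right, n_loci,
    mean_phs`` (NaN mean for empty bins). Counts conserve the locus total."""
    phs = table.phs
    if phs.size == 0:
        raise ValueError(f"PHS table for scheme {table.scheme} is empty")
    idx = bin_index(phs, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=phs, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    width = 1.0 / n_bins
    return pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "left": np.arange(n_bins) * width,
            "right": (np.arange(n_bins) + 1) * width,
            "n_loci": counts,
            "mean_phs": means,
        }
    )


@dataclass
class SchemeComparison:
    """Pairwise Pearson correlation of per-bin locus counts between schemes."""

    r: pd.DataFrame
    p: pd.DataFrame

    def mean_r(self, reference: str) -> float:
        """Mean correlation of ``reference`` against every other scheme."""
        others = [s for s in self.r.columns if s != reference]
        return float(self.r.loc[reference, others].mean())


def scheme_pairwise_correlation(
    binnings: dict[str, pd.DataFrame], log_counts: bool = False
) -> SchemeComparison:
    """Pearson r (and two-sided p) between the per-bin SNP counts of each
    scheme pair. ``log_counts`` correlates log10(count + 1) instead of raw
    counts. Zero-variance count vectors yield NaN."""
    names = list(binnings)
    vectors = {}
    for name in names:
        v = binnings[name]["n_loci"].to_numpy(dtype=float)
        vectors[name] = np.log10(v + 1.0) if log_counts else v
    n = len(names)
    sizes = {len(v) for v in vectors.values()}
    if len(sizes) != 1:
        raise ValueError("all binnings must have the same number of bins")
    r = pd.DataFrame(np.eye(n), index=names, columns=names)
    p = pd.DataFrame(np.zeros((n, n)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va, vb = vectors[a], vectors[b]
            if np.ptp(va) == 0 or np.ptp(vb) == 0:
                rv, pv = np.nan, np.nan
            else:
                res = stats.pearsonr(va, vb)
                rv, pv = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return SchemeComparison(r=r, p=p)


def expected_het_by_bin(table: PHSTable, n_bins: int = N_BINS) -> pd.Series:
    """Mean PHS within each bin (NaN for empty bins) — the simulated-offspring
    heterozygosity curve."""
    binned = bin_phs_counts(table, n_bins)
    return pd.Series(binned["mean_phs"].to_numpy(), index=binned["bin"], name="mean_phs")


@dataclass
class ObservedHetFit:
    """Observed per-bin heterozygote fraction of one individual and its
    Pearson correlation against the expected (bin-mean PHS) curve."""

    per_bin: pd.DataFrame
    r: float
    p_value: float


def observed_het_by_bin(
    genotypes: np.ndarray, table: PHSTable, n_bins: int = N_BINS
) -> ObservedHetFit:
    """Fraction of heterozygous genotypes of one individual in each PHS bin.

    ``genotypes`` must be aligned with ``table.table`` rows (missing = -1).
    The correlation is computed over bins that contain at least one called
    genotype and are non-empty in the expected curve.
    """
    geno = np.asarray(genotypes)
    if geno.shape[0] != len(table.table):
        raise ValueError("genotype vector is not aligned with the PHS table")
    idx = bin_index(table.phs, n_bins)
    called = geno != MISSING
    n_called = np.bincount(idx[called], minlength=n_bins)
    n_het = np.bincount(idx[called & (geno == 1)], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_called > 0, n_het / n_called, np.nan)
    expected = expected_het_by_bin(table, n_bins).to_numpy()
    per_bin = pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "n_loci": np.bincount(idx, minlength=n_bins),
            "n_called": n_called,
            "n_het": n_het,
            "obs_het_fraction": frac,
            "mean_phs": expected,
        }
    )
    ok = (n_called > 0) & ~np.isnan(expected)
    if ok.sum() >= 2 and np.ptp(frac[ok]) > 0 and np.ptp(expected[ok]) > 0:
        res = stats.pearsonr(frac[ok], expected[ok])
        r, p = float(res.statistic), float(res.pvalue)
    else:
        r, p = np.nan, np.nan
    return ObservedHetFit(per_bin=per_bin, r=r, p_value=p)


def high_phs_markers(table: PHSTable, threshold: float = 0.9) -> pd.DataFrame:
    """Loci with PHS strictly greater than ``threshold`` — candidate markers
    expected heterozygous in nearly every crossbred offspring."""
    out = table.table.loc[table.table["phs"] > threshold, LOCUS_COLUMNS + ["phs"]]
    order = np.lexsort((out["pos"].to_numpy(), out["chrom"].to_numpy()))
    return out.iloc[order].reset_index(drop=True)
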