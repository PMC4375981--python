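"""Per-SNP F_ST, the genome-wide empirical null, and the Q_ST divergence test.

F_ST is estimated per SNP with the Weir & Cockerham (1984) theta across all
populations (variance components a, b, c for diploid samples with unequal
sizes, using observed heterozygote counts; no Hardy–Weinberg assumption).
A "mean pairwise" mode averaging theta over all population pairs is also
available.  The empirical distribution of the per-SNP estimates supplies a
neutral-divergence threshold (the 99th percentile by default): a trait
whose Q_ST point estimate exceeds it is flagged as a candidate for
divergent selection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gardenqg.exceptions import DegenerateInputError

MISSING = -1  # dosage sentinel


@dataclass
class GenotypeMatrix:
    """Diploid SNP dosages (individuals x SNPs) with population labels."""

    dosages: np.ndarray            # int8/int16, values {0,1,2,MISSING}
    populations: np.ndarray        # population label per individual
    snp_ids: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        self.populations = np.asarray(self.populations)
        self.snp_ids = np.asarray(self.snp_ids)
        n, m = self.dosages.shape
        if len(self.populations) != n:
            raise ValueError("population labels do not match individual count")
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids do not match SNP count")
        valid = np.isin(self.dosages, [0, 1, 2, MISSING])
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or the missing sentinel")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    # --- I/O ---------------------------------------------------------------

    def to_dosage_csv(self, path) -> None:
        df = pd.DataFrame(self.dosages, columns=self.snp_ids)
        df.insert(0, "population", self.populations)
        df.to_csv(path, index_label="individual")

    @classmethod
    def from_dosage_csv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col=0)
        pops = df.pop("population").to_numpy()
        return cls(
            dosages=df.to_numpy(dtype=np.int16),
            populations=pops,
            snp_ids=df.columns.to_numpy(),
        )

    def to_vcf(self, path) -> None:
        """Write a minimal uncompressed VCFv4.2 (REF=A, ALT=C, GT only)."""
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        samples = [f"ind{i}" for i in range(self.n_individuals)]
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=gardenqg\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("##contig=<ID=1>\n")
            for i, ind in enumerate(samples):
                fh.write(f"##SAMPLE=<ID={ind},Population={self.populations[i]}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(samples) + "\n")
            for j in range(self.n_snps):
                gts = "\t".join(gt_map[int(d)] for d in self.dosages[:, j])
                fh.write(f"1\t{j + 1}\t{self.snp_ids[j]}\tA\tC\t.\t.\t.\tGT\t{gts}\n")

    @classmethod
    def from_vcf(cls, path, populations) -> "GenotypeMatrix":
        """Read biallelic SNPs from a VCF; multi-allelic records are skipped.

        ``populations`` maps sample name -> population, or is an array in
        sample order.
        """
        from cyvcf2 import VCF  # optional dependency, imported lazily

        vcf = VCF(str(path))
        samples = vcf.samples
        if isinstance(populations, dict):
            pops = np.asarray([populations[s] for s in samples])
        else:
            pops = np.asarray(populations)
            if len(pops) != len(samples):
                raise ValueError("population array does not match VCF samples")
        cols, ids, n_skipped = [], [], 0
        for var in vcf:
            if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
                n_skipped += 1
                continue
            g = var.genotype.array()[:, :2]
            dos = np.where((g < 0).any(axis=1), MISSING, g.clip(min=0).sum(axis=1))
            cols.append(dos.astype(np.int16))
            ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        mat = cls(
            dosages=np.column_stack(cols) if cols else np.empty((len(samples), 0), int),
            populations=pops,
            snp_ids=np.asarray(ids, dtype=object),
        )
        mat.n_multiallelic_skipped = n_skipped
        return mat


# --- Weir–Cockerham estimator ---------------------------------------------


def _population_counts(matrix: GenotypeMatrix):
    """Per-population allele statistics for every SNP.

    Returns (n, p, h): population x SNP arrays of genotyped-individual
    counts, alternate-allele frequencies and observed heterozygosities.
    """
    pops = np.unique(matrix.populations)
    dos = matrix.dosages
    called = dos != MISSING
    n = np.empty((len(pops), matrix.n_snps))
    alt = np.empty_like(n)
    het = np.empty_like(n)
    for i, pop in enumerate(pops):
        rows = matrix.populations == pop
        sub = dos[rows]
        ok = called[rows]
        n[i] = ok.sum(axis=0)
        alt[i] = np.where(ok, sub, 0).sum(axis=0)
        het[i] = (ok & (sub == 1)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)
        h = het / n
    return n, p, h


def weir_cockerham_components(n, p, h):
    """WC84 variance components (a, b, c) for diploid multi-population data.

    Parameters are population x SNP arrays: sample sizes in individuals
    (n), alternate-allele frequencies (p) and observed heterozygote
    proportions (h).  Populations with no data at a SNP are ignored
    (complete-case per SNP).  Returns per-SNP (a, b, c, r_eff) with r_eff
    the number of populations contributing.
    """
    n = np.atleast_2d(np.asarray(n, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    h = np.atleast_2d(np.asarray(h, dtype=float))
    has = n > 0
    r = has.sum(axis=0).astype(float)
    n_sum = np.where(has, n, 0.0).sum(axis=0)
    nbar = n_sum / r
    n2_sum = np.where(has, n**2, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_sum - n2_sum / n_sum) / (r - 1.0)
        pbar = np.where(has, n * p, 0.0).sum(axis=0) / n_sum
        s2 = np.where(has, n * (p - pbar) ** 2, 0.0).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = np.where(has, n * h, 0.0).sum(axis=0) / n_sum
        inner = (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - hbar / 4.0
        )
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    return a, b, c, r


def snp_fst(matrix: GenotypeMatrix, snp, estimator: str = "wc") -> float:
    """F_ST for a single SNP (by id or column index).

    ``estimator="wc"``: multi-population Weir–Cockerham theta.
    ``estimator="pairwise_mean"``: mean of theta over all population pairs.

    Raises
    ------
    DegenerateInputError
        If the SNP is monomorphic in the analyzed sample.
    """
    if isinstance(snp, (int, np.integer)):
        j = int(snp)
    else:
        hits = np.nonzero(matrix.snp_ids == snp)[0]
        if not len(hits):
            raise KeyError(f"unknown SNP id: {snp!r}")
        j = int(hits[0])
    sub = GenotypeMatrix(
        matrix.dosages[:, [j]], matrix.populations, matrix.snp_ids[[j]]
    )
    theta, used = per_snp_fst(sub, estimator=estimator)
    if not used[0]:
        raise DegenerateInputError(f"SNP {matrix.snp_ids[j]!r} is monomorphic or unusable")
    return float(theta[0])


def per_snp_fst(matrix: GenotypeMatrix, estimator: str = "wc"):
    """Vectorized per-SNP F_ST.

    Returns (theta, usable): theta is NaN where a SNP is monomorphic in
    the analyzed sample or fewer than two populations have data.
    """
    n, p, h = _population_counts(matrix)
    if estimator == "wc":
        theta, usable = _theta_from_counts(n, p, h)
    elif estimator == "pairwise_mean":
        n_pop = n.shape[0]
        acc = np.zeros(matrix.n_snps)
        cnt = np.zeros(matrix.n_snps)
        for i, k in itertools.combinations(range(n_pop), 2):
            th, ok = _theta_from_counts(n[[i, k]], p[[i, k]], h[[i, k]])
            acc += np.where(ok, th, 0.0)
            cnt += ok
        usable = cnt > 0
        with np.errstate(invalid="ignore"):
            theta = np.where(usable, acc / np.maximum(cnt, 1), np.nan)
    else:
        raise ValueError(f"unknown estimator: {estimator!r}")
    return theta, usable


def _theta_from_counts(n, p, h):
    a, b, c, r = weir_cockerham_components(n, p, h)
    n_sum = np.where(n > 0, n, 0.0).sum(axis=0)
    alt_total = np.where(n > 0, 2.0 * n * p, 0.0).sum(axis=0)
    segregating = (alt_total > 0) & (alt_total < 2.0 * n_sum)
    denom = a + b + c
    usable = (r >= 2) & segregating & np.isfinite(denom) & (denom != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(usable, a / denom, np.nan)
    return theta, usable


@dataclass
class FstDistribution:
    """Empirical genome-wide F_ST distribution and its tail threshold."""

    per_snp_fst: np.ndarray
    n_used: int
    percentile_99: float
    estimator: str = "wc"
    n_excluded: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_snp_fst))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "estimator": self.estimator,
                "n_used": self.n_used,
                "n_excluded": self.n_excluded,
                "mean_fst": self.mean,
                "percentile_99": self.percentile_99,
            }]
        )


def empirical_distribution(
    matrix: GenotypeMatrix, estimator: str = "wc", percentile: float = 99.0
) -> FstDistribution:
    """Per-SNP F_ST over the panel and its empirical tail percentile.

    The percentile uses the linear-interpolation convention of
    ``numpy.percentile``.  Negative per-SNP estimates (standard for the WC
    theta near zero differentiation) are retained.  Fewer than 100 usable
    SNPs triggers a warning but the distribution is still returned.
    """
    theta, usable = per_snp_fst(matrix, estimator=estimator)
    vals = theta[usable]
    if len(vals) < 100:
        import warnings

        warnings.warn(
            f"only {len(vals)} usable SNPs; the {percentile}th percentile "
            "will be noisy",
            stacklevel=2,
        )
    if len(vals) == 0:
        raise DegenerateInputError("no usable SNPs in the panel")
    return FstDistribution(
        per_snp_fst=vals,
        n_used=int(len(vals)),
        percentile_99=float(np.percentile(vals, percentile)),
        estimator=estimator,
        n_excluded=int((~usable).sum()),
    )


@dataclass
class DivergenceReport:
    """Per-trait Q_ST vs the empirical F_ST tail threshold."""

    table: pd.DataFrame
    percentile_99: float

    def exceeding(self) -> list[str]:
        return self.table.loc[self.table["exceeds"], "trait"].tolist()


def classify_traits(qst_records, dist: FstDistribution) -> DivergenceReport:
    """Label each trait by whether its Q_ST exceeds the F_ST threshold."""
    if not qst_records:
        raise ValueError("no Q_ST records to classify")
    rows = [
        {
            "trait": rec.trait,
            "qst": rec.qst,
            "fst_percentile_99": dist.percentile_99,
            "exceeds": bool(rec.qst > dist.percentile_99),
        }
        for rec in qst_records
    ]
    return DivergenceReport(table=pd.DataFrame(rows), percentile_99=dist.percentile_99)
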