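"""Genotype containers, PLINK text I/O, quality control, and the genomic
relationship matrix.

Genotypes are held as counts of the minor allele (0/1/2, missing = -1) in an
``individuals x SNPs`` integer array with a per-SNP map (id, chromosome, bp).
The marker matrix M centres each column by twice the allele frequency, and
the genomic relationship matrix follows VanRaden:

    G = M M' / (2 * sum_i p_i (1 - p_i))
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "MarkerMatrix",
    "GRM",
    "QCThresholds",
    "QCReport",
    "read_plink_text",
    "write_plink_text",
    "apply_qc",
    "build_marker_matrix",
    "compute_grm",
]


class GenotypeParseError(ValueError):
    """Malformed PLINK text input (names the offending line)."""


@dataclass
class GenotypeMatrix:
    """Raw genotype codes with SNP map and optional per-genotype quality.

    Parameters
    ----------
    codes
        ``(n_individuals, n_snps)`` int array of minor-allele counts in
        {0, 1, 2}; missing genotypes are coded ``-1``.
    snp_map
        DataFrame with columns ``id``, ``chrom`` (string label), ``bp``
        (1-based position).
    individual_ids
        One identifier per row of ``codes``.
    quality
        Optional ``(n_individuals, n_snps)`` array of per-genotype call
        scores in [0, 1] (GenCall-like).
    alleles
        Optional per-SNP (minor, major) allele labels used when writing
        PLINK text files.
    """

    codes: np.ndarray
    snp_map: pd.DataFrame
    individual_ids: list[str]
    quality: np.ndarray | None = None
    alleles: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x SNPs)")
        n, m = self.codes.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match codes rows")
        if len(self.snp_map) != m:
            raise ValueError("snp_map rows do not match codes columns")
        valid = np.isin(self.codes, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("codes must be in {0,1,2} or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def allele_freqs(self) -> np.ndarray:
        """Per-SNP frequency of the counted (minor) allele, ignoring missing."""
        codes = np.where(self.missing_mask, np.nan, self.codes.astype(float))
        with np.errstate(invalid="ignore"):
            return np.nanmean(codes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        alleles = None
        if self.alleles is not None:
            idx = np.flatnonzero(keep) if keep.dtype == bool else keep
            alleles = [self.alleles[i] for i in idx]
        return GenotypeMatrix(
            codes=self.codes[:, keep],
            snp_map=self.snp_map.loc[keep].reset_index(drop=True)
            if keep.dtype == bool
            else self.snp_map.iloc[keep].reset_index(drop=True),
            individual_ids=list(self.individual_ids),
            quality=None if self.quality is None else self.quality[:, keep],
            alleles=alleles,
        )


@dataclass
class MarkerMatrix:
    """Real-valued marker matrix M with the allele frequencies it was built from."""

    M: np.ndarray
    freqs: np.ndarray
    centered: bool

    @property
    def N(self) -> int:
        return self.M.shape[1]


@dataclass
class GRM:
    """VanRaden genomic relationship matrix and its scaling denominator."""

    G: np.ndarray
    denominator: float


@dataclass
class QCThresholds:
    """Marker quality-control thresholds.

    Defaults follow common SNP-chip practice: genotypes with call score
    below 0.15 are set missing, then unmapped and Y-chromosome SNPs are
    dropped, then SNPs with more than 5% missing genotypes, then SNPs with
    minor allele frequency strictly below 1%.
    """

    min_quality: float = 0.15
    max_missing: float = 0.05
    min_maf: float = 0.01
    exclude_unmapped: bool = True
    exclude_y: bool = True


@dataclass
class QCReport:
    n_input_snps: int
    n_low_quality_genotypes: int = 0
    n_removed_unmapped: int = 0
    n_removed_y: int = 0
    n_removed_missing: int = 0
    n_removed_maf: int = 0
    n_retained_snps: int = 0
    n_retained_individuals: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_removed_snps(self) -> int:
        return (
            self.n_removed_unmapped
            + self.n_removed_y
            + self.n_removed_missing
            + self.n_removed_maf
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input_snps", self.n_input_snps),
            ("low_quality_genotypes_set_missing", self.n_low_quality_genotypes),
            ("removed_unmapped", self.n_removed_unmapped),
            ("removed_y_chromosome", self.n_removed_y),
            ("removed_high_missingness", self.n_removed_missing),
            ("removed_low_maf", self.n_removed_maf),
            ("retained_snps", self.n_retained_snps),
            ("retained_individuals", self.n_retained_individuals),
        ]
        return pd.DataFrame(rows, columns=["filter", "count"])


# ---------------------------------------------------------------------------
# PLINK text I/O
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text .ped/.map files into a :class:`GenotypeMatrix`.

    Allele pairs are recoded to counts of the minor allele; "0 0" becomes
    missing. The minor allele is the less frequent one at each SNP; an
    exact 50/50 tie is broken in favour of the allele seen first in file
    order.
    """
    snp_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise GenotypeParseError(
                    f"{map_path}:{lineno}: expected 3 or 4 columns, got {len(parts)}"
                )
            chrom, snp_id = parts[0], parts[1]
            bp = int(parts[-1])
            snp_rows.append((snp_id, chrom, bp))
    snp_map = pd.DataFrame(snp_rows, columns=["id", "chrom", "bp"])
    n_snps = len(snp_map)

    individual_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 6 or (len(parts) - 6) % 2 != 0:
                raise GenotypeParseError(
                    f"{ped_path}:{lineno}: ragged line ({len(parts)} fields)"
                )
            n_pairs = (len(parts) - 6) // 2
            if n_pairs != n_snps:
                raise GenotypeParseError(
                    f"{ped_path}:{lineno}: {n_pairs} genotype pairs but "
                    f"{n_snps} SNPs in {map_path}"
                )
            individual_ids.append(parts[1])
            allele_rows.append(parts[6:])

    n_ind = len(individual_ids)
    codes = np.full((n_ind, n_snps), MISSING, dtype=np.int16)
    alleles_out: list[tuple[str, str]] = []
    for j in range(n_snps):
        counts: dict[str, int] = {}
        order: list[str] = []
        col = []
        for i in range(n_ind):
            a1 = allele_rows[i][2 * j]
            a2 = allele_rows[i][2 * j + 1]
            col.append((a1, a2))
            for a in (a1, a2):
                if a == "0":
                    continue
                if a not in counts:
                    counts[a] = 0
                    order.append(a)
                counts[a] += 1
        if len(counts) > 2:
            raise GenotypeParseError(
                f"SNP {snp_map['id'][j]} (column {j + 1}) is not biallelic: "
                f"alleles {sorted(counts)}"
            )
        if not counts:  # entirely missing column
            alleles_out.append(("A", "B"))
            continue
        if len(counts) == 1:
            minor, major = order[0], order[0]
        else:
            a, b = order
            if counts[a] < counts[b]:
                minor, major = a, b
            elif counts[b] < counts[a]:
                minor, major = b, a
            else:  # tie: first seen wins
                minor, major = a, b
        alleles_out.append((minor, major if major != minor else "B"))
        for i, (a1, a2) in enumerate(col):
            if a1 == "0" or a2 == "0":
                codes[i, j] = MISSING
            else:
                codes[i, j] = int(a1 == minor) + int(a2 == minor)

    return GenotypeMatrix(
        codes=codes,
        snp_map=snp_map,
        individual_ids=individual_ids,
        alleles=alleles_out,
    )


def write_plink_text(geno: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PLINK text .ped/.map. Round-trips bit-exactly with
    :func:`read_plink_text` for files whose coded allele is minor (or ties
    broken by first appearance)."""
    with open(map_path, "w") as fh:
        for _, row in geno.snp_map.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['bp']}\n")
    alleles = geno.alleles or [("A", "B")] * geno.n_snps
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(geno.individual_ids):
            fields = [str(ind), str(ind), "0", "0", "0", "-9"]
            for j in range(geno.n_snps):
                c = geno.codes[i, j]
                minor, major = alleles[j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [major, major]
                elif c == 1:
                    fields += [minor, major]
                else:
                    fields += [minor, minor]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def apply_qc(
    geno: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply marker QC in the order: call-score masking, unmapped / Y-chromosome
    removal, missingness, minor allele frequency.

    Each SNP is attributed to the first filter it fails. MAF uses a strict
    "less than" rule, so a SNP at exactly the threshold is retained. QC is
    idempotent: a second pass removes nothing.
    """
    thr = thresholds or QCThresholds()
    report = QCReport(n_input_snps=geno.n_snps)

    codes = geno.codes.copy()
    if geno.quality is not None:
        low = (geno.quality < thr.min_quality) & (codes != MISSING)
        report.n_low_quality_genotypes = int(low.sum())
        codes[low] = MISSING

    chrom = geno.snp_map["chrom"].astype(str).str.upper().to_numpy()
    bp = geno.snp_map["bp"].to_numpy()
    removed = np.zeros(geno.n_snps, dtype=bool)

    if thr.exclude_unmapped:
        unmapped = (chrom == "0") | (chrom == "") | (bp <= 0)
        report.n_removed_unmapped = int(unmapped.sum())
        removed |= unmapped
    if thr.exclude_y:
        is_y = (chrom == "Y") & ~removed
        report.n_removed_y = int(is_y.sum())
        removed |= is_y

    miss_frac = (codes == MISSING).mean(axis=0)
    high_miss = (miss_frac > thr.max_missing) & ~removed
    report.n_removed_missing = int(high_miss.sum())
    removed |= high_miss

    with np.errstate(invalid="ignore"):
        p = np.nanmean(np.where(codes == MISSING, np.nan, codes.astype(float)), axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    low_maf = (np.nan_to_num(maf, nan=0.0) < thr.min_maf) & ~removed
    report.n_removed_maf = int(low_maf.sum())
    removed |= low_maf

    keep = ~removed
    out = GenotypeMatrix(
        codes=codes[:, keep],
        snp_map=geno.snp_map.loc[keep].reset_index(drop=True),
        individual_ids=list(geno.individual_ids),
        quality=None if geno.quality is None else geno.quality[:, keep],
        alleles=None
        if geno.alleles is None
        else [geno.alleles[i] for i in np.flatnonzero(keep)],
    )
    report.n_retained_snps = out.n_snps
    report.n_retained_individuals = out.n_individuals
    if out.n_snps == 0:
        report.warnings.append("all SNPs removed by QC")
    return out, report


# ---------------------------------------------------------------------------
# Marker matrix and GRM
# ---------------------------------------------------------------------------

def build_marker_matrix(geno: GenotypeMatrix, center: bool = True) -> MarkerMatrix:
    """Build M from genotype codes.

    Missing cells are imputed to the column mean (2 p_i) before optional
    centering by 2 p_i, which preserves the allele frequency and leaves
    imputed cells at zero in the centered matrix.
    """
    codes = np.where(geno.missing_mask, np.nan, geno.codes.astype(float))
    with np.errstate(invalid="ignore"):
        p = np.nanmean(codes, axis=0) / 2.0
    if np.any(np.isnan(p)) or np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError(
            "monomorphic or all-missing SNP present; apply QC before building M"
        )
    M = np.where(np.isnan(codes), 2.0 * p, codes)
    if center:
        M = M - 2.0 * p
    return MarkerMatrix(M=M, freqs=p, centered=center)


def compute_grm(mm: MarkerMatrix) -> GRM:
    """VanRaden G = M M' / (2 sum p_i (1 - p_i))."""
    p = mm.freqs
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("zero GRM denominator: no polymorphic SNPs")
    G = (mm.M @ mm.M.T) / denom
    G = 0.5 * (G + G.T)  # enforce exact symmetry
    return GRM(G=G, denominator=denom)


def blend_grm(grm: GRM, weight: float = 0.99) -> GRM:
    """Condition G for inversion: G <- w*G + (1-w)*I (deterministic)."""
    n = grm.G.shape[0]
    return GRM(G=weight * grm.G + (1.0 - weight) * np.eye(n), denominator=grm.denominator)


def write_grm_tsv(grm: GRM, ids: list[str], path) -> None:
    df = pd.DataFrame(grm.G, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format="%.10g")
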