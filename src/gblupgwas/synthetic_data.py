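"""Synthetic genotypes and phenotypes with the generative structure of the
GBLUP association models.

Two trait families are emulated, mirroring the reproductive count traits the
models target:

* a stillbirth-like count trait: population mean about 1.2 per litter,
  repeated litters per sow sharing additive and permanent-environment
  effects, herd-year-season and parity as fixed effects, modelled on the
  log-latent scale;
* a teat-number-like trait: mean about 15.3, one record per animal,
  herd-year-season and sex fixed effects, well approximated as Gaussian.

Genotypes are drawn gamete-wise. Local linkage disequilibrium uses a
first-order Markov copying scheme: each gamete carries a latent uniform that
is copied from the previous SNP with probability ``ld_decay`` and refreshed
otherwise, so the marginal allele frequency at every SNP is exact while
adjacent SNPs are positively correlated with geometrically decaying range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, build_marker_matrix

__all__ = [
    "SimConfig",
    "TrueValues",
    "PhenotypeTable",
    "simulate_genotypes",
    "simulate_gaussian_trait",
    "simulate_poisson_trait",
]

SNP_SPACING_BP = 65_000  # chip-like average inter-SNP distance


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Settings for one synthetic dataset.

    ``fixed_effect_levels`` maps an effect name to the trait-scale (latent
    scale for the Poisson family) values of its levels; levels are assigned
    to records uniformly at random. The first level of each effect acts as
    the reference in downstream design matrices.
    """

    n_individuals: int = 200
    n_snps_per_chrom: list[int] = field(default_factory=lambda: [500])
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.0
    n_qtl: int = 10
    var_additive: float = 0.3575
    var_permanent: float = 0.33
    var_residual: float = 3.9125
    fixed_effect_levels: dict[str, list[float]] = field(default_factory=dict)
    records_per_individual: int = 1
    family: str = "gaussian"
    intercept: float = 0.0
    missing_rate: float = 0.0
    round_gaussian: bool = False
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimConfigError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.n_individuals <= 0 or any(m <= 0 for m in self.n_snps_per_chrom):
            raise SimConfigError("dimensions must be positive")
        if not (0.0 <= self.ld_decay < 1.0):
            raise SimConfigError("ld_decay must be in [0, 1)")
        if min(self.var_additive, self.var_permanent, self.var_residual) < 0:
            raise SimConfigError("variances must be nonnegative")
        if self.records_per_individual < 1:
            raise SimConfigError("records_per_individual must be >= 1")
        if self.n_qtl > sum(self.n_snps_per_chrom):
            raise SimConfigError("n_qtl exceeds total SNP count")
        if self.family not in ("gaussian", "poisson"):
            raise SimConfigError(f"unknown family {self.family!r}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimConfigError("missing_rate must be in [0, 1)")


@dataclass
class TrueValues:
    """Ground truth underlying one simulated trait, for recovery tests."""

    beta_true: np.ndarray
    u_true: np.ndarray
    p_true: np.ndarray
    alpha_true: np.ndarray
    qtl_indices: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = len(self.alpha_true)
        df = pd.DataFrame({"snp_index": np.arange(n), "alpha_true": self.alpha_true})
        df["is_qtl"] = np.isin(np.arange(n), self.qtl_indices)
        return df


@dataclass
class PhenotypeTable:
    """Observations with their record-to-individual map and fixed-effect labels."""

    y: np.ndarray
    individual: np.ndarray  # individual id per record
    fixed: pd.DataFrame  # one categorical column per fixed effect
    record_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.individual = np.asarray(self.individual)
        if self.record_id is None:
            self.record_id = np.arange(len(self.y))
        if len(self.fixed) != len(self.y) or len(self.individual) != len(self.y):
            raise ValueError("phenotype table columns have inconsistent lengths")

    @property
    def n_records(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.individual, "record_id": self.record_id, "y": self.y})
        for col in self.fixed.columns:
            df[col] = self.fixed[col].to_numpy()
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhenotypeTable":
        fixed_cols = [c for c in df.columns if c not in ("id", "record_id", "y")]
        return cls(
            y=df["y"].to_numpy(dtype=float),
            individual=df["id"].to_numpy(),
            fixed=df[fixed_cols].astype(str).reset_index(drop=True),
            record_id=df["record_id"].to_numpy() if "record_id" in df else None,
        )

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"id": str}))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw genotypes gamete-wise with per-SNP MAF uniform in ``maf_range``.

    Deterministic for a fixed config (seeded); positions are laid out on an
    even chip-like grid of 65 kb within each chromosome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    all_codes = []
    map_rows = []
    for c, n_snps in enumerate(config.n_snps_per_chrom, start=1):
        freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_snps)
        gametes = np.empty((2 * n, n_snps), dtype=np.int16)
        u = rng.uniform(size=2 * n)
        gametes[:, 0] = u < freqs[0]
        for j in range(1, n_snps):
            fresh = rng.uniform(size=2 * n)
            copy = rng.uniform(size=2 * n) < config.ld_decay
            u = np.where(copy, u, fresh)
            gametes[:, j] = u < freqs[j]
        all_codes.append(gametes[0::2] + gametes[1::2])
        for j in range(n_snps):
            map_rows.append((f"SNP{c}_{j + 1}", str(c), (j + 1) * SNP_SPACING_BP))

    codes = np.hstack(all_codes)
    if config.missing_rate > 0:
        miss = rng.uniform(size=codes.shape) < config.missing_rate
        codes[miss] = MISSING

    return GenotypeMatrix(
        codes=codes,
        snp_map=pd.DataFrame(map_rows, columns=["id", "chrom", "bp"]),
        individual_ids=[f"ind{i + 1}" for i in range(n)],
    )


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def _draw_effects(geno: GenotypeMatrix, config: SimConfig, rng: np.random.Generator):
    """QTL effects, genetic values, PE effects and fixed-effect assignment."""
    n = geno.n_individuals
    n_snps = geno.n_snps

    alpha = np.zeros(n_snps)
    u = np.zeros(n)
    qtl_idx = np.sort(rng.choice(n_snps, size=config.n_qtl, replace=False)) if config.n_qtl else np.array([], dtype=int)
    if config.var_additive > 0 and config.n_qtl > 0:
        mm = build_marker_matrix(geno, center=True)
        raw = rng.standard_normal(config.n_qtl)
        u_raw = mm.M[:, qtl_idx] @ raw
        v = u_raw.var()
        scale = np.sqrt(config.var_additive / v) if v > 0 else 0.0
        alpha[qtl_idx] = raw * scale
        u = mm.M @ alpha  # equals u_raw * scale plus exact zeros elsewhere

    p_eff = np.zeros(n)
    has_pe = config.records_per_individual > 1
    if has_pe and config.var_permanent > 0:
        p_eff = rng.normal(0.0, np.sqrt(config.var_permanent), size=n)

    r = config.records_per_individual
    ind_index = np.repeat(np.arange(n), r)
    n_rec = n * r

    fixed_cols = {}
    beta_parts = [np.array([config.intercept])]
    eta_fixed = np.full(n_rec, config.intercept)
    for name, levels in config.fixed_effect_levels.items():
        values = np.asarray(levels, dtype=float)
        assign = rng.integers(0, len(values), size=n_rec)
        fixed_cols[name] = pd.Categorical.from_codes(
            assign, categories=[f"{name}{k + 1}" for k in range(len(values))]
        ).astype(str)
        eta_fixed = eta_fixed + values[assign]
        beta_parts.append(values)
    fixed = pd.DataFrame(fixed_cols, index=range(n_rec))
    beta_true = np.concatenate(beta_parts)

    truth = TrueValues(
        beta_true=beta_true,
        u_true=u,
        p_true=p_eff,
        alpha_true=alpha,
        qtl_indices=qtl_idx,
    )
    return ind_index, eta_fixed, truth, fixed


def _latent(geno, config, rng):
    ind_index, eta_fixed, truth, fixed = _draw_effects(geno, config, rng)
    n_rec = len(ind_index)
    e = (
        rng.normal(0.0, np.sqrt(config.var_residual), size=n_rec)
        if config.var_residual > 0
        else np.zeros(n_rec)
    )
    lat = eta_fixed + truth.u_true[ind_index] + truth.p_true[ind_index] + e
    ids = np.asarray(geno.individual_ids)[ind_index]
    return lat, ids, truth, fixed


def simulate_gaussian_trait(
    geno: GenotypeMatrix, config: SimConfig
) -> tuple[PhenotypeTable, TrueValues]:
    """y = Xb + Zu (+ Wp for repeated records) + e with the configured variances."""
    config.validate()
    if config.family != "gaussian":
        raise SimConfigError("simulate_gaussian_trait requires family='gaussian'")
    rng = np.random.default_rng(config.seed + 1)
    y, ids, truth, fixed = _latent(geno, config, rng)
    if config.round_gaussian:
        y = np.rint(y)
    pheno = PhenotypeTable(y=y, individual=ids, fixed=fixed)
    return pheno, truth


def simulate_poisson_trait(
    geno: GenotypeMatrix, config: SimConfig
) -> tuple[PhenotypeTable, TrueValues]:
    """Counts y_i ~ Poisson(exp(l_i)) with the latent l built as in the
    Gaussian model; repeated records share their individual's u and p."""
    config.validate()
    if config.family != "poisson":
        raise SimConfigError("simulate_poisson_trait requires family='poisson'")
    rng = np.random.default_rng(config.seed + 1)
    lat, ids, truth, fixed = _latent(geno, config, rng)
    if np.max(lat) > 30.0:
        raise FloatingPointError(
            f"latent value {np.max(lat):.2f} would overflow the Poisson rate "
            "(exp(l) too large); reduce intercept or variances"
        )
    y = rng.poisson(np.exp(lat)).astype(float)
    pheno = PhenotypeTable(y=y, individual=ids, fixed=fixed)
    return pheno, truth


def write_true_values_tsv(truth: TrueValues, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)
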