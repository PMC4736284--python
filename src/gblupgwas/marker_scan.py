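"""Per-SNP posterior effects back-solved from GEBV samples, with HPD and
PPN0 significance calls.

At every retained MCMC iteration k the GEBV vector u^(k) is converted to a
vector of allele-substitution effects through the SNP-BLUP identity

    alpha^(k) = M' (M M')^- u^(k),

with (M M')^- a pseudo-inverse computed once and reused. Each SNP's retained
chain of alpha samples is then summarized by its 95% highest posterior
density interval (declared significant when zero falls outside) and by
PPN0, the posterior probability that the effect is greater than zero for
positive posterior means or smaller than zero for negative ones (declared
significant when strictly above 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes_gblup import ChainStore, geweke_diagnostic
from .genotype_io import MarkerMatrix

__all__ = [
    "SNPEffectChains",
    "backsolve_effects",
    "hpd_interval",
    "posterior_prob_nonzero",
    "summarize_scan",
]

PINV_RTOL = 1e-10


@dataclass
class SNPEffectChains:
    """Retained-iterations x N matrix of per-SNP effect samples."""

    alpha: np.ndarray
    snp_ids: list[str]

    @property
    def n_retained(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alpha.shape[1]


def backsolve_effects(chains: ChainStore, mm: MarkerMatrix, snp_ids=None) -> SNPEffectChains:
    """alpha^(k) = M'(MM')^- u^(k) for every retained GEBV sample.

    M must be the same (same centering) matrix used to build G. When MM' is
    full rank the back-solve is an exact projection: M alpha^(k) = u^(k).
    """
    M = mm.M
    if chains.u.shape[1] != M.shape[0]:
        raise ValueError(
            f"chain GEBV dimension {chains.u.shape[1]} does not match "
            f"marker matrix rows {M.shape[0]}"
        )
    MMt_pinv = np.linalg.pinv(M @ M.T, rcond=PINV_RTOL)
    backsolver = M.T @ MMt_pinv  # (N, n), computed once
    alpha = chains.u @ backsolver.T
    if snp_ids is None:
        snp_ids = [f"snp{j + 1}" for j in range(M.shape[1])]
    return SNPEffectChains(alpha=alpha, snp_ids=list(snp_ids))


def hpd_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of the empirical distribution holding
    ceil(prob * n) sample points; ties go to the lowest start index."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError(f"need >= 100 samples for an HPD interval, got {n}")
    if not (0.0 < prob < 1.0):
        raise ValueError("prob must be in (0, 1)")
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest start
    return float(x[i]), float(x[i + m - 1])


def posterior_prob_nonzero(samples: np.ndarray) -> float:
    """PPN0: fraction of samples on the side of zero indicated by the
    posterior mean (exact zeros count for neither side)."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 100:
        raise ValueError(f"need >= 100 samples for PPN0, got {len(x)}")
    if x.mean() > 0:
        return float(np.mean(x > 0))
    return float(np.mean(x < 0))


def summarize_scan(
    effchains: SNPEffectChains,
    snp_map: pd.DataFrame,
    prob: float = 0.95,
    ppn0_threshold: float = 0.95,
    geweke_alpha: float = 0.01,
) -> pd.DataFrame:
    """One row per SNP: posterior mean/sd, 95% HPD bounds, PPN0, both
    significance flags, and the per-chain Geweke p-value.

    A SNP is flagged ``sig_hpd`` when zero lies outside its HPD interval and
    ``sig_ppn0`` when PPN0 strictly exceeds the threshold; chains failing
    the Geweke test at ``geweke_alpha`` are flagged (``geweke_ok`` False),
    never dropped. Rows are sorted by chromosome then position.
    """
    if len(snp_map) != effchains.n_snps:
        raise ValueError("snp_map rows do not match effect chain columns")
    rows = []
    for j in range(effchains.n_snps):
        a = effchains.alpha[:, j]
        lo, hi = hpd_interval(a, prob)
        ppn0 = posterior_prob_nonzero(a)
        try:
            _, gp = geweke_diagnostic(a)
        except ZeroDivisionError:
            gp = np.nan
        rows.append(
            {
                "snp": snp_map["id"].iat[j],
                "chrom": str(snp_map["chrom"].iat[j]),
                "bp": int(snp_map["bp"].iat[j]),
                "mean": float(a.mean()),
                "sd": float(a.std(ddof=1)),
                "hpd_low": lo,
                "hpd_high": hi,
                "ppn0": ppn0,
                "sig_hpd": not (lo <= 0.0 <= hi),
                "sig_ppn0": ppn0 > ppn0_threshold,
                "geweke_p": gp,
            }
        )
    df = pd.DataFrame(rows)
    df["geweke_ok"] = ~(df["geweke_p"] < geweke_alpha)
    df["significant"] = df["sig_hpd"] | df["sig_ppn0"]
    return df.sort_values(["chrom", "bp"], kind="stable").reset_index(drop=True)
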