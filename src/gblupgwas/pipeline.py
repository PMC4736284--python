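"""End-to-end orchestration: simulate or load genotypes, QC, GRM, fit one or
both trait families, compare by DIC, back-solve the marker scan, call QTL
regions, and emit flanking intervals — all from one config with one seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes_gblup import (
    ChainStore,
    MCMCConfig,
    build_design,
    compare_models,
    compute_dic,
    elicit_priors,
    fit,
)
from .genotype_io import (
    GenotypeMatrix,
    QCThresholds,
    apply_qc,
    build_marker_matrix,
    compute_grm,
    read_plink_text,
    write_grm_tsv,
    write_plink_text,
)
from .ld_blocks import flanking_intervals, gabriel_regions, write_bed
from .marker_scan import backsolve_effects, summarize_scan
from .synthetic_data import (
    PhenotypeTable,
    SimConfig,
    simulate_gaussian_trait,
    simulate_genotypes,
    simulate_poisson_trait,
    write_true_values_tsv,
)

__all__ = ["RunConfig", "load_run_config", "run_gwas"]

PROFILES = {
    "paper": {"n_iter": 100_000, "burn_in": 50_000, "thin": 2},
    "desk": {"n_iter": 10_000, "burn_in": 5_000, "thin": 2},
}


@dataclass
class RunConfig:
    """Everything one GWAS run needs; serializable to/from flat YAML."""

    out_dir: str = "gwas_run"
    seed: int = 0
    families: list[str] = field(default_factory=lambda: ["gaussian"])
    profile: str = "desk"
    flank: int = 32_500
    write_grm: bool = False
    simulate: SimConfig | None = None
    ped: str | None = None
    map: str | None = None
    phenotype: str | None = None
    priors: dict[str, float] = field(
        default_factory=lambda: {
            "sigma2_star_u": 0.3575,
            "sigma2_star_p": 0.33,
            "sigma2_star_e": 3.9125,
        }
    )
    mcmc: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.families:
            raise ValueError("at least one family must be requested")
        for fam in self.families:
            if fam not in ("gaussian", "poisson"):
                raise ValueError(f"unknown family {fam!r}")
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {sorted(PROFILES)}")
        if self.simulate is None:
            for path_attr in ("ped", "map", "phenotype"):
                p = getattr(self, path_attr)
                if p is None:
                    raise FileNotFoundError(
                        f"config needs either a simulate block or a {path_attr} path"
                    )
                if not Path(p).exists():
                    raise FileNotFoundError(f"{path_attr} file not found: {p}")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # location, not an analysis setting
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def mcmc_config(self, seed_offset: int = 0) -> MCMCConfig:
        settings = dict(PROFILES[self.profile])
        settings.update(self.mcmc)
        settings.setdefault("seed", self.seed + seed_offset)
        if seed_offset and "seed" in self.mcmc:
            settings["seed"] = self.mcmc["seed"] + seed_offset
        return MCMCConfig(**settings)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    cfg = RunConfig(**raw)
    if sim is not None:
        if "n_snps_per_chrom" in sim:
            sim["n_snps_per_chrom"] = list(sim["n_snps_per_chrom"])
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        fel = sim.get("fixed_effect_levels")
        if fel:
            sim["fixed_effect_levels"] = {k: list(v) for k, v in fel.items()}
        cfg.simulate = SimConfig(**sim)
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def _chains_dir(out: Path, family: str) -> Path:
    return out / "chains" / family


def _save_chains(chains: ChainStore, cdir: Path) -> None:
    cdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(cdir / "u.tsv", chains.u, delimiter="\t", fmt="%.17g")
    np.savetxt(cdir / "beta.tsv", chains.beta, delimiter="\t", fmt="%.17g")
    if chains.p is not None:
        np.savetxt(cdir / "p.tsv", chains.p, delimiter="\t", fmt="%.17g")
    var_cols = {"sigma2_u": chains.sigma2_u, "sigma2_e": chains.sigma2_e,
                "deviance": chains.deviance, "retained_iter": chains.retained_iters}
    if chains.sigma2_p is not None:
        var_cols["sigma2_p"] = chains.sigma2_p
    pd.DataFrame(var_cols).to_csv(cdir / "scalars.tsv", sep="\t", index=False)
    meta = {
        "family": chains.family,
        "mh_accept_rate": chains.mh_accept_rate,
        "column_names": chains.column_names,
        "config": dataclasses.asdict(chains.config),
    }
    if chains.l_mean is not None:
        np.savetxt(cdir / "l_mean.tsv", chains.l_mean, delimiter="\t", fmt="%.17g")
    (cdir / "meta.json").write_text(json.dumps(meta, indent=1))


def _load_chains(cdir: Path) -> ChainStore:
    meta = json.loads((cdir / "meta.json").read_text())
    scalars = pd.read_csv(cdir / "scalars.tsv", sep="\t")
    p_path = cdir / "p.tsv"
    l_path = cdir / "l_mean.tsv"
    return ChainStore(
        family=meta["family"],
        u=np.atleast_2d(np.loadtxt(cdir / "u.tsv", delimiter="\t")),
        beta=np.atleast_2d(np.loadtxt(cdir / "beta.tsv", delimiter="\t")),
        p=np.atleast_2d(np.loadtxt(p_path, delimiter="\t")) if p_path.exists() else None,
        sigma2_u=scalars["sigma2_u"].to_numpy(),
        sigma2_p=scalars["sigma2_p"].to_numpy() if "sigma2_p" in scalars else None,
        sigma2_e=scalars["sigma2_e"].to_numpy(),
        deviance=scalars["deviance"].to_numpy(),
        l_mean=np.loadtxt(l_path, delimiter="\t") if l_path.exists() else None,
        retained_iters=scalars["retained_iter"].to_numpy(dtype=np.int64),
        mh_accept_rate=meta["mh_accept_rate"],
        config=MCMCConfig(**meta["config"]),
        column_names=meta["column_names"],
    )


def run_gwas(config: RunConfig, resume: bool = False) -> dict:
    """Run the full workflow and write artifacts under ``config.out_dir``.

    Returns a summary dict (paths, DIC per family, preferred family,
    significant SNP count). On failure a FAILED marker naming the stage is
    left next to any partial artifacts.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log_lines = [
        f"gblupgwas {__version__}",
        f"config_hash={chash}",
        f"seed={config.seed}",
        f"profile={config.profile}",
    ]
    stage = "setup"
    t0 = time.time()
    try:
        # -- inputs ---------------------------------------------------------
        stage = "data"
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            geno = simulate_genotypes(sim)
            if sim.family == "poisson":
                pheno, truth = simulate_poisson_trait(geno, sim)
            else:
                pheno, truth = simulate_gaussian_trait(geno, sim)
            write_plink_text(geno, out / "simulated.ped", out / "simulated.map")
            pheno.to_tsv(out / "simulated_phenotypes.tsv")
            write_true_values_tsv(truth, out / "simulated_truth.tsv")
        else:
            geno = read_plink_text(config.ped, config.map)
            pheno = PhenotypeTable.from_tsv(config.phenotype)

        # -- QC / GRM -------------------------------------------------------
        stage = "qc"
        geno, qc_report = apply_qc(geno, QCThresholds(**config.qc))
        _write_tsv(qc_report.to_frame(), out / "qc_report.tsv", chash)
        stage = "grm"
        mm = build_marker_matrix(geno, center=True)
        grm = compute_grm(mm)
        if config.write_grm:
            write_grm_tsv(grm, geno.individual_ids, out / "grm.tsv")
        design = build_design(pheno, geno.individual_ids)
        priors = elicit_priors(
            config.priors["sigma2_star_u"],
            config.priors.get("sigma2_star_p") if design.has_pe else None,
            config.priors["sigma2_star_e"],
        )

        # -- fits -----------------------------------------------------------
        all_chains: dict[str, ChainStore] = {}
        dics = {}
        for k, family in enumerate(config.families):
            stage = f"fit:{family}"
            cdir = _chains_dir(out, family)
            if resume and (cdir / "meta.json").exists():
                chains = _load_chains(cdir)
                log_lines.append(f"fit {family}: resumed from stored chains")
            else:
                chains = fit(pheno, design, grm, family, priors, config.mcmc_config(k))
                _save_chains(chains, cdir)
            all_chains[family] = chains
            dics[family] = compute_dic(chains, pheno, design, family)
            if chains.mh_accept_rate is not None:
                log_lines.append(
                    f"fit {family}: MH acceptance rate {chains.mh_accept_rate:.3f}"
                )

        stage = "model_comparison"
        rows = [
            {
                "family": fam,
                "DIC": d.DIC,
                "D_at_mean": d.D_at_mean,
                "mean_deviance": d.mean_deviance,
                "p_D": d.p_D,
            }
            for fam, d in dics.items()
        ]
        summary = pd.DataFrame(rows)
        preferred = min(dics, key=lambda f: dics[f].DIC)
        if len(config.families) == 2:
            a, b = config.families
            cmpres = compare_models(dics[a], dics[b])
            summary["comparison"] = cmpres.label
            summary["preferred"] = preferred if cmpres.preferred else "either"
        else:
            summary["preferred"] = preferred
        _write_tsv(summary, out / "fit_summary.tsv", chash)

        # -- marker scan -----------------------------------------------------
        stage = "scan"
        chains = all_chains[preferred]
        effchains = backsolve_effects(chains, mm, snp_ids=geno.snp_map["id"])
        scan = summarize_scan(effchains, geno.snp_map)
        _write_tsv(scan, out / "scan_results.tsv", chash)
        geweke_fail = int((~scan["geweke_ok"]).sum())
        log_lines.append(
            f"scan ({preferred}): {int(scan['significant'].sum())} significant SNPs "
            f"of {len(scan)}; {geweke_fail} chains flagged by Geweke at 0.01"
        )

        # -- QTL regions and flanks -----------------------------------------
        stage = "regions"
        sig = scan.loc[scan["significant"], ["snp", "chrom", "bp"]].reset_index(drop=True)
        if len(sig) >= 2:
            regions, singletons = gabriel_regions(sig, geno)
        else:
            regions, singletons = [], sig
        reg_rows = [
            {
                "region": f"QTL{k + 1}_{r.chrom}",
                "chrom": r.chrom,
                "start_bp": r.start,
                "end_bp": r.end,
                "n_snps": len(r.snps),
                "snps": ",".join(r.snps),
            }
            for k, r in enumerate(regions)
        ]
        _write_tsv(
            pd.DataFrame(reg_rows, columns=["region", "chrom", "start_bp", "end_bp", "n_snps", "snps"]),
            out / "qtl_regions.tsv",
            chash,
        )
        flanks = flanking_intervals(regions, singletons, flank=config.flank)
        write_bed(flanks, out / "flanks.bed")

        log_lines.append(
            f"regions: {len(regions)} QTL regions, {len(singletons)} singleton SNPs"
        )
        log_lines.append(f"elapsed_seconds={time.time() - t0:.1f}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        return {
            "out_dir": str(out),
            "config_hash": chash,
            "dic": {f: d.DIC for f, d in dics.items()},
            "preferred_family": preferred,
            "n_significant": int(scan["significant"].sum()),
            "n_regions": len(regions),
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc!r}\n")
        (out / "run.log").write_text("\n".join(log_lines + [f"FAILED at {stage}: {exc!r}"]) + "\n")
        raise
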