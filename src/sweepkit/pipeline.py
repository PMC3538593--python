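"""Config-driven orchestration of the full per-region analysis.

For every configured region: read and classify the alignment, compute the
summary-statistics block, run the frequency-spectrum tests with fixed-S
coalescent null distributions (standard-neutral and bottleneck demography,
at the genetic-map recombination rate R_M and at R_M/4), run the CLR sweep
scan against both nulls, and—when the scan is significant against both—the
GOF follow-up. Results are written as three TSV tables plus a JSON manifest
(seeds, versions, acceptance rates) sufficient to reproduce every number.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

import sweepkit
from sweepkit import coalsim, report
from sweepkit.coalsim import DemographyModel, SimulationConfig, empirical_pvalue
from sweepkit.diversity import (
    SiteFrequencySpectrum,
    mean_pairwise_differences,
    summarize_region,
    watterson_theta,
)
from sweepkit.neutrality import fay_wu_H_normalized, tajima_D
from sweepkit.regions import classify_sites, read_alignment, read_gff3, variant_table
from sweepkit.sweepscan import (
    InsufficientDataError,
    clr_null_distribution,
    clr_scan,
    gof_test,
)
from sweepkit._util import UNDEFINED, is_undefined

THETA_PRIOR = (0.001, 0.06)


@dataclass
class RegionConfig:
    fasta: str
    gff: str
    outgroup_id: Optional[str] = None
    inheritance_factor: float = 1.0
    rm: float = 0.02  # per-site population recombination rate, 2N units
    label: Optional[str] = None


@dataclass
class PipelineConfig:
    regions: list[RegionConfig]
    bottleneck: Optional[DemographyModel] = None
    reps: int = 1000
    gof_reps: int = 200
    seed: int = 1
    outdir: str = "results"
    alpha_level: float = 0.05
    force_gof: bool = False
    clr_null_reps: Optional[int] = None  # defaults to reps
    n_windows: Optional[int] = None  # override the recombination-window count

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        regions = [RegionConfig(**r) for r in cfg["regions"]]
        bn = None
        if "bottleneck" in cfg:
            b = cfg["bottleneck"]
            if isinstance(b, str):
                bn = DemographyModel.from_yaml(b)
            else:
                bn = DemographyModel(
                    epochs=[(float(t), float(r)) for t, r in b["epochs"]],
                    label=str(b.get("label", "BN")),
                )
        return cls(
            regions=regions,
            bottleneck=bn,
            reps=int(cfg.get("reps", 1000)),
            gof_reps=int(cfg.get("gof_reps", 200)),
            seed=int(cfg.get("seed", 1)),
            outdir=str(cfg.get("outdir", "results")),
            force_gof=bool(cfg.get("force_gof", False)),
            clr_null_reps=(
                int(cfg["clr_null_reps"]) if "clr_null_reps" in cfg else None
            ),
            n_windows=int(cfg["n_windows"]) if "n_windows" in cfg else None,
        )


def _child_seed(base: int, *keys) -> int:
    h = zlib.crc32("/".join(str(k) for k in keys).encode())
    return int(np.random.SeedSequence([base, h]).generate_state(1)[0] % (2**31))


def _sim_stats(reps_set) -> tuple[np.ndarray, np.ndarray]:
    """(D, H) per simulated replicate."""
    n = reps_set.config.n
    pis = reps_set.pi_counts()
    D = np.full(reps_set.reps, np.nan)
    H = np.full(reps_set.reps, np.nan)
    for r in range(reps_set.reps):
        cnt = reps_set.counts[r]
        cnt = cnt[(cnt >= 1) & (cnt <= n - 1)]
        if len(cnt) == 0:
            continue
        sfs = SiteFrequencySpectrum.from_counts(n, cnt)
        d = tajima_D(sfs.S, pis[r], n)
        h = fay_wu_H_normalized(sfs)
        D[r] = float(d) if not is_undefined(d) else np.nan
        H[r] = float(h) if not is_undefined(h) else np.nan
    return D, H


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis; returns the result bundle (also written)."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest = {
        "version": sweepkit.__version__,
        "seed": config.seed,
        "reps": config.reps,
        "theta_prior": list(THETA_PRIOR),
        "regions": [],
        "acceptance_rates": {},
    }
    stats_rows, neut_rows, sweep_rows = [], [], []
    bundle = {}

    for reg in config.regions:
        label = reg.label or os.path.basename(reg.fasta).split(".")[0]
        aln = read_alignment(reg.fasta, outgroup_id=reg.outgroup_id, region_id=label)
        ann = read_gff3(reg.gff)
        classification = classify_sites(aln, ann)
        table = variant_table(aln, classification, polarize=aln.has_outgroup)
        stats = summarize_region(aln, classification)
        bundle[label] = {"stats": stats, "table": table}
        manifest["regions"].append(
            {"label": label, "fasta": reg.fasta, "gff": reg.gff, "n": aln.n,
             "L": aln.length, "S": table.S}
        )
        for cf in ("intronic", "synonymous", "silent", "nonsynonymous", "total"):
            stats_rows.append(
                dict(
                    region=label,
                    **{"class": cf},
                    sites=report.fmt_count(stats.sites[cf]),
                    S=report.fmt_s_with_singletons(stats.S[cf], stats.singletons[cf]),
                    pi=report.fmt(stats.pi[cf]),
                    K=report.fmt(stats.K.get(cf)),
                )
            )
        stats_rows.append(
            dict(
                region=label,
                **{"class": "summary"},
                sites=report.fmt_count(classification.counts["total"]),
                S=f"h={stats.h} Hd={report.fmt(stats.Hd)}",
                pi=f"Ka={report.fmt(stats.Ka)} Ks={report.fmt(stats.Ks)}",
                K=f"omega={report.fmt(stats.omega)}",
            )
        )

        # frequency-spectrum tests with simulated nulls
        n, L, S_total = aln.n, aln.length, table.S
        pi_count = mean_pairwise_differences(table)
        D_obs = tajima_D(S_total, pi_count, n) if S_total else UNDEFINED
        if aln.has_outgroup:
            sfs_obs = SiteFrequencySpectrum.from_table(table)
            H_obs = fay_wu_H_normalized(sfs_obs) if sfs_obs.S else UNDEFINED
        else:
            H_obs = UNDEFINED

        demographies = {"SNM": DemographyModel.snm(
            inheritance_factor=reg.inheritance_factor)}
        if config.bottleneck is not None:
            bn = DemographyModel(
                epochs=config.bottleneck.epochs,
                inheritance_factor=reg.inheritance_factor,
                label="BN",
            )
            demographies["BN"] = bn
        for r_label, rho in (("RM", reg.rm), ("R0.25", reg.rm / 4.0)):
            pvals = {"D": {}, "H": {}}
            for dem_label, dem in demographies.items():
                if S_total == 0:
                    continue
                seed = _child_seed(config.seed, label, r_label, dem_label)
                cfg = SimulationConfig(
                    n=n, L=L, theta_prior=THETA_PRIOR, fixed_S=S_total,
                    rho_per_site=rho, reps=config.reps, seed=seed,
                    n_windows=config.n_windows,
                )
                reps_set = coalsim.simulate_fixed_S(cfg, dem)
                manifest["acceptance_rates"][f"{label}/{r_label}/{dem_label}"] = (
                    reps_set.acceptance_rate
                )
                D_sim, H_sim = _sim_stats(reps_set)
                if not is_undefined(D_obs):
                    pvals["D"][dem_label] = empirical_pvalue(
                        float(D_obs), D_sim, "lower")
                if not is_undefined(H_obs):
                    pvals["H"][dem_label] = empirical_pvalue(
                        float(H_obs), H_sim, "lower")
            for stat_name, obs in (("D", D_obs), ("H", H_obs)):
                neut_rows.append(
                    dict(
                        region=label,
                        statistic=stat_name,
                        value=report.fmt_stat(obs),
                        R=r_label,
                        p_SNM=report.fmt_pvalue(pvals[stat_name].get("SNM")),
                        p_BN=report.fmt_pvalue(pvals[stat_name].get("BN")),
                    )
                )

        # CLR sweep scan + GOF
        for r_label, rho in (("RM", reg.rm), ("R0.25", reg.rm / 4.0)):
            row = dict(
                region=label, L=L, S=table.S, R=f"{rho:.3f}", R_label=r_label,
                p_SNM=report.NA, p_BN=report.NA, alpha=report.NA, X=report.NA,
                GOF=report.NA,
            )
            if not aln.has_outgroup:
                sweep_rows.append(row)
                continue
            pol = table.polarized()
            pos = pol["column"].to_numpy(dtype=float)
            cnt = pol["derived_count"].to_numpy(dtype=int)
            theta_w = watterson_theta(table.S, n, max(L, 1))
            try:
                fit = clr_scan(pos, cnt, n, L, theta_w, rho)
            except InsufficientDataError:
                sweep_rows.append(row)
                continue
            null_reps = config.clr_null_reps or config.reps
            sig = {}
            for dem_label, dem in demographies.items():
                seed = _child_seed(config.seed, label, r_label, dem_label, "clr")
                null = clr_null_distribution(
                    n=n, L=L, rho_per_site=rho, reps=null_reps, seed=seed,
                    theta_prior=THETA_PRIOR, fixed_S=len(pos) if len(pos) >= 2 else None,
                    demography=dem, n_windows=config.n_windows,
                )
                sig[dem_label] = empirical_pvalue(fit.clr, null, "upper")
            fit.p_snm = sig.get("SNM")
            fit.p_bottleneck = sig.get("BN")
            row["p_SNM"] = report.fmt_pvalue(fit.p_snm)
            row["p_BN"] = report.fmt_pvalue(fit.p_bottleneck)
            significant = all(
                sig[k].value <= config.alpha_level for k in sig
            ) and fit.alpha_hat > 0
            if significant or (config.force_gof and fit.alpha_hat > 0):
                row["alpha"] = f"{fit.alpha_hat:.2f}"
                row["X"] = f"{int(fit.x_hat)}"
                seed = _child_seed(config.seed, label, r_label, "gof")
                gof = gof_test(
                    fit, pos, cnt, reps=config.gof_reps, seed=seed,
                    n_windows=config.n_windows,
                )
                row["GOF"] = report.fmt(gof.p_value, 3)
            sweep_rows.append(row)
            bundle[label][f"clr_{r_label}"] = fit

    _write_tsv(os.path.join(config.outdir, "region_statistics.tsv"), stats_rows)
    _write_tsv(os.path.join(config.outdir, "neutrality_tests.tsv"), neut_rows)
    _write_tsv(os.path.join(config.outdir, "sweep_scan.tsv"), sweep_rows)
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    bundle["manifest"] = manifest
    return bundle


def _write_tsv(path, rows) -> None:
    if not rows:
        with open(path, "w") as fh:
            fh.write("")
        return
    cols = list(rows[0].keys())
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r.get(c, report.NA)) for c in cols) + "\n")
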