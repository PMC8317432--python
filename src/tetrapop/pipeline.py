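"""Seeded, logged orchestration of the full analysis chain.

Stages: simulate -> genotype -> inheritance diagnosis -> diversity ->
individual structure -> IBD/IBE decomposition -> selection scan.  A
single :class:`PipelineConfig` carries every numeric parameter with the
pipeline's standard defaults (minimum depth 5, at most 10% missing
individuals per site, 999 Mantel and 1,000 MMRR permutations,
collinearity cutoff |r| > 0.9, 100,000 PODs at the 99%/99.9%
quantiles).  One global seed is fanned out to per-stage seeds by a
fixed counter scheme, so toggling one stage never perturbs another's
randomness; reruns with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import inheritance as ih
from . import io as tio
from . import landscape as ls
from . import scan as sc
from . import structure as st
from .genotyping import call_genotypes
from .simulate import _stage_seed, simulate_dataset

ALL_STAGES = (
    "simulate",
    "genotype",
    "inheritance",
    "diversity",
    "structure",
    "ibd_ibe",
    "scan",
)


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the pipeline's standards."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulation
    n_localities: int = 16
    n_per_pop: int = 9
    n_loci: int = 5000
    extent_km: float = 500.0
    base_sd: float = 0.5
    ibd_range: float = 200.0
    n_adaptive: int = 0
    effect_size: float = 0.0
    mode: str = "tetrasomic"
    subgenome_divergence: float = 0.0
    mean_depth: float = 16.0
    depth_dispersion: float = 12.8
    error_rate: float = 0.005
    n_covariates: int = 3
    # genotyping
    min_depth: int = 5
    max_missing: float = 0.10
    maf_min: float = 0.05
    min_carriers: int = 2
    # inheritance
    bin_width: float = 0.02
    band: tuple[float, float] = (0.4, 0.6)
    # diversity
    locus_length_bp: int = 94
    # IBD/IBE
    mantel_perms: int = 999
    mmrr_perms: int = 1000
    collinearity_cutoff: float = 0.9
    n_env_covariates: int = 3
    # scan
    pod_count: int = 100_000
    pod_quantiles: tuple[float, float] = (0.99, 0.999)
    omega_shrinkage: float = 0.05

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["band"] = list(d["band"])
        d["pod_quantiles"] = list(d["pod_quantiles"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("stages", "band", "pod_quantiles"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        cfg = cls(**d)
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def rank_covariates_by_mantel(
    genetic: pd.DataFrame, covariates: pd.DataFrame, n_perm: int = 0, seed: int = 0
) -> pd.DataFrame:
    """Rank covariates by the Mantel r of their one-variable distance
    matrix against the genetic distance matrix.

    A transparent stand-in for machine-learning importance rankings:
    each covariate's single-variable environmental distance matrix is
    correlated with the genetic one and covariates are sorted by r.
    """
    rows = []
    for name in covariates.columns:
        E = ls.environmental_distance(covariates[[name]])
        if n_perm > 0:
            r, p = ls.mantel(genetic, E, n_perm=n_perm, seed=seed)
        else:
            r = float(
                np.corrcoef(
                    ls.lower_triangle(np.asarray(genetic, dtype=float)),
                    ls.lower_triangle(E.to_numpy()),
                )[0, 1]
            )
            p = np.nan
        rows.append({"covariate": name, "mantel_r": r, "p": p})
    return (
        pd.DataFrame(rows).sort_values("mantel_r", ascending=False).set_index("covariate")
    )


def run(config: PipelineConfig, out_dir: str) -> dict:
    """Execute the enabled stages in dependency order.

    Writes each stage's outputs under ``out_dir`` plus a manifest with
    the full config and a content hash per file.  Returns a results
    dictionary with the main in-memory objects.
    """
    os.makedirs(out_dir, exist_ok=True)
    results: dict = {"out_dir": out_dir}
    files: dict[str, str] = {}
    stages = set(config.stages)

    need_data = stages & set(ALL_STAGES[1:]) or "simulate" in stages
    if need_data:
        truth, reads = simulate_dataset(
            n_localities=config.n_localities,
            n_per_pop=config.n_per_pop,
            n_loci=config.n_loci,
            extent_km=config.extent_km,
            base_sd=config.base_sd,
            ibd_range=config.ibd_range,
            n_adaptive=config.n_adaptive,
            effect_size=config.effect_size,
            mode=config.mode,
            subgenome_divergence=config.subgenome_divergence,
            mean_depth=config.mean_depth,
            depth_dispersion=config.depth_dispersion,
            error_rate=config.error_rate,
            n_covariates=config.n_covariates,
            seed=config.seed,
        )
        results["truth"], results["reads"] = truth, reads
    if "simulate" in stages:
        files.update(tio.write_simulated_dataset(out_dir, truth, reads))

    genotypes = None
    if stages & set(ALL_STAGES[1:]):
        genotypes, site_info = call_genotypes(
            reads,
            min_depth=config.min_depth,
            max_missing=config.max_missing,
            maf_min=config.maf_min,
            min_carriers=config.min_carriers,
        )
        results["genotypes"], results["site_info"] = genotypes, site_info
        membership = truth.membership
        results["membership"] = membership
    if "genotype" in stages:
        files["dosages"] = os.path.join(out_dir, "dosages.tsv")
        tio.write_dosage_tsv(genotypes, files["dosages"])
        files["genotypes_vcf"] = os.path.join(out_dir, "genotypes.vcf")
        tio.write_dosage_vcf(genotypes, files["genotypes_vcf"])
        files["site_info"] = os.path.join(out_dir, "site_info.tsv")
        site_info.to_csv(files["site_info"], sep="\t", index=False)

    if "inheritance" in stages:
        profile = ih.genotype_frequency_profile(genotypes, config.bin_width)
        label, score = ih.classify_inheritance(profile, config.band)
        try:
            d_stat = ih.heterozygote_balance(genotypes, config.band)
        except ValueError:
            d_stat = float("nan")
        results["inheritance"] = {"label": label, "score": score, "D": d_stat}
        files["profile"] = os.path.join(out_dir, "genotype_profile.tsv")
        profile.to_frame().to_csv(files["profile"], sep="\t", index=False)
        files["inheritance"] = os.path.join(out_dir, "inheritance.json")
        with open(files["inheritance"], "w") as fh:
            json.dump(results["inheritance"], fh, indent=2)

    fst = None
    if stages & {"diversity", "ibd_ibe"}:
        fst = dv.pairwise_fst(genotypes, membership)
        results["fst"] = fst
    if "diversity" in stages:
        regions = pd.Series(
            truth.pops.frame.set_index("locality")["region"]
        )
        div = dv.diversity_table(
            genotypes,
            membership,
            total_callable_bp=config.locus_length_bp * len(genotypes.site_ids),
            regions=regions,
        )
        results["diversity"] = div
        results["region_summary"] = {
            col: dv.region_summary(div[col], div["region"])
            for col in ("pi", "he", "fis")
        }
        files["diversity"] = os.path.join(out_dir, "diversity.tsv")
        div.to_csv(files["diversity"], sep="\t")
        files["fst"] = os.path.join(out_dir, "fst.tsv")
        fst.to_csv(files["fst"], sep="\t")
        files["fst_linearized"] = os.path.join(out_dir, "fst_linearized.tsv")
        ls.linearize_fst(fst).to_csv(files["fst_linearized"], sep="\t")

    if "structure" in stages:
        rel = st.relatedness_matrix(genotypes)
        pca = st.pca_dosage(genotypes, n_components=10)
        results["relatedness"], results["pca"] = rel, pca
        files["relatedness"] = os.path.join(out_dir, "relatedness.tsv")
        rel.to_csv(files["relatedness"], sep="\t")
        files["pca_scores"] = os.path.join(out_dir, "pca_scores.tsv")
        pca.scores.to_csv(files["pca_scores"], sep="\t")
        files["pca_explained"] = os.path.join(out_dir, "pca_explained.tsv")
        pd.DataFrame(
            {"component": pca.scores.columns, "explained_pct": pca.explained_pct}
        ).to_csv(files["pca_explained"], sep="\t", index=False)

    if "ibd_ibe" in stages:
        seed_m = _stage_seed(config.seed, 10)
        gen_dist = ls.linearize_fst(fst)
        geo = ls.geographic_distance(truth.pops)
        covs = truth.pops.covariates()
        kept = ls.prune_collinear(covs, config.collinearity_cutoff)
        ranking = rank_covariates_by_mantel(gen_dist, covs[kept])
        selected = list(ranking.index[: config.n_env_covariates])
        env = ls.environmental_distance(covs, selected)
        r_geo, p_geo = ls.mantel(gen_dist, geo, config.mantel_perms, seed_m)
        r_env, p_env = ls.mantel(gen_dist, env, config.mantel_perms, seed_m + 1)
        pr_geo, pp_geo = ls.partial_mantel(
            gen_dist, geo, env, config.mantel_perms, seed_m + 2
        )
        pr_env, pp_env = ls.partial_mantel(
            gen_dist, env, geo, config.mantel_perms, seed_m + 3
        )
        mm = ls.mmrr(
            gen_dist, [geo, env], config.mmrr_perms, seed_m + 4, names=["GEO", "ENV"]
        )
        ca = ls.commonality_two(gen_dist, geo, env)
        results["ibd_ibe"] = {
            "selected_covariates": selected,
            "mantel_geo": (r_geo, p_geo),
            "mantel_env": (r_env, p_env),
            "partial_mantel_geo": (pr_geo, pp_geo),
            "partial_mantel_env": (pr_env, pp_env),
            "mmrr": mm,
            "commonality": ca,
        }
        flat = pd.DataFrame(
            [
                ("mantel_geo", r_geo, p_geo),
                ("mantel_env", r_env, p_env),
                ("partial_mantel_geo", pr_geo, pp_geo),
                ("partial_mantel_env", pr_env, pp_env),
                ("mmrr_r2", mm.r_squared, mm.model_pvalue),
                ("mmrr_beta_GEO", mm.betas[1], mm.beta_pvalues[0]),
                ("mmrr_beta_ENV", mm.betas[2], mm.beta_pvalues[1]),
                ("commonality_unique_GEO", ca.unique["GEO"], np.nan),
                ("commonality_unique_ENV", ca.unique["ENV"], np.nan),
                ("commonality_common", ca.common, np.nan),
            ],
            columns=["statistic", "estimate", "p"],
        )
        files["ibd_ibe"] = os.path.join(out_dir, "ibd_ibe.tsv")
        flat.to_csv(files["ibd_ibe"], sep="\t", index=False)

    if "scan" in stages:
        res = sc.scan(
            genotypes,
            membership,
            truth.pops.covariates(),
            n_pods=config.pod_count,
            seed=_stage_seed(config.seed, 20),
            shrinkage=config.omega_shrinkage,
        )
        results["scan"] = res
        files["scan_table"] = os.path.join(out_dir, "scan.tsv")
        res.table.to_csv(files["scan_table"], sep="\t")
        files["omega"] = os.path.join(out_dir, "omega.tsv")
        res.omega.to_csv(files["omega"], sep="\t")
        files["thresholds"] = os.path.join(out_dir, "thresholds.json")
        with open(files["thresholds"], "w") as fh:
            json.dump(
                {k: v for k, v in res.thresholds.items() if not isinstance(v, np.ndarray)},
                fh,
                indent=2,
            )

    manifest = {
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=list)),
        "files": {k: {"path": v, "sha256": _sha256(v)} for k, v in files.items()},
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    results["files"] = files
    return results


def membership_from_ids(individual_ids, localities) -> pd.Series:
    """Derive locality membership from `<locality>_iN` sample names."""
    out = {}
    locs = set(localities)
    for ind in individual_ids:
        loc = ind.rsplit("_i", 1)[0]
        if loc not in locs:
            raise ValueError(f"sample {ind!r} has no matching locality")
        out[ind] = loc
    return pd.Series(out)


def validate_inputs(vcf_path: str, pops_path: str) -> dict:
    """Validate a counts VCF against a population metadata table.

    Checks: files readable, records biallelic with AD, coordinates in
    range, and every sample mappable to a listed locality.  Returns a
    machine-readable report; problems are listed, not raised, except
    for unreadable files.
    """
    report: dict = {"errors": [], "warnings": [], "n_records": 0, "rejected_records": []}
    pops = tio.read_population_table(pops_path)
    report["n_localities"] = pops.n_localities

    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    report["n_samples"] = len(samples)
    try:
        membership_from_ids(samples, pops.locality_ids)
    except ValueError as exc:
        report["errors"].append(str(exc))
    for var in vcf:
        report["n_records"] += 1
        if len(var.ALT) != 1:
            report["rejected_records"].append(
                {"id": var.ID or f"{var.CHROM}:{var.POS}", "reason": "multiallelic"}
            )
            continue
        if var.format("AD") is None:
            report["rejected_records"].append(
                {"id": var.ID or f"{var.CHROM}:{var.POS}", "reason": "missing AD"}
            )
    vcf.close()
    report["clean"] = not report["errors"] and not report["rejected_records"]
    return report
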