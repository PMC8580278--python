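"""End-to-end orchestration: simulate -> EWAS -> confirmation -> mediation -> MR.

The stages run in the causal-chain order: (1) smoking EWAS among controls,
(2) repeated-measures confirmation (LMRSE) and the change-on-change analysis,
(3) lung-cancer EWAS without smoking adjustment, (4) overlap of the two hit
lists and counterfactual mediation of each candidate plus the weighted
methylation score, (5) two-step MR — one-sample 2SLS of methylation on
smoking via the 3-SNP score, then two-sample Wald/IVW of lung cancer on
methylation via mQTL instruments.

A single global seed fans out to per-stage substreams through
``numpy.random.SeedSequence`` so any stage can be rerun in isolation.  Every
run writes a manifest recording the config hash, seed, stage timings and
output checksums.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mcio
from . import mediation as med
from . import mr as mrmod
from . import repeated as rep
from .containers import MethylationMatrix
from .ewas import LinearEWAS, LogisticEWAS
from .phenotypes import beta_to_m
from .simcohort import (
    SimulationConfig,
    simulate_cohort,
    simulate_mqtl_summary,
    simulate_outcome_gwas,
)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    genomewide_alpha: float = 5e-8
    n_svs: int = 12
    n_boot: int = 1000
    ci_level: float = 0.95
    run_repeated: bool = True
    run_mediation: bool = True
    run_mr: bool = True
    cis_only: bool = False
    mqtl_gwas_n: int = 5101
    outcome_gwas_n: int = 85716
    outcome_gwas_cases: int = 29266

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        known = {f.name for f in fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown pipeline config keys: {sorted(bad)}")
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["wave_transition_probs"] = np.asarray(
            d["simulation"]["wave_transition_probs"]).tolist()
        return d


def overlap_sites(smoking_hits, cancer_hits) -> list:
    """Sorted intersection of two hit lists by site id."""
    return sorted(set(smoking_hits) & set(cancer_hits))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: PipelineConfig, seed: int | None = None,
                      outdir=None) -> dict:
    """Run every enabled stage; returns the manifest with stage results attached.

    The manifest's ``results`` entry holds the in-memory stage outputs; when
    ``outdir`` is given the tabular outputs are also written there and their
    checksums recorded.
    """
    t_start = time.time()
    simcfg = (config.simulation if seed is None
              else SimulationConfig(**{**asdict(config.simulation), "seed": seed}))
    # fan the global seed out to pipeline-level substreams (independent of the
    # simulator's own internal spawning)
    ss = np.random.SeedSequence(simcfg.seed + 1_000_003)
    rng_mr = np.random.default_rng(ss.spawn(1)[0])

    cfg_yaml = yaml.safe_dump(
        {**config.to_dict(), "simulation": {**config.to_dict()["simulation"],
                                            "seed": simcfg.seed}},
        sort_keys=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": simcfg.seed,
        "stages": [],
        "warnings": [],
        "outputs": {},
    }
    results: dict = {}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        manifest["stages"].append({"name": name, "seconds": None})
        return time.time()

    def done(t0):
        manifest["stages"][-1]["seconds"] = round(time.time() - t0, 3)

    def emit(name, writer, obj):
        if outdir is None:
            return
        path = outdir / name
        writer(obj, path)
        manifest["outputs"][name] = _checksum(path)

    # ---- simulate -------------------------------------------------------
    t0 = stage("simulate")
    cohort, truth = simulate_cohort(simcfg)
    results["cohort"], results["truth"] = cohort, truth
    emit("phenotypes.csv", mcio.write_phenotypes, cohort.pheno)
    emit("genotypes.tsv", mcio.write_genotypes, cohort.genotypes)
    emit("truth.yaml", lambda tr, p: mcio.write_truth(tr, p), truth)
    done(t0)

    nested = cohort.nested_ids()
    pheno = cohort.pheno
    controls = nested[~pheno.loc[nested, "case"]]
    controls = controls[pheno.loc[controls, "phenotype_w1"].notna()]
    cells = cohort.cells_w1.iloc[:, :-1]  # drop one simplex component

    def covars(ids):
        return pd.concat(
            [pheno.loc[ids, ["sex", "age_w1"]], cells.loc[ids]], axis=1)

    # ---- smoking EWAS (controls, wave 1) --------------------------------
    t0 = stage("ewas_smoking")
    meth_ctrl = cohort.meth_w1.subset_samples(controls)
    n_svs = min(config.n_svs,
                max(0, len(controls) - (3 + cells.shape[1]) - 12))
    smoking_scan = LinearEWAS(n_svs=n_svs, genomewide_alpha=config.genomewide_alpha)
    smoking_scan.fit(meth_ctrl, pheno.loc[controls, "phenotype_w1"].to_numpy(),
                     covars(controls))
    smoking_hits = list(smoking_scan.significant_sites())
    results["ewas_smoking"] = smoking_scan.results_
    results["smoking_hits"] = smoking_hits
    emit("ewas_smoking.tsv", lambda d, p: mcio.write_table(d, p, "site_id"),
         smoking_scan.results_)
    done(t0)

    # ---- repeated-measures confirmation ---------------------------------
    if config.run_repeated and smoking_hits:
        t0 = stage("repeated")
        m1 = cohort.meth_w1.subset_sites(smoking_hits).subset_samples(controls)
        m2 = cohort.meth_w2.subset_sites(smoking_hits).subset_samples(controls)
        panel = rep.build_panel(m1, m2, pheno["phenotype_w1"],
                                covariates=covars(controls))
        lmrse = rep.lmrse_scan(panel, bonferroni_m=len(smoking_hits))
        results["lmrse"] = lmrse
        results["lmrse_confirmed"] = list(lmrse.index[lmrse["bonferroni"]])
        results["ewas_lmrse_correlation"] = rep.compare_estimates(
            smoking_scan.results_.loc[smoking_hits, "coef"], lmrse["coef"])
        delta = (m2.beta.to_numpy() - m1.beta.to_numpy())
        change = pheno.loc[controls, "smoking_change"].to_numpy()
        results["change_analysis"] = rep.run_change_analysis(
            delta, change, bonferroni_m=len(smoking_hits),
            site_ids=pd.Index(smoking_hits))
        emit("lmrse.tsv", lambda d, p: mcio.write_table(d, p, "site_id"), lmrse)
        emit("change_analysis.tsv", lambda d, p: mcio.write_table(d, p, "site_id"),
             results["change_analysis"])
        done(t0)

    # ---- lung-cancer EWAS (nested subset, wave 1, no smoking term) ------
    t0 = stage("ewas_cancer")
    meth_cc = cohort.meth_w1.subset_samples(nested)
    cancer_scan = LogisticEWAS(adjust_smoking=False, n_svs=0,
                               genomewide_alpha=config.genomewide_alpha)
    cancer_scan.fit(meth_cc, pheno.loc[nested, "case"].astype(int).to_numpy(),
                    covars(nested))
    cancer_hits = list(cancer_scan.significant_sites())
    results["ewas_cancer"] = cancer_scan.results_
    results["cancer_hits"] = cancer_hits
    emit("ewas_cancer.tsv", lambda d, p: mcio.write_table(d, p, "site_id"),
         cancer_scan.results_)
    done(t0)

    # ---- overlap + mediation -------------------------------------------
    candidates = overlap_sites(smoking_hits, cancer_hits)
    results["overlap"] = candidates
    identified: list = []
    if config.run_mediation:
        t0 = stage("mediation")
        expo = pheno.loc[nested, "phenotype_w1"]
        keep = expo.notna()
        ids = nested[keep.to_numpy()]
        weights = cancer_scan.results_["coef"]
        table, score_res = med.run_mediation_screen(
            cohort.meth_w1.beta[ids], candidates, weights,
            pheno.loc[ids, "phenotype_w1"].to_numpy(),
            pheno.loc[ids, "case"].astype(int).to_numpy(),
            covariates=covars(ids).to_numpy(),
            n_boot=config.n_boot, random_state=simcfg.seed,
            ci_level=config.ci_level)
        results["mediation"] = table
        results["mediation_score"] = score_res
        identified = list(table.index[table["identified"]]) if len(table) else []
        results["mediators"] = identified
        if len(table):
            emit("mediation.tsv", lambda d, p: mcio.write_table(d, p, "site_id"),
                 table)
        done(t0)

    # ---- two-step MR ----------------------------------------------------
    if config.run_mr:
        t0 = stage("mr_first_step")
        score = mrmod.build_genetic_score(cohort.genotypes)
        ids = controls
        sc = score.loc[ids].to_numpy()
        expo = pheno.loc[ids, "phenotype_w1"].to_numpy()
        r2, f = mrmod.instrument_strength(sc, expo)
        first = []
        mvals = beta_to_m(cohort.meth_w1.beta.loc[smoking_hits, ids].to_numpy()) \
            if smoking_hits else np.empty((0, len(ids)))
        for j, site in enumerate(smoking_hits):
            res = mrmod.two_stage_least_squares(sc, expo, mvals[j])
            first.append({"site_id": site, "estimate": res.estimate,
                          "se": res.se, "p": res.p})
        results["mr_first_step"] = (pd.DataFrame(first).set_index("site_id")
                                    if first else pd.DataFrame())
        results["mr_instrument_r2"] = r2
        results["mr_instrument_f"] = f
        done(t0)

        t0 = stage("mr_second_step")
        mq = simulate_mqtl_summary(truth, rng_mr, n=config.mqtl_gwas_n)
        gwas = simulate_outcome_gwas(truth, rng_mr, n=config.outcome_gwas_n,
                                     n_cases=config.outcome_gwas_cases)
        sites_mr = identified if identified else candidates
        mq_sub = mq[mq["cpg_id"].isin(sites_mr)]
        if len(mq_sub):
            screen = mrmod.mr_second_step_screen(
                mq_sub, gwas, bonferroni_m=len(sites_mr),
                cis_only=config.cis_only)
            results["mr_second_step"] = screen
            emit("mr_second_step.tsv",
                 lambda d, p: mcio.write_table(d, p, "cpg_id"), screen)
        else:
            results["mr_second_step"] = pd.DataFrame()
        done(t0)

    manifest["total_seconds"] = round(time.time() - t_start, 3)
    manifest["results"] = results
    if outdir is not None:
        # timings are kept out of the written manifest so that identical
        # config + seed produce byte-identical files
        clean = {
            "config_hash": manifest["config_hash"],
            "seed": manifest["seed"],
            "stages": [s["name"] for s in manifest["stages"]],
            "outputs": manifest["outputs"],
            "warnings": manifest["warnings"],
        }
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(clean, fh, sort_keys=True)
    return manifest
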