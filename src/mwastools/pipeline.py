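"""End-to-end orchestration of the simulated analysis.

Runs, in order: cohort simulation, prescription-derived exposure
derivation, demographics, GRM-BLUP residualization, standardization and
ORM, MWAS for both exposure phenotypes (plus optional MDD-subgroup and
sex-stratified runs), effect-set comparison, DMR scan, cross-phenotype
circular enrichment, profile-score training, external-cohort scoring, and
random-effects pooling.  Every stage writes declared files into the run
directory and records its status in a JSON manifest; all randomness flows
from named seeds in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .dmr import dmr_results_frame, run_dmr
from .enrichment import circular_enrichment
from .exposure import derive_exposure, mdd_subgroup_mask
from .mps import cohort_association, dl_meta, score_mps, train_mps
from .mwas import compare_effect_sets, compute_orm, reml_blup_residualize, run_mwas, standardize_probes
from .synthetic import SimulationConfig, make_cohort, simulate_external_cohorts

log = logging.getLogger("mwastools.pipeline")

DEFAULT_CONFIG = {
    "simulate": {
        "n_samples": 2000,
        "n_probes": 5000,
        "n_families": 100,
        "family_size": 2,
        "causal_probes": ["cg0000010", "cg0000011", "cg0000012", "cg0002000"],
        "causal_effect": 0.4,
        "exposure_prevalence": 0.2,
        "local_corr": 0.4,
        "h2_family": 0.2,
        "seed": 7,
    },
    "exposure": {"grace_days": 30, "lead_days": 7, "tail_days": 7},
    "mwas": {"mode": "fast", "significance": 9.42e-8},
    "dmr": {"max_gap": 500, "p_thresh": 0.05, "min_probes": 2, "enumerate_subregions": False},
    "enrichment": {"fractions": [0.001, 0.005, 0.01], "n_perm": 199, "seed": 11},
    "mps": {"n_folds": 10, "seed": 13, "k_external": 3, "n_per_cohort": 600, "score_effect": 0.3},
    "subgroups": {"mdd": True, "sex_stratified": True},
}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _merge(default: dict, override: dict) -> dict:
    out = {}
    for key, val in default.items():
        if isinstance(val, dict):
            out[key] = _merge(val, override.get(key, {}))
        else:
            out[key] = override.get(key, val)
    return out


def _covariate_design(pheno: pd.DataFrame, include_sex: bool = True) -> pd.DataFrame:
    cols = {
        "age": pheno["age"].astype(float),
        "smoking_proxy_M": pheno["smoking_proxy_M"].astype(float),
        "monocyte_prop": pheno["monocyte_prop"].astype(float),
        "lymphocyte_prop": pheno["lymphocyte_prop"].astype(float),
    }
    if include_sex:
        cols["sex_M"] = (pheno["sex"] == "M").astype(float)
    return pd.DataFrame(cols, index=pheno.index)


def run_pipeline(config: dict | None = None, out_dir: str | Path = "run") -> Path:
    """Execute the full simulated pipeline; returns the run directory."""
    config = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    manifest = {"config": config, "config_hash": chash, "stages": {}}

    def _stage(name):
        def deco(fn):
            try:
                fn()
                manifest["stages"][name] = "ok"
                log.info("stage %s ok", name)
            except Exception as exc:  # preserve partial outputs + status
                manifest["stages"][name] = f"failed: {exc}"
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
                raise
        return deco

    state: dict = {}

    @_stage("simulate")
    def _simulate():
        sim = config["simulate"]
        sc = SimulationConfig(**{k: v for k, v in sim.items()})
        cohort = make_cohort(sc)
        state["cohort"] = cohort
        mio.write_methylation(cohort.methylation, out / "methylation.tsv")
        mio.write_annotation(cohort.annotation, out / "annotation.tsv")
        mio.write_grm(cohort.grm, out / "grm.tsv")
        mio.write_phenotypes(cohort.phenotypes, out / "phenotypes.tsv")
        mio.write_prescriptions(cohort.prescriptions, out / "prescriptions.csv")

    @_stage("exposure")
    def _exposure():
        cohort = state["cohort"]
        exp_cfg = config["exposure"]
        draw_days = cohort.phenotypes["draw_day"].astype(int).to_dict()
        calls = derive_exposure(
            cohort.prescriptions, draw_days,
            grace_days=exp_cfg["grace_days"],
            lead_days=exp_cfg["lead_days"],
            tail_days=exp_cfg["tail_days"],
        )
        calls.to_csv(out / "exposure.tsv", sep="\t")
        state["exposure"] = calls

    @_stage("mwas")
    def _mwas():
        cohort = state["cohort"]
        Z, _ = standardize_probes(cohort.methylation)
        orm = compute_orm(Z)
        state["Z"], state["orm"] = Z, orm
        pheno = cohort.phenotypes
        covs = _covariate_design(pheno)
        mode = config["mwas"]["mode"]

        runs = {}
        calls = state["exposure"]
        presc = (calls["status"] == "EXPOSED").astype(float)
        keep = calls["status"] != "EXCLUDED"
        phenos = {
            "self-report": pd.Series(pheno["reported_use"].astype(float), index=pheno.index),
            "prescription-derived": presc.where(keep),
        }
        for label, y in phenos.items():
            sel = y.dropna().index
            K = cohort.grm.subset_samples(sel)
            y_res, _, _ = reml_blup_residualize(y.loc[sel].to_numpy(), K)
            Zs = Z.subset_samples(sel)
            omega = orm.subset_samples(sel)
            res = run_mwas(y_res, Zs, covs.loc[sel], omega, mode=mode, analysis=label)
            runs[label] = res
            fname = out / f"mwas_{label.replace(' ', '_')}.tsv"
            mio.write_results(res, cohort.annotation, fname)

        if config["subgroups"]["mdd"]:
            mdd = mdd_subgroup_mask(pheno)
            sel = pheno.index[mdd]
            if len(sel) >= 50:
                y = phenos["self-report"].loc[sel]
                y_res, _, _ = reml_blup_residualize(y.to_numpy(), cohort.grm.subset_samples(sel))
                res = run_mwas(
                    y_res, Z.subset_samples(sel), covs.loc[sel],
                    orm.subset_samples(sel), mode=mode, analysis="self-report-mdd",
                )
                runs["self-report-mdd"] = res
                mio.write_results(res, cohort.annotation, out / "mwas_self-report-mdd.tsv")

        if config["subgroups"]["sex_stratified"]:
            for sex in ("F", "M"):
                sel = pheno.index[pheno["sex"] == sex]
                if len(sel) < 50:
                    continue
                y = phenos["self-report"].loc[sel]
                y_res, _, _ = reml_blup_residualize(y.to_numpy(), cohort.grm.subset_samples(sel))
                res = run_mwas(
                    y_res, Z.subset_samples(sel), _covariate_design(pheno.loc[sel], include_sex=False),
                    orm.subset_samples(sel), mode=mode, analysis=f"self-report-{sex}",
                )
                runs[f"self-report-{sex}"] = res
                mio.write_results(res, cohort.annotation, out / f"mwas_self-report-{sex}.tsv")
        state["runs"] = runs

    @_stage("compare")
    def _compare():
        runs = state["runs"]
        cmp = compare_effect_sets(runs["self-report"], runs["prescription-derived"])
        summary = {k: v for k, v in cmp.items() if k != "per_probe"}
        (out / "effect_comparison.json").write_text(json.dumps(summary, indent=2))
        cmp["per_probe"].to_csv(out / "effect_comparison.tsv", sep="\t", index=False)

    @_stage("dmr")
    def _dmr():
        cohort, runs = state["cohort"], state["runs"]
        dmr_cfg = config["dmr"]
        results = run_dmr(
            runs["self-report"], state["Z"], cohort.annotation,
            max_gap=dmr_cfg["max_gap"], p_thresh=dmr_cfg["p_thresh"],
            min_probes=dmr_cfg["min_probes"],
            enumerate_subregions=dmr_cfg["enumerate_subregions"],
        )
        frame = dmr_results_frame(results)
        frame.to_csv(out / "dmr.tsv", sep="\t", index=False)
        mio.write_dmr_bed(frame, out / "dmr.bed")

    @_stage("enrichment")
    def _enrich():
        runs = state["runs"]
        enr_cfg = config["enrichment"]
        res = circular_enrichment(
            runs["self-report"], runs["prescription-derived"],
            fractions=enr_cfg["fractions"], n_perm=enr_cfg["n_perm"],
            seed=enr_cfg["seed"], annotation=state["cohort"].annotation,
        )
        payload = {
            "pairs": [
                {
                    "fraction_a": p.fraction_a, "fraction_b": p.fraction_b,
                    "table": p.table, "odds_ratio": p.odds_ratio,
                    "p_empirical": p.p_empirical,
                }
                for p in res.pairs
            ],
            "best_pair": list(res.best_pair),
            "p_corrected": res.p_corrected,
            "n_permutations": res.n_permutations,
            "seed": res.seed,
            "statistic": res.statistic,
        }
        (out / "enrichment.json").write_text(json.dumps(payload, indent=2))

    @_stage("mps")
    def _mps():
        cohort = state["cohort"]
        mps_cfg = config["mps"]
        pheno = cohort.phenotypes
        y = pheno["reported_use"].astype(float).to_numpy()
        y_res, _, _ = reml_blup_residualize(y, cohort.grm)
        mask = set(cohort.annotation.loc[
            cohort.annotation["on_450k"] & cohort.annotation["on_epic"], "probe_id"
        ])
        model = train_mps(
            y_res, state["Z"], mask=mask,
            n_folds=mps_cfg["n_folds"], seed=mps_cfg["seed"],
        )
        mio.write_mps_model(model, out / "mps_model.tsv")
        cohorts = simulate_external_cohorts(
            model, mps_cfg["k_external"], mps_cfg["n_per_cohort"],
            mps_cfg["score_effect"], seed=mps_cfg["seed"] + 1,
        )
        assocs = []
        for i, (mat, exposure, covs) in enumerate(cohorts):
            score, _ = score_mps(model, mat)
            assocs.append(
                cohort_association(score, exposure, cohort=f"sim{i + 1}")
            )
        meta = dl_meta(assocs)
        table = pd.DataFrame(
            {
                "cohort": [a.cohort for a in assocs],
                "beta": [a.beta for a in assocs],
                "se": [a.se for a in assocs],
                "p": [a.p for a in assocs],
                "nagelkerke_r2": [a.nagelkerke_r2 for a in assocs],
                "n_exposed": [a.n_exposed for a in assocs],
                "n_unexposed": [a.n_unexposed for a in assocs],
                "model_type": [a.model_type for a in assocs],
            }
        )
        table.to_csv(out / "mps_cohorts.tsv", sep="\t", index=False)
        (out / "mps_meta.json").write_text(
            json.dumps(
                {
                    "beta_pooled": meta.beta_pooled, "se_pooled": meta.se_pooled,
                    "ci95": list(meta.ci95), "Q": meta.Q, "df": meta.df,
                    "tau2": meta.tau2, "i2_percent": meta.i2_percent, "k": meta.k,
                },
                indent=2,
            )
        )

    manifest["stages"] = {k: v for k, v in manifest["stages"].items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
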