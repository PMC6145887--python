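"""End-to-end orchestration: synthetic-or-load -> anthropometrics -> curves
-> diversity -> taxon merging -> functional regressions -> selection ->
covariate models, with per-stage artifacts and manifests."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anthro import (
    GrowthReference,
    classify_rapid,
    cohort_zscores,
    cwg_zscores,
    read_anthropometry,
)
from .covariates import CovariateTable, best_subset, multi_regression, prune_correlated
from .curves import CurveSet, fit_fpca, predict_curves, register_curves
from .diversity import (
    AbundanceTable,
    diversity_summary,
    mw_one_tailed,
    rarefy,
    read_counts,
)
from .errors import ConfigurationError, GrowthMicroError
from .flame import fit_flame
from .fosr import fit_fosr
from .merge import merge_taxa
from .synthetic import SyntheticConfig, simulate_cohort
from .trees import TaxTree

log = logging.getLogger("growthmicro.pipeline")


@dataclass
class PipelineConfig:
    """Paths-or-synthetic input plus all stage parameters."""

    outdir: str = "growthmicro_out"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    paths: dict | None = None        # counts (site->path), tree, anthro, covariates, reference
    # stage parameters (documented defaults)
    depth: int = 100_000
    min_count: float = 5
    prevalence: float = 0.90
    r_threshold: float = 0.7
    lambda_s: float = 10_000.0
    n_basis: int = 102
    fve: float = 0.99
    cv_folds: int = 10
    register: bool = True
    fosr_grid_size: int = 147
    flame_lambda_points: int = 8
    skip_flame: bool = False
    skip_covariates: bool = False

    def __post_init__(self):
        if self.synthetic is None and self.paths is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
        if self.synthetic is not None and self.paths is not None:
            raise ConfigurationError("give either paths or a synthetic block, not both")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if syn is not None:
            syn.setdefault("seed", cfg.seed)
            if "visit_ages" in syn:
                syn["visit_ages"] = tuple(syn["visit_ages"])
            if "effect_map" in syn:
                syn["effect_map"] = tuple(tuple(e) for e in syn["effect_map"])
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg

    def manifest_params(self) -> dict:
        return {
            "depth": self.depth, "min_count": self.min_count,
            "prevalence": self.prevalence, "r_threshold": self.r_threshold,
            "lambda_s": self.lambda_s, "n_basis": self.n_basis,
            "fve": self.fve, "cv_folds": self.cv_folds, "seed": self.seed,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _StageRunner:
    def __init__(self, outdir: Path, params: dict):
        self.outdir = outdir
        self.params = params

    def manifest(self, stage: str, inputs: list[Path], extra: dict | None = None):
        payload = {
            "stage": stage,
            "version": __version__,
            "parameters": self.params,
            "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        }
        if extra:
            payload.update(extra)
        path = self.outdir / f"manifest_{stage}.json"
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a report dict (also written to report.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runner = _StageRunner(outdir, config.manifest_params())
    report: dict = {"stages": []}
    t0 = time.time()
    stage = "init"
    try:
        # ---- stage: data -------------------------------------------------
        stage = "data"
        if config.synthetic is not None:
            cohort = simulate_cohort(config.synthetic)
            paths = cohort.write(outdir / "data")
            tables = cohort.tables
            tree = cohort.tree
            records = cohort.records
            reference = cohort.reference
            covariates = cohort.covariates
        else:
            p = config.paths
            tree = TaxTree.read(p["tree"])
            tables = {site: read_counts(path) for site, path in p["counts"].items()}
            for t in tables.values():
                t.tree = tree
                if not t.taxonomy:
                    t.taxonomy = tree.taxonomy()
            records = read_anthropometry(p["anthro"])
            reference = GrowthReference.read(p["reference"])
            covariates = CovariateTable.read(p["covariates"])
            paths = dict(p.get("counts", {}), **{k: v for k, v in p.items()
                                                 if k != "counts"})
        runner.manifest(stage, [Path(v) for v in paths.values()
                                if isinstance(v, str)])
        report["stages"].append(stage)

        # ---- stage: anthropometrics -------------------------------------
        stage = "anthro"
        zs = cohort_zscores(records, reference)
        cwg = cwg_zscores(zs["waz_birth"], zs["waz_6m"], zs["laz_birth"],
                          zs["laz_6m"], zs["age_6m"],
                          child_ids=zs["child_id"].tolist())
        cwg.write(outdir / "cwg.csv")
        rapid, non_rapid = classify_rapid(cwg)
        report["n_rapid"], report["n_non_rapid"] = len(rapid), len(non_rapid)
        runner.manifest(stage, [outdir / "cwg.csv"],
                        {"design_columns": list(cwg.design_columns)})
        report["stages"].append(stage)

        # ---- stage: growth curves ---------------------------------------
        stage = "curves"
        model = fit_fpca(records, fve_threshold=config.fve)
        curves = predict_curves(model, n_basis=config.n_basis)
        if config.register:
            curves = register_curves(curves)
        curves.write(outdir / "curves.csv", outdir / "basis.json")
        report["fpca_components"] = model.n_components
        report["fpca_sigma2"] = model.sigma2
        runner.manifest(stage, [outdir / "curves.csv", outdir / "basis.json"],
                        {"fpca": model.meta})
        report["stages"].append(stage)

        # ---- stage: diversity -------------------------------------------
        stage = "diversity"
        summaries = {}
        for site, table in tables.items():
            depth = min(config.depth, int(table.counts.sum(axis=1).min()))
            rare_tab = rarefy(table, depth, seed=config.seed)
            summ = diversity_summary(rare_tab)
            summ.to_csv(outdir / f"diversity_{site}.csv")
            summaries[site] = summ
        runner.manifest(stage, [outdir / f"diversity_{s}.csv" for s in tables])
        report["stages"].append(stage)

        # per-child features aligned with curve child ids
        child_ids = list(curves.child_ids)
        features = pd.DataFrame(index=pd.Index(child_ids, name="child_id"))
        for site, summ in summaries.items():
            vals = summ.reset_index(drop=True)
            vals.index = [f"c{i:04d}" for i in range(len(vals))]
            features[f"{site}_inverse_simpson"] = vals["inverse_simpson"].reindex(child_ids)
            features[f"{site}_fb_ratio"] = vals["fb_ratio"].reindex(child_ids)

        # rapid vs non-rapid one-tailed comparisons (lower diversity, higher F:B)
        comparisons = {}
        for col in features.columns:
            direction = "greater" if col.endswith("fb_ratio") else "less"
            a = features.loc[features.index.isin(rapid), col].dropna()
            b = features.loc[features.index.isin(non_rapid), col].dropna()
            if len(a) >= 2 and len(b) >= 2:
                comparisons[col] = mw_one_tailed(a, b, direction)
        report["rapid_comparisons"] = comparisons

        # ---- stage: taxon merging ---------------------------------------
        stage = "merge"
        merges = {}
        for site, table in tables.items():
            result = merge_taxa(table, tree, min_count=config.min_count,
                                prevalence=config.prevalence,
                                r_threshold=config.r_threshold)
            result.write(outdir / f"merged_{site}.tsv",
                         outdir / f"groups_{site}.json",
                         outdir / f"audit_{site}.tsv")
            merges[site] = result
            report[f"n_groups_{site}"] = result.n_groups
        runner.manifest(stage, [outdir / f"merged_{s}.tsv" for s in tables])
        report["stages"].append(stage)

        # ---- stage: function-on-scalar regressions ----------------------
        stage = "fosr"
        grid = np.linspace(curves.basis.domain[0], curves.basis.domain[1],
                           config.fosr_grid_size)
        Y = pd.DataFrame(curves.evaluate(grid), index=child_ids, columns=grid)
        fosr_fits = {}
        for col in features.columns:
            x = features[col]
            ok = x.notna()
            fit = fit_fosr(Y.loc[ok], x[ok].to_frame(), lambda_s=config.lambda_s,
                           mc_draws=20_000)
            fosr_fits[col] = fit
            (outdir / f"fosr_{col}.json").write_text(json.dumps(fit.to_dict()))
        report["fosr_pvalues"] = {
            col: fit.pvalues.get(col, {}) for col, fit in fosr_fits.items()
        }
        runner.manifest(stage, [outdir / f"fosr_{c}.json" for c in features.columns])
        report["stages"].append(stage)

        # ---- stage: FLAME selection -------------------------------------
        if not config.skip_flame:
            stage = "flame"
            for site, result in merges.items():
                Xg = result.matrix.copy()
                Xg.index = [f"c{i:04d}" for i in range(len(Xg))]
                Xg = Xg.reindex(child_ids).dropna()
                sel = fit_flame(Y.loc[Xg.index], Xg,
                                n_folds=min(config.cv_folds, 5),
                                lambda_grid=None, seed=config.seed)
                (outdir / f"flame_{site}.json").write_text(json.dumps(sel.to_dict()))
                report[f"flame_selected_{site}"] = list(sel.selected)
            runner.manifest(stage, [outdir / f"flame_{s}.json" for s in merges])
            report["stages"].append(stage)

        # ---- stage: covariate models ------------------------------------
        if not config.skip_covariates:
            stage = "covariates"
            cov = covariates
            cov_ids = [i for i in child_ids if i in cov.frame.index]
            prune = prune_correlated(cov.diet.loc[cov_ids], cutoff=config.r_threshold)
            report["diet_retained"] = prune.retained
            report["diet_dropped"] = [d[0] for d in prune.dropped]
            selections = {}
            diet_kept = cov.diet.loc[cov_ids, prune.retained]
            all_covs = pd.concat(
                [cov.dummies(cov.factor_columns).loc[cov_ids], diet_kept], axis=1)
            for col in features.columns:
                yv = features.loc[cov_ids, col]
                ok = yv.notna()
                if ok.sum() < 30:
                    continue
                reg = multi_regression(yv[ok], diet_kept.loc[ok.index[ok]],
                                       response_name=col)
                (outdir / f"diet_regression_{col}.txt").write_text(reg.to_text())
                if all_covs.shape[1] <= 20:
                    sel = best_subset(yv[ok], all_covs.loc[ok.index[ok]],
                                      response_name=col)
                    selections[col] = list(sel.selected)
            report["best_subset_selected"] = selections
            # joint functional regression: microbiota summary + retained diet
            joint_p = {}
            for col in ("gut_inverse_simpson", "gut_fb_ratio"):
                if col not in features.columns:
                    continue
                x = features.loc[cov_ids, col]
                ok = x.notna()
                ids_ok = x.index[ok]
                design = pd.concat([x[ok], diet_kept.loc[ids_ok]], axis=1)
                fit = fit_fosr(Y.loc[ids_ok], design, lambda_s=config.lambda_s,
                               mc_draws=20_000)
                joint_p[col] = fit.pvalues.get(col, {})
            report["joint_fosr_pvalues"] = joint_p
            runner.manifest(stage, [])
            report["stages"].append(stage)

        report["elapsed_s"] = round(time.time() - t0, 2)
        (outdir / "report.json").write_text(json.dumps(report, indent=1,
                                                       sort_keys=True, default=str))
        return report
    except GrowthMicroError:
        (outdir / "FAILED").write_text(f"stage: {stage}\n")
        log.error("pipeline failed at stage %s", stage)
        raise
    except Exception:
        (outdir / "FAILED").write_text(f"stage: {stage}\n")
        log.error("pipeline failed at stage %s", stage)
        raise
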