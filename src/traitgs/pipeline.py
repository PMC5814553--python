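"""End-to-end orchestration: QC -> GRM -> stage 1 -> strategies -> reports.

Every numeric output is reproducible from the config alone: the config's
seed drives the CV folds, and each written table carries the seed and a
config hash in a comment header.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import qc_filter, mean_impute, vanraden_grm
from .spatial import Stage1Model, select_model, combine_years, AdjustedMeans
from .strategies import (StrategyName, make_folds, compare_strategies,
                         coincidence_of_result)
from .io import (RunConfig, read_genotypes, read_plot_table,
                 read_adjusted_means, write_relationship, write_table)

__all__ = ["run_pipeline"]

log = logging.getLogger("traitgs")


def _strategy_spec(name: str, config: RunConfig) -> StrategyName:
    sec = tuple(config.secondary_traits)
    if name == "standard":
        return StrategyName(name, config.focal_trait)
    if name == "multi_trait_indirect":
        return StrategyName(name, config.focal_trait, sec)
    return StrategyName(name, config.focal_trait, sec[:1])


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis described by ``config``; returns the run dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    meta = {"seed": config.seed, "config_hash": config.digest(),
            "traitgs_version": __version__}
    stages: list[dict] = []
    try:
        _run_stages(config, out, meta, stages)
    except Exception as e:
        (out / "FAILED").write_text(f"{type(e).__name__}: {e}\n")
        _write_manifest(config, out, stages, failed=True)
        raise
    _write_manifest(config, out, stages, failed=False)
    return out


def _run_stages(config, out, meta, stages):
    log.info("reading genotypes from %s", config.genotypes)
    geno = read_genotypes(config.genotypes)
    geno, report = qc_filter(geno, config.max_missing, config.min_maf)
    stages.append({"stage": "qc",
                   "individuals_dropped": report.n_individuals_dropped_missing,
                   "markers_dropped_missing": report.n_markers_dropped_missing,
                   "markers_dropped_maf": report.n_markers_dropped_maf,
                   "n_genotypes": geno.shape[0], "n_markers": geno.shape[1]})
    geno = mean_impute(geno)
    grm = vanraden_grm(geno)
    write_relationship(grm, out / "grm.tsv", meta=meta)
    stages.append({"stage": "grm", "mean_diagonal": float(np.diag(grm.values).mean())})

    if config.plot_table is not None:
        plots = read_plot_table(config.plot_table)
        means = _stage1(config, plots, out, meta, stages)
    else:
        means = read_adjusted_means(config.adjusted_means)
    write_table(means if isinstance(means, pd.DataFrame) else means.values,
                out / "adjusted_means.tsv", meta=meta)

    xbar = means.values if isinstance(means, AdjustedMeans) else means
    common = [g for g in grm.genotype_ids if g in set(xbar.index)]
    if len(common) < len(grm.genotype_ids):
        log.warning("restricting to %d genotypes present in both inputs", len(common))
        keep = grm.index_of(common)
        from .genotypes import RelationshipMatrix
        grm = RelationshipMatrix(grm.values[np.ix_(keep, keep)], common)
        xbar = xbar.loc[common]

    # full-data stage-2 fit report + GEBV table per trait
    from .gblup import reml_univariate
    fit_rows, gebvs = [], {}
    for trait in [config.focal_trait, *config.secondary_traits]:
        f = reml_univariate(xbar[trait], grm)
        fit_rows.append({"trait": trait, "sigma2_g": f.sigma2_g,
                         "sigma2_e": f.sigma2_e, "h2_g": f.h2_g,
                         "reml_loglik": f.reml_loglik, "converged": f.converged})
        gebvs[trait] = f.gebv
        log.info("stage2 %s: h2_g=%.3f converged=%s", trait, f.h2_g, f.converged)
    write_table(pd.DataFrame(fit_rows), out / "stage2_fits.tsv", meta=meta,
                index=False)
    write_table(pd.DataFrame(gebvs), out / "gebv.tsv", meta=meta)
    stages.append({"stage": "stage2", "n_fits": len(fit_rows)})

    scheme = make_folds(len(grm.genotype_ids), config.k, config.n_repeats,
                        config.seed)
    specs = [_strategy_spec(s, config) for s in config.strategies]
    results = compare_strategies(xbar, grm, specs, scheme)
    rows, summary = [], []
    for name, res in results.items():
        for rep, (r, sd) in enumerate(zip(res.accuracies, res.gebv_sd)):
            rows.append({"strategy": name, "repeat": rep, "accuracy": r,
                         "gebv_sd": sd})
        ci_top = coincidence_of_result(res, xbar, config.intensity, "top")
        ci_bot = coincidence_of_result(res, xbar, config.intensity, "bottom")
        summary.append({"strategy": name, "mean_accuracy": res.mean,
                        "sd_accuracy": res.sd,
                        "mean_gebv_sd": float(np.mean(res.gebv_sd)),
                        "ci_top_mean": ci_top.mean, "ci_top_sd": ci_top.sd,
                        "ci_bottom_mean": ci_bot.mean, "ci_bottom_sd": ci_bot.sd})
        stages.append({"stage": f"cv:{name}", "mean_accuracy": res.mean,
                       "scheme_fingerprint": res.scheme_fingerprint})
    write_table(pd.DataFrame(rows), out / "accuracies.tsv", meta=meta, index=False)
    write_table(pd.DataFrame(summary), out / "summary.tsv", meta=meta, index=False)


def _stage1(config, plots, out, meta, stages):
    candidates = [Stage1Model(include_block="block" in plots.columns,
                              residual_structure=s)
                  for s in config.stage1_candidates]
    per_trait = {}
    report_rows = []
    for trait, sub_t in plots.groupby("trait"):
        per_year = {}
        years = sub_t.groupby("year") if "year" in sub_t.columns else [("1", sub_t)]
        for year, sub in years:
            fit = select_model(sub, candidates)
            per_year[year] = fit
            report_rows.append({
                "trait": trait, "year": year,
                "structure": fit.model.residual_structure,
                "sigma2_b": fit.sigma2_b, "sigma2_e": fit.sigma2_e,
                "rho_row": fit.rho_row, "rho_col": fit.rho_col,
                "reml_loglik": fit.reml_loglik, "aic": fit.aic,
                "converged": fit.converged})
            log.info("stage1 %s/%s: %s selected (AIC %.2f, converged=%s)",
                     trait, year, fit.model.residual_structure, fit.aic,
                     fit.converged)
        xbar, ny = combine_years(per_year, scaling=config.scaling)
        per_trait[trait] = (xbar, ny)
    write_table(pd.DataFrame(report_rows), out / "stage1_report.tsv",
                meta=meta, index=False)
    stages.append({"stage": "stage1", "n_fits": len(report_rows)})
    return AdjustedMeans.from_traits(per_trait)


def _write_manifest(config, out, stages, failed):
    import scipy
    manifest = {
        "failed": failed,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": json.loads(json.dumps(config.__dict__, default=str)),
        "versions": {"traitgs": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
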