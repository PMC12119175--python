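"""End-to-end orchestration: config, staging, report tables and run log."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from habseg import dataprep, segregation, simulate
from habseg.competition import asymmetry_report, fit_competition_model
from habseg.errors import ConfigError, DataError
from habseg.glmm import ModelSpec, select_family_and_structure
from habseg.partition import (contrast_partition, model_r2,
                              per_variable_partial_r2, r2_ci)
from habseg.selection import (average_coefficients, best_significant_model,
                              competing_set, enumerate_and_rank)

DEFAULT_PREDICTORS = ("tcov", "moist", "hcov", "rocks")


@dataclass
class RunConfig:
    """Everything a full run needs; mirrored one-to-one by CLI flags."""

    seed: int
    input_csv: str | None = None
    simulation: dict = field(default_factory=dict)
    species: tuple = ("af", "cg")
    predictors: tuple = DEFAULT_PREDICTORS
    elevation_cut: float = 1300.0
    alpha: float = 0.05
    delta_aicc: float = 2.0
    convention: str = "mean-weight"
    family_policy: str = "auto"          # 'auto' | 'poisson' | 'negbin'
    random_intercept: str = "auto"       # 'auto' | 'year' | 'none'
    jackknife: bool = True
    n_boot: int = 0                      # r2 bootstrap draws; 0 skips the CI
    standardize_scope: str = "subset"    # 'subset' | 'global'
    outdir: str = "habseg_results"

    def validate(self) -> None:
        if self.alpha <= 0 or self.delta_aicc <= 0:
            raise ConfigError("alpha/delta_aicc: thresholds must be positive")
        if len(set(self.species)) != len(self.species):
            raise ConfigError("species: columns must be distinct")
        if self.convention not in segregation.CONVENTIONS:
            raise ConfigError(f"convention: must be one of {segregation.CONVENTIONS}")
        if self.standardize_scope not in ("subset", "global"):
            raise ConfigError("standardize_scope: must be 'subset' or 'global'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigError("seed: mandatory in the config file")
        for key in ("species", "predictors"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def validate_input(path) -> dict:
    """Schema/range validation report for a transect CSV."""
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise DataError(f"cannot read {path}: {exc}") from exc
    errors = dataprep.validate_records(df)
    return {"path": str(path), "n_rows": len(df), "errors": errors,
            "passed": not errors}


def _load_data(cfg: RunConfig) -> pd.DataFrame:
    if cfg.input_csv:
        return dataprep.read_transects(cfg.input_csv)
    sim_kwargs = dict(cfg.simulation)
    sim_kwargs.setdefault("seed", cfg.seed)
    replica = sim_kwargs.pop("study_replica", True)
    if replica:
        seed = sim_kwargs.pop("seed")
        return simulate.generate_study_replica(seed, **sim_kwargs)
    return simulate.generate_dataset(simulate.SimulationConfig(**sim_kwargs))


def _analyse_subset(df_subset, species, cfg: RunConfig, log: dict, name: str):
    """Selection pipeline for one subset x species; returns a result dict."""
    candidates = list(cfg.predictors)
    zdf = dataprep.standardize_frame(df_subset, candidates)
    base = ModelSpec(species=f"count_{species}", predictors=tuple(candidates))
    if cfg.family_policy == "auto" or cfg.random_intercept == "auto":
        final, trail = select_family_and_structure(base, zdf, alpha=cfg.alpha)
        family = final.family if cfg.family_policy == "auto" else cfg.family_policy
        rint = (final.random_intercept if cfg.random_intercept == "auto"
                else cfg.random_intercept)
    else:
        family, rint, trail = cfg.family_policy, cfg.random_intercept, []
    log.setdefault("decisions", {})[f"{name}:{species}"] = trail
    base = ModelSpec(species=f"count_{species}", family=family,
                     random_intercept=rint)
    table = enumerate_and_rank(candidates, zdf, base)
    cs = competing_set(table, threshold=cfg.delta_aicc)
    avg = average_coefficients(cs, mode="full", variables=candidates)
    best, path = best_significant_model(table, zdf, alpha=cfg.alpha,
                                        threshold=cfg.delta_aicc)
    log["decisions"][f"{name}:{species}:best_model_path"] = path
    return {"zdf": zdf, "table": table, "competing": cs, "avg": avg,
            "best": best, "species": species}


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; write report CSVs and a JSON run log."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": asdict(config), "decisions": {}}

    df = _load_data(config)
    errors = dataprep.validate_records(df)
    if errors:
        raise DataError("input failed validation: " + "; ".join(errors))

    low, high = dataprep.split_by_elevation(df, config.elevation_cut)
    odd, even = dataprep.split_by_year_parity(df)
    log["splits"] = {"n": len(df), "low": len(low), "high": len(high),
                     "odd": len(odd), "even": len(even)}

    # --- abundance comparisons (Wilcoxon on trapping rates) ---------------
    wilcoxon_rows = []
    for sp in config.species:
        col = f"count_{sp}"
        for label, (g1, g2) in {"LOW_vs_HIGH": (low, high),
                                "ODD_vs_EVEN": (odd, even)}.items():
            w, p = segregation.wilcoxon_rank_sum(
                dataprep.trapping_rate(g1[col], g1["effort"]),
                dataprep.trapping_rate(g2[col], g2["effort"]))
            wilcoxon_rows.append({"species": sp, "contrast": label,
                                  "W": w, "p": p})
    pd.DataFrame(wilcoxon_rows).to_csv(outdir / "wilcoxon.csv", index=False,
                                       float_format="%.6g")

    # --- overall habitat models and the contrast partition ----------------
    overall = {sp: _analyse_subset(df, sp, config, log, "ALL")
               for sp in config.species}
    sp_a, sp_c = config.species
    zdf_all = overall[sp_a]["zdf"]
    best_a = overall[sp_a]["best"]
    best_c_spec = overall[sp_c]["best"].spec
    from habseg.glmm import fit_count_model
    best_c = fit_count_model(best_c_spec, zdf_all)  # same frame for both
    part = contrast_partition(best_a, best_c, zdf_all, alpha=config.alpha)

    rows = []
    for sp, best in ((sp_a, best_a), (sp_c, best_c)):
        pr2 = per_variable_partial_r2(best, zdf_all)
        frame = best.to_frame()
        frame["species"] = sp
        frame["partial_r2"] = frame["term"].map(pr2)
        frame["group"] = frame["term"].map(
            lambda t: "contrasting" if t in part.contrasting
            else ("shared" if t in part.shared else ""))
        frame["model_r2"] = part.model_r2[f"count_{sp}"]
        frame["contrasting_r2"] = part.contrasting_r2[f"count_{sp}"]
        if config.n_boot >= 100:
            lo, hi, _ = r2_ci(best, n_boot=config.n_boot, seed=config.seed)
            frame["model_r2_lo"], frame["model_r2_hi"] = lo, hi
        rows.append(frame)
    pd.concat(rows).to_csv(outdir / "best_models.csv", index=False,
                           float_format="%.6g")
    log["contrast_partition"] = {
        "contrasting": part.contrasting, "shared": part.shared,
        "model_r2": part.model_r2, "contrasting_r2": part.contrasting_r2,
        "share_pct": part.share_pct}

    # --- per-stratum responses, distances, jackknife ----------------------
    policies = {}
    for sp in config.species:
        fam = (config.family_policy if config.family_policy != "auto"
               else overall[sp]["best"].spec.family)
        rint = (config.random_intercept if config.random_intercept != "auto"
                else overall[sp]["best"].spec.random_intercept)
        policies[sp] = (fam, rint)

    def stratum_vectors(stratum_df, name):
        return {sp: segregation.species_response(
            stratum_df, sp, list(config.predictors), stratum=name,
            family=policies[sp][0], random_intercept=policies[sp][1],
            threshold=config.delta_aicc) for sp in config.species}

    vec_low = stratum_vectors(low, "LOW")
    vec_high = stratum_vectors(high, "HIGH")

    avg_rows = []
    for name, vecs in (("LOW", vec_low), ("HIGH", vec_high)):
        for sp, v in vecs.items():
            for var, b, w in zip(v.names, v.beta, v.weight):
                avg_rows.append({"stratum": name, "species": sp,
                                 "variable": var, "beta": b,
                                 "partial_r2": w})
    pd.DataFrame(avg_rows).to_csv(outdir / "averaged_coefficients.csv",
                                  index=False, float_format="%.6g")

    def stratum_distance(stratum_df):
        vecs = stratum_vectors(stratum_df, "jk")
        return segregation.weighted_distance(vecs[sp_a], vecs[sp_c],
                                             config.convention)

    d_low = segregation.weighted_distance(vec_low[sp_a], vec_low[sp_c],
                                          config.convention)
    d_high = segregation.weighted_distance(vec_high[sp_a], vec_high[sp_c],
                                           config.convention)
    dist_rows = [{"stratum": "LOW", "distance": d_low},
                 {"stratum": "HIGH", "distance": d_high}]
    if config.jackknife:
        report = segregation.jackknife_distances(low, high, stratum_distance)
        dist_rows = [
            {"stratum": "LOW", "distance": report.d_low,
             "jackknife_mean": report.mean_low,
             "ci_lo": report.ci_low[0], "ci_hi": report.ci_low[1],
             "n_pairs": len(report.pairs), "t": report.t,
             "df": report.df, "p": report.p},
            {"stratum": "HIGH", "distance": report.d_high,
             "jackknife_mean": report.mean_high,
             "ci_lo": report.ci_high[0], "ci_hi": report.ci_high[1],
             "n_pairs": len(report.pairs), "t": report.t,
             "df": report.df, "p": report.p},
        ]
        log["jackknife"] = {"n_pairs": int(len(report.pairs)),
                            "failed_pairs": int(report.failed_pairs),
                            "t": report.t, "df": report.df, "p": report.p,
                            "mean_diff": report.mean_diff}
    pd.DataFrame(dist_rows).to_csv(outdir / "distances.csv", index=False,
                                   float_format="%.6g")
    log["distances"] = {"convention": config.convention,
                        "d_low": d_low, "d_high": d_high}

    # --- competition (both directions, overall data) ----------------------
    res_c_on_a = fit_competition_model(best_a, sp_c, zdf_all, alpha=config.alpha)
    res_a_on_c = fit_competition_model(best_c, sp_a, zdf_all, alpha=config.alpha)
    asym = asymmetry_report(res_c_on_a, res_a_on_c, alpha=config.alpha)
    comp_rows = []
    for res in (res_c_on_a, res_a_on_c):
        comp_rows.append({"focal": res.focal, "competitor": res.competitor,
                          "b": res.b, "se": res.se, "chi2": res.chi2,
                          "df": res.df, "p": res.p, "share": res.share,
                          "direction": res.direction})
    pd.DataFrame(comp_rows).to_csv(outdir / "competition.csv", index=False,
                                   float_format="%.6g")
    log["competition"] = asym

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return log
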