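"""End-to-end analysis pipeline: calibrate -> harmonize -> group tests ->
trajectories -> associations -> mediation.

Configured from a plain dict / YAML block; every stochastic stage is
seeded from the config seed, so two runs with the same config produce
byte-identical deterministic outputs. Stages never mutate their input
table; each stage logs row counts and writes tidy CSV/JSON outputs plus a
run manifest (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import associations as assoc
from . import calibration as calib
from . import harmonize as harm
from . import trajectory as traj
from .cohort import (CohortSpec, add_measure, generate_cohort,
                     generate_retest, write_cohort_csv)

logger = logging.getLogger("adbrainage")

__all__ = ["AnalysisConfig", "ResultsBundle", "run_pipeline", "read_cohort",
           "write_bundle", "demo_config"]

REQUIRED_COLUMNS = ["participant_id", "family_id", "site_id", "group",
                    "age", "eyo", "sex", "education", "apoe4",
                    "raw_predicted_age"]

_NA_TOKEN = ""


@dataclass
class AnalysisConfig:
    """Pipeline configuration.

    ``cohort_csv`` may be None when a ``simulate`` block is given, in which
    case the cohort is generated synthetically at run time.
    """
    output_dir: str = "results"
    seed: int = 0
    cohort_csv: str | None = None
    retest_csv: str | None = None
    simulate: dict | None = None
    harmonization: dict = field(default_factory=lambda: {
        "batch": "site_id",
        "covariates": ["age", "sex", "education", "group", "eyo", "apoe4",
                       "variant"],
        "sequential_scanner": False,
    })
    gamm: dict = field(default_factory=lambda: {
        "k": 4, "grid_step": 0.05, "level": 0.834, "n_draws": 10000,
        "n_boot": 500, "boot_grid_step": 0.25, "boot_n_draws": 500,
        "measures": ["bag"],
    })
    association: dict = field(default_factory=lambda: {
        "biomarkers": ["pib_suvr", "csf_ab42_40", "csf_ptau_ab40",
                       "plasma_ptau181", "csf_nfl", "plasma_nfl"],
        "covariates": ["sex", "education", "apoe4"],
        "n_boot_mediation": 1000,
        "outcome": "cognitive_composite",
    })
    verbosity: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        cfg = cls()
        for key, val in d.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
                merged = dict(getattr(cfg, key))
                merged.update(val)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, val)
        return cfg

    def to_dict(self) -> dict:
        return {
            "output_dir": self.output_dir, "seed": self.seed,
            "cohort_csv": self.cohort_csv, "retest_csv": self.retest_csv,
            "simulate": self.simulate, "harmonization": self.harmonization,
            "gamm": self.gamm, "association": self.association,
            "verbosity": self.verbosity,
        }


@dataclass
class ResultsBundle:
    cohort: pd.DataFrame
    bag_table: pd.DataFrame
    performance: dict
    reliability: dict | None
    harmonization_report: pd.DataFrame
    batch_tests: dict
    group_tests: dict
    bands: dict                 # measure -> DataFrame(grid, fit, lower, upper)
    divergence: traj.DivergenceResult | None
    association_table: pd.DataFrame
    mediation_table: pd.DataFrame
    manifest: dict


def demo_config(seed: int = 1, output_dir: str = "results",
                n_boot: int = 200) -> AnalysisConfig:
    """Self-contained demo: synthetic cohort plus one extra MRI-like
    measure compared against BAG in the divergence bootstrap."""
    cfg = AnalysisConfig(output_dir=output_dir, seed=seed)
    cfg.simulate = {"extra_measures": {"atrophy_proxy": {"divergence_eyo": -5.0}}}
    cfg.gamm = dict(cfg.gamm)
    cfg.gamm.update({"n_boot": n_boot, "n_draws": 2000,
                     "measures": ["bag", "atrophy_proxy"],
                     "grid_step": 0.05})
    cfg.association = dict(cfg.association)
    cfg.association["n_boot_mediation"] = 500
    return cfg


def apply_site_eligibility(table: pd.DataFrame, min_per_site: int = 5,
                           site_col: str = "site_id") -> pd.DataFrame:
    """Keep only sites with at least ``min_per_site`` participants.

    Site/scanner characterization and harmonization need several
    participants per site; smaller sites are excluded from the analysis
    set (the standard eligibility rule for multi-site harmonization).
    """
    counts = table[site_col].value_counts()
    keep = counts.index[counts >= min_per_site]
    dropped = len(table) - int(table[site_col].isin(keep).sum())
    if dropped:
        logger.info("site eligibility: dropping %d participants from %d "
                    "small sites", dropped, (counts < min_per_site).sum())
    return table[table[site_col].isin(keep)].reset_index(drop=True)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (UTF-8, header row, empty-string NA token)."""
    try:
        df = pd.read_csv(path, na_values=[_NA_TOKEN], encoding="utf-8")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed cohort CSV {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    return df


def _hash_config(cfg: AnalysisConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=False).values.tobytes()
    ).hexdigest()[:16]


def _encode_harmonization_covariates(table: pd.DataFrame, names) -> pd.DataFrame:
    out = {}
    for c in names:
        if c not in table.columns:
            continue
        s = table[c]
        if s.dtype == object:
            for lv in sorted(map(str, s.dropna().unique()))[1:]:
                out[f"{c}[{lv}]"] = (s.astype(str) == lv).astype(float)
        else:
            out[c] = s.astype(float)
    return pd.DataFrame(out, index=table.index)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def run_pipeline(config: AnalysisConfig) -> ResultsBundle:
    """Execute all stages in order and write outputs to the config's
    output directory."""
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(rng.integers(2**31)) for name in
                   ("simulate", "retest", "bands", "bootstrap", "mediation")}

    # ---- input stage -----------------------------------------------------
    if config.cohort_csv:
        cohort = read_cohort(config.cohort_csv)
        spec = None
    else:
        sim = dict(config.simulate or {})
        extra = sim.pop("extra_measures", {})
        spec = CohortSpec(**sim)
        cohort = generate_cohort(spec, seed=stage_seeds["simulate"])
        for i, (name, kw) in enumerate(sorted(extra.items())):
            cohort = add_measure(cohort, spec, name,
                                 seed=stage_seeds["simulate"] + 1 + i, **kw)
        write_cohort_csv(cohort, out_dir / "cohort.csv")
    cohort = apply_site_eligibility(
        cohort, config.harmonization.get("min_per_site", 5))
    logger.info("cohort: %d rows, %d families", len(cohort),
                cohort["family_id"].nunique())
    input_hash = _hash_frame(cohort)

    # ---- calibration -----------------------------------------------------
    nc = cohort[cohort["group"] == "NC"]
    model = calib.fit_calibration(nc)
    corrected = calib.apply_calibration(
        model, cohort["raw_predicted_age"].to_numpy())
    perf = calib.performance_metrics(nc["raw_predicted_age"], nc["age"])
    performance = {"r": perf.r, "r2": perf.r2, "mae": perf.mae,
                   "rmse": perf.rmse, "n": perf.n,
                   "calibration": {"intercept": model.intercept,
                                   "slope": model.slope, "n_fit": model.n_fit}}
    logger.info("calibration fit on %d NCs: slope=%.3f intercept=%.2f",
                model.n_fit, model.slope, model.intercept)

    # ---- reliability -----------------------------------------------------
    reliability = None
    retest = None
    if config.retest_csv:
        retest = pd.read_csv(config.retest_csv)
    elif spec is not None:
        retest = generate_retest(cohort, spec.icc_target,
                                 seed=stage_seeds["retest"])
    if retest is not None and len(retest) >= 3:
        rep = calib.icc_a1(retest["visit1"], retest["visit2"])
        reliability = {"icc": rep.icc, "ci_low": rep.ci_low,
                       "ci_high": rep.ci_high, "n_pairs": rep.n_pairs}

    # ---- harmonization ---------------------------------------------------
    hcfg = config.harmonization
    batch_col = hcfg.get("batch", "site_id")
    cov_df = _encode_harmonization_covariates(cohort, hcfg.get("covariates", []))
    pre_h, pre_df, pre_p = harm.batch_difference_test(
        corrected - cohort["age"].to_numpy(), cohort[batch_col])
    bm = harm.fit_combat(corrected, cohort[batch_col], cov_df)
    harmonized = harm.apply_combat(bm, corrected, cohort[batch_col], cov_df)
    if hcfg.get("sequential_scanner") and "scanner_id" in cohort.columns:
        bm2 = harm.fit_combat(harmonized, cohort["scanner_id"], cov_df)
        harmonized = harm.apply_combat(bm2, harmonized, cohort["scanner_id"],
                                       cov_df)
    bag = calib.compute_bag(harmonized, cohort["age"].to_numpy())
    post_h, post_df, post_p = harm.batch_difference_test(bag, cohort[batch_col])
    batch_tests = {
        "pre": {"h": pre_h, "df": pre_df, "p": pre_p},
        "post": {"h": post_h, "df": post_df, "p": post_p},
    }
    if "scanner_id" in cohort.columns and \
            cohort["scanner_id"].nunique() >= 2:
        sh, sdf, sp = harm.batch_difference_test(bag, cohort["scanner_id"])
        batch_tests["post_scanner"] = {"h": sh, "df": sdf, "p": sp}
    harmonization_report = pd.DataFrame({
        "batch": bm.batch_levels,
        "n": bm.batch_sizes,
        "gamma_star": bm.gamma_star,
        "delta_star": bm.delta_star,
    })
    logger.info("harmonization: site KW p %.3f -> %.3f", pre_p, post_p)

    analysis = cohort.copy()
    analysis["corrected_predicted_age"] = harmonized
    analysis["bag"] = bag
    bag_table = analysis[["participant_id", "group", "age", "eyo",
                          "raw_predicted_age", "corrected_predicted_age",
                          "bag"]]

    # ---- group tests -----------------------------------------------------
    gc = assoc.group_comparison(analysis["bag"], analysis["group"])
    lw, lp = assoc.levene_test(analysis["bag"], analysis["group"])
    d_sym = assoc.cohens_d(
        analysis.loc[analysis["group"] == "sym_MC", "bag"],
        analysis.loc[analysis["group"] == "NC", "bag"])
    group_tests = {
        "kruskal": {"h": gc.h, "df": gc.df, "p": gc.p},
        "pairwise": gc.pairs.to_dict(orient="records"),
        "levene": {"w": lw, "p": lp},
        "cohens_d_sym_vs_nc": {"d": d_sym[0], "ci": list(d_sym[1])},
    }

    # ---- trajectories ----------------------------------------------------
    gcfg = config.gamm
    measures = [m for m in gcfg.get("measures", ["bag"])
                if m in analysis.columns]
    grid = traj._common_grid(analysis, gcfg.get("grid_step", 0.05))
    bands = {}
    divergence_summary = {}
    for m in measures:
        fit = traj.fit_gamm(analysis, response=m, k=gcfg.get("k", 4))
        b_nc = traj.simultaneous_band(fit, "s(eyo):NC", grid,
                                      gcfg.get("level", 0.834),
                                      gcfg.get("n_draws", 10000),
                                      stage_seeds["bands"])
        b_mc = traj.simultaneous_band(fit, "s(eyo):MC", grid,
                                      gcfg.get("level", 0.834),
                                      gcfg.get("n_draws", 10000),
                                      stage_seeds["bands"] + 1)
        eyo_star = traj.find_divergence(b_mc, b_nc)
        edf_mc, p_mc = traj.smooth_term_test(fit, "s(eyo):MC")
        edf_nc, p_nc = traj.smooth_term_test(fit, "s(eyo):NC")
        bands[m] = pd.DataFrame({
            "eyo": grid,
            "fit_nc": b_nc.fit, "lower_nc": b_nc.lower, "upper_nc": b_nc.upper,
            "fit_mc": b_mc.fit, "lower_mc": b_mc.lower, "upper_mc": b_mc.upper,
        })
        divergence_summary[m] = {
            "eyo_star": eyo_star,
            "edf_mc": edf_mc, "p_mc": p_mc,
            "edf_nc": edf_nc, "p_nc": p_nc,
            "var_family": fit.var_family,
        }
        logger.info("measure %s: divergence at %s EYO (MC EDF %.2f)",
                    m, f"{eyo_star:.2f}" if eyo_star is not None else "none",
                    edf_mc)

    divergence = None
    if gcfg.get("n_boot", 0) >= 100 and len(measures) >= 1:
        divergence = traj.bootstrap_divergence(
            analysis, measures, n_boot=gcfg["n_boot"],
            seed=stage_seeds["bootstrap"],
            k=gcfg.get("k", 4),
            grid_step=gcfg.get("boot_grid_step", 0.25),
            level=gcfg.get("level", 0.834),
            n_draws=gcfg.get("boot_n_draws", 500))
        for m in measures:
            s = divergence.measures[m]
            divergence_summary[m].update(
                {"boot_median": s["median"], "boot_ci": list(s["ci"]),
                 "n_censored": s["n_censored"]})

    # ---- associations ----------------------------------------------------
    acfg = config.association
    rows = []
    med_rows = []
    for biom in acfg.get("biomarkers", []):
        if biom not in analysis.columns:
            continue
        try:
            fit = assoc.fit_lme_biomarker(analysis, biom,
                                          covariates=acfg["covariates"])
        except ValueError as exc:
            logger.warning("skipping %s: %s", biom, exc)
            continue
        t = fit.table.copy()
        t.insert(0, "biomarker", biom)
        t["n"] = fit.n
        rows.append(t)
        for grp in ("sym_MC", "asym_MC"):
            try:
                r, p, n = assoc.group_correlations(analysis, biom, grp)
            except ValueError:
                continue
            rows.append(pd.DataFrame(
                [{"biomarker": biom, "term": f"pearson[{grp}]", "estimate": r,
                  "se": np.nan, "stat": np.nan, "df": np.nan, "p": p,
                  "eta_p2": np.nan, "n": n}]))
        try:
            med = assoc.mediate(analysis, biom, "bag", acfg["outcome"],
                                covariates=acfg["covariates"],
                                n_boot=acfg.get("n_boot_mediation", 1000),
                                seed=stage_seeds["mediation"])
            med_rows.append({"biomarker": biom, "a": med.a, "b": med.b,
                             "indirect": med.indirect, "direct": med.direct,
                             "total": med.total, "ci_low": med.ci_low,
                             "ci_high": med.ci_high, "label": med.label,
                             "n": med.n})
        except ValueError as exc:
            logger.warning("mediation skipped for %s: %s", biom, exc)
    association_table = pd.concat(rows, ignore_index=True) if rows else \
        pd.DataFrame(columns=["biomarker", "term", "estimate", "se", "stat",
                              "df", "p", "eta_p2", "n"])
    mediation_table = pd.DataFrame(med_rows)

    if _hash_frame(cohort) != input_hash:
        raise RuntimeError("pipeline stage mutated its input table")

    manifest = {
        "package_version": __version__,
        "config_hash": _hash_config(config),
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "n_rows": len(cohort),
        "input_hash": input_hash,
    }
    bundle = ResultsBundle(
        cohort=cohort, bag_table=bag_table, performance=performance,
        reliability=reliability, harmonization_report=harmonization_report,
        batch_tests=batch_tests, group_tests=group_tests, bands=bands,
        divergence=divergence, association_table=association_table,
        mediation_table=mediation_table, manifest=manifest)
    write_bundle(bundle, out_dir, divergence_summary)
    return bundle


def write_bundle(bundle: ResultsBundle, out_dir,
                 divergence_summary: dict | None = None) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.bag_table.to_csv(out_dir / "bag_table.csv", index=False)
    _dump_json(bundle.performance, out_dir / "performance.json")
    if bundle.reliability is not None:
        _dump_json(bundle.reliability, out_dir / "reliability.json")
    bundle.harmonization_report.to_csv(
        out_dir / "harmonization_report.csv", index=False)
    _dump_json(bundle.batch_tests, out_dir / "batch_tests.json")
    _dump_json(bundle.group_tests, out_dir / "group_tests.json")
    for m, df in bundle.bands.items():
        df.to_csv(out_dir / f"bands_{m}.csv", index=False)
    if divergence_summary is not None:
        _dump_json(divergence_summary, out_dir / "divergence.json")
    if bundle.divergence is not None:
        _dump_json({f"{a}|{b}": p
                    for (a, b), p in bundle.divergence.pairwise_p.items()},
                   out_dir / "divergence_pairwise.json")
    bundle.association_table.to_csv(out_dir / "associations.csv", index=False)
    bundle.mediation_table.to_csv(out_dir / "mediation.csv", index=False)
    _dump_json(bundle.manifest, out_dir / "manifest.json")
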