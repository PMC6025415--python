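"""YAML-configured orchestration of the full analysis.

``run_pipeline`` reads a survey bundle (sample table, blank, per-sample
EEMs and absorbance spectra), applies the configured preprocessing order,
then writes one CSV per stage — FRI volumes, CDOM indices, PAE
composition, per-sample risk, correlations and the DEP~Φ regressions —
plus a run manifest.  The pipeline is a pure function of (inputs, config):
re-running with the same inputs reproduces the same tables.

Partial outputs are removed when a stage fails, so an output directory is
either complete or empty of this run's files.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, absorption, association, fri, preprocess, risk
from .dataio import read_absorbance, read_eem, read_samples
from .exceptions import MissingInputError, ValidationError

__all__ = ["run_pipeline", "load_config"]

DEFAULT_CONFIG: dict = {
    "io": {"samples": "samples.csv", "blank": None,
           "eem_dir": "eems", "absorbance_dir": "absorbance"},
    "preprocess": {
        "order": ["blank", "inner_filter", "scatter"],
        "scatter": {"halfwidth1_nm": 15.0, "halfwidth2_nm": 15.0, "mode": "interpolate"},
        "ife": {"enabled": True},
    },
    "fri": {"multiplication_factors": False, "regions": None},
    "risk": {"dr": 2.0, "ef": 350.0, "ed": 30.0, "bw": 60.0, "at": 26280.0,
             "rfd": {"DMP": 1.0, "DEP": 0.8, "DBP": 0.1}, "csf": {}},
    "association": {"columns": None},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path) -> dict:
    """Load a pipeline YAML, filling unspecified keys with defaults."""
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"config file not found: {path}")
    with path.open() as fh:
        user = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, user)
    cfg["_base_dir"] = str(path.parent)
    return cfg


def _regions_from_config(cfg_fri: dict):
    spec_rows = cfg_fri.get("regions")
    if not spec_rows:
        return fri.DEFAULT_REGIONS
    return tuple(
        fri.RegionDef(int(r["region_id"]), (float(r["ex_low"]), float(r["ex_high"])),
                      (float(r["em_low"]), float(r["em_high"])), str(r.get("label", "")))
        for r in spec_rows)


def _risk_params(cfg_risk: dict) -> risk.RiskParams:
    rfd = dict(cfg_risk.get("rfd") or {})
    if "rfd_ug_per_kg_day" in cfg_risk:  # µg-based entry converted once at load
        rfd.update({k: v / 1000.0 for k, v in cfg_risk["rfd_ug_per_kg_day"].items()})
    return risk.RiskParams(
        dr_l_per_day=float(cfg_risk.get("dr", 2.0)),
        ef_days_per_year=float(cfg_risk.get("ef", 350.0)),
        ed_years=float(cfg_risk.get("ed", 30.0)),
        bw_kg=float(cfg_risk.get("bw", 60.0)),
        at_days=float(cfg_risk.get("at", 26280.0)),
        rfd_mg_per_kg_day=rfd,
        csf_per_mg_per_kg_day=dict(cfg_risk.get("csf") or {}),
    )


def run_pipeline(config, out_dir, force_uncorrected: bool = False) -> dict:
    """Execute every stage and write the result tables under ``out_dir``.

    ``config`` is a YAML path or an already-merged dict.  Returns the run
    manifest (also written as ``manifest.json``).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    base = Path(config.get("_base_dir", "."))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    run_warnings: list[str] = []

    def _resolve(rel) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else base / p

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            manifest = _run_stages(config, base, out, written, force_uncorrected,
                                   _resolve)
        run_warnings.extend(f"{w.category.__name__}: {w.message}" for w in caught)
        manifest["warnings"] = run_warnings
        manifest_path = out / "manifest.json"
        with manifest_path.open("w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _run_stages(config, base, out, written, force_uncorrected, resolve) -> dict:
    import numpy
    import scipy

    io_cfg = config["io"]
    samples_path = resolve(io_cfg["samples"])
    survey = read_samples(samples_path)

    blank = None
    if io_cfg.get("blank"):
        blank = read_eem(resolve(io_cfg["blank"]))

    eem_dir = resolve(io_cfg["eem_dir"])
    abs_dir = resolve(io_cfg["absorbance_dir"])
    if not eem_dir.is_dir():
        raise MissingInputError(f"EEM directory not found: {eem_dir}")
    if not abs_dir.is_dir():
        raise MissingInputError(f"absorbance directory not found: {abs_dir}")

    pp_cfg = config["preprocess"]
    scatter_cfg = pp_cfg["scatter"]
    regions = _regions_from_config(config["fri"])
    params = _risk_params(config["risk"])

    fri_rows, index_rows, risk_rows = [], [], []
    for record in survey.records:
        sid = record.sample_id
        eem_path = eem_dir / f"{sid}.csv"
        abs_path = abs_dir / f"{sid}.csv"
        if not eem_path.exists():
            raise MissingInputError(f"preprocess stage: EEM missing for {sid}: {eem_path}")
        if not abs_path.exists():
            raise MissingInputError(f"absorption stage: spectrum missing for {sid}: {abs_path}")
        eem = read_eem(eem_path, sample_id=sid)
        spectrum = read_absorbance(abs_path, sample_id=sid)

        for step in pp_cfg["order"]:
            if step == "blank":
                if blank is not None:
                    eem = preprocess.subtract_blank(eem, blank)
            elif step == "inner_filter":
                if pp_cfg["ife"]["enabled"]:
                    eem = preprocess.inner_filter_correct(eem, spectrum)
            elif step == "scatter":
                eem = preprocess.remove_scatter(
                    eem, float(scatter_cfg["halfwidth1_nm"]),
                    float(scatter_cfg["halfwidth2_nm"]), scatter_cfg["mode"])
            else:
                raise ValidationError(f"preprocess stage: unknown step {step!r}")

        res = fri.fri_components(eem, regions=regions, force=force_uncorrected,
                                 multiplication_factors=config["fri"]["multiplication_factors"])
        row = {"sample_id": sid, "season": record.season, "site_id": record.site_id}
        for rid in sorted(res.phi):
            row[f"phi{rid}"] = res.phi[rid]
            row[f"p{rid}"] = res.p[rid] if res.p else math.nan
        row.update({"phi_total": res.phi_total, "f_allo": res.f_allo,
                    "f_auto": res.f_auto, "unassigned": res.unassigned})
        fri_rows.append(row)

        idx = absorption.cdom_indices(spectrum, record.doc_mg_per_l, eem=eem)
        index_rows.append({"sample_id": sid, "season": record.season,
                           "site_id": record.site_id, "fi370": idx.fi370,
                           "fi310": idx.fi310, "s275_295": idx.s275_295_per_nm,
                           "a350": idx.a350_per_m, "a254": idx.a254_per_m,
                           "e250_365": idx.e250_365,
                           "suva254": idx.suva254_l_per_mgc_per_m,
                           "slope_ratio_sr": idx.slope_ratio_sr,
                           "source_origin": idx.source_origin,
                           "source_autochthony": idx.source_autochthony})

        assessment = risk.assess_sample(record.pae_concentrations(), params, sid)
        risk_row = {"sample_id": sid, "season": record.season, "site_id": record.site_id}
        for congener, add in assessment.add_mg_per_kg_day.items():
            risk_row[f"add_{congener}"] = add
            risk_row[f"hq_{congener}"] = assessment.hq[congener]
        risk_row.update({"hi": assessment.hi, "classification": assessment.classification,
                         "carcinogenic_tier": assessment.carcinogenic_tier})
        risk_rows.append(risk_row)

    fri_table = pd.DataFrame(fri_rows)
    index_table = pd.DataFrame(index_rows)
    risk_table = pd.DataFrame(risk_rows)
    composition = risk.pae_composition(survey.records).reset_index()

    assoc_table = fri_table[["sample_id", "phi1", "phi2", "phi3", "phi4", "phi5"]].merge(
        index_table[["sample_id", "fi370", "fi310", "a350"]], on="sample_id")
    survey_frame = survey.to_frame()
    survey_frame["sample_id"] = [r.sample_id for r in survey.records]
    assoc_table = assoc_table.merge(
        survey_frame[["sample_id", "doc_mg_per_l", "chla_ug_per_l",
                      "dmp_mg_per_l", "dep_mg_per_l", "dbp_mg_per_l"]],
        on="sample_id")
    columns = config["association"]["columns"] or [
        c for c in assoc_table.columns if c != "sample_id"]
    correlations = association.pearson_matrix(assoc_table, columns)

    regression_rows = []
    for rid in range(1, 6):
        fit = association.regress_simple(assoc_table[f"phi{rid}"],
                                         assoc_table["dep_mg_per_l"])
        regression_rows.append({"predictor": f"phi{rid}", "response": "dep_mg_per_l",
                                "slope": fit.slope, "intercept": fit.intercept,
                                "r2": fit.r2, "p": fit.p, "n": fit.n})
    regressions = pd.DataFrame(regression_rows)

    outputs = {"fri.csv": fri_table, "indices.csv": index_table,
               "risk.csv": risk_table, "composition.csv": composition,
               "correlations.csv": correlations, "regressions.csv": regressions}
    for name, frame in outputs.items():
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)

    config_for_hash = {k: v for k, v in config.items() if not k.startswith("_")}
    return {
        "package_version": __version__,
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config_for_hash, sort_keys=True).encode()).hexdigest(),
        "n_samples": len(survey.records),
        "outputs": sorted(outputs),
    }
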