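"""Workflow orchestration: empirical-style fitting, model prediction, sweeps,
and the global extrapolation.

Every numeric in a report is produced by a library call from the other
modules; this layer only sequences them and serializes results (JSON report
plus TSV tables, each TSV carrying a header comment with the config hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import data_io, dynamics, model_selection, synthetic
from .distributions import (DistributionSpec, FAMILIES, FitError, fit_mle,
                            log_pmf)

__all__ = ["run_fit", "run_simulate", "run_sweep", "run_synth",
           "extrapolate_max_array", "load_config"]

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# config_hash={cfg_hash} schema={REPORT_SCHEMA_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _write_report(report: dict, out_dir: Path, cfg_hash: str, force: bool) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists (use force to overwrite)")
    report = {"schema_version": REPORT_SCHEMA_VERSION,
              "config_hash": cfg_hash, **report}
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path


def _fit_summary(fr) -> dict:
    return {"family": fr.spec.family,
            "params": fr.spec.params,
            "loglikelihood": fr.loglikelihood,
            "n": fr.n,
            "i_min": fr.i_min,
            "alpha_ci": list(fr.alpha_ci) if fr.alpha_ci else None,
            "converged": fr.converged}


def run_fit(config: dict, out_dir, force: bool = False) -> dict:
    """Empirical-style workflow: dataset -> pooled fits -> ranking table ->
    optional per-group summary.

    Config keys: ``input`` (TSV path), ``i_min`` (default 1), ``per_group``
    (optional: "sample" or "habitat"), ``significance`` (default 0.05).
    """
    out_dir = Path(out_dir)
    cfg_hash = _config_hash(config)
    ds = data_io.read_spacer_counts(config["input"])
    log.info("loaded %d arrays from %d samples", len(ds),
             ds.records["sample_id"].nunique())
    i_min = int(config.get("i_min", 1))
    significance = float(config.get("significance", 0.05))

    stats = data_io.summarize(ds)
    hist = data_io.size_histogram(ds)
    fits = {}
    for fam in FAMILIES:
        try:
            fits[fam] = fit_mle(fam, ds.counts, i_min=i_min)
        except FitError as exc:
            log.warning("fit of %s failed: %s", fam, exc)
    if not fits:
        raise FitError("every family fit failed")
    ranking = model_selection.rank_candidates(
        ds.counts, i_min=i_min, significance=significance)
    best = max(fits, key=lambda f: fits[f].loglikelihood)

    report = {
        "mode": "fit",
        "summary": asdict(stats),
        "fits": {f: _fit_summary(r) for f, r in fits.items()},
        "best_family": best,
        "ranking": [dataclasses.asdict(r) for r in ranking],
    }

    out_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(pd.DataFrame({"spacer_count": list(hist),
                             "n_arrays": list(hist.values())}),
               out_dir / "histogram.tsv", cfg_hash)
    _write_tsv(model_selection.comparisons_to_frame(ranking),
               out_dir / "ranking.tsv", cfg_hash)

    group_key = config.get("per_group")
    if group_key:
        summary = model_selection.per_group_best_fit(
            ds, group_key=group_key, significance=significance)
        curve = model_selection.proportion_vs_group_size(summary)
        _write_tsv(summary, out_dir / "per_group.tsv", cfg_hash)
        _write_tsv(curve, out_dir / "proportion_vs_size.tsv", cfg_hash)
        ok = summary[summary["status"] == "ok"]
        report["per_group"] = {
            "group_key": group_key,
            "n_groups": int(len(summary)),
            "n_ok": int(len(ok)),
            "n_insufficient": int((summary["status"] == "insufficient").sum()),
            "proportion_powerlaw_best":
                float(ok["powerlaw_best"].mean()) if len(ok) else None,
            "proportion_all_significant":
                float(ok["all_significant"].mean()) if len(ok) else None,
        }
    _write_report(report, out_dir, cfg_hash, force)
    return report


def _params_from_config(config: dict) -> dynamics.DynamicsParams:
    fields = {f.name for f in dataclasses.fields(dynamics.DynamicsParams)}
    kwargs = {k: v for k, v in config.items() if k in fields}
    return dynamics.DynamicsParams(**kwargs)


def run_simulate(config: dict, out_dir, force: bool = False) -> dict:
    """Model workflow: parameters -> stationary distribution -> fitted
    (alpha, lambda), with an optional eigenvector cross-check.

    Config keys: the :class:`~spacerlaw.dynamics.DynamicsParams` fields,
    plus ``eigen_check`` (bool).  A stationary state with N_nu* = 0 has no
    birth-death turnover (the chain is frozen); it is reported with a
    ``degenerate`` flag and no fit.
    """
    out_dir = Path(out_dir)
    cfg_hash = _config_hash(config)
    params = _params_from_config(config)
    res = dynamics.iterate_to_stationarity(params)
    log.info("stationarity: %d iterations, converged=%s, N_nu*=%.6g",
             res.iterations, res.converged, res.N_nu_star)

    degenerate = res.N_nu_star == 0.0
    report = {
        "mode": "simulate",
        "params": asdict(params),
        "iterations": res.iterations,
        "converged": res.converged,
        "N_nu_star": res.N_nu_star,
        "degenerate": degenerate,
    }
    if degenerate:
        report["fit"] = None
        log.warning("degenerate stationary state (N_nu*=0): fit skipped")
    else:
        fit = dynamics.fit_stationary(res)
        report["fit"] = _fit_summary(fit)

    if config.get("eigen_check") and not degenerate:
        eig = dynamics.stationary_eigen(params, res.N_nu_star)
        l1 = float(np.abs(eig.distribution - res.distribution).sum())
        report["eigen_l1_distance"] = l1
        log.info("eigenvector cross-check: L1 distance %.3g", l1)

    out_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(pd.DataFrame({"spacer_count": res.classes,
                             "probability": res.distribution}),
               out_dir / "stationary.tsv", cfg_hash)
    _write_report(report, out_dir, cfg_hash, force)
    return report


def run_sweep(config: dict, out_dir, force: bool = False) -> dict:
    """Parameter sweep: stationarity + truncated-power-law fit per value.

    Config keys: DynamicsParams fields for the base point, plus ``vary``
    (field name) and ``values`` (list).
    """
    out_dir = Path(out_dir)
    cfg_hash = _config_hash(config)
    params = _params_from_config(config)
    records = dynamics.sweep(params, config["vary"], config["values"])
    rows = []
    for rec in records:
        fit = rec["fit"]
        rows.append({
            "varied_value": rec["value"],
            "alpha": fit.spec.params["alpha"] if fit else math.nan,
            "lam": fit.spec.params["lam"] if fit else math.nan,
            "converged": rec["stationary"].converged if rec["stationary"] else False,
            "error": rec["error"] or "",
        })
    df = pd.DataFrame(rows)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(df, out_dir / "sweep.tsv", cfg_hash)
    report = {"mode": "sweep", "vary": config["vary"],
              "points": df.drop(columns="error").to_dict("records")}
    _write_report(report, out_dir, cfg_hash, force)
    return report


def run_synth(config: dict, out_dir, force: bool = False) -> dict:
    """Generate a synthetic dataset TSV from a config block."""
    out_dir = Path(out_dir)
    cfg_hash = _config_hash(config)
    gen_cfg = config.get("generator", {})
    gen = DistributionSpec(gen_cfg.get("family", "truncated_powerlaw"),
                           gen_cfg.get("params", {"alpha": 2.57, "lam": 0.004}))
    spec = synthetic.SyntheticSpec(
        generator=gen,
        n_metagenomes=int(config.get("n_metagenomes", 100)),
        arrays_per_metagenome=config.get("arrays_per_metagenome"),
        habitat_mix=config.get("habitat_mix"),
        seed=int(config.get("seed", 0)))
    ds = synthetic.generate_dataset(spec)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "dataset.tsv"
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists (use force to overwrite)")
    data_io.write_spacer_counts(ds, path)
    report = {"mode": "synth", "n_records": len(ds),
              "generator": {"family": gen.family, "params": gen.params},
              "seed": spec.seed, "output": str(path)}
    _write_report(report, out_dir, cfg_hash, force)
    return report


def extrapolate_max_array(alpha: float, lam: float,
                          population_size: float) -> int:
    """Largest spacer count whose expected number of carriers is >= 1.

    Under the normalized discrete truncated power law
    ``p(i) = i^{-alpha} e^{-lam i} / Z`` on i >= 1, returns the largest i
    with ``population_size * p(i) >= 1`` — the longest array one expects to
    find anywhere in a population of that size.  Returns 0 if even i = 1
    falls below one expected carrier.
    """
    if alpha <= 0 or lam <= 0:
        raise ValueError("alpha and lam must be > 0")
    if population_size < 1:
        raise ValueError("population_size must be >= 1")
    spec = DistributionSpec("truncated_powerlaw", {"alpha": alpha, "lam": lam})
    target = -math.log(population_size)  # log p(i) >= target
    if log_pmf(spec, 1) < target:
        return 0
    # log p(i) is strictly decreasing: bracket then bisect
    hi = 2
    while log_pmf(spec, hi) >= target:
        hi *= 2
    lo = hi // 2
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if log_pmf(spec, mid) >= target:
            lo = mid
        else:
            hi = mid
    return lo
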