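"""End-to-end orchestration: simulate/ingest, derive, fit, test, report.

``run_pipeline`` executes the full fingerprint analysis:

1. ingest (or first materialize, from a synthetic scenario) the four input
   table families;
2. derive annual response series per taxon/station;
3. fit per-unit OLS trends against year and against mean annual temperature,
   and pool them with the unweighted fixed-effects meta-analysis;
4. segmented regression on temperature (breakpoint years, SEs, phase slopes)
   and across every long response series, pooling significant breakpoint
   years and testing their distribution against constructed nulls;
5. penalized-spline smooth of temperature with derivative-based phase labels.

All artifacts are plain TSV/JSON in the output directory, plus a manifest
(config echo, seed, package version) that fully determines the outputs:
re-running with the same config and seed reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, breakpoints, ingest, responses, smooth, synth, trends

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_synthetic_inputs"]


@dataclass
class PipelineConfig:
    outdir: str | Path = "ecofp_out"
    seed: int = 0
    scenario: synth.Scenario | None = None
    # input paths per dataset role (filled in by the simulator when a
    # scenario is given; any absent role skips its stages)
    occurrences_path: str | None = None
    phenology_path: str | None = None
    abundance_path: str | None = None
    diversity_path: str | None = None
    temperature_path: str | None = None
    rules: ingest.FilterRules = field(default_factory=ingest.FilterRules)
    peak: responses.PeakFlowerConfig = field(default_factory=responses.PeakFlowerConfig)
    controls: breakpoints.SegmentedControls = field(default_factory=breakpoints.SegmentedControls)
    basis_dim: int = 13
    alpha: float = 0.05
    n_sims: int = 199           # Monte-Carlo replicates for breakpoint p-values
    min_span: int = 80          # years a response must span to enter the breakpoint pool
    null_sample_size: int = 10_000
    abundance_min_total: int = 100


def write_synthetic_inputs(scenario: synth.Scenario, indir: Path) -> dict[str, str]:
    """Materialize every synthetic input table as CSV; returns role -> path."""
    indir.mkdir(parents=True, exist_ok=True)
    temp_series, _ = synth.simulate_temperature(scenario)
    # station-month rows whose annual mean equals the simulated annual value
    temp_rows = [
        {"station": "st1", "year": int(y), "month": m, "value": round(float(v), 6)}
        for y, v in zip(temp_series.years, temp_series.values) for m in range(1, 13)
    ]
    paths: dict[str, str] = {}
    pd.DataFrame(temp_rows).to_csv(indir / "temperature.csv", index=False)
    paths["temperature"] = str(indir / "temperature.csv")

    specimens, _ = synth.simulate_phenology(scenario, temp_series)
    pheno_rows = [
        {"taxon": sp.taxon, "date": sp.event_date.isoformat(), "intensity": round(sp.intensity, 3)}
        for specs in specimens.values() for sp in specs
    ]
    pd.DataFrame(pheno_rows).to_csv(indir / "phenology.csv", index=False)
    paths["phenology"] = str(indir / "phenology.csv")

    records, _ = synth.simulate_occurrences(scenario)
    occ_rows = [
        {
            "scientificName": r.taxon,
            "eventDate": r.event_date.isoformat() if r.event_date else str(r.year),
            "decimalLatitude": round(r.latitude, 5),
            "decimalLongitude": round(r.longitude, 5),
            "occurrenceStatus": r.status,
            "institutionCode": r.source,
        }
        for r in records
    ]
    pd.DataFrame(occ_rows).to_csv(indir / "occurrences.csv", index=False)
    paths["occurrences"] = str(indir / "occurrences.csv")

    abund, _ = synth.simulate_response("abundance", scenario, temp_series)
    abund.to_csv(indir / "abundance.csv", index=False)
    paths["abundance"] = str(indir / "abundance.csv")
    richness, _ = synth.simulate_response("diversity", scenario, temp_series)
    richness.to_csv(indir / "diversity.csv", index=False)
    paths["diversity"] = str(indir / "diversity.csv")
    return paths


def _write_forest(path: Path, estimates: list[trends.SlopeEstimate],
                  pooled: trends.MetaEstimate) -> None:
    rows = [
        {
            "unit_label": e.unit_label, "slope": e.slope, "se": e.se,
            "ci_low": e.ci[0], "ci_high": e.ci[1], "n": e.n,
            "first_year": e.first_year, "last_year": e.last_year,
        }
        for e in estimates
    ]
    rows.append({
        "unit_label": "POOLED", "slope": pooled.pooled, "se": pooled.se,
        "ci_low": pooled.ci_low, "ci_high": pooled.ci_high, "n": pooled.k,
        "first_year": "", "last_year": "",
    })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _config_digest(config: PipelineConfig) -> str:
    """Hash of the analysis parameters (not the file locations)."""
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        if callable(o):
            return getattr(o, "__name__", "callable")
        return str(o)
    payload = dataclasses.asdict(config)
    for key in list(payload):
        if key == "outdir" or key.endswith("_path"):
            payload.pop(key)
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage the configured inputs allow; returns the report bundle."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    skipped: list[str] = []
    report: dict = {}

    if config.scenario is not None:
        paths = write_synthetic_inputs(config.scenario, out / "inputs")
        for role, p in paths.items():
            if getattr(config, f"{role}_path") is None:
                setattr(config, f"{role}_path", p)

    # --- temperature ---------------------------------------------------
    temperature = None
    if config.temperature_path:
        temp_table = pd.read_csv(config.temperature_path)
        temperature = ingest.aggregate_temperature(temp_table, "annual_mean_across_stations")
        temperature.to_frame().to_csv(out / "temperature.tsv", sep="\t", index=False)

        seg = breakpoints.fit_segmented(temperature.years.astype(float), temperature.values,
                                        n_breaks=2, controls=config.controls)
        seg_test = breakpoints.test_n_breakpoints(
            temperature.years.astype(float), temperature.values,
            max_breaks=2, alpha=config.alpha, controls=config.controls,
            n_sims=config.n_sims, rng=np.random.default_rng(config.seed),
        )
        report["temperature_segmented"] = {
            "psi": [float(p) for p in seg.psi],
            "psi_se": [float(v) for v in seg.psi_se],
            "segment_slopes": [float(v) for v in seg.segment_slopes],
            "slope_se": [float(v) for v in seg.slope_se],
            "converged": bool(seg.converged),
            "k_selected": seg_test.k,
            "p_values": seg_test.p_values,
            "n": len(temperature),
        }
        (out / "segmented.json").write_text(json.dumps(report["temperature_segmented"], indent=1))

        fit = smooth.fit_penalized_spline(temperature, basis_dim=config.basis_dim)
        phases = smooth.classify_phases(fit)
        pd.DataFrame({
            "year": fit.grid, "fitted": fit.fitted, "se": fit.fitted_se,
            "derivative": fit.derivative, "lo": fit.deriv_lo, "hi": fit.deriv_hi,
            "phase": [next(lab for (a, b), lab in phases if a <= y <= b) for y in fit.grid],
        }).to_csv(out / "smooth_phases.tsv", sep="\t", index=False)
        report["phases"] = [{"start": a, "end": b, "label": lab} for (a, b), lab in phases]
    else:
        skipped += ["temperature", "segmented", "smooth"]

    # --- responses ------------------------------------------------------
    all_responses: list[responses.ResponseSeries] = []
    if config.phenology_path:
        specimens = ingest.read_phenology(config.phenology_path)
        by_taxon: dict[str, list] = {}
        for sp in specimens:
            by_taxon.setdefault(sp.taxon, []).append(sp)
        for taxon in sorted(by_taxon):
            rs = responses.earliest_peak_flowering(by_taxon[taxon], config.peak)
            if rs is not None:
                all_responses.append(rs)
    else:
        skipped.append("phenology")

    if config.occurrences_path:
        records = ingest.read_occurrences(config.occurrences_path)
        records, drops = ingest.filter_occurrences(records, config.rules)
        (out / "filter_drops.json").write_text(json.dumps(drops, indent=1))
        ingest.records_to_frame(records).to_csv(out / "canonical_occurrences.tsv",
                                                sep="\t", index=False)
        report["filter_drops"] = drops
        by_taxon2: dict[str, list] = {}
        for r in records:
            by_taxon2.setdefault(r.taxon, []).append(r)
        for taxon in sorted(by_taxon2):
            all_responses.append(responses.leading_edge_latitude(by_taxon2[taxon]))
    else:
        skipped.append("distribution")

    if config.abundance_path:
        table = pd.read_csv(config.abundance_path)
        all_responses.extend(responses.abundance_series(table, config.abundance_min_total))
    else:
        skipped.append("abundance")

    if config.diversity_path:
        table = pd.read_csv(config.diversity_path)
        all_responses.extend(responses.richness_series(table))
    else:
        skipped.append("diversity")

    # one TSV per derived response series, with a manifest keyed by
    # response_id/unit_label
    resp_dir = out / "responses"
    resp_dir.mkdir(exist_ok=True)
    resp_manifest: dict[str, str] = {}
    for r in all_responses:
        safe_unit = r.unit_label.replace(" ", "_").replace("/", "_")
        fname = f"{r.response_id}__{safe_unit}.tsv"
        frame = r.series.to_frame()
        if r.covariates:
            frame["method"] = [r.covariates[int(y)] for y in r.series.years]
        frame.to_csv(resp_dir / fname, sep="\t", index=False)
        resp_manifest[f"{r.response_id}/{r.unit_label}"] = fname
    (resp_dir / "manifest.json").write_text(json.dumps(resp_manifest, indent=1, sort_keys=True))

    # --- trends + pooling ----------------------------------------------
    pooled_out: dict = {}
    predictors: list[tuple[str, object]] = [("year", None)]
    if temperature is not None:
        predictors.append(("temperature", temperature))
    for rid in sorted({r.response_id for r in all_responses}):
        subset = [r for r in all_responses if r.response_id == rid]
        for pname, pred in predictors:
            ests = []
            for r in subset:
                try:
                    e = trends.fit_trend(r, pred)
                except trends.EstimationError:
                    continue
                e.scaled_abs_log = trends.scaled_effect_size(r, pred)
                ests.append(e)
            if not ests:
                continue
            pooled = trends.pool_slopes(ests)
            _write_forest(out / f"forest_{rid}_{pname}.tsv", ests, pooled)
            pooled_out[f"{rid}_{pname}"] = {
                "pooled": pooled.pooled, "se": pooled.se,
                "ci": [pooled.ci_low, pooled.ci_high], "k": pooled.k,
            }
    (out / "pooled.json").write_text(json.dumps(pooled_out, indent=1))
    report["pooled"] = pooled_out

    # --- breakpoints across long responses + null tests -----------------
    bp_entries = breakpoints.collect_breakpoints(
        all_responses, min_span=config.min_span, alpha=config.alpha,
        controls=config.controls, n_sims=config.n_sims,
        rng=np.random.default_rng(config.seed + 1),
    )
    pd.DataFrame(bp_entries).to_csv(out / "breakpoints.tsv", sep="\t", index=False)
    report["breakpoint_years"] = [e["year"] for e in bp_entries]
    # histogram-ready counts of pooled breakpoint years
    year_counts = pd.Series(report["breakpoint_years"], dtype=int).value_counts().sort_index()
    year_counts.rename_axis("year").rename("count").reset_index().to_csv(
        out / "breakpoint_year_counts.tsv", sep="\t", index=False)
    seg_info = report.get("temperature_segmented")
    if seg_info and len(report["breakpoint_years"]) >= 8:
        nt = breakpoints.breakpoint_null_tests(
            report["breakpoint_years"], seg_info["psi"], seg_info["psi_se"],
            null_sample_size=config.null_sample_size, seed=config.seed + 2,
        )
        null_out = {
            "ks_uniform": nt.ks_uniform, "ks_normal": nt.ks_normal,
            "ks_bimodal": nt.ks_bimodal, "shapiro": nt.shapiro,
            "n_breakpoints": len(nt.observed_years),
        }
        (out / "null_tests.json").write_text(json.dumps(null_out, indent=1))
        report["null_tests"] = null_out
    else:
        skipped.append("null_tests")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": _config_digest(config),
        "skipped_stages": skipped,
        "n_responses": len(all_responses),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    report["manifest"] = manifest
    return report
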