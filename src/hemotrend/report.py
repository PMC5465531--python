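"""End-to-end orchestration: CSV in, structured report and figures out.

``run_full_analysis`` loads a raw- or derived-schema CSV (auto-detected by
header, never guessed), derives CO per patient-timepoint, and runs the full
statistical sequence: Pearson correlation, Bland-Altman bias and limits of
agreement, percentage error, replicate precision and least significant
change (raw input only — derived tables carry no replicates), per-patient
changes, four-quadrant and polar trending, and the change-detection ROC.

Statistical degeneracies (single-class ROC, all change pairs inside an
exclusion zone, no second timepoint) do not crash the pipeline: the
corresponding report entry becomes ``{"undefined": <reason>}`` and the run
is flagged. The report is a plain JSON-serialisable dict, schema-validated
before it is returned, with the config echoed verbatim for provenance.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import BlandAltmanAgreement, PairedCO
from .config import AnalysisConfig
from .exceptions import DegenerateDataError, SchemaError
from .io import derive_co, read_derived_csv, read_raw_csv, detect_schema
from .measurement import ReplicatePrecision
from .threshold import ChangeDetectionROC
from .trending import FourQuadrantConcordance, PolarTrending, compute_deltas

REPORT_SECTIONS = ("agreement", "precision_ref", "precision_test", "trending", "roc")


def _undefined(reason: str) -> dict:
    return {"undefined": str(reason)}


def _load(input_path) -> tuple[pd.DataFrame, list | None, list | None]:
    header = pd.read_csv(input_path, nrows=0)
    schema = detect_schema(header.columns)
    if schema == "raw":
        echo, pac = read_raw_csv(input_path)
        return derive_co(echo, pac), echo, pac
    return read_derived_csv(input_path), None, None


def run_full_analysis(
    input_path,
    config: AnalysisConfig | None = None,
    out_dir=None,
    figures: bool = True,
    write_json: bool = True,
) -> dict:
    """Run the complete method-comparison analysis on one input file.

    Returns the report dict; when ``out_dir`` is given, also writes
    ``report.json``, ``derived_co.csv`` and (optionally) the four figures.
    """
    config = config or AnalysisConfig()
    derived, echo, pac = _load(input_path)
    report: dict = {"provenance": _provenance(input_path, config, len(derived))}

    pairs = [
        PairedCO(patient_id=r.patient_id, timepoint=r.timepoint, co_ref=r.co_pac, co_test=r.co_tte)
        for r in derived.itertuples()
    ]
    ba = BlandAltmanAgreement(
        central_tendency=config.central_tendency, loa_multiplier=config.loa_multiplier
    )
    try:
        report["agreement"] = ba.fit(pairs).result().to_dict()
    except DegenerateDataError as exc:
        ba = None
        report["agreement"] = _undefined(exc)

    if echo is not None:
        prec = ReplicatePrecision(k=config.precision_k)
        report["precision_ref"] = prec.fit([s.bolus_co for s in pac]).result("CO-PAC").__dict__
        report["precision_test"] = prec.fit([m.vti_values for m in echo]).result("CO-TTE").__dict__
    else:
        reason = "raw replicates not available in a derived-schema input"
        report["precision_ref"] = _undefined(reason)
        report["precision_test"] = _undefined(reason)

    t1 = [p for p in pairs if p.timepoint == 1]
    t2 = [p for p in pairs if p.timepoint == 2]
    deltas = compute_deltas(t1, t2)
    fq = polar = roc = None
    if not deltas:
        reason = "no patient has measurements at both timepoints"
        report["trending"] = _undefined(reason)
        report["roc"] = _undefined(reason)
    else:
        trending: dict = {"n_change_pairs": len(deltas)}
        try:
            fq = FourQuadrantConcordance(zone_pct=config.fq_zone_pct).fit(deltas)
            trending["four_quadrant"] = {
                "concordance_pct": fq.concordance_pct_,
                "n_included": fq.n_included_,
                "n_excluded": fq.n_excluded_,
                "good_trending": fq.good_trending_,
            }
        except DegenerateDataError as exc:
            trending["four_quadrant"] = _undefined(exc)
        try:
            polar = PolarTrending(
                zone_lmin=config.polar_zone_lmin,
                band_deg=config.polar_band_deg,
                loa_multiplier=config.loa_multiplier,
            ).fit(deltas)
            trending["polar"] = {
                "n_included": polar.n_included_,
                "mean_polar_angle_deg": polar.mean_angle_deg_,
                "radial_loa_low_deg": polar.radial_loa_low_deg_,
                "radial_loa_high_deg": polar.radial_loa_high_deg_,
                "concordance_pct": polar.concordance_pct_,
                "good_trending": polar.good_trending_,
            }
        except DegenerateDataError as exc:
            trending["polar"] = _undefined(exc)
        report["trending"] = trending
        try:
            roc = ChangeDetectionROC(
                positive_pct=config.roc_positive_pct,
                operating_threshold_pct=config.operating_threshold_pct,
                ci_method=config.ci_method,
                random_state=config.seed,
            ).fit(deltas)
            r = roc.result().to_dict()
            r.pop("curve")
            r["sensitivity_pct"] = roc.sensitivity_pct_
            r["specificity_pct"] = roc.specificity_pct_
            r["operating_threshold_pct"] = config.operating_threshold_pct
            r["youden_threshold"] = roc.youden_threshold_
            report["roc"] = r
        except DegenerateDataError as exc:
            report["roc"] = _undefined(exc)

    report["has_undefined"] = sorted(_undefined_sections(report))
    validate_report(report)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        derived.to_csv(out_dir / "derived_co.csv", index=False)
        if write_json:
            with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
        if figures:
            from . import plots

            if ba is not None:
                plots.bland_altman_plot(pairs, ba, out_dir / "bland_altman")
            if fq is not None:
                plots.four_quadrant_plot(deltas, fq, out_dir / "four_quadrant")
            if polar is not None:
                plots.polar_plot(polar, out_dir / "polar")
            if roc is not None:
                plots.roc_plot(roc, out_dir / "roc")
    return report


def _provenance(input_path, config: AnalysisConfig, n_rows: int) -> dict:
    digest = hashlib.sha256(Path(input_path).read_bytes()).hexdigest()
    return {
        "software": "hemotrend",
        "version": __version__,
        "input": str(input_path),
        "input_sha256": digest,
        "n_rows": n_rows,
        "config": config.to_dict(),
    }


def _undefined_sections(report: dict) -> list[str]:
    out = []
    for key in REPORT_SECTIONS:
        section = report[key]
        if "undefined" in section:
            out.append(key)
            continue
        for sub, val in section.items():
            if isinstance(val, dict) and "undefined" in val:
                out.append(f"{key}.{sub}")
    return out


def validate_report(report: dict) -> None:
    """Schema check: all sections present; every numeric finite or the
    section explicitly marked undefined."""
    missing = [k for k in REPORT_SECTIONS + ("provenance", "has_undefined") if k not in report]
    if missing:
        raise SchemaError(f"report missing sections: {missing}")

    def walk(obj, path):
        if isinstance(obj, dict):
            for k, v in obj.items():
                walk(v, f"{path}.{k}")
        elif isinstance(obj, float) and not math.isfinite(obj):
            raise SchemaError(f"report field {path} is non-finite")

    for key in REPORT_SECTIONS:
        walk(report[key], key)
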