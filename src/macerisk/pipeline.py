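"""End-to-end validation pipeline.

``run_validation`` reproduces the registry analysis on any cohort
(real CSV input or a synthetic one): risk scoring, per-class
Aalen–Johansen cumulative incidences (1-year and full horizon),
Fine–Gray regressions for four model forms (ESC four-class indicators,
CARDIOSOR two-class, ESC dichotomized very-high-vs-rest, CARDIOSOR as
a linear integer predictor) with AIC/BIC, and Harrell/Wolbers
concordance per score with paired comparisons against the ESC
four-class reference.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .catalogue import EscItemCatalogue, default_catalogue
from .competing import cif_aalen_johansen, fit_fine_gray
from .concordance import compare_c, harrell_c, wolbers_c
from .profiles import SubjectProfile
from .records import SurvivalRecord, records_to_arrays
from .scoring import TIER_ORDER, score_cohort

__all__ = ["run_validation", "subgroup_run", "ValidationReport", "ONE_YEAR_DAYS"]

ONE_YEAR_DAYS = 365.25

TIER_RANK = {t: i for i, t in enumerate(TIER_ORDER)}


class PipelineError(ValueError):
    pass


class ValidationReport(dict):
    """Dict-backed report with JSON and aligned-text rendering."""

    def to_json(self, **kwargs) -> str:
        return json.dumps(self, default=_jsonify, sort_keys=True, **kwargs)

    def to_text(self) -> str:
        lines = []
        for model_name, block in self.get("models", {}).items():
            lines.append(model_name.upper())
            hdr = f"  {'CLASS':<12}{'N (%)':>12}{'EVENTS (%)':>14}{'1-YR %':>9}{'CUM %':>8}{'sHR':>8}{'95% CI':>18}{'P':>9}"
            lines.append(hdr)
            for row in block["classes"]:
                if row.get("reference"):
                    shr, ci, p = "1 (ref)", "", ""
                elif row.get("shr") is None:
                    shr, ci, p = "NA", "", ""
                else:
                    shr = f"{row['shr']:.3f}"
                    ci = f"{row['ci95'][0]:.3f}-{row['ci95'][1]:.3f}"
                    p = f"{row['p']:.3g}"
                n_pct = f"{row['n']} ({row['pct']:.1f})"
                ev = f"{row['events']} ({row['events_pct']:.1f})"
                oyr = "NA" if row["risk_1yr_pct"] is None else f"{row['risk_1yr_pct']:.1f}"
                cum = "NA" if row["risk_cum_pct"] is None else f"{row['risk_cum_pct']:.1f}"
                lines.append(
                    f"  {row['label']:<12}{n_pct:>12}{ev:>14}{oyr:>9}{cum:>8}{shr:>8}{ci:>18}{p:>9}"
                )
            lines.append(f"  AIC {block['aic']:.1f}  BIC {block['bic']:.1f}")
            lines.append("")
        if "concordance" in self:
            lines.append("CONCORDANCE")
            for name, c in self["concordance"].items():
                h, w = c["harrell"], c["wolbers"]
                cmp_p = c.get("p_vs_reference")
                cmp_txt = "-" if cmp_p is None else f"{cmp_p:.3f}"
                lines.append(
                    f"  {name:<22} Harrell {h['c']:.3f} ({h['ci95'][0]:.3f}-{h['ci95'][1]:.3f})"
                    f"  P {cmp_txt}"
                    f"  Wolbers {w['c']:.3f} ({w['ci95'][0]:.3f}-{w['ci95'][1]:.3f})"
                )
        return "\n".join(lines)


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _class_block(time, event, member_masks, labels, reference, horizon_cum):
    """Per-class counts, AJ risks and a Fine–Gray indicator fit."""
    n = time.size
    total_events = int((event == 1).sum())
    rows = []
    kept = []
    for lab in labels:
        mask = member_masks[lab]
        n_c = int(mask.sum())
        ev_c = int((event[mask] == 1).sum())
        if n_c == 0:
            warnings.warn(f"class {lab!r} empty; dropped from the regression")
            continue
        kept.append(lab)
        cif1 = cif_aalen_johansen(time[mask], event[mask], cause=1, horizon=ONE_YEAR_DAYS)
        cifc = cif_aalen_johansen(time[mask], event[mask], cause=1, horizon=horizon_cum)
        rows.append(
            {
                "label": lab,
                "n": n_c,
                "pct": 100.0 * n_c / n,
                "events": ev_c,
                "events_pct": 100.0 * ev_c / total_events if total_events else 0.0,
                "risk_1yr_pct": 100.0 * cif1.cif_at_horizon,
                "risk_cum_pct": 100.0 * cifc.cif_at_horizon,
                "reference": lab == reference,
            }
        )
    # Fine–Gray with indicators for non-reference classes; classes with
    # zero cause-1 events are inestimable strata: dropped from the
    # regression with a warning, their row flagged.
    events_by_label = {r["label"]: r["events"] for r in rows}
    non_ref = [lab for lab in kept if lab != reference]
    estimable = [lab for lab in non_ref if events_by_label[lab] > 0]
    for lab in set(non_ref) - set(estimable):
        warnings.warn(f"class {lab!r} has no events; sHR inestimable")
    X = np.column_stack([member_masks[lab].astype(float) for lab in estimable])
    fit = fit_fine_gray(time, event, X, covariate_names=estimable)
    by_label = {lab: i for i, lab in enumerate(estimable)}
    for row in rows:
        if row["reference"]:
            row["shr"] = 1.0
            row["ci95"] = None
            row["p"] = None
        elif row["label"] in by_label:
            i = by_label[row["label"]]
            row["shr"] = float(fit.shr[i])
            row["ci95"] = [float(fit.ci95[i, 0]), float(fit.ci95[i, 1])]
            row["p"] = float(fit.pvalues[i])
        else:
            row["shr"] = None
            row["ci95"] = None
            row["p"] = None
            row["inestimable"] = True
    return rows, fit


def _linear_block(time, event, points, horizon_cum):
    n = time.size
    total_events = int((event == 1).sum())
    fit = fit_fine_gray(time, event, points.astype(float)[:, None],
                        covariate_names=["cardiosor_points"])
    rows = [
        {
            "label": "per point",
            "n": n,
            "pct": 100.0,
            "events": total_events,
            "events_pct": 100.0,
            "risk_1yr_pct": None,
            "risk_cum_pct": None,
            "reference": False,
            "shr": float(fit.shr[0]),
            "ci95": [float(fit.ci95[0, 0]), float(fit.ci95[0, 1])],
            "p": float(fit.pvalues[0]),
        }
    ]
    return rows, fit


def run_validation(
    profiles: list[SubjectProfile],
    records: list[SurvivalRecord],
    catalogue: Optional[EscItemCatalogue] = None,
    seed: int = 0,
    include_concordance: bool = True,
    horizon_cum: Optional[float] = None,
    annotation: Optional[dict] = None,
) -> ValidationReport:
    """Score a cohort and validate both risk scores against MACE outcomes.

    Profiles and records must join 1:1 on subject_id. ``horizon_cum``
    fixes the full-horizon cumulative-risk evaluation time (default:
    last observed event time). Deterministic given inputs and seed.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    if len(profiles) < 2:
        raise PipelineError("cohort must contain at least 2 subjects")
    scores = score_cohort(profiles, catalogue)
    ids_r, time, event = records_to_arrays(records)
    rec_index = {sid: i for i, sid in enumerate(ids_r)}
    if len(rec_index) != len(ids_r):
        raise PipelineError("duplicate subject_id in records")
    missing = [p.subject_id for p in profiles if p.subject_id not in rec_index]
    if missing or len(profiles) != len(records):
        raise PipelineError(
            f"profiles and records do not join 1:1 (first missing: {missing[:5]})"
        )
    order = np.array([rec_index[p.subject_id] for p in profiles])
    time, event = time[order], event[order]

    if (event == 1).sum() < 1:
        raise PipelineError("no MACE events in the cohort; nothing to validate")
    if horizon_cum is None:
        horizon_cum = float(time[event > 0].max())

    esc = scores["esc_tier"].to_numpy()
    cs_points = scores["cardiosor_points"].to_numpy()
    cs_class = scores["cardiosor_class"].to_numpy()

    models = {}
    fits = {}
    masks4 = {t: esc == t for t in TIER_ORDER}
    rows, fit = _class_block(time, event, masks4, list(TIER_ORDER), "low", horizon_cum)
    models["esc_4class"] = {"classes": rows, "aic": fit.aic, "bic": fit.bic}
    fits["esc_4class"] = fit

    masks_cs = {"low": cs_class == "low", "high": cs_class == "high"}
    rows, fit = _class_block(time, event, masks_cs, ["low", "high"], "low", horizon_cum)
    models["cardiosor_2class"] = {"classes": rows, "aic": fit.aic, "bic": fit.bic}
    fits["cardiosor_2class"] = fit

    masks_d = {"other": esc != "very_high", "very_high": esc == "very_high"}
    rows, fit = _class_block(time, event, masks_d, ["other", "very_high"], "other", horizon_cum)
    models["esc_dichotomized"] = {"classes": rows, "aic": fit.aic, "bic": fit.bic}
    fits["esc_dichotomized"] = fit

    rows, fit = _linear_block(time, event, cs_points, horizon_cum)
    models["cardiosor_linear"] = {"classes": rows, "aic": fit.aic, "bic": fit.bic}
    fits["cardiosor_linear"] = fit

    report = ValidationReport()
    report["models"] = models
    report["n"] = int(time.size)
    report["n_events_mace"] = int((event == 1).sum())
    report["n_competing_deaths"] = int((event == 2).sum())
    report["horizon_cum_days"] = horizon_cum

    if include_concordance:
        score_sets = {
            "esc_4class": np.array([TIER_RANK[t] for t in esc], float),
            "esc_dichotomized": (esc == "very_high").astype(float),
            "cardiosor_2class": (cs_class == "high").astype(float),
            "cardiosor_linear": cs_points.astype(float),
        }
        conc = {}
        ref = score_sets["esc_4class"]
        for name, s in score_sets.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                h = harrell_c(time, event, s)
                w = wolbers_c(time, event, s)
                if name == "esc_4class":
                    p_cmp = None
                else:
                    # comparison defined for the Harrell variant only
                    _, p_cmp = compare_c(time, event, ref, s, method="harrell", seed=seed)
            conc[name] = {
                "harrell": {"c": h.c, "ci95": list(h.ci95), "n_pairs": h.n_comparable_pairs},
                "wolbers": {"c": w.c, "ci95": list(w.ci95), "n_pairs": w.n_comparable_pairs},
                "p_vs_reference": p_cmp,
            }
        report["concordance"] = conc

    prov = {
        "seed": seed,
        "software_version": __version__,
        "n_subjects": int(time.size),
        "input_hash": hashlib.sha256(
            (scores.to_csv(index=False) + np.array2string(time) + np.array2string(event)).encode()
        ).hexdigest()[:16],
    }
    if annotation:
        prov.update(annotation)
    report["provenance"] = prov
    return report


def subgroup_run(
    profiles: list[SubjectProfile],
    records: list[SurvivalRecord],
    subgroup: Callable[[SubjectProfile], bool] | str,
    **kwargs,
) -> ValidationReport:
    """Run the identical pipeline on a profile-filtered subset.

    ``subgroup`` is a predicate over profiles, or the string "viral"
    (viral liver-disease etiology, the registry's sensitivity analysis).
    """
    if subgroup == "viral":
        name, pred = "viral", lambda p: p.etiology == "viral"
    elif callable(subgroup):
        name, pred = getattr(subgroup, "__name__", "custom"), subgroup
    else:
        raise PipelineError(f"unknown subgroup {subgroup!r}")
    keep_ids = {p.subject_id for p in profiles if pred(p)}
    sub_profiles = [p for p in profiles if p.subject_id in keep_ids]
    sub_records = [r for r in records if r.subject_id in keep_ids]
    annotation = dict(kwargs.pop("annotation", {}) or {})
    annotation.update({"subgroup": name, "subgroup_n": len(sub_profiles)})
    return run_validation(sub_profiles, sub_records, annotation=annotation, **kwargs)
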