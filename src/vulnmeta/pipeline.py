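"""End-to-end orchestration: CSV in, analysis report out.

The pipeline chains the four analytic stages on a study collection:

1. association meta-analysis (genotype → CVD, all designs pooled by
   random effects, OR standing in for RR in case-control studies);
2. meta-regression of the carrier log-RR on study mean LDL;
3. standardized stratified trial meta-analysis (per-mmol/L effects pooled
   separately among carriers and non-carriers);
4. the predicted-vs-observed comparison of differential benefit, plus the
   design-subset sensitivity table for the meta-regression.

Input is a flat CSV with one row per study-stratum(-arm); see
:data:`CSV_COLUMNS`.  Reports serialize to JSON deterministically.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
import logging
from dataclasses import dataclass
from typing import Sequence

from .effects import EffectEstimate
from .exceptions import InsufficientStudiesError, NoDataError, SchemaError
from .metareg import MetaRegression, MetaRegressionResults
from .pooling import MetaAnalysisResults, RandomEffectsMeta
from .simulate import (
    CollectionConfig,
    StudyRecord,
    VulnerabilityModel,
    simulate_collection,
    trial_arm_records,
)
from .trials import (
    BenefitComparison,
    StratifiedTrialRecord,
    invert_ratio,
    pool_stratified_trials,
    predicted_vs_observed,
    ratio_via_metaregression,
)

__all__ = [
    "CSV_COLUMNS",
    "AnalysisSettings",
    "AnalysisReport",
    "read_studies",
    "write_studies",
    "studies_to_csv",
    "run_association_meta",
    "run_meta_regression",
    "run_trials_analysis",
    "run_sensitivity",
    "run_full_analysis",
    "forest_table",
]

logger = logging.getLogger("vulnmeta")

CSV_COLUMNS = (
    "study_id",
    "design",
    "arm",
    "stratum",
    "events",
    "total",
    "mean_ldl",
    "delta_ldl",
    "trial_type",
)

_VALID_DESIGNS = {"cohort", "case_control", "trial"}
_VALID_STRATA = {"carrier", "noncarrier", "argarg", "argtrp", "trptrp"}
_VALID_ARMS = {"na", "control", "active"}

# Design subsets mirroring the sensitivity analysis of the effect
# modification: each predicate selects meta-regression-eligible records.
SENSITIVITY_SUBSETS = {
    "all": lambda s: True,
    "cohorts": lambda s: s.design == "cohort",
    "placebo_arms": lambda s: s.design == "trial_arm"
    and s.arm == "control"
    and s.trial_type == "placebo",
    "cohorts_and_placebo_arms": lambda s: s.design == "cohort"
    or (s.design == "trial_arm" and s.arm == "control" and s.trial_type == "placebo"),
    "control_arms": lambda s: s.design == "trial_arm" and s.arm == "control",
    "cohorts_and_control_arms": lambda s: s.design == "cohort"
    or (s.design == "trial_arm" and s.arm == "control"),
    "cohorts_and_active_arms": lambda s: s.design == "cohort"
    or (s.design == "trial_arm" and s.arm == "active"),
}


# ---------------------------------------------------------------------------
# CSV I/O


def studies_to_csv(
    studies: Sequence[StudyRecord], trials: Sequence[StratifiedTrialRecord]
) -> str:
    """Serialize a collection to CSV text (one row per study-stratum-arm).

    Trial arms are written as ``design=trial`` rows carrying the arm label,
    the arm's achieved mean LDL and the between-arm LDL difference Y;
    ``trial_arm`` study records are views of those trials and are not
    duplicated.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)

    def fmt(x):
        return "" if x is None else f"{x:g}" if isinstance(x, float) else str(x)

    for s in studies:
        if s.design == "trial_arm":
            continue
        for stratum in sorted(s.strata):
            x, y = s.strata[stratum]
            events, total = (x, x + y) if s.design == "case_control" else (x, y)
            writer.writerow(
                [s.id, s.design, "na", stratum, events, total, fmt(s.mean_ldl), "", ""]
            )
    for t in trials:
        ttype = "placebo" if t.placebo_controlled else "intensity"
        for arm, strata, ldl in (
            ("control", t.control, t.control_ldl),
            ("active", t.active, t.active_ldl),
        ):
            for stratum in sorted(strata):
                e, n = strata[stratum]
                writer.writerow(
                    [t.id, "trial", arm, stratum, e, n, fmt(ldl), fmt(t.delta_ldl), ttype]
                )
    return buf.getvalue()


def write_studies(
    studies: Sequence[StudyRecord],
    trials: Sequence[StratifiedTrialRecord],
    path,
) -> str:
    """Write the collection CSV to ``path``; returns the text written."""
    text = studies_to_csv(studies, trials)
    with open(path, "w", newline="") as fh:
        fh.write(text)
    return text


def _parse_rows(text: str):
    """Yield validated row dicts; collect schema problems with line numbers."""
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise SchemaError(["line 1: empty file"])
    if tuple(h.strip() for h in header) != CSV_COLUMNS:
        raise SchemaError(
            [f"line 1: header must be {','.join(CSV_COLUMNS)}, got {','.join(header)}"]
        )
    problems, rows = [], []
    for lineno, raw in enumerate(reader, start=2):
        if not raw or all(not c.strip() for c in raw):
            continue
        if len(raw) != len(CSV_COLUMNS):
            problems.append(f"line {lineno}: expected {len(CSV_COLUMNS)} columns")
            continue
        row = dict(zip(CSV_COLUMNS, (c.strip() for c in raw)))
        row["_line"] = lineno
        if row["design"] not in _VALID_DESIGNS:
            problems.append(f"line {lineno}: unknown design {row['design']!r}")
            continue
        if row["stratum"] not in _VALID_STRATA:
            problems.append(f"line {lineno}: unknown stratum {row['stratum']!r}")
            continue
        if row["arm"] not in _VALID_ARMS:
            problems.append(f"line {lineno}: unknown arm {row['arm']!r}")
            continue
        for col in ("events", "total"):
            try:
                row[col] = int(row[col])
            except ValueError:
                problems.append(f"line {lineno}: {col} must be an integer")
                row[col] = None
        if row["events"] is not None and row["events"] < 0:
            problems.append(f"line {lineno}: negative events count")
            continue
        if row["total"] is not None and row["total"] < 0:
            problems.append(f"line {lineno}: negative total count")
            continue
        if (
            row["events"] is not None
            and row["total"] is not None
            and row["events"] > row["total"]
        ):
            problems.append(f"line {lineno}: events exceed total")
            continue
        for col in ("mean_ldl", "delta_ldl"):
            row[col] = float(row[col]) if row[col] else None
        if row["design"] == "trial":
            if row["arm"] == "na":
                problems.append(f"line {lineno}: trial row needs arm control|active")
            if row["delta_ldl"] is None:
                problems.append(f"line {lineno}: trial row missing delta_ldl (Y)")
            elif row["delta_ldl"] <= 0:
                problems.append(f"line {lineno}: delta_ldl must be > 0")
        rows.append(row)
    return rows, problems


def read_studies(
    path,
) -> tuple[list[StudyRecord], list[StratifiedTrialRecord]]:
    """Read a study-collection CSV.

    Returns ``(studies, trials)`` where ``studies`` includes one
    ``trial_arm`` record per trial arm (the paper-style convention of
    treating each allocation arm as a separate cohort), so downstream
    stages can consume a single list.
    """
    with open(path, newline="") as fh:
        text = fh.read()
    rows, problems = _parse_rows(text)
    if problems:
        raise SchemaError(problems)

    by_study: dict[str, list[dict]] = {}
    order: list[str] = []
    for row in rows:
        if row["study_id"] not in by_study:
            order.append(row["study_id"])
        by_study.setdefault(row["study_id"], []).append(row)

    studies: list[StudyRecord] = []
    trials: list[StratifiedTrialRecord] = []
    problems = []
    for sid in order:
        grp = by_study[sid]
        designs = {r["design"] for r in grp}
        if len(designs) > 1:
            problems.append(
                f"study {sid}: mixed designs {sorted(designs)} "
                f"(lines {[r['_line'] for r in grp]})"
            )
            continue
        design = grp[0]["design"]
        if design == "trial":
            arms = {"control": {}, "active": {}}
            ldl = {"control": None, "active": None}
            ys = {r["delta_ldl"] for r in grp}
            ttypes = {r["trial_type"] or "placebo" for r in grp}
            if len(ys) > 1:
                problems.append(f"study {sid}: inconsistent delta_ldl values {ys}")
                continue
            for r in grp:
                arms[r["arm"]][r["stratum"]] = (r["events"], r["total"])
                ldl[r["arm"]] = r["mean_ldl"]
            if not arms["control"] or not arms["active"]:
                problems.append(f"study {sid}: trial must have both arms")
                continue
            trial = StratifiedTrialRecord(
                id=sid,
                control=arms["control"],
                active=arms["active"],
                delta_ldl=ys.pop(),
                control_ldl=ldl["control"],
                active_ldl=ldl["active"],
                placebo_controlled=ttypes == {"placebo"},
            )
            trials.append(trial)
            studies.extend(trial_arm_records(trial))
        else:
            strata = {}
            for r in grp:
                e, n = r["events"], r["total"]
                strata[r["stratum"]] = (
                    (e, n - e) if design == "case_control" else (e, n)
                )
            studies.append(
                StudyRecord(
                    id=sid,
                    design=design,
                    mean_ldl=grp[0]["mean_ldl"],
                    strata=strata,
                )
            )
    if problems:
        raise SchemaError(problems)
    return studies, trials


# ---------------------------------------------------------------------------
# Analysis stages


def _eligible_for_stratification(s: StudyRecord, stratification: str) -> bool:
    if stratification == "carrier":
        return s.has_genotype_strata or (
            "carrier" in s.strata
            and ("noncarrier" in s.strata or "trptrp" in s.strata)
        )
    return s.has_genotype_strata


def run_association_meta(
    studies: Sequence[StudyRecord],
    stratification: str = "carrier",
    correction: bool = True,
    ci_level: float = 0.95,
) -> MetaAnalysisResults:
    """Pool the genotype → CVD association across all eligible designs.

    ``stratification`` selects the contrast: ``carrier`` (any 719Arg vs
    Trp/Trp), ``homozygous`` (Arg/Arg vs Trp/Trp) or ``heterozygous``
    (Arg/Trp vs Trp/Trp).
    """
    eligible = [s for s in studies if _eligible_for_stratification(s, stratification)]
    if not eligible:
        raise NoDataError(f"no studies eligible for {stratification} stratification")
    estimates = [
        s.effect(stratification, correction, ci_level) for s in eligible
    ]
    result = RandomEffectsMeta.from_estimates(
        estimates, [s.id for s in eligible]
    ).fit("dl")
    logger.info(
        "association meta (%s): k=%d pooled=%.4f tau2=%s",
        stratification,
        result.k,
        result.pooled.point,
        f"{result.tau_squared:.5f}" if result.tau2_estimable else "n/e",
    )
    return result


def metareg_eligible(studies: Sequence[StudyRecord]) -> list[StudyRecord]:
    """Prospective units with a usable mean LDL (the meta-regression set)."""
    return [s for s in studies if s.prospective and s.mean_ldl is not None]


def run_meta_regression(
    studies: Sequence[StudyRecord],
    method: str = "reml",
    stratification: str = "carrier",
    correction: bool = True,
    ci_level: float = 0.95,
) -> MetaRegressionResults:
    """Regress the carrier log-RR on study mean LDL (mmol/L)."""
    eligible = [
        s
        for s in metareg_eligible(studies)
        if _eligible_for_stratification(s, stratification)
    ]
    if len(eligible) < 3:
        raise InsufficientStudiesError(
            f"meta-regression needs k >= 3, found {len(eligible)}"
        )
    model = MetaRegression(
        [s.effect(stratification, correction, ci_level).log_point for s in eligible],
        [s.effect(stratification, correction, ci_level).se for s in eligible],
        [s.mean_ldl for s in eligible],
        labels=[s.id for s in eligible],
        ci_level=ci_level,
    )
    result = model.fit(method)
    logger.info(
        "meta-regression (%s, %s): k=%d slope=%.4f tau2=%.5f R2=%.1f%%",
        stratification,
        method,
        result.k,
        result.params[1],
        result.tau_squared_residual,
        result.r_squared,
    )
    return result


@dataclass(frozen=True)
class TrialsAnalysis:
    """Stratified per-mmol/L trial pools and the observed benefit ratio."""

    carriers: MetaAnalysisResults
    non_carriers: MetaAnalysisResults
    via_metareg: MetaRegressionResults | None

    def to_dict(self) -> dict:
        return {
            "carriers": self.carriers.to_dict(),
            "non_carriers": self.non_carriers.to_dict(),
            "observed_via_metareg": (
                None if self.via_metareg is None else self.via_metareg.to_dict()
            ),
        }


def run_trials_analysis(
    trials: Sequence[StratifiedTrialRecord],
    method: str = "reml",
    correction: bool = True,
    ci_level: float = 0.95,
) -> TrialsAnalysis:
    """Pool standardized trial effects per genotype stratum."""
    carriers, non_carriers = pool_stratified_trials(trials, correction, ci_level)
    via = None
    if len(trials) >= 2:
        via = ratio_via_metaregression(trials, method, correction, ci_level)
    return TrialsAnalysis(carriers, non_carriers, via)


@dataclass(frozen=True)
class SensitivityEntry:
    """One design-subset refit of the effect-modification meta-regression."""

    subset: str
    study_ids: tuple[str, ...]
    k: int
    estimable: bool
    ratio_per_mmol_decrease: EffectEstimate | None
    r_squared: float | None

    def to_dict(self) -> dict:
        d = {
            "subset": self.subset,
            "study_ids": list(self.study_ids),
            "k": self.k,
            "estimable": self.estimable,
        }
        if self.estimable:
            lo, hi = self.ratio_per_mmol_decrease.ci
            d.update(
                ratio_per_mmol_decrease=self.ratio_per_mmol_decrease.point,
                ci=[lo, hi],
                p=self.ratio_per_mmol_decrease.p_value,
                r_squared_pct=self.r_squared,
            )
        else:
            d.update(ratio_per_mmol_decrease=None, ci=None, p=None, r_squared_pct=None)
        return d


def run_sensitivity(
    studies: Sequence[StudyRecord],
    method: str = "reml",
    correction: bool = True,
    ci_level: float = 0.95,
    subsets: dict | None = None,
) -> dict[str, SensitivityEntry]:
    """Refit the meta-regression on named design subsets.

    Each entry reports the per-mmol/L-*decrease* ratio of RRs (the
    differential-benefit re-expression of the slope).  Subsets with fewer
    than three studies are flagged not-estimable rather than erroring.
    """
    subsets = subsets or SENSITIVITY_SUBSETS
    out: dict[str, SensitivityEntry] = {}
    for name, pred in subsets.items():
        members = [s for s in metareg_eligible(studies) if pred(s)]
        ids = tuple(s.id for s in members)
        try:
            fit = run_meta_regression(members, method, "carrier", correction, ci_level)
        except (InsufficientStudiesError, NoDataError):
            out[name] = SensitivityEntry(name, ids, len(members), False, None, None)
            continue
        ratio = invert_ratio(fit.slope)
        out[name] = SensitivityEntry(
            name, ids, fit.k, True, ratio, fit.r_squared
        )
    return out


# ---------------------------------------------------------------------------
# Full chain


@dataclass(frozen=True)
class AnalysisSettings:
    tau2_method: str = "reml"
    ci_level: float = 0.95
    correction: bool = True

    def to_dict(self) -> dict:
        return {
            "tau2_method": self.tau2_method,
            "ci_level": self.ci_level,
            "correction": self.correction,
        }


@dataclass(frozen=True)
class AnalysisReport:
    """Everything the pipeline computes, ready for JSON serialization."""

    association: MetaAnalysisResults
    association_by_genotype: dict[str, MetaAnalysisResults]
    metareg: MetaRegressionResults
    trials: TrialsAnalysis
    benefit: BenefitComparison
    sensitivity: dict[str, SensitivityEntry]
    settings: AnalysisSettings
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "settings": self.settings.to_dict(),
            "provenance": self.provenance,
            "association": self.association.to_dict(),
            "association_by_genotype": {
                k: v.to_dict() for k, v in self.association_by_genotype.items()
            },
            "metareg": self.metareg.to_dict(),
            "trials": self.trials.to_dict(),
            "benefit": self.benefit.to_dict(),
            "sensitivity": {k: v.to_dict() for k, v in self.sensitivity.items()},
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def run_full_analysis(
    studies: Sequence[StudyRecord],
    trials: Sequence[StratifiedTrialRecord],
    settings: AnalysisSettings | None = None,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Run the whole inference chain on a study collection.

    Deterministic given the inputs and settings: identical collections
    produce byte-identical JSON reports.
    """
    st = settings or AnalysisSettings()
    association = run_association_meta(
        studies, "carrier", st.correction, st.ci_level
    )
    by_genotype = {}
    for strat in ("homozygous", "heterozygous"):
        try:
            by_genotype[strat] = run_association_meta(
                studies, strat, st.correction, st.ci_level
            )
        except NoDataError:
            pass
    metareg = run_meta_regression(
        studies, st.tau2_method, "carrier", st.correction, st.ci_level
    )
    trial_res = run_trials_analysis(
        trials, st.tau2_method, st.correction, st.ci_level
    )
    benefit = predicted_vs_observed(
        metareg, trial_res.carriers, trial_res.non_carriers, st.ci_level
    )
    sensitivity = run_sensitivity(
        studies, st.tau2_method, st.correction, st.ci_level
    )
    prov = dict(provenance or {})
    prov.setdefault(
        "input_digest",
        hashlib.sha256(studies_to_csv(studies, trials).encode()).hexdigest(),
    )
    return AnalysisReport(
        association=association,
        association_by_genotype=by_genotype,
        metareg=metareg,
        trials=trial_res,
        benefit=benefit,
        sensitivity=sensitivity,
        settings=st,
        provenance=prov,
    )


def run_simulated_analysis(
    model: VulnerabilityModel | None = None,
    config: CollectionConfig | None = None,
    seed: int = 0,
    settings: AnalysisSettings | None = None,
) -> AnalysisReport:
    """Generate a collection under the vulnerability model and analyse it."""
    model = model or VulnerabilityModel()
    studies, trials = simulate_collection(model, config, seed)
    return run_full_analysis(
        studies,
        trials,
        settings,
        provenance={"seed": seed, "model": model.to_dict()},
    )


# ---------------------------------------------------------------------------
# Text forest table


def forest_table(result: MetaAnalysisResults, title: str = "") -> str:
    """Fixed-width text forest table: study, estimate, CI, weight."""
    import math

    from .effects import z_critical

    zc = z_critical(result.pooled.ci_level)
    total_w = float(result.weights.sum())
    width = max([len(l) for l in result.labels] + [len("(pooled)"), 8])
    lines = []
    if title:
        lines.append(title)
    lines.append(
        f"{'study':<{width}}  {result.pooled.measure_label:>8}  "
        f"{'95% CI':>17}  {'weight':>7}"
    )
    for label, y, se, w in zip(result.labels, result.y, result.se, result.weights):
        lo, hi = math.exp(y - zc * se), math.exp(y + zc * se)
        lines.append(
            f"{label:<{width}}  {math.exp(y):8.3f}  "
            f"[{lo:7.3f}, {hi:7.3f}]  {100 * w / total_w:6.1f}%"
        )
    lines.append(
        f"{'(pooled)':<{width}}  {result.pooled.point:8.3f}  "
        f"[{result.pooled.ci[0]:7.3f}, {result.pooled.ci[1]:7.3f}]  "
        f"{100.0:6.1f}%"
    )
    lines.append(
        f"Q = {result.Q:.2f} (df {result.df}), I^2 = {result.i_squared:.1f}%, "
        + (
            f"tau^2 = {result.tau_squared:.4f}"
            if result.tau2_estimable
            else "tau^2 not estimable"
        )
    )
    return "\n".join(lines)
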