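"""Synthetic study collections under a genotype-by-LDL vulnerability model.

The generator exists so every stage of the analysis chain can be exercised
end-to-end without access to the original study-level data.  Its risk model
is log-linear in LDL on the relative-risk scale:

    risk(G, L) = r0 · exp[ β_L (L − L_ref) + G·(β_G + β_GL (L − L_ref)) ]

where G ∈ {0, 1} indicates carrying at least one variant allele, β_L is the
ln RR per mmol/L of LDL among non-carriers, β_GL is the interaction (the
ln ratio of RRs per mmol/L) and β_G is pinned by the "null-crossing" LDL
L₀ at which carriers and non-carriers have equal risk:
β_G = −β_GL (L₀ − L_ref).  Straight lines on the log-risk scale mean the
ratio of RRs per mmol/L is constant — the structural assumption under which
the effect modification of genotype on the LDL→CVD association and of LDL
on the genotype→CVD association are the same number, and under which a
collection of studies centered at L₀ shows no *marginal* genotype
association despite a strong interaction.

Genotypes are drawn in Hardy-Weinberg proportions; events are binomial per
genotype stratum at the study-mean LDL (one LDL value per study — the
analysis consumes study-level means, so within-study LDL variation is not
modeled).  Case-control sampling inverts the population mixture by Bayes'
rule so the odds ratio estimates the model RR in the rare-disease regime.

Seeding: a master seed fans out to per-study child streams keyed by a
stable CRC-32 hash of the study id, so adding a study never perturbs the
draws of another.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .effects import EffectEstimate, GenotypeCounts, TwoByTwo, odds_ratio, relative_risk
from .exceptions import ParameterizationError
from .trials import StratifiedTrialRecord

__all__ = [
    "VulnerabilityModel",
    "StudyRecord",
    "CohortSpec",
    "CaseControlSpec",
    "TrialSpec",
    "CollectionConfig",
    "risk",
    "simulate_cohort",
    "simulate_case_control",
    "simulate_trial",
    "simulate_collection",
]

GENOTYPES = ("argarg", "argtrp", "trptrp")


@dataclass(frozen=True)
class VulnerabilityModel:
    """Log-linear CVD risk model with a genotype × LDL interaction.

    Defaults are plumbing for demonstrations: variant allele frequency 0.37
    (common-polymorphism regime), 5% baseline risk at a reference LDL of
    3.0 mmol/L, ln(1.25) per mmol/L among non-carriers, interaction
    ln(1.15) per mmol/L, and a null-crossing LDL of 3.5 mmol/L.
    """

    baseline_risk: float = 0.05
    beta_L: float = math.log(1.25)
    beta_GL: float = math.log(1.15)
    ldl_null: float = 3.5
    allele_freq: float = 0.37
    ldl_ref: float = 3.0

    def __post_init__(self):
        if not 0.0 < self.baseline_risk < 1.0:
            raise ParameterizationError(
                f"baseline_risk must be in (0, 1), got {self.baseline_risk}"
            )
        if not 0.0 < self.allele_freq < 1.0:
            raise ParameterizationError(
                f"allele_freq must be in (0, 1), got {self.allele_freq}"
            )

    @property
    def beta_G(self) -> float:
        """Main genotype effect implied by the null-crossing LDL."""
        return -self.beta_GL * (self.ldl_null - self.ldl_ref)

    def risk(self, carrier: bool, ldl: float) -> float:
        """Event probability for a genotype stratum at a study-mean LDL.

        Never clamped: a parameterization that pushes the probability to 1
        or above is rejected outright.
        """
        dl = ldl - self.ldl_ref
        log_rr = self.beta_L * dl
        if carrier:
            log_rr += self.beta_G + self.beta_GL * dl
        r = self.baseline_risk * math.exp(log_rr)
        if not 0.0 < r < 1.0:
            raise ParameterizationError(
                f"risk {r:.4g} outside (0, 1) at ldl={ldl}, carrier={carrier}"
            )
        return r

    def validate_range(self, ldl_lo: float, ldl_hi: float) -> None:
        """Reject parameterizations whose risks leave (0,1) on an LDL range."""
        for ldl in (ldl_lo, ldl_hi):
            for carrier in (False, True):
                self.risk(carrier, ldl)

    @property
    def genotype_probs(self) -> np.ndarray:
        """Hardy-Weinberg genotype proportions (argarg, argtrp, trptrp)."""
        q = self.allele_freq
        return np.array([q * q, 2 * q * (1 - q), (1 - q) * (1 - q)])

    def to_dict(self) -> dict:
        return {
            "baseline_risk": self.baseline_risk,
            "beta_L": self.beta_L,
            "beta_GL": self.beta_GL,
            "ldl_null": self.ldl_null,
            "allele_freq": self.allele_freq,
            "ldl_ref": self.ldl_ref,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VulnerabilityModel":
        return cls(**{k: float(v) for k, v in d.items()})


def risk(model: VulnerabilityModel, carrier: bool, ldl: float) -> float:
    """Functional alias for :meth:`VulnerabilityModel.risk`."""
    return model.risk(carrier, ldl)


@dataclass(frozen=True)
class StudyRecord:
    """One study-level unit: a cohort, case-control study, or trial arm.

    ``strata`` maps stratum name → a pair of counts whose meaning depends on
    the design: (events, persons at risk) for prospective designs
    (``cohort`` and ``trial_arm``), (cases, controls) for ``case_control``.
    Strata are genotype-level (argarg/argtrp/trptrp) when available, else
    carrier-level (carrier/noncarrier).
    """

    id: str
    design: str
    mean_ldl: float | None
    strata: dict[str, tuple[int, int]]
    arm: str = "na"
    delta_ldl: float | None = None
    trial_type: str | None = None

    _DESIGNS = frozenset({"cohort", "case_control", "trial_arm"})

    def __post_init__(self):
        if self.design not in self._DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if not self.strata:
            raise ValueError(f"study {self.id}: no strata")
        for name, (x, y) in self.strata.items():
            if x < 0 or y < 0:
                raise ValueError(f"study {self.id}/{name}: negative count")

    @property
    def prospective(self) -> bool:
        return self.design in {"cohort", "trial_arm"}

    @property
    def has_genotype_strata(self) -> bool:
        return all(g in self.strata for g in GENOTYPES)

    def genotype_counts(self) -> GenotypeCounts:
        """Total genotyped individuals per class (events + non-events)."""
        if not self.has_genotype_strata:
            raise KeyError(f"study {self.id} lacks genotype-level strata")

        def total(g):
            x, y = self.strata[g]
            return x + y if self.design == "case_control" else y

        return GenotypeCounts(total("argarg"), total("argtrp"), total("trptrp"))

    def _pair(self, name: str) -> tuple[int, int]:
        x, y = self.strata[name]
        # normalize to (events, non-events): prospective rows store
        # (events, persons at risk); case-control rows store (cases, controls)
        return (x, y - x) if self.prospective else (x, y)

    def table(self, stratification: str = "carrier") -> TwoByTwo:
        """Build the exposed-vs-unexposed 2x2 table for a genotype contrast.

        ``stratification``: ``carrier`` (Arg/Arg + Arg/Trp vs Trp/Trp),
        ``homozygous`` (Arg/Arg vs Trp/Trp), or ``heterozygous`` (Arg/Trp
        vs Trp/Trp).
        """
        if stratification == "carrier":
            if "carrier" in self.strata:
                a, b = self._pair("carrier")
            else:
                e1, n1 = self._pair("argarg")
                e2, n2 = self._pair("argtrp")
                a, b = e1 + e2, n1 + n2
            c, d = self._pair("trptrp" if "trptrp" in self.strata else "noncarrier")
        elif stratification in {"homozygous", "heterozygous"}:
            key = "argarg" if stratification == "homozygous" else "argtrp"
            a, b = self._pair(key)
            c, d = self._pair("trptrp")
        else:
            raise ValueError(f"unknown stratification {stratification!r}")
        return TwoByTwo(a, b, c, d)

    def effect(
        self,
        stratification: str = "carrier",
        correction: bool = True,
        ci_level: float = 0.95,
    ) -> EffectEstimate:
        """RR for prospective designs, OR for case-control."""
        table = self.table(stratification)
        if self.design == "case_control":
            return odds_ratio(table, correction, ci_level)
        return relative_risk(table, correction, ci_level)


def _child_rng(seed: int, study_id: str) -> np.random.Generator:
    """Per-study stream: master seed combined with a stable id hash."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(study_id.encode("utf-8"))])
    )


def _genotype_ldl_events(
    model: VulnerabilityModel, n: int, ldl: float, rng: np.random.Generator
) -> dict[str, tuple[int, int]]:
    """Draw HWE genotype counts, then binomial events at the study LDL."""
    counts = rng.multinomial(n, model.genotype_probs)
    strata = {}
    for geno, n_g in zip(GENOTYPES, counts):
        carrier = geno != "trptrp"
        p = model.risk(carrier, ldl)
        events = int(rng.binomial(n_g, p)) if n_g > 0 else 0
        strata[geno] = (events, int(n_g))
    return strata


def simulate_cohort(
    model: VulnerabilityModel,
    n: int,
    mean_ldl: float,
    seed: int,
    study_id: str = "cohort",
) -> StudyRecord:
    """Prospective cohort: HWE genotypes, binomial incident events."""
    if n <= 0:
        raise ValueError(f"cohort size must be positive, got {n}")
    rng = _child_rng(seed, study_id)
    strata = _genotype_ldl_events(model, n, mean_ldl, rng)
    return StudyRecord(study_id, "cohort", mean_ldl, strata)


def simulate_case_control(
    model: VulnerabilityModel,
    n_cases: int,
    n_controls: int,
    mean_ldl: float,
    seed: int,
    study_id: str = "case_control",
) -> StudyRecord:
    """Case-control study: genotype mixtures among cases and controls.

    The genotype distribution among prevalent cases (controls) follows from
    Bayes' rule applied to the population HWE mixture and the risk model at
    the study-mean LDL, so the sample odds ratio estimates the model RR
    when events are rare.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    rng = _child_rng(seed, study_id)
    g = model.genotype_probs
    risks = np.array(
        [model.risk(geno != "trptrp", mean_ldl) for geno in GENOTYPES]
    )
    p_case = g * risks / float(g @ risks)
    p_ctrl = g * (1 - risks) / float(g @ (1 - risks))
    cases = rng.multinomial(n_cases, p_case)
    controls = rng.multinomial(n_controls, p_ctrl)
    strata = {
        geno: (int(c), int(ct)) for geno, c, ct in zip(GENOTYPES, cases, controls)
    }
    return StudyRecord(study_id, "case_control", mean_ldl, strata)


def simulate_trial(
    model: VulnerabilityModel,
    n_per_arm: int,
    baseline_ldl: float,
    delta_ldl: float,
    seed: int,
    study_id: str = "trial",
    placebo_controlled: bool = True,
) -> StratifiedTrialRecord:
    """Two-arm trial: control arm at baseline LDL, active at baseline − Y.

    Both arms draw genotypes from the same Hardy-Weinberg mixture
    (randomization), then binomial events at the arm's achieved LDL.
    """
    if n_per_arm <= 0:
        raise ValueError("n_per_arm must be positive")
    if not delta_ldl > 0:
        raise ValueError(f"delta_ldl (Y) must be > 0, got {delta_ldl}")
    rng = _child_rng(seed, study_id)
    control = _genotype_ldl_events(model, n_per_arm, baseline_ldl, rng)
    active = _genotype_ldl_events(model, n_per_arm, baseline_ldl - delta_ldl, rng)
    return StratifiedTrialRecord(
        id=study_id,
        control=control,
        active=active,
        delta_ldl=delta_ldl,
        control_ldl=baseline_ldl,
        active_ldl=baseline_ldl - delta_ldl,
        placebo_controlled=placebo_controlled,
    )


def trial_arm_records(trial: StratifiedTrialRecord) -> list[StudyRecord]:
    """View each treatment-allocation arm as a separate prospective cohort."""
    records = []
    for arm, strata, ldl in (
        ("control", trial.control, trial.control_ldl),
        ("active", trial.active, trial.active_ldl),
    ):
        records.append(
            StudyRecord(
                id=f"{trial.id}_{arm}",
                design="trial_arm",
                mean_ldl=ldl,
                strata=dict(strata),
                arm=arm,
                delta_ldl=trial.delta_ldl,
                trial_type="placebo" if trial.placebo_controlled else "intensity",
            )
        )
    return records


# ---------------------------------------------------------------------------
# Collection configuration


@dataclass(frozen=True)
class CohortSpec:
    n: int
    mean_ldl: float


@dataclass(frozen=True)
class CaseControlSpec:
    n_cases: int
    n_controls: int
    mean_ldl: float


@dataclass(frozen=True)
class TrialSpec:
    n_per_arm: int
    baseline_ldl: float
    delta_ldl: float
    placebo_controlled: bool = True


def _default_cohorts() -> tuple[CohortSpec, ...]:
    # three large population cohorts spanning the LDL range
    return tuple(
        CohortSpec(12825, ldl) for ldl in (2.6, 3.5, 4.4)
    )


def _default_case_controls() -> tuple[CaseControlSpec, ...]:
    ldls = np.linspace(2.5, 4.5, 18)
    return tuple(CaseControlSpec(987, 2146, float(l)) for l in ldls)


def _default_trials() -> tuple[TrialSpec, ...]:
    # five placebo-controlled trials (larger Y) and three intensity trials
    placebo = [(5.0, 1.1), (3.6, 1.0), (3.8, 1.0), (3.4, 1.2), (2.8, 1.25)]
    intensity = [(2.7, 0.65), (2.5, 0.6), (3.1, 0.55)]
    specs = [TrialSpec(3129, b, y, True) for b, y in placebo]
    specs += [TrialSpec(3129, b, y, False) for b, y in intensity]
    return tuple(specs)


@dataclass(frozen=True)
class CollectionConfig:
    """Shapes a simulated study collection.

    The default emulates the structure of a large published evidence base:
    3 prospective cohorts (~12.8k persons each), 18 case-control studies
    (~1k cases / ~2.1k controls), and 8 two-arm trials (5 placebo-controlled,
    3 intensity-comparison; ~3.1k per arm) — so 37 association-eligible
    units of which 19 (cohorts + 16 trial arms) carry a mean LDL and are
    meta-regression-eligible.
    """

    cohorts: tuple[CohortSpec, ...] = field(default_factory=_default_cohorts)
    case_controls: tuple[CaseControlSpec, ...] = field(
        default_factory=_default_case_controls
    )
    trials: tuple[TrialSpec, ...] = field(default_factory=_default_trials)

    def scaled(self, factor: float) -> "CollectionConfig":
        """Uniformly rescale all sample sizes (minimum 50 per group)."""

        def s(n):
            return max(50, int(round(n * factor)))

        return CollectionConfig(
            cohorts=tuple(CohortSpec(s(c.n), c.mean_ldl) for c in self.cohorts),
            case_controls=tuple(
                CaseControlSpec(s(c.n_cases), s(c.n_controls), c.mean_ldl)
                for c in self.case_controls
            ),
            trials=tuple(
                TrialSpec(s(t.n_per_arm), t.baseline_ldl, t.delta_ldl,
                          t.placebo_controlled)
                for t in self.trials
            ),
        )

    def to_dict(self) -> dict:
        return {
            "cohorts": [{"n": c.n, "mean_ldl": c.mean_ldl} for c in self.cohorts],
            "case_controls": [
                {
                    "n_cases": c.n_cases,
                    "n_controls": c.n_controls,
                    "mean_ldl": c.mean_ldl,
                }
                for c in self.case_controls
            ],
            "trials": [
                {
                    "n_per_arm": t.n_per_arm,
                    "baseline_ldl": t.baseline_ldl,
                    "delta_ldl": t.delta_ldl,
                    "placebo_controlled": t.placebo_controlled,
                }
                for t in self.trials
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CollectionConfig":
        return cls(
            cohorts=tuple(CohortSpec(**c) for c in d.get("cohorts", [])),
            case_controls=tuple(
                CaseControlSpec(**c) for c in d.get("case_controls", [])
            ),
            trials=tuple(TrialSpec(**t) for t in d.get("trials", [])),
        )

    @classmethod
    def from_yaml(cls, path) -> tuple["CollectionConfig", "VulnerabilityModel", int]:
        """Load (config, model, seed) from a YAML file.

        Recognized top-level keys: ``model`` (risk-model parameters),
        ``seed``, and the collection lists ``cohorts`` / ``case_controls`` /
        ``trials``.  Missing sections fall back to defaults.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        model = VulnerabilityModel.from_dict(raw.get("model", {}))
        seed = int(raw.get("seed", 0))
        coll = {
            k: raw[k] for k in ("cohorts", "case_controls", "trials") if k in raw
        }
        default = cls()
        config = cls(
            cohorts=tuple(CohortSpec(**c) for c in coll["cohorts"])
            if "cohorts" in coll
            else default.cohorts,
            case_controls=tuple(
                CaseControlSpec(**c) for c in coll["case_controls"]
            )
            if "case_controls" in coll
            else default.case_controls,
            trials=tuple(TrialSpec(**t) for t in coll["trials"])
            if "trials" in coll
            else default.trials,
        )
        return config, model, seed

    def to_yaml(self, path, model: VulnerabilityModel, seed: int) -> None:
        payload = {"model": model.to_dict(), "seed": seed, **self.to_dict()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def simulate_collection(
    model: VulnerabilityModel,
    config: CollectionConfig | None = None,
    seed: int = 0,
) -> tuple[list[StudyRecord], list[StratifiedTrialRecord]]:
    """Generate a full study collection under the vulnerability model.

    Returns ``(studies, trials)`` where ``studies`` contains the cohorts,
    the case-control studies, and one ``trial_arm`` record per treatment
    allocation arm (each arm treated as a separate prospective cohort, so
    the default configuration yields 37 association-eligible units of which
    19 are meta-regression-eligible).
    """
    config = config or CollectionConfig()
    ldls = [c.mean_ldl for c in config.cohorts] + [c.mean_ldl for c in config.case_controls]
    ldls += [t.baseline_ldl for t in config.trials]
    ldls += [t.baseline_ldl - t.delta_ldl for t in config.trials]
    if ldls:
        model.validate_range(min(ldls), max(ldls))

    studies: list[StudyRecord] = []
    trials: list[StratifiedTrialRecord] = []
    for i, c in enumerate(config.cohorts, 1):
        studies.append(
            simulate_cohort(model, c.n, c.mean_ldl, seed, f"cohort_{i:02d}")
        )
    for i, c in enumerate(config.case_controls, 1):
        studies.append(
            simulate_case_control(
                model, c.n_cases, c.n_controls, c.mean_ldl, seed, f"cc_{i:02d}"
            )
        )
    for i, t in enumerate(config.trials, 1):
        trial = simulate_trial(
            model,
            t.n_per_arm,
            t.baseline_ldl,
            t.delta_ldl,
            seed,
            f"trial_{i:02d}",
            placebo_controlled=t.placebo_controlled,
        )
        trials.append(trial)
        studies.extend(trial_arm_records(trial))
    return studies, trials
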