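"""Configuration objects for simulation, cohort selection and episode construction.

All dates in the package are integer day offsets from a global origin
(2010-01-01 by convention); intervals are therefore plain day counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

#: The four biologic classes analysed: adalimumab, infliximab, secukinumab, ustekinumab.
DRUGS = ("ADL", "IFX", "SCK", "UST")

#: Calendar anchor for day-offset <-> ISO-date conversion on disk.
DATE_ORIGIN = "2010-01-01"

_PROB_TOL = 1e-9


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class GapPolicy:
    """Per-drug refill-gap rule defining discontinuation.

    The *treatment interval* is the scheduled number of days between successive
    claims under the approved regimen (30 d for ADL/IFX/SCK, 90 d for UST).
    The *medication gap* is the extra refill delay tolerated beyond it (60 d in
    the base case).  Their sum is the *non-refill period*: a span without an
    index-drug claim longer than this proves discontinuation.
    """

    treatment_interval_days: Mapping[str, int] = field(
        default_factory=lambda: {"ADL": 30, "IFX": 30, "SCK": 30, "UST": 90}
    )
    medication_gap_days: Mapping[str, int] = field(
        default_factory=lambda: {d: 60 for d in DRUGS}
    )
    label: str = "base"

    def __post_init__(self) -> None:
        for drug in self.treatment_interval_days:
            if self.treatment_interval_days[drug] <= 0:
                raise ValueError(f"treatment interval for {drug} must be positive")
            if self.medication_gap_days.get(drug, -1) <= 0:
                raise ValueError(f"medication gap for {drug} must be positive")

    def interval(self, drug: str) -> int:
        return int(self.treatment_interval_days[drug])

    def gap(self, drug: str) -> int:
        return int(self.medication_gap_days[drug])

    def non_refill_days(self, drug: str) -> int:
        """Treatment interval + medication gap for ``drug``."""
        return self.interval(drug) + self.gap(drug)

    def with_gap(self, gap_days: int, label: str | None = None) -> "GapPolicy":
        """Return a policy with the same intervals and a uniform medication gap."""
        return GapPolicy(
            treatment_interval_days=dict(self.treatment_interval_days),
            medication_gap_days={d: gap_days for d in self.treatment_interval_days},
            label=label or f"gap{gap_days}",
        )


def _expand_range(lo: str, hi: str) -> tuple[str, ...]:
    """Expand an ICD-10 block like ('M05','M06') into individual 3-char prefixes."""
    letter = lo[0]
    return tuple(f"{letter}{i:02d}" for i in range(int(lo[1:]), int(hi[1:]) + 1))


def _diabetes_sets() -> tuple[tuple[str, ...], tuple[str, ...]]:
    # E10-E14 with 4th character 0-8 -> "with complication"; .9 / bare code -> "without".
    with_c = tuple(f"E1{d}.{c}" for d in range(5) for c in range(9))
    without = tuple(f"E1{d}.9" for d in range(5))
    return without, with_c


@dataclass(frozen=True)
class CodePolicy:
    """ICD-10 prefix sets driving cohort inclusion, exclusion and comorbidity flags.

    Matching is by code prefix, so ``"L40"`` matches ``"L40.5"``.  Defaults:
    psoriasis L40 for inclusion; rheumatoid arthritis M05-M06, inflammatory
    bowel disease K50-K51, ankylosing spondylitis M45 and juvenile arthritis
    M08 for exclusion; a conventional comorbidity map (obesity E66, diabetes
    E10-E14 split on the fourth character, hypertension I10-I15,
    hyperlipidemia E78, old myocardial infarction I21/I22/I25.2, heart
    failure I50).  All sets are overridable.
    """

    inclusion_codes: tuple[str, ...] = ("L40",)
    exclusion_codes: tuple[str, ...] = field(
        default_factory=lambda: _expand_range("M05", "M06")
        + _expand_range("K50", "K51")
        + ("M45", "M08")
    )
    comorbidity_code_map: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "obesity": ("E66",),
            "diabetes_without_complication": _diabetes_sets()[0],
            "diabetes_with_complication": _diabetes_sets()[1],
            "hypertension": _expand_range("I10", "I15"),
            "hyperlipidemia": ("E78",),
            "old_myocardial_infarction": ("I21", "I22", "I25.2"),
            "heart_failure": ("I50",),
        }
    )

    def __post_init__(self) -> None:
        overlap = {
            c
            for c in self.inclusion_codes
            for e in self.exclusion_codes
            if c.startswith(e) or e.startswith(c)
        }
        if overlap:
            raise ValueError(f"inclusion and exclusion codes overlap: {sorted(overlap)}")

    @staticmethod
    def matches(code: str, prefixes: tuple[str, ...]) -> bool:
        return any(code.startswith(p) for p in prefixes)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic claims generator.

    Defaults emulate the observed study conditions of the Japanese
    employer-insurance psoriasis cohort the package targets: the biologic mix,
    the BT-naive fraction, per-30-day discontinuation hazards back-solved from
    the reported 12-month naive persistence rates, comorbidity prevalences,
    and monthly cost magnitudes in JPY.

    ``monthly_discontinuation_hazard`` is the per-drug probability of stopping
    within each 30-day cycle of therapy; discontinuation times are geometric
    on the 30-day grid so that 12-month survival equals ``(1-h)**12``.
    """

    n_patients: int = 200
    drug_mix: Mapping[str, float] = field(
        default_factory=lambda: {"ADL": 42 / 205, "IFX": 52 / 205, "SCK": 21 / 205, "UST": 90 / 205}
    )
    monthly_discontinuation_hazard: Mapping[str, float] = field(
        default_factory=lambda: {"ADL": 0.061, "IFX": 0.052, "SCK": 0.048, "UST": 0.019}
    )
    switch_probability: float = 0.3
    dosing_interval_days: Mapping[str, int] = field(
        default_factory=lambda: {"ADL": 30, "IFX": 30, "SCK": 30, "UST": 90}
    )
    # monthly non-biologic cost (JPY) by category: (mean, dispersion) of a gamma draw
    pre_cost_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"IP": (15_000, 1.5), "OP": (17_000, 0.8), "RX": (20_000, 0.8)}
    )
    post_cost_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"IP": (30_000, 1.5), "OP": (25_000, 0.8), "RX": (20_000, 0.8)}
    )
    # cost (JPY) of one biologic administration, per drug (mean of a gamma draw)
    bt_claim_cost_jpy: Mapping[str, float] = field(
        default_factory=lambda: {"ADL": 110_000, "IFX": 170_000, "SCK": 150_000, "UST": 570_000}
    )
    bt_cost_dispersion: float = 0.05
    inpatient_claim_fraction: float = 0.05
    enrollment_span_days: int = 1095
    index_day_range: tuple[int, int] = (365, 795)
    naive_fraction: float = 177 / 205
    l40_fraction: float = 1.0
    exclusion_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "rheumatoid_arthritis": 0.08,
            "inflammatory_bowel_disease": 0.04,
            "ankylosing_spondylitis": 0.03,
            "juvenile_arthritis": 0.01,
        }
    )
    comorbidity_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "obesity": 0.005,
            "diabetes_without_complication": 0.059,
            "diabetes_with_complication": 0.034,
            "hypertension": 0.239,
            "hyperlipidemia": 0.224,
            "old_myocardial_infarction": 0.010,
            "heart_failure": 0.068,
        }
    )
    female_fraction: float = 0.181
    age_mean: float = 47.1
    age_sd: float = 11.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError(f"n_patients must be non-negative, got {self.n_patients}")
        total = sum(self.drug_mix.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"drug_mix must sum to 1, got {total!r}")
        for drug, p in self.drug_mix.items():
            _check_prob(f"drug_mix[{drug}]", p)
        for drug, h in self.monthly_discontinuation_hazard.items():
            _check_prob(f"monthly_discontinuation_hazard[{drug}]", h)
        for name in ("switch_probability", "naive_fraction", "l40_fraction",
                     "female_fraction", "inpatient_claim_fraction"):
            _check_prob(name, getattr(self, name))
        for cond, p in {**self.exclusion_prevalence, **self.comorbidity_prevalence}.items():
            _check_prob(f"prevalence[{cond}]", p)
        for label, params in (("pre_cost_params", self.pre_cost_params),
                              ("post_cost_params", self.post_cost_params)):
            for cat, (mean, disp) in params.items():
                if mean < 0:
                    raise ValueError(f"{label}[{cat}] mean must be >= 0, got {mean}")
                if disp <= 0:
                    raise ValueError(f"{label}[{cat}] dispersion must be > 0, got {disp}")
        for drug, interval in self.dosing_interval_days.items():
            if interval <= 0:
                raise ValueError(f"dosing_interval_days[{drug}] must be positive")
        if self.enrollment_span_days <= 0:
            raise ValueError("enrollment_span_days must be positive")
        lo, hi = self.index_day_range
        if not (0 <= lo <= hi):
            raise ValueError(f"index_day_range must be ordered and non-negative, got {self.index_day_range}")

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings: input mode, policies, horizons, output."""

    input_mode: str = "synthetic"  # "synthetic" | "files"
    input_dir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    codes: CodePolicy = field(default_factory=CodePolicy)
    gap_policy: GapPolicy = field(default_factory=GapPolicy)
    sensitivity_gaps: tuple[int, ...] = (30, 90)
    horizons: tuple[int, ...] = (365, 730)
    reference_drug: str = "UST"
    output_dir: str = "out"
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "files"):
            raise ValueError(f"input_mode must be 'synthetic' or 'files', got {self.input_mode!r}")
        if self.input_mode == "files" and not self.input_dir:
            raise ValueError("input_mode 'files' requires input_dir")
        if list(self.horizons) != sorted(self.horizons) or min(self.horizons) <= 0:
            raise ValueError("horizons must be positive and ascending")


def load_pipeline_config(path: str) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Recognised top-level keys mirror the dataclass fields; ``simulation`` and
    ``gap_policy`` are nested mappings, unknown keys raise.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimulationConfig(**raw.pop("simulation", {}))
    gap_kwargs = raw.pop("gap_policy", {})
    gap = GapPolicy(**gap_kwargs) if gap_kwargs else GapPolicy()
    codes_kwargs = raw.pop("codes", {})
    codes = CodePolicy(**{k: tuple(v) if isinstance(v, list) else v for k, v in codes_kwargs.items()})
    for key in ("sensitivity_gaps", "horizons"):
        if key in raw:
            raw[key] = tuple(raw[key])
    known = {f for f in PipelineConfig.__dataclass_fields__}  # noqa: C416
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    return PipelineConfig(simulation=sim, gap_policy=gap, codes=codes, **raw)
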