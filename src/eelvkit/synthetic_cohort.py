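"""Synthetic cohort generator for paired EELV method-comparison data.

The generator emulates the design of a saline-lavage ARDS validation
experiment in piglets: for each animal an ARDS-onset measurement at zero
PEEP, a decremental PEEP trial from 20 to 2 cm H2O in 2 cm H2O steps, and
an 8-level tidal-volume ladder (4-20 mL/kg) applied at a per-animal
"optimal" PEEP.  The reference method (CT) reads a per-animal logistic
recruitment curve plus measurement noise; the test method (washin-washout)
reads the same true volume plus a structured bias:

* a proportional component ``b0 + b1 * m`` in the pairwise mean ``m``
  (the bias grows more negative as lung volume increases);
* a PEEP-excess component active above a knee (default 10 cm H2O),
  amplified when tidal volume is low and when baseline EELV is low —
  mirroring a three-way PEEP x V_T x EELV_Base interaction;
* a per-animal random offset and white measurement noise.

A missingness mask knocks out one method on a configurable fraction of
non-baseline rows, so that the expected number of fully paired rows
matches the 218 retained in the emulated design (out of 14 x 19 = 266).
Ground truth (noise-free volume and bias) is recorded in a sidecar table
for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from eelvkit.errors import ConfigError, DomainError
from eelvkit.study_data import Stage, StudyTable

_DEFAULT_PEEP_SCHEDULE = tuple(range(20, 0, -2))  # 20, 18, ..., 2 cm H2O
_DEFAULT_VT_LADDER = (4.0, 5.0, 6.0, 7.0, 8.0, 10.0, 15.0, 20.0)  # mL/kg


@dataclass(frozen=True)
class RecruitmentParams:
    """Per-cohort distribution of the logistic PEEP-recruitment curve.

    Baseline (PEEP 0) volumes are drawn from a Gamma distribution with the
    given mean/SD (strictly positive support, matching a collapsed
    post-lavage lung); the fully recruited volume at PEEP 20 is Gaussian.
    The curve between the two anchors is logistic in PEEP with a
    per-animal midpoint and steepness.
    """

    baseline_mean: float = 236.0    # mL, cohort mean at PEEP 0
    baseline_sd: float = 143.0      # mL
    peep20_mean: float = 1206.0     # mL, cohort mean at PEEP 20
    peep20_sd: float = 185.0        # mL
    midpoint_mean: float = 10.0     # cm H2O, logistic inflection
    midpoint_sd: float = 2.0
    steepness_mean: float = 3.0     # cm H2O, logistic scale
    steepness_sd: float = 0.5
    vt_recruitment: float = 4.0     # mL per mL/kg of V_T above 6, ladder only


@dataclass(frozen=True)
class BiasParams:
    """Structured inter-method bias (washin-washout minus CT), in mL.

    Expected bias at the noise-free fixed point is::

        d = intercept + slope * m + peep_gain * max(0, peep - knee) * amp

    with ``amp = (1 + low_vt_amplifier * [vt < vt_cutoff])
    * (1 + low_base_amplifier * [eelv_base < base_cutoff])``.
    """

    intercept: float = 85.8         # mL (b0)
    slope: float = -0.4503          # per mL of mean volume (b1)
    peep_gain: float = -6.0         # mL per cm H2O above the knee
    knee: float = 10.0              # cm H2O
    low_vt_amplifier: float = 0.5
    low_base_amplifier: float = 0.5
    vt_cutoff: float = 170.0        # mL, high/low V_T classification
    base_cutoff: float = 157.0      # mL, high/low baseline-EELV classification
    animal_sd: float = 25.0         # mL, per-animal random bias offset


@dataclass(frozen=True)
class CohortConfig:
    """Full description of one simulated cohort."""

    n_animals: int = 14
    weight_mean: float = 28.0       # kg
    weight_sd: float = 2.0          # kg
    peep_schedule: tuple = _DEFAULT_PEEP_SCHEDULE     # cm H2O, decremental
    vt_ladder: tuple = _DEFAULT_VT_LADDER             # mL/kg at optimal PEEP
    optimal_peep_rule: str = "random"  # random | best_eelv | best_compliance_proxy | peep_fio2_table
    recruitment: RecruitmentParams = field(default_factory=RecruitmentParams)
    bias: BiasParams = field(default_factory=BiasParams)
    noise_sd_ct: float = 30.0       # mL
    noise_sd_wiwo: float = 130.0    # mL
    missing_fraction: float = 48.0 / 252.0  # of non-baseline rows
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_animals < 1:
            problems.append(f"n_animals must be >= 1, got {self.n_animals}")
        if self.weight_mean <= 0 or self.weight_sd < 0:
            problems.append("weight_mean must be > 0 and weight_sd >= 0")
        if not 0 <= self.missing_fraction < 1:
            problems.append(
                f"missing_fraction must be in [0, 1), got {self.missing_fraction}"
            )
        for sd_name in ("noise_sd_ct", "noise_sd_wiwo"):
            if getattr(self, sd_name) < 0:
                problems.append(f"{sd_name} must be >= 0")
        for p in self.peep_schedule:
            if p % 2 != 0 or not 0 <= p <= 20:
                problems.append(f"peep_schedule value {p} not an even level in [0, 20]")
        if any(v <= 0 for v in self.vt_ladder):
            problems.append("vt_ladder values must be > 0 mL/kg")
        if self.optimal_peep_rule not in (
            "random",
            "best_eelv",
            "best_compliance_proxy",
            "peep_fio2_table",
        ):
            problems.append(f"unknown optimal_peep_rule {self.optimal_peep_rule!r}")
        if problems:
            raise ConfigError("invalid CohortConfig: " + "; ".join(problems))


@dataclass(frozen=True)
class AnimalParams:
    """One animal's draw of the recruitment curve and bias offset."""

    baseline: float       # mL at PEEP 0
    peep20: float         # mL at PEEP 20
    midpoint: float       # cm H2O
    steepness: float      # cm H2O
    bias_offset: float    # mL
    weight: float         # kg


@dataclass(frozen=True)
class SimulatedCohort:
    """A generated cohort plus its ground-truth sidecar.

    ``truth`` has one row per record with the noise-free CT volume
    (``true_eelv_ct_mL``), the noise-free test-method volume
    (``true_eelv_wiwo_mL``) and their difference (``true_bias_mL``).
    """

    table: StudyTable
    truth: pd.DataFrame
    config: CohortConfig

    def write(self, table_path: str | Path, truth_path: str | Path | None = None) -> None:
        self.table.to_csv(table_path)
        if truth_path is not None:
            self.truth.to_csv(truth_path, index=False)


# ---------------------------------------------------------------------------
# component operations


def draw_animal(config: CohortConfig, rng: np.random.Generator) -> AnimalParams:
    """Sample one animal's recruitment-curve parameters and bias offset."""
    rec = config.recruitment
    # Gamma parametrized by mean/SD keeps baselines strictly positive while
    # preserving the target cohort mean exactly.
    shape = (rec.baseline_mean / rec.baseline_sd) ** 2
    scale = rec.baseline_sd**2 / rec.baseline_mean
    baseline = float(rng.gamma(shape, scale))
    peep20 = float(rng.normal(rec.peep20_mean, rec.peep20_sd))
    peep20 = max(peep20, baseline + 50.0)  # recruited lung exceeds collapsed lung
    return AnimalParams(
        baseline=baseline,
        peep20=peep20,
        midpoint=float(rng.normal(rec.midpoint_mean, rec.midpoint_sd)),
        steepness=max(0.5, float(rng.normal(rec.steepness_mean, rec.steepness_sd))),
        bias_offset=float(rng.normal(0.0, config.bias.animal_sd)),
        weight=max(10.0, float(rng.normal(config.weight_mean, config.weight_sd))),
    )


def recruitment_curve(peep, animal: AnimalParams):
    """True end-expiratory CT volume (mL) at a given PEEP for one animal.

    Logistic in PEEP, renormalized so the curve passes exactly through the
    animal's baseline draw at PEEP 0 and its recruited volume at PEEP 20;
    monotone non-decreasing for any parameter draw.
    """
    p = np.asarray(peep, dtype=float)
    if np.any(p < 0):
        raise DomainError(f"peep must be >= 0 cm H2O, got {peep}")

    def g(x):
        return 1.0 / (1.0 + np.exp(-(x - animal.midpoint) / animal.steepness))

    frac = (g(p) - g(0.0)) / (g(20.0) - g(0.0))
    out = animal.baseline + (animal.peep20 - animal.baseline) * frac
    return float(out) if np.isscalar(peep) else out


def expected_bias(
    m, peep, vt, eelv_base, params: BiasParams, animal_offset: float = 0.0
):
    """Noise-free expected bias (mL) at pairwise mean ``m``."""
    m = np.asarray(m, dtype=float)
    excess = np.maximum(0.0, np.asarray(peep, dtype=float) - params.knee)
    amp = (1.0 + params.low_vt_amplifier * (np.asarray(vt) < params.vt_cutoff)) * (
        1.0 + params.low_base_amplifier * (np.asarray(eelv_base) < params.base_cutoff)
    )
    return params.intercept + params.slope * m + params.peep_gain * excess * amp + animal_offset


def apply_bias(
    eelv_ct_true: float,
    peep: float,
    vt: float,
    eelv_base: float,
    params: BiasParams,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    animal_offset: float = 0.0,
) -> float:
    """Test-method reading (mL) for a true CT volume under the bias model.

    The bias is defined on the pairwise mean ``m = (ct + wiwo)/2``, which
    depends on the result itself; the noise-free fixed point is solved in
    closed form before additive Gaussian noise is applied.  The result is
    floored at 0 mL (a gas volume cannot be negative).
    """
    if abs(1.0 - params.slope / 2.0) < 1e-12:
        raise DomainError("bias slope of 2 makes the mean-based bias ill-defined")
    excess = max(0.0, peep - params.knee)
    amp = (1.0 + params.low_vt_amplifier * (vt < params.vt_cutoff)) * (
        1.0 + params.low_base_amplifier * (eelv_base < params.base_cutoff)
    )
    offset = params.intercept + params.peep_gain * excess * amp + animal_offset
    # solve wiwo = ct + offset + slope*(ct + wiwo)/2 for wiwo
    wiwo_nf = (eelv_ct_true * (1.0 + params.slope / 2.0) + offset) / (
        1.0 - params.slope / 2.0
    )
    noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
    return max(0.0, wiwo_nf + noise)


def _noise_free_wiwo(ct_true, peep, vt, eelv_base, params, animal_offset):
    excess = np.maximum(0.0, np.asarray(peep, dtype=float) - params.knee)
    amp = (1.0 + params.low_vt_amplifier * (np.asarray(vt) < params.vt_cutoff)) * (
        1.0 + params.low_base_amplifier * (np.asarray(eelv_base) < params.base_cutoff)
    )
    offset = params.intercept + params.peep_gain * excess * amp + animal_offset
    return (np.asarray(ct_true) * (1.0 + params.slope / 2.0) + offset) / (
        1.0 - params.slope / 2.0
    )


def _select_optimal_peep(
    config: CohortConfig, animal: AnimalParams, rule: str, rng: np.random.Generator
) -> float:
    if rule == "random":
        return float(rng.choice([8, 10, 12, 14, 16]))
    if rule == "best_eelv":
        # lowest trial PEEP whose true volume keeps >= 95% of the PEEP-20 volume
        for p in sorted(config.peep_schedule):
            if recruitment_curve(p, animal) >= 0.95 * animal.peep20:
                return float(p)
        return float(max(config.peep_schedule))
    if rule == "best_compliance_proxy":
        # compliance peaks just above the recruitment inflection
        p = 2.0 * round((animal.midpoint + 2.0) / 2.0)
        return float(min(20.0, max(2.0, p)))
    if rule == "peep_fio2_table":
        return 12.0
    raise ConfigError(f"unknown optimal_peep_rule {rule!r}")


def _rr_for_vt(vt_ml_per_kg: float) -> float:
    # high RR for lung protection, reduced at large tidal volumes to cap
    # airway pressure
    if vt_ml_per_kg <= 8:
        return 35.0
    if vt_ml_per_kg <= 10:
        return 30.0
    if vt_ml_per_kg <= 15:
        return 22.0
    return 16.0


# ---------------------------------------------------------------------------
# cohort assembly


def simulate_cohort(config: CohortConfig | None = None) -> SimulatedCohort:
    """Generate one cohort: StudyTable plus ground-truth sidecar.

    Deterministic given ``config.seed``; all draws flow from a single root
    generator.  Per animal the timeline is: ARDS onset (PEEP 0, V_T
    10 mL/kg), the decremental PEEP trial (V_T 6 mL/kg), then the
    tidal-volume ladder at the animal's optimal PEEP.  The missingness
    mask never touches the ARDS-onset row (the baseline covariate must
    exist for every animal).
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    rec = config.recruitment

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for i in range(config.n_animals):
        animal_id = f"pig{i + 1:02d}"
        animal = draw_animal(config, rng)
        optimal_peep = _select_optimal_peep(config, animal, config.optimal_peep_rule, rng)

        conditions: list[tuple[Stage, float, float, float]] = []
        conditions.append((Stage.ARDS_ONSET, 0.0, 10.0 * animal.weight, 30.0))
        for p in config.peep_schedule:
            conditions.append((Stage.PEEP_TRIAL, float(p), 6.0 * animal.weight, 35.0))
        for vt_kg in config.vt_ladder:
            conditions.append(
                (Stage.VT_LADDER, optimal_peep, vt_kg * animal.weight, _rr_for_vt(vt_kg))
            )

        eelv_base_true = animal.baseline
        for order, (stage, peep, vt, rr) in enumerate(conditions):
            true_ct = recruitment_curve(peep, animal)
            if stage is Stage.VT_LADDER:
                # short-term tidal recruitment around the ladder's 6 mL/kg anchor
                true_ct += rec.vt_recruitment * (vt / animal.weight - 6.0)
                true_ct = max(0.0, true_ct)
            true_wiwo = float(
                _noise_free_wiwo(
                    true_ct, peep, vt, eelv_base_true, config.bias, animal.bias_offset
                )
            )
            eelv_ct = max(0.0, true_ct + float(rng.normal(0.0, config.noise_sd_ct)))
            eelv_wiwo = max(
                0.0, true_wiwo + float(rng.normal(0.0, config.noise_sd_wiwo))
            )

            missing_ct = missing_wiwo = False
            if stage is not Stage.ARDS_ONSET and config.missing_fraction > 0:
                if rng.random() < config.missing_fraction:
                    # technical washin-washout failures dominate the losses
                    if rng.random() < 0.75:
                        missing_wiwo = True
                    else:
                        missing_ct = True

            rows.append(
                {
                    "animal_id": animal_id,
                    "weight_kg": round(animal.weight, 2),
                    "stage": stage.value,
                    "order_index": order,
                    "peep_cmH2O": peep,
                    "vt_mL": round(vt, 1),
                    "rr_bpm": rr,
                    "eelv_ct_mL": np.nan if missing_ct else round(eelv_ct, 2),
                    "eelv_wiwo_mL": np.nan if missing_wiwo else round(eelv_wiwo, 2),
                }
            )
            truth_rows.append(
                {
                    "animal_id": animal_id,
                    "order_index": order,
                    "true_eelv_ct_mL": true_ct,
                    "true_eelv_wiwo_mL": true_wiwo,
                    "true_bias_mL": true_wiwo - true_ct,
                    "true_eelv_base_mL": eelv_base_true,
                    "optimal_peep_cmH2O": optimal_peep,
                }
            )

    table = StudyTable(pd.DataFrame(rows))
    return SimulatedCohort(table=table, truth=pd.DataFrame(truth_rows), config=config)


def expected_paired_rows(config: CohortConfig) -> float:
    """Expected number of fully paired rows after masking.

    One baseline row per animal is exempt; each remaining row loses one
    method with probability ``missing_fraction``.
    """
    per_animal = 1 + len(config.peep_schedule) + len(config.vt_ladder)
    maskable = config.n_animals * (per_animal - 1)
    return config.n_animals + maskable * (1.0 - config.missing_fraction)


def population_bias_line(
    config: CohortConfig, n_animals: int = 400, seed: int = 12345
) -> tuple[float, float]:
    """Monte-Carlo estimate of the generator's population bias line.

    Simulates a large cohort under ``config`` (same noise, same design)
    and returns the population least-squares line of the observed bias
    ``d`` on the observed mean ``m`` — the estimand that a Bland-Altman
    style regression targets under this generator, including the
    attenuation and noise-correlation effects of measurement error.
    """
    big = dataclasses.replace(config, n_animals=n_animals, seed=seed)
    from eelvkit.study_data import paired_series

    series = paired_series(simulate_cohort(big).table)
    slope, intercept = np.polyfit(series.m, series.d, 1)
    return float(intercept), float(slope)


# ---------------------------------------------------------------------------
# config I/O


def config_from_yaml(path: str | Path) -> CohortConfig:
    """Load a :class:`CohortConfig` from YAML; unknown keys are rejected."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def config_from_dict(data: dict) -> CohortConfig:
    data = dict(data)
    kwargs = {}
    for sub_name, sub_cls in (("recruitment", RecruitmentParams), ("bias", BiasParams)):
        if sub_name in data:
            sub = data.pop(sub_name)
            unknown = set(sub) - {f.name for f in dataclasses.fields(sub_cls)}
            if unknown:
                raise ConfigError(f"unknown {sub_name} fields: {sorted(unknown)}")
            kwargs[sub_name] = sub_cls(**sub)
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    for key in ("peep_schedule", "vt_ladder"):
        if key in data:
            data[key] = tuple(data[key])
    config = CohortConfig(**data, **kwargs)
    config.validate()
    return config


def table_to_csv_bytes(table: StudyTable) -> bytes:
    """Canonical CSV serialization (used for byte-level determinism checks)."""
    buf = io.StringIO()
    table.frame.to_csv(buf, index=False)
    return buf.getvalue().encode()
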