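"""Deterministic discrete-time virtual patient for the two training cases.

The simulator stands in for the training mannequin: vitals deteriorate under
delayed or missing treatment and respond to interventions.  The dynamics are
intentionally simple and fully declared in the scenario YAML files:

* blood volume (as a fraction of normal) falls at the sum of the uncontrolled
  bleed-source rates and rises at the transfusion rate;
* heart rate, systolic blood pressure and respiratory rate are memoryless
  piecewise-linear functions of the volume fraction;
* SpO2 declines while tension physiology is undecompressed or the airway is
  unsecured, and recovers otherwise;
* GCS degrades while systolic pressure is below the cerebral-perfusion
  threshold;
* death occurs when systolic pressure or the volume fraction crosses its
  declared floor, after which the state is frozen.

:func:`step` is a pure function of (state, profile, interventions, dt), so
whole-session traces are reproducible bit-exactly.  The numeric parameters
are synthetic fixture content constrained by the case definitions (initial
class-III shock; severe TBI in case B; untreated death within a plausible
10-20 min), not clinical measurements.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .decisions import VitalSigns
from .errors import InapplicableInterventionError, ScenarioError

CONTENT_DIR = Path(__file__).parent / "content"

INTERVENTION_KINDS = (
    "pressure_dressing",
    "chest_decompression",
    "chest_tube",
    "pelvic_binder",
    "airway_secured",
    "oxygen",
    "txa",
    "transfusion",
    "surgery_transfer",
)

# kinds whose effect is tied to one bleed source
_TARGETED_KINDS = ("pressure_dressing",)


@dataclass(frozen=True)
class Intervention:
    kind: str
    applied_at: int  # seconds since session start
    target: str | None = None

    def __post_init__(self):
        if self.kind not in INTERVENTION_KINDS:
            raise ScenarioError(f"unknown intervention kind {self.kind!r}")
        if self.applied_at < 0:
            raise ScenarioError("applied_at must be within the session")


@dataclass(frozen=True)
class Bleed:
    source: str
    rate_per_min: float  # volume fraction lost per minute
    controllable_by: tuple
    attenuators: tuple = ()  # ((kind, factor), ...)


@dataclass(frozen=True)
class InjuryProfile:
    scenario_id: str
    bleeds: tuple
    thoracic_injury: dict | None
    neuro_injury: dict | None
    region_ais: dict
    injury_time_offset_min: float
    pelvis_unstable: bool
    free_abdominal_fluid: bool
    applicable_interventions: tuple
    dynamics: dict
    applied: tuple = ()  # Interventions, in application order


@dataclass(frozen=True)
class PatientState:
    t: int
    heart_rate: float
    systolic_bp: float
    spo2: float
    resp_rate: float
    gcs: float
    blood_volume_fraction: float
    airway_patent: bool
    tension_physiology: bool
    alive: bool
    low_perfusion_s: int = 0  # accumulator driving GCS decline

    def __post_init__(self):
        if not (0 <= self.heart_rate <= 220 and 0 <= self.systolic_bp <= 250):
            raise ScenarioError("vitals outside physiological bounds")
        if not (0 <= self.spo2 <= 100 and 0 <= self.resp_rate <= 60):
            raise ScenarioError("vitals outside physiological bounds")
        if not (3 <= self.gcs <= 15 and 0 <= self.blood_volume_fraction <= 1):
            raise ScenarioError("vitals outside physiological bounds")


def _load_scenario_spec(scenario_id: str, content_dir: Path | None = None) -> dict:
    content_dir = content_dir or CONTENT_DIR
    path = content_dir / "scenarios" / f"case_{scenario_id.lower()}.yaml"
    if not path.exists():
        raise ScenarioError(f"unknown scenario {scenario_id!r}")
    with open(path) as fh:
        return yaml.safe_load(fh)


def make_scenario(
    scenario_id: str, content_dir: Path | None = None
) -> tuple[PatientState, InjuryProfile]:
    """Build the initial patient state and injury profile for case A or B."""
    spec = _load_scenario_spec(scenario_id, content_dir)
    init = spec["initial"]
    state = PatientState(
        t=0,
        heart_rate=float(init["heart_rate"]),
        systolic_bp=float(init["systolic_bp"]),
        spo2=float(init["spo2"]),
        resp_rate=float(init["resp_rate"]),
        gcs=float(init["gcs"]),
        blood_volume_fraction=float(init["blood_volume_fraction"]),
        airway_patent=bool(init["airway_patent"]),
        tension_physiology=bool(init["tension_physiology"]),
        alive=True,
    )
    bleeds = tuple(
        Bleed(
            source=b["source"],
            rate_per_min=float(b["rate_per_min"]),
            controllable_by=tuple(b.get("controllable_by", ())),
            attenuators=tuple(sorted((b.get("attenuators") or {}).items())),
        )
        for b in spec["bleeds"]
    )
    profile = InjuryProfile(
        scenario_id=spec["scenario_id"],
        bleeds=bleeds,
        thoracic_injury=spec.get("thoracic_injury"),
        neuro_injury=spec.get("neuro_injury"),
        region_ais=dict(spec.get("region_ais") or {}),
        injury_time_offset_min=float(spec["injury_time_offset_min"]),
        pelvis_unstable=bool(spec["pelvis_unstable"]),
        free_abdominal_fluid=bool(spec["free_abdominal_fluid"]),
        applicable_interventions=tuple(spec["applicable_interventions"]),
        dynamics=dict(spec["dynamics"]),
    )
    return state, profile


# ---------------------------------------------------------------------------
# Dynamics


def _has(interventions, kind: str, target: str | None = None) -> bool:
    return any(
        iv.kind == kind and (target is None or iv.target == target)
        for iv in interventions
    )


def _txa_active(profile: InjuryProfile, interventions) -> bool:
    for iv in interventions:
        if iv.kind == "txa":
            minutes = profile.injury_time_offset_min + iv.applied_at / 60.0
            if minutes < profile.dynamics["txa_window_min"]:
                return True
    return False


def effective_bleed_rates(profile: InjuryProfile, interventions) -> dict:
    """Per-source loss rate (fraction/min) under the given interventions."""
    txa = _txa_active(profile, interventions)
    rates = {}
    for bleed in profile.bleeds:
        controlled = any(
            iv.kind in bleed.controllable_by
            and (iv.kind not in _TARGETED_KINDS or iv.target == bleed.source)
            for iv in interventions
        )
        if controlled:
            rates[bleed.source] = 0.0
            continue
        rate = bleed.rate_per_min
        for kind, factor in bleed.attenuators:
            if _has(interventions, kind):
                rate *= factor
        if txa:
            rate *= profile.dynamics["txa_bleed_factor"]
        rates[bleed.source] = rate
    return rates


def _interp(mapping, x: float) -> float:
    pts = sorted(mapping)
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return float(np.interp(x, xs, ys))


def step(
    state: PatientState,
    profile: InjuryProfile,
    interventions,
    dt: int = 1,
) -> PatientState:
    """Advance the patient by ``dt`` seconds under the active interventions.

    Pure function; raises on nonpositive ``dt`` or a dead patient.
    Interventions are active from their ``applied_at`` second onward (the
    list normally comes from ``profile.applied``).
    """
    if dt <= 0:
        raise ScenarioError("dt must be positive")
    if not state.alive:
        raise ScenarioError("cannot step a dead patient")
    dyn = profile.dynamics
    active = [iv for iv in interventions if iv.applied_at <= state.t]

    loss = sum(effective_bleed_rates(profile, active).values())
    gain = dyn["transfusion_rate_per_min"] if _has(active, "transfusion") else 0.0
    volume = min(1.0, max(0.0, state.blood_volume_fraction + (gain - loss) * dt / 60.0))

    hr = min(220.0, max(0.0, _interp(dyn["hr_map"], volume)))
    sbp = min(250.0, max(0.0, _interp(dyn["sbp_map"], volume)))
    rr = min(60.0, max(0.0, _interp(dyn["rr_map"], volume)))

    tension_unrelieved = state.tension_physiology and not (
        _has(active, "chest_decompression") or _has(active, "chest_tube")
    )
    airway_compromised = not state.airway_patent and not _has(active, "airway_secured")
    if tension_unrelieved or airway_compromised:
        spo2 = max(dyn["spo2_floor"], state.spo2 - dyn["spo2_decline_per_s"] * dt)
    else:
        recovery = dyn["spo2_recovery_per_s"] * (2.0 if _has(active, "oxygen") else 1.0)
        spo2 = min(dyn["spo2_ceiling"], state.spo2 + recovery * dt)

    gcs = state.gcs
    low_s = state.low_perfusion_s
    if sbp < dyn["gcs_decline_sbp_threshold"]:
        low_s += dt
        gcs = max(3.0, gcs - dyn["gcs_decline_per_30s"] / 30.0 * dt)

    alive = not (sbp < dyn["death_sbp"] or volume < dyn["death_volume_fraction"])
    return replace(
        state,
        t=state.t + int(dt),
        heart_rate=hr,
        systolic_bp=sbp,
        spo2=spo2,
        resp_rate=rr,
        gcs=gcs,
        blood_volume_fraction=volume,
        airway_patent=state.airway_patent,
        tension_physiology=state.tension_physiology,
        alive=alive,
        low_perfusion_s=low_s,
    )


def apply_intervention(
    profile: InjuryProfile, state: PatientState, intervention: Intervention
) -> tuple[InjuryProfile, PatientState]:
    """Record an intervention and apply its instantaneous effects.

    Idempotent per (kind, target): re-applying is a no-op.  An intervention
    kind that is not applicable to the scenario raises
    :class:`InapplicableInterventionError` (callers log it as a treatment
    error and leave the state unchanged).
    """
    if intervention.kind not in profile.applicable_interventions:
        raise InapplicableInterventionError(
            f"{intervention.kind!r} is not applicable in scenario {profile.scenario_id}"
        )
    if intervention.kind in _TARGETED_KINDS:
        sources = {b.source for b in profile.bleeds}
        if intervention.target not in sources:
            raise InapplicableInterventionError(
                f"{intervention.kind!r} needs a bleed-source target, got {intervention.target!r}"
            )
    if any(
        iv.kind == intervention.kind and iv.target == intervention.target
        for iv in profile.applied
    ):
        return profile, state

    new_state = state
    if intervention.kind in ("chest_decompression", "chest_tube"):
        new_state = replace(state, tension_physiology=False)
    elif intervention.kind == "airway_secured":
        new_state = replace(state, airway_patent=True)
    new_profile = replace(profile, applied=profile.applied + (intervention,))
    return new_profile, new_state


_MENTAL_BANDS = (
    (15, "alert"),
    (13, "anxious"),
    (9, "confused"),
    (6, "lethargic"),
    (3, "unresponsive"),
)


def mental_status_from_gcs(gcs: float) -> str:
    g = int(gcs)
    for floor, label in _MENTAL_BANDS:
        if g >= floor:
            return label
    return "unresponsive"


def vitals(state: PatientState) -> VitalSigns:
    """Project the patient state onto the vitals the decision logic consumes."""
    return VitalSigns(
        heart_rate=state.heart_rate,
        systolic_bp=state.systolic_bp,
        resp_rate=state.resp_rate,
        spo2=state.spo2,
        mental_status=mental_status_from_gcs(state.gcs),
    )


def trace_to_csv(states) -> str:
    """Simulation trace export: one row per state."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["t", "heart_rate", "systolic_bp", "spo2", "resp_rate", "gcs",
                     "blood_volume_fraction", "alive"])
    for s in states:
        writer.writerow([
            s.t, f"{s.heart_rate:.2f}", f"{s.systolic_bp:.2f}", f"{s.spo2:.2f}",
            f"{s.resp_rate:.2f}", f"{s.gcs:.2f}", f"{s.blood_volume_fraction:.5f}",
            int(s.alive),
        ])
    return buf.getvalue()
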