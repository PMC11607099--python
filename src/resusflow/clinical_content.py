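"""Bundled executable treatment content and its cross-validated registry.

The content directory ships three workflow models (the cABCDE main process
plus the circulatory-shock and resuscitation subprocesses), the decision
tables they reference, the ordered stage metadata, the 12-item
essential-step rubric, and the two training scenarios.  ``load_content``
parses and cross-validates all of it; any unresolved reference or structural
defect aborts with the offending file and issue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .decisions import GcsComponents, glasgow_coma_scale
from .errors import ContentError
from .model_io import Registry, load_decision_model, load_process_model, validate

CONTENT_DIR = Path(__file__).parent / "content"

MAIN_MODEL_ID = "cabcde_main"
SHOCK_MODEL_ID = "circulatory_shock"
RESUS_MODEL_ID = "resuscitation"

STAGE_ORDER = ("c", "A", "B", "C", "D", "E")

SCENARIO_IDS = ("A", "B")

RUBRIC_TOTAL_POINTS = 12
RUBRIC_GENERIC_COUNT = 9


@dataclass(frozen=True)
class StageDescriptor:
    stage_id: str
    name: str
    signal_id: str
    entry_task: str
    reevaluation_task: str


@dataclass(frozen=True)
class RubricItem:
    item_id: str
    description: str
    scope: str  # generic | scenario_specific
    applicable_scenarios: tuple
    predicate: dict
    points: int = 1


@dataclass
class ContentRegistry:
    registry: Registry
    stages: tuple = ()
    rubric: tuple = ()
    scenarios: dict = field(default_factory=dict)
    content_dir: Path = CONTENT_DIR

    @property
    def workflow_models(self):
        return self.registry.workflow_models

    @property
    def decision_models(self):
        return self.registry.decision_models


def gcs_total_service(variables: dict) -> dict:
    """Service handler wired to the disability stage: total GCS from the
    documented components."""
    components = GcsComponents(
        eye=int(variables["gcs_eye"]),
        verbal=int(variables["gcs_verbal"]),
        motor=int(variables["gcs_motor"]),
    )
    return {"gcs": glasgow_coma_scale(components)}


SERVICES = {"gcs_total": gcs_total_service}


def load_content(content_dir: Path | None = None) -> ContentRegistry:
    """Parse and cross-validate the bundled content from a clean checkout."""
    content_dir = Path(content_dir or CONTENT_DIR)
    registry = Registry(services=dict(SERVICES))

    for path in sorted((content_dir / "decisions").glob("*.dmn.xml")):
        try:
            model = load_decision_model(path)
        except Exception as exc:
            raise ContentError(f"{path.name}: {exc}") from exc
        registry.decision_models[model.decision_id] = model

    for path in sorted((content_dir / "workflows").glob("*.bpmn.xml")):
        try:
            model = load_process_model(path)
        except Exception as exc:
            raise ContentError(f"{path.name}: {exc}") from exc
        registry.workflow_models[model.model_id] = model

    for model_id, model in registry.workflow_models.items():
        issues = validate(model, registry)
        if issues:
            raise ContentError(
                f"workflow {model_id!r}: " + "; ".join(str(i) for i in issues)
            )

    expected = {MAIN_MODEL_ID, SHOCK_MODEL_ID, RESUS_MODEL_ID}
    if set(registry.workflow_models) != expected:
        raise ContentError(
            f"expected workflow models {sorted(expected)}, found "
            f"{sorted(registry.workflow_models)}"
        )

    with open(content_dir / "stages.yaml") as fh:
        stage_spec = yaml.safe_load(fh)["stages"]
    stages = tuple(
        StageDescriptor(
            stage_id=s["id"],
            name=s["name"],
            signal_id=s["signal"],
            entry_task=s["entry_task"],
            reevaluation_task=s["reevaluation_task"],
        )
        for s in stage_spec
    )
    if tuple(s.stage_id for s in stages) != STAGE_ORDER:
        raise ContentError(f"stage order must be {STAGE_ORDER}")
    main = registry.workflow_models[MAIN_MODEL_ID]
    for stage in stages:
        if stage.signal_id not in main.signals:
            raise ContentError(f"stage {stage.stage_id}: signal {stage.signal_id!r} undeclared")
        for task in (stage.entry_task, stage.reevaluation_task):
            try:
                node = main.node(task)
            except KeyError:
                raise ContentError(f"stage {stage.stage_id}: task {task!r} not in main model")
            if node.kind != "user_task":
                raise ContentError(f"stage {stage.stage_id}: {task!r} is not a user task")

    with open(content_dir / "rubric.yaml") as fh:
        rubric_spec = yaml.safe_load(fh)["items"]
    rubric = tuple(
        RubricItem(
            item_id=item["item_id"],
            description=item["description"],
            scope=item["scope"],
            applicable_scenarios=tuple(item.get("applicable_scenarios", SCENARIO_IDS)),
            predicate=item["predicate"],
        )
        for item in rubric_spec
    )
    generic = [i for i in rubric if i.scope == "generic"]
    if len(generic) != RUBRIC_GENERIC_COUNT:
        raise ContentError(f"rubric must have {RUBRIC_GENERIC_COUNT} generic items")

    scenarios = {}
    for path in sorted((content_dir / "scenarios").glob("*.yaml")):
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        scenarios[spec["scenario_id"]] = spec
    if set(scenarios) != set(SCENARIO_IDS):
        raise ContentError(f"expected scenarios {SCENARIO_IDS}, found {sorted(scenarios)}")

    content = ContentRegistry(
        registry=registry,
        stages=stages,
        rubric=rubric,
        scenarios=scenarios,
        content_dir=content_dir,
    )
    for scenario_id in SCENARIO_IDS:
        if len(rubric_for(content, scenario_id)) != RUBRIC_TOTAL_POINTS:
            raise ContentError(f"scenario {scenario_id}: rubric must total 12 items")
    return content


def stage_sequence(content: ContentRegistry) -> tuple:
    """The six primary-survey stage descriptors in fixed c,A,B,C,D,E order."""
    return content.stages


def rubric_for(content: ContentRegistry, scenario_id: str) -> list:
    """The 12 rubric items scoring one scenario: 9 generic + 3 specific."""
    if scenario_id not in SCENARIO_IDS:
        raise ContentError(f"unknown scenario {scenario_id!r}")
    return [i for i in content.rubric if scenario_id in i.applicable_scenarios]
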