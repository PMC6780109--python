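"""Project configuration for the step-wise workflow.

A single YAML document drives all steps: sample roles (training /
optimisation / full), picker grids, classifier settings, score weights,
integration and annotation settings, one global seed, and the worker count.
Training and optimisation samples must be disjoint (warned otherwise): the
classifier should never score the samples it was calibrated on.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .annotation import AnnotationConfig
from .integration import IntegrationConfig
from .optimization import DEFAULT_WEIGHTS, ScoreWeights
from .peak_detection import PickerParams, expand_grid

__all__ = ["ProjectConfig", "load_config"]

_DEFAULT_GRIDS = {
    "matched_filter": {"fwhm": [1.5, 2.35, 4.0], "snthresh": [2.0, 5.0, 10.0],
                       "step": [0.5, 1.0, 2.0]},
    "cwt": {"peakwidth_max": [4.0, 6.0, 9.0], "snthresh": [2.0, 5.0, 10.0],
            "prefilter_i": [50.0, 500.0, 5000.0]},
}

#: fixed parameters appended to every grid point of a picker
_GRID_CONSTANTS = {"cwt": {"peakwidth_min": 1.0, "prefilter_k": 3}}


@dataclass
class ProjectConfig:
    project_dir: Path
    seed: int = 1
    scan_hz: float = 5.0
    rt_range: tuple[float, float] = (60.0, 1560.0)
    pickers: list[str] = field(default_factory=lambda: ["matched_filter", "cwt"])
    grids: dict[str, dict[str, list[float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_GRIDS.items()})
    simulate: dict[str, Any] = field(default_factory=dict)
    classifier: dict[str, Any] = field(default_factory=dict)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    groups: dict[str, str] = field(default_factory=dict)
    n_workers: int = 1
    raw: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.project_dir = Path(self.project_dir)
        train = set(self.samples("training"))
        opt = set(self.samples("optimization"))
        if train & opt:
            warnings.warn(
                f"training and optimisation samples overlap: {sorted(train & opt)}",
                stacklevel=2)

    # -- sample roles ------------------------------------------------------
    def samples(self, role: str) -> list[str]:
        roles = self.simulate.get("samples", {})
        defaults = {"training": ["qc_train"],
                    "optimization": ["qc_opt1", "qc_opt2"],
                    "full": ["s01", "s02", "s03", "s04"]}
        return list(roles.get(role, defaults[role]))

    # -- grids -------------------------------------------------------------
    def grid_for(self, picker: str) -> list[PickerParams]:
        axes = self.grids.get(picker)
        if not axes:
            raise KeyError(f"no grid configured for picker {picker!r}")
        params = expand_grid(picker, {k: list(v) for k, v in axes.items()})
        for p in params:
            for name, value in _GRID_CONSTANTS.get(picker, {}).items():
                p.values.setdefault(name, value)
        return params

    # -- misc --------------------------------------------------------------
    def step_seed(self, step: str) -> int:
        """Per-step seed derived from the global seed by counter hashing."""
        digest = hashlib.sha256(f"{self.seed}:{step}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path, seed: int | None = None) -> ProjectConfig:
    path = Path(path)
    data = yaml.safe_load(path.read_text()) or {}
    project_dir = Path(data.get("project_dir", path.parent / "project"))
    if not project_dir.is_absolute():
        project_dir = path.parent / project_dir
    weights = ScoreWeights({**DEFAULT_WEIGHTS, **data.get("weights", {})})
    cfg = ProjectConfig(
        project_dir=project_dir,
        seed=int(seed if seed is not None else data.get("seed", 1)),
        scan_hz=float(data.get("scan_hz", 5.0)),
        rt_range=tuple(data.get("rt_range", (60.0, 1560.0))),
        pickers=list(data.get("pickers", ["matched_filter", "cwt"])),
        grids={**{k: dict(v) for k, v in _DEFAULT_GRIDS.items()},
               **data.get("grids", {})},
        simulate=data.get("simulate", {}),
        classifier=data.get("classifier", {}),
        weights=weights,
        integration=IntegrationConfig(**data.get("integration", {})),
        annotation=AnnotationConfig(**data.get("annotation", {})),
        groups=data.get("groups", {}),
        n_workers=int(data.get("n_workers", 1)),
        raw=data,
    )
    return cfg
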