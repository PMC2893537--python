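"""Run configuration: one structured YAML file drives the whole pipeline.

Every published constant of the method (Canny thresholds 0.8 / 0.5, fill
gray 35, 0.6 gamma, 20–90 px radius search at 0.2 px, 90% onset and 75%
plateau levels, 30 fps, 25 flashes at 1 Hz) appears as a named default, so
an empty config reproduces the published setup.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detect import DetectConfig
from .synthetic import (EyeSceneSpec, FlashProtocol, PLRModel,
                        flash_train_protocol, healthy_train_model,
                        single_flash_protocol)
from .trace import ExtractionConfig


def _from_dict(cls, data: dict | None, what: str):
    if not data:
        return cls()
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        coerced[k] = v
    return cls(**coerced)


def build_protocol(data: dict | None) -> FlashProtocol:
    """Protocol from config: named kind plus optional overrides."""
    data = dict(data or {})
    kind = data.pop("kind", "single")
    if "flash_times_s" in data:
        return FlashProtocol(tuple(data.pop("flash_times_s")),
                             data.pop("recording_duration_s"),
                             fps=data.pop("fps", 30.0))
    if kind == "single":
        return single_flash_protocol(**data)
    if kind == "train25":
        return flash_train_protocol(**data)
    raise ValueError(f"unknown protocol kind {kind!r}")


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    scene: EyeSceneSpec = field(default_factory=EyeSceneSpec)
    model: PLRModel = field(default_factory=PLRModel)
    protocol: FlashProtocol = field(default_factory=single_flash_protocol)
    detect: DetectConfig = field(default_factory=DetectConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    frames_dir: str | None = None
    trace_csv: str | None = None
    cohort_csv: str | None = None
    roi: tuple[int, int, int, int] | None = None
    blink_intervals: tuple[tuple[int, int], ...] = ()
    seed: int = 0
    alpha: float = 0.05
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "scene": dataclasses.asdict(self.scene),
            "model": dataclasses.asdict(self.model),
            "protocol": dataclasses.asdict(self.protocol),
            "detect": dataclasses.asdict(self.detect),
            "extraction": dataclasses.asdict(self.extraction),
            "frames_dir": self.frames_dir,
            "trace_csv": self.trace_csv,
            "cohort_csv": self.cohort_csv,
            "roi": self.roi,
            "blink_intervals": [list(iv) for iv in self.blink_intervals],
            "seed": self.seed,
            "alpha": self.alpha,
            "log_level": self.log_level,
        }


def load_config(path: str | Path | None) -> RunConfig:
    """Parse the YAML run configuration (missing file sections = defaults)."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    protocol = build_protocol(data.get("protocol"))
    model_data = dict(data.get("model") or {})
    if model_data.pop("preset", None) == "train":
        base = dataclasses.asdict(healthy_train_model())
        base.update(model_data)
        model_data = base
    cfg = RunConfig(
        scene=_from_dict(EyeSceneSpec, data.get("scene"), "scene"),
        model=_from_dict(PLRModel, model_data, "model"),
        protocol=protocol,
        detect=_from_dict(DetectConfig, data.get("detect"), "detect"),
        extraction=_from_dict(ExtractionConfig, data.get("extraction"),
                              "extraction"),
        frames_dir=data.get("frames_dir"),
        trace_csv=data.get("trace_csv"),
        cohort_csv=data.get("cohort_csv"),
        roi=tuple(data["roi"]) if data.get("roi") else None,
        blink_intervals=tuple(tuple(iv) for iv
                              in data.get("blink_intervals", [])),
        seed=int(data.get("seed", 0)),
        alpha=float(data.get("alpha", 0.05)),
        log_level=str(data.get("log_level", "INFO")),
    )
    return cfg
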