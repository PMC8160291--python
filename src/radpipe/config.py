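"""Run configuration: every tunable of every stage, YAML round-trippable."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline invocation.

    Defaults mirror the documented per-stage defaults; the full config is
    frozen inside each run directory for auditability.
    """

    # stage toggles
    simulate: bool = True
    segment: bool = True
    extract: bool = True
    select: bool = True
    evaluate: bool = True

    # cohort simulation
    n_patients: int = 128
    seed: int = 0

    # paths (used when simulate is off, or for outputs)
    input_dir: str | None = None
    output_dir: str = "runs"

    # feature extraction
    n_bins: int = 32
    glcm_distance: int = 1
    texture_mode: str = "3d"

    # segmentation
    fcm_fuzziness: float = 2.0
    fcm_tol: float = 1.0e-5
    fcm_max_iter: int = 200

    # SVM / selection
    C: float = 1.0
    k_folds: int = 10
    n_repeats: int = 50
    max_features: int = 4
    min_improvement: float = 1.0e-6
    objective: str = "auc"       # selection CV metric: "auc" or "accuracy"
    scoring: str = "cv"          # "cv" (out-of-fold) or "refit"

    # evaluation
    gate_p: float = 0.05

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def schema(cls) -> str:
        """Printable field/default listing for the CLI."""
        lines = []
        for f in dataclasses.fields(cls):
            lines.append(f"{f.name}: {f.default!r}")
        return "\n".join(lines)
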