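"""Pipeline configuration: YAML parsing, validation, defaults, fan-out seeds."""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .counts_io import QCThresholds


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Fully-resolved pipeline settings.

    ``counts`` may be None, in which case the pipeline simulates the
    default four-stage preset instead of reading data.  A single global
    ``seed`` is fanned out to per-stage sub-seeds by fixed derivation.
    """

    counts: str | None = None
    counts_format: str = "mtx_triplet"
    knowledge_matrix: str | None = None
    modules: str | None = None
    ortholog_map: str | None = None
    bulk_timecourse: str | None = None
    outdir: str = "sctube_out"
    seed: int = 0
    n_cells_per_stage: int = 800
    qc: QCThresholds | None = None  # None: data defaults, or relaxed sim defaults
    n_bins: int = 24
    n_ctrl: int = 100
    binarize_method: str = "otsu"
    max_mismatch: int = 0
    min_score: float = 0.0
    min_cells: int = 10
    mito_prefix: str = "MT-"
    skip: list[str] = field(default_factory=list)

    _STAGES = ("simulate", "qc", "score", "classify", "compare", "dynamics", "dp")

    def __post_init__(self) -> None:
        unknown = set(self.skip) - set(self._STAGES)
        if unknown:
            raise ConfigError(f"skip names unknown stages: {sorted(unknown)}")

    def resolved_qc(self) -> QCThresholds:
        """QC thresholds: user-set, else the data defaults, else thresholds
        suited to the synthetic preset's shallower libraries."""
        if self.qc is not None:
            return self.qc
        if self.counts is not None:
            return QCThresholds()
        return QCThresholds(min_genes=50, max_genes=None, max_mito_frac=0.15)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed derived from the global seed."""
        idx = self._STAGES.index(stage)
        return int(np.random.SeedSequence(self.seed).generate_state(len(self._STAGES))[idx])

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


_PATH_KEYS = ("counts", "knowledge_matrix", "modules", "ortholog_map", "bulk_timecourse")


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config file into a :class:`PipelineConfig`.

    Unknown keys warn (they are ignored); referenced input paths must
    exist; defaults fill every unset field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in raw.items() if k in known}
    if "qc" in kwargs and isinstance(kwargs["qc"], dict):
        kwargs["qc"] = QCThresholds(**kwargs["qc"])
    cfg = PipelineConfig(**kwargs)
    for key in _PATH_KEYS:
        value = getattr(cfg, key)
        if value is not None and not Path(value).exists():
            raise ConfigError(f"config key {key!r} points at a missing path: {value}")
    return cfg
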