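"""Pipeline configuration.

Configs live in plain-text ``key = value`` files (one per line, ``#``
comments allowed) so a run is fully described by one human-diffable
file; CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    # input tables
    positive_pairs: str = ""        # TSV pair list(s), ';'-separated for multiple sources
    known_pairs: str = ""           # known-PPI exclusion list (defaults to positives)
    go_annotations: str = ""        # protein<TAB>term[<TAB>name] TSV
    kegg_annotations: str = ""
    localization: str = ""
    expression: str = ""
    candidate_pairs: str = ""       # optional pre-built candidate list
    truth_pairs: str = ""           # optional planted-interaction list for recovery scoring
    out_dir: str = "autoppi_run"

    # protocol
    train_fraction: float = 0.7
    cv_folds: int = 10
    n_bins: int = 5
    error_ceiling: float = 0.15
    nb_alpha: float = 1.0
    dt_max_depth: int = 6
    dt_min_leaf: int = 5
    knn_k: int = 5
    n_candidates: int = 300
    process_keyword: str = "autophagy"
    threshold_rule: str = "f1"

    # network
    node_score_cutoff: float = 0.2
    k_core: int = 2
    top_modules: int = 4

    random_seed: int = 0

    def validate(self) -> "PipelineConfig":
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        for name in ("error_ceiling", "node_score_cutoff"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.k_core < 1:
            raise ValueError(f"k_core must be >= 1, got {self.k_core}")
        return self


_FIELD_TYPES = {f.name: f.type for f in fields(PipelineConfig)}


def _coerce(name: str, raw: str):
    target = _FIELD_TYPES[name]
    if target == "int":
        return int(raw)
    if target == "float":
        return float(raw)
    return raw


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Parse a key = value config file; ``overrides`` win over file values."""
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in _FIELD_TYPES:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = _coerce(key, raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values).validate()


def save_config(config: PipelineConfig, path: str | Path) -> None:
    lines = [f"{f.name} = {getattr(config, f.name)}" for f in fields(PipelineConfig)]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")
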