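"""Run configuration: every tunable of the pipeline, YAML round-trippable."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Fully resolved configuration of a pipeline run.

    Defaults follow the method's stated conventions: alpha = 0.9,
    subsample fraction 0.75 (25% of samples held out per run), N = 2n
    resamples (``n_resamples=None``),
    lambda = 3 with budgets in {2..6}, 200 k-SVD iterations at tol 1e-4.
    """

    # dictionary learning
    n_atoms: int = 50
    lambda_exp: float = 3.0
    t_min: int = 2
    t_max: int = 6
    max_iter: int = 200
    tol: float = 1e-4
    center: bool = True
    # inference
    alpha: float = 0.9
    method: str = "pearson"
    subsample_fraction: float = 0.75
    n_resamples: int | None = None
    # simulation (used by the simulate stage only)
    n_samples: int = 20
    p_genes: int = 1500
    k_regulators: int = 50
    snr: float = 10.0
    degree_min: int = 2
    degree_max: int = 6
    # bookkeeping
    seed: int = 0
    expression: str | None = None
    regulators: str | None = None
    gold: str | None = None
    outdir: str = "dlgrn_run"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)
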