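"""Flat JSON run configuration shared by the CLI subcommands."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .interactions import InteractionSpec
from .topology import BlockSpec, modularity_bounds

log = logging.getLogger("blockstab")

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Every knob of a simulation run, serializable to a flat JSON document.

    Defaults follow the full-scale study conditions: 50 replicates per arm
    and a 20-point modularity grid.
    """

    S: int
    alpha: float
    C: float
    mu: float
    Q: float = 0.0
    sigma2: float = 1.0
    rho: float = 0.0
    xi: float = 0.0
    theta: float = 0.0
    n_reps: int = 50
    n_steps: int = 20
    seed: int = 0
    mode: str = "random"
    out: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("random", "cascade"):
            raise ValueError("mode must be 'random' or 'cascade'")
        q_min, q_max = modularity_bounds(self.alpha, self.C)
        if not q_min - 1e-12 <= self.Q <= q_max + 1e-12:
            raise ValueError(
                f"Q={self.Q} outside modularity_bounds(alpha={self.alpha}, "
                f"C={self.C}) = ({q_min:.6g}, {q_max:.6g})"
            )

    def block_spec(self) -> BlockSpec:
        spec = BlockSpec(S=self.S, alpha=self.alpha, C=self.C, Q=self.Q)
        log.info(
            "resolved connectances: C_w=%.6g C_b=%.6g", spec.C_w, spec.C_b
        )
        return spec

    def interaction_spec(self) -> InteractionSpec:
        return InteractionSpec(
            mu=self.mu, sigma2=self.sigma2, rho=self.rho, xi=self.xi, theta=self.theta
        )


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a flat JSON config; unknown keys are rejected."""
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError("config must be a flat JSON object")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**doc)
    except TypeError as exc:  # missing required field
        raise ValueError(f"invalid config: {exc}") from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(cfg), indent=2) + "\n")
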