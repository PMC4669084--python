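"""Run configuration: YAML round-trip, validation and the run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run depends on.

    Either a named simulation ``scenario`` or paths to measurement
    tables must be given.  All analysis thresholds default to the
    published values: +1 ‰ gas-phase fractionation correction, logit
    tolerance 0.1, relative-enrichment filter 0.001.
    """

    scenario: str | None = None
    vial_table: str | None = None
    plfa_table: str | None = None
    isolate_db: str | None = None
    gas_correction: float = 1.0
    logit_tolerance: float = 0.1
    enrichment_filter: float = 0.001
    pls_components: int = 2
    time_average: bool = True
    seed: int = 0
    outdir: str = "sipriming_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.scenario is None and self.vial_table is None:
            raise ValueError("config needs either a scenario or a vial_table path")
        for attr in ("vial_table", "plfa_table", "isolate_db"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        if self.logit_tolerance <= 0:
            raise ValueError("logit_tolerance must be positive")
        if not (0.0 <= self.enrichment_filter < 1.0):
            raise ValueError("enrichment_filter must be in [0, 1)")
        if self.pls_components < 1:
            raise ValueError("pls_components must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration (for the run manifest)."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def manifest(self, versions: dict[str, str]) -> dict:
        return {
            "config": asdict(self),
            "config_sha256": self.digest(),
            "seed": self.seed,
            "versions": versions,
        }
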