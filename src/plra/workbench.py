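"""Configuration, serialization, and reproducibility plumbing.

Configs and reports are JSON; tabular outputs are CSV.  Floats are
serialized at a fixed 10 significant digits so that identical config +
master seed reproduces byte-identical report files.  A single master seed
deterministically derives every stage's seed (see :func:`plra.core.derive_seeds`).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

from .core import derive_seeds  # re-exported for convenience
from .escalation import EscalationReport, RunConfig

__all__ = ["ConfigError", "load_config", "write_config", "write_report", "read_report", "derive_seeds"]


class ConfigError(ValueError):
    """Raised with the full list of validation violations, not just the first."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            "invalid run config:\n" + "\n".join(f"  - {v}" for v in violations)
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and fully validate a JSON run config."""
    with open(path) as fh:
        raw = json.load(fh)
    try:
        config = RunConfig.from_dict(raw)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError([f"structural error: {exc}"]) from exc
    violations = config.validate()
    if violations:
        raise ConfigError(violations)
    return config


def write_config(config: RunConfig, path: str | Path) -> None:
    # configs are written at full float precision so a stored config
    # reproduces its run exactly
    Path(path).write_text(json.dumps(config.to_dict(), indent=1))


def _round_floats(obj: Any) -> Any:
    """Normalize every float to 10 significant digits, recursively."""
    if isinstance(obj, float):
        return float(f"{obj:.10g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_report(report: EscalationReport, path: str | Path) -> Path:
    """Write an escalation report as JSON plus a per-tier CSV alongside.

    The CSV (same stem, ``.csv`` suffix) has one row per evaluated tier.
    Serialization is lossless at the fixed float precision:
    ``read_report(write_report(r))`` reproduces ``r``.
    """
    path = Path(path)
    payload = _round_floats(report.to_dict())
    path.write_text(json.dumps(payload, indent=1))
    rows = [
        {
            "tier": r["tier"],
            "raw_endpoint": r["raw_endpoint"],
            "control_endpoint": r["control_endpoint"],
            "scaled_effect": r["scaled_effect"],
            "decision": r["decision"],
            "conservatism": r["conservatism"],
        }
        for r in payload["results"]
    ]
    pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)
    return path


def read_report(path: str | Path) -> EscalationReport:
    with open(path) as fh:
        return EscalationReport.from_dict(json.load(fh))
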