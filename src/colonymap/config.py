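"""YAML configuration loading for the CLI.

A single structured file may carry a ``colony`` section (ColonyConfig
fields) and an ``expression`` section (ExpressionSimConfig fields); every
simulator default is overridable there.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .expression_sim import ExpressionSimConfig
from .simulate import ColonyConfig, ConfigError, MarkerPanelSpec


def _colony_from_dict(d: dict) -> ColonyConfig:
    d = dict(d)
    if "marker_panel_spec" in d and isinstance(d["marker_panel_spec"], dict):
        d["marker_panel_spec"] = MarkerPanelSpec(**d["marker_panel_spec"])
    if "genome" in d:
        d["genome"] = tuple(tuple(row) for row in d["genome"])
    if "panel_interval" in d:
        d["panel_interval"] = tuple(d["panel_interval"])
    try:
        return ColonyConfig(**d)
    except TypeError as exc:
        raise ConfigError(f"bad colony config: {exc}") from exc


def _expression_from_dict(d: dict) -> ExpressionSimConfig:
    d = dict(d)
    for key in ("control_genes", "reads_range"):
        if key in d:
            d[key] = tuple(d[key])
    if "cell_types" in d:
        d["cell_types"] = {t: tuple(v) for t, v in d["cell_types"].items()}
    try:
        return ExpressionSimConfig(**d)
    except TypeError as exc:
        raise ConfigError(f"bad expression config: {exc}") from exc


def load_config(
    path: str | Path | None,
    seed: int | None = None,
) -> tuple[ColonyConfig, ExpressionSimConfig]:
    """Load (colony, expression) configs; ``seed`` overrides both."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    colony = _colony_from_dict(data.get("colony", {}))
    expr = _expression_from_dict(data.get("expression", {}))
    if seed is not None:
        colony = _colony_from_dict({**colony.__dict__, "seed": seed})
        expr = _expression_from_dict({**expr.__dict__, "seed": seed})
    return colony, expr
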