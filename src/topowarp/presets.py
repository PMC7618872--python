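"""Named experiment presets: model configuration plus data conditions.

Each preset is a YAML file shipped with the package, with a ``model``
block (ModelConfig fields) and a ``data`` block (PhantomSpec fields
for the synthetic presets, or dataset geometry notes for the real-data
configurations, which require externally supplied images).
"""

from __future__ import annotations

from importlib import resources

import yaml

from .network import ModelConfig
from .phantoms import PhantomSpec

__all__ = ["available_presets", "load_preset"]


def available_presets() -> list[str]:
    pkg = resources.files("topowarp") / "presets"
    return sorted(p.name.removesuffix(".yaml") for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> dict:
    """Load a preset by name; returns dict with 'model' (ModelConfig)
    and, when the preset is synthetic, 'data' (PhantomSpec)."""
    pkg = resources.files("topowarp") / "presets" / f"{name}.yaml"
    if not pkg.is_file():
        raise KeyError(f"unknown preset {name!r}; available: {available_presets()}")
    raw = yaml.safe_load(pkg.read_text())
    out: dict = {"name": name}
    out["model"] = ModelConfig(**raw["model"])
    if "data" in raw and raw["data"].get("task"):
        data = dict(raw["data"])
        task = data.pop("task")
        out["data"] = PhantomSpec.for_task(task, **data)
    return out
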