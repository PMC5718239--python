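"""Run configuration: fully defaulted, optionally overridden from TOML.

An empty configuration reproduces the default study run (default phantom,
default material table, all presets, seed 0).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .materials import K_PE_DEFAULT, MaterialTable, default_materials, load_material_table
from .phantom import PhantomSpec, default_study_phantom
from .sweeps import PRESETS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    materials: MaterialTable = field(default_factory=default_materials)
    k_pe: float = K_PE_DEFAULT
    phantom: PhantomSpec = field(default_factory=default_study_phantom)
    presets: tuple[str, ...] = tuple(PRESETS)
    n_realizations: int = 5
    seed: int = 0
    out_dir: Path = Path("fidmark-report")
    verbosity: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path | None) -> "RunConfig":
        """Load overrides from a TOML file; a missing/empty file keeps defaults.

        Recognized sections: ``[materials.<name>]`` (see
        :func:`~fidmark.materials.load_material_table`), ``[physics]``
        (``k_pe``), ``[run]`` (``seed``, ``n_realizations``, ``presets``,
        ``out_dir``, ``verbosity``), and ``phantom = "spec.toml"`` at top
        level pointing at a phantom description.
        """
        cfg = cls()
        if path is None:
            return cfg
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "materials" in raw:
            cfg.materials = load_material_table(path)
        physics = raw.get("physics", {})
        cfg.k_pe = float(physics.get("k_pe", cfg.k_pe))
        if "phantom" in raw:
            cfg.phantom = PhantomSpec.from_toml((path.parent / raw["phantom"]))
        run = raw.get("run", {})
        cfg.seed = int(run.get("seed", cfg.seed))
        cfg.n_realizations = int(run.get("n_realizations", cfg.n_realizations))
        cfg.presets = tuple(run.get("presets", cfg.presets))
        cfg.out_dir = Path(run.get("out_dir", cfg.out_dir))
        cfg.verbosity = str(run.get("verbosity", cfg.verbosity))
        return cfg
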