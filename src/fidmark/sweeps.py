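"""Protocol sweeps, aggregation and reporting.

Runs the study's parameter grids (kVp, mAs, slice thickness, MU, scan mode)
over the default phantom, computes per-marker CNR on every simulated image,
aggregates per material over noise realizations, and writes CSV tables,
trend figures and a run manifest.

Reproducibility: the Poisson seed of realization ``r`` at axis-value index
``v`` is ``SeedSequence((base_seed, v, r)).generate_state(1)[0] % 2**31`` --
independent of execution order, so re-running any preset with the same base
seed reproduces every number exactly. One acquisition images all nine
markers at once (as in the physical study), so noise is shared across
materials within a realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ProtocolError
from .imaging import (
    ImagingProtocol,
    ct_mean_transmission,
    realize_projections,
    reconstruct_hu,
    simulate_planar,
)
from .materials import K_PE_DEFAULT, MaterialTable, default_materials
from .metrics import (
    artifact_index,
    compute_cnr,
    detect_marker_center,
    ring_artifact_profile,
    roi_stats,
)
from .phantom import PhantomSpec, default_study_phantom

__all__ = [
    "AnalysisParams",
    "SweepResult",
    "PRESETS",
    "run_sweep",
    "run_preset",
    "run_artifact_study",
    "visibility_report",
    "trend_summary",
    "write_report",
]

_AXES_BY_MODALITY = {
    "CT": {"kvp", "slice_thickness", "mas"},
    "CBCT": {"kvp", "mas"},
    "KV_PLANAR": {"kvp", "mas"},
    "MV_PLANAR": {"mu"},
    "MVCT": {"mode"},
}

MARKER_PLANE_Z_MM = 75.0  # central-layer plane of the default phantom


@dataclass(frozen=True)
class AnalysisParams:
    """Metric settings applied to every simulated image."""

    search_radius: float = 5.0
    roi_half_width: float = 75.0
    exclusion_radius: float = 7.5
    signal_radius: float = 2.5
    fov_mm: float = 32.0
    grid_n: int = 128


@dataclass
class SweepResult:
    """CNR samples of one parameter sweep.

    ``samples[material]`` is an (n_values, n_realizations) array of
    per-realization CNRs (each already averaged over that material's three
    markers); ``records`` holds the marker-level rows.
    """

    modality: str
    axis: str
    values: tuple
    fixed: dict[str, Any]
    materials: tuple[str, ...]
    samples: dict[str, np.ndarray]
    records: pd.DataFrame
    n_realizations: int
    base_seed: int
    name: str = ""

    def mean_cnr(self, material: str) -> np.ndarray:
        return self.samples[material].mean(axis=1)

    def sd_cnr(self, material: str) -> np.ndarray:
        if self.n_realizations < 2:
            return np.zeros(len(self.values))
        return self.samples[material].std(axis=1, ddof=1)

    def summary(self) -> pd.DataFrame:
        rows = []
        for mat in self.materials:
            for v, m, s in zip(self.values, self.mean_cnr(mat), self.sd_cnr(mat)):
                rows.append({"material": mat, self.axis: v, "mean_cnr": m, "sd_cnr": s,
                             "n_realizations": self.n_realizations})
        return pd.DataFrame(rows)


def _child_seed(base_seed: int, value_index: int, realization: int) -> int:
    ss = np.random.SeedSequence((int(base_seed), int(value_index), int(realization)))
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(
    phantom: PhantomSpec,
    modality: str,
    axis: str,
    values: Sequence,
    fixed_params: dict[str, Any] | None = None,
    n_realizations: int = 5,
    base_seed: int = 0,
    materials: MaterialTable | None = None,
    analysis: AnalysisParams = AnalysisParams(),
    k_pe: float = K_PE_DEFAULT,
    name: str = "",
) -> SweepResult:
    """Simulate every (axis value, realization), locate markers, compute CNR.

    Deterministic for fixed ``base_seed``; tomographic sweeps share the
    noise-free projection core across realizations.
    """
    if len(values) == 0:
        raise ProtocolError("sweep needs at least one axis value")
    if axis not in _AXES_BY_MODALITY.get(modality, set()):
        raise ProtocolError(f"axis {axis!r} is not sweepable for modality {modality!r}")
    table = materials or default_materials()
    fixed = dict(fixed_params or {})
    mat_names = tuple(sorted({m.material for m in phantom.markers}))
    all_centers = [(m.center[1], m.center[0]) for m in phantom.markers]

    rows = []
    samples = {mat: np.zeros((len(values), n_realizations)) for mat in mat_names}
    for vi, value in enumerate(values):
        params = fixed | {axis: value}
        core = None
        if modality in ("CT", "CBCT", "MVCT"):
            probe = ImagingProtocol(modality=modality, **params)
            core = ct_mean_transmission(phantom, probe, MARKER_PLANE_Z_MM, table, k_pe)
        for r in range(n_realizations):
            seed = _child_seed(base_seed, vi, r)
            protocol = ImagingProtocol(modality=modality, seed=seed, **params)
            per_marker = _analyze_realization(
                phantom, protocol, core, table, analysis, all_centers, k_pe
            )
            per_mat: dict[str, list[float]] = {mat: [] for mat in mat_names}
            for (mat, idx), cnr in per_marker.items():
                per_mat[mat].append(cnr)
                rows.append({"material": mat, "marker_index": idx, "axis": axis,
                             "value": value, "realization": r, "seed": seed, "cnr": cnr})
            for mat in mat_names:
                samples[mat][vi, r] = float(np.mean(per_mat[mat]))
    return SweepResult(
        modality=modality, axis=axis, values=tuple(values), fixed=fixed,
        materials=mat_names, samples=samples, records=pd.DataFrame(rows),
        n_realizations=n_realizations, base_seed=base_seed, name=name,
    )


def _analyze_realization(phantom, protocol, core, table, analysis, all_centers, k_pe):
    """CNR per (material, marker index) for one noise realization."""
    out = {}
    if core is not None:
        rng = np.random.default_rng(protocol.seed)
        p = realize_projections(core, protocol, rng)
        for mat in sorted({m.material for m in phantom.markers}):
            for idx, m in enumerate(phantom.markers_of(mat)):
                c = (m.center[1], m.center[0])
                img = reconstruct_hu(p, core, protocol, fov_center_mm=c,
                                     fov_mm=analysis.fov_mm, grid_n=analysis.grid_n)
                center = detect_marker_center(img, c, analysis.search_radius)
                st = roi_stats(img, center, analysis.roi_half_width,
                               analysis.exclusion_radius, analysis.signal_radius)
                out[(mat, idx)] = compute_cnr(st)
    else:
        img = simulate_planar(phantom, protocol, table, k_pe)
        for mat in sorted({m.material for m in phantom.markers}):
            for idx, m in enumerate(phantom.markers_of(mat)):
                c = (m.center[1], m.center[0])
                center = detect_marker_center(img, c, analysis.search_radius)
                neighbors = [p for p in all_centers
                             if (p[0] - c[0]) ** 2 + (p[1] - c[1]) ** 2 > 1.0]
                st = roi_stats(img, center, analysis.roi_half_width,
                               analysis.exclusion_radius, analysis.signal_radius,
                               exclude_centers=neighbors)
                out[(mat, idx)] = compute_cnr(st)
    return out


#: The study's parameter grids.
PRESETS: dict[str, dict[str, Any]] = {
    "ct-kvp": {"modality": "CT", "axis": "kvp", "values": (80, 100, 120, 140),
               "fixed": {"slice_thickness": 1.25, "mas": 200}},
    "ct-slice": {"modality": "CT", "axis": "slice_thickness",
                 "values": (0.625, 1.25, 2.5, 3.75, 5.0),
                 "fixed": {"kvp": 120, "mas": 200}},
    "obi-kvp": {"modality": "KV_PLANAR", "axis": "kvp",
                "values": (60, 70, 75, 80, 90, 100, 110, 120), "fixed": {"mas": 200}},
    "obi-mas": {"modality": "KV_PLANAR", "axis": "mas",
                "values": (50, 63, 80, 100, 125, 160, 200), "fixed": {"kvp": 80}},
    "cbct-kv": {"modality": "CBCT", "axis": "kvp", "values": (60, 90, 100, 125),
                "fixed": {"mas": 80, "slice_thickness": 2.5}},
    "mv": {"modality": "MV_PLANAR", "axis": "mu", "values": (1, 2), "fixed": {}},
    "mvct": {"modality": "MVCT", "axis": "mode", "values": ("normal", "fine"),
             "fixed": {}},
}


def run_preset(
    preset: str,
    phantom: PhantomSpec | None = None,
    n_realizations: int = 5,
    base_seed: int = 0,
    **kwargs,
) -> SweepResult:
    if preset not in PRESETS:
        raise ProtocolError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    return run_sweep(
        phantom or default_study_phantom(),
        cfg["modality"], cfg["axis"], cfg["values"], cfg["fixed"],
        n_realizations=n_realizations, base_seed=base_seed, name=preset, **kwargs,
    )


def run_artifact_study(
    phantom: PhantomSpec | None = None,
    kvp: float = 120.0,
    slice_thickness: float = 1.25,
    analysis: AnalysisParams = AnalysisParams(),
    materials: MaterialTable | None = None,
) -> dict[str, Any]:
    """Noise-free streak-artifact comparison: ring-SD profiles around one
    marker of each material on kV CT, plus gold under MVCT.

    Profiles are computed on the unclipped reconstruction (the 12-bit clip
    would flatten gold's bloomed core to SD 0 at small radii). Returns ring
    profiles, artifact indices, and the MVCT/kV-CT gold index ratio.
    """
    phantom = phantom or default_study_phantom()
    table = materials or default_materials()
    profiles: dict[str, Any] = {}
    indices: dict[str, float] = {}

    def _profile(protocol, marker):
        core = ct_mean_transmission(phantom, protocol, MARKER_PLANE_Z_MM, table)
        p = realize_projections(core, protocol)
        c = (marker.center[1], marker.center[0])
        img = reconstruct_hu(p, core, protocol, fov_center_mm=c,
                             fov_mm=analysis.fov_mm, grid_n=analysis.grid_n, clip=False)
        return ring_artifact_profile(img, c)

    ct = ImagingProtocol(modality="CT", kvp=kvp, slice_thickness=slice_thickness, noise=False)
    for mat in ("gold", "carbon", "polymer"):
        prof = _profile(ct, phantom.markers_of(mat)[1])
        profiles[mat] = prof
        indices[mat] = artifact_index(prof)
    mvct = ImagingProtocol(modality="MVCT", mode="fine", noise=False)
    prof_mv = _profile(mvct, phantom.markers_of("gold")[1])
    profiles["gold_mvct"] = prof_mv
    indices["gold_mvct"] = artifact_index(prof_mv)
    return {
        "profiles": profiles,
        "indices": indices,
        "mvct_to_kvct_gold_ratio": indices["gold_mvct"] / indices["gold"],
    }


def visibility_report(result: SweepResult, threshold: float = 4.0) -> pd.DataFrame:
    """Per-material visibility (Rose criterion: mean CNR >= threshold)."""
    if threshold <= 0:
        raise ProtocolError("visibility threshold must be positive")
    rows = []
    for mat in result.materials:
        means = result.mean_cnr(mat)
        for v, m in zip(result.values, means):
            rows.append({"material": mat, result.axis: v, "mean_cnr": m,
                         "visible": bool(m >= threshold)})
    return pd.DataFrame(rows)


def trend_summary(result: SweepResult) -> pd.DataFrame:
    """Least-squares slope sign and peak location of mean CNR per material.

    Ties at the maximum break toward the smaller parameter value.
    """
    if len(result.values) < 3:
        raise DataError("trend summary needs at least 3 grid values")
    try:
        x = np.asarray(result.values, dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError("trend summary requires a numeric axis") from exc
    rows = []
    for mat in result.materials:
        y = result.mean_cnr(mat)
        slope = float(np.polyfit(x, y, 1)[0])
        peak = result.values[int(np.argmax(y))]  # argmax returns first max: ties -> smaller
        rows.append({"material": mat, "slope": slope,
                     "slope_sign": int(np.sign(slope)), "peak_value": peak})
    return pd.DataFrame(rows)


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_report(
    results: Sequence[SweepResult],
    out_dir: str | Path,
    make_figures: bool = True,
) -> dict[str, Path]:
    """Write one CSV per sweep, one trend figure per sweep, and a manifest.

    Idempotent for fixed seeds: CSVs are byte-identical across reruns.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    manifest = ["# fidmark sweep report manifest", 'tool = "fidmark"']
    from . import __version__

    manifest.append(f'version = "{__version__}"')
    for i, res in enumerate(results):
        name = res.name or f"sweep{i}"
        csv_path = out / f"{name}_cnr.csv"
        res.records.to_csv(csv_path, index=False)
        written[f"{name}_csv"] = csv_path
        summary_path = out / f"{name}_summary.csv"
        res.summary().to_csv(summary_path, index=False)
        written[f"{name}_summary"] = summary_path
        manifest += [
            f"[sweeps.{name.replace('-', '_')}]",
            f"modality = {_toml_scalar(res.modality)}",
            f"axis = {_toml_scalar(res.axis)}",
            f"values = [{', '.join(_toml_scalar(v) for v in res.values)}]",
            f"n_realizations = {res.n_realizations}",
            f"base_seed = {res.base_seed}",
        ]
        if make_figures:
            written[f"{name}_figure"] = _trend_figure(res, out / f"{name}_cnr.png")
    (out / "manifest.toml").write_text("\n".join(manifest) + "\n")
    written["manifest"] = out / "manifest.toml"
    return written


def _trend_figure(result: SweepResult, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    numeric = all(isinstance(v, (int, float)) for v in result.values)
    x = np.asarray(result.values, dtype=float) if numeric else np.arange(len(result.values))
    markers = {"gold": "D", "carbon": "s", "polymer": "^"}
    for mat in result.materials:
        ax.errorbar(x, result.mean_cnr(mat), yerr=result.sd_cnr(mat),
                    marker=markers.get(mat, "o"), capsize=2, label=mat)
    if not numeric:
        ax.set_xticks(x, [str(v) for v in result.values])
    ax.set_xlabel(result.axis)
    ax.set_ylabel("CNR")
    ax.set_title(f"{result.modality}: CNR vs {result.axis}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
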