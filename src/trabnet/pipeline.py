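"""Pipeline orchestration: volumes to descriptor reports.

A :class:`RunConfig` captures every stage parameter (threshold band,
component-size floor, skeleton cleaning, ITA binning, subsampled-test
settings, Young's modulus) plus the input regions, and
:func:`run_pipeline` executes preprocess -> skeletonize -> descriptors ->
statistics -> mechanics for each region, followed by all pairwise region
comparisons.  Reports echo the configuration and every seed, so a rerun
of the same config reproduces all numbers exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import descriptors as desc
from . import mechanics, stats
from .graph import SpatialGraph, deduplicate, read_avizo_spatialgraph, read_graph
from .skeleton import skeleton_to_graph
from .synthetic import generate_network, spec_from_dict
from .volume import (DEFAULT_BAND, DEFAULT_CONNECTIVITY, DEFAULT_MIN_SIZE,
                     extract_subvolume, preprocess, read_volume)

log = logging.getLogger("trabnet")

#: descriptor variables compared between regions
COMPARISON_VARIABLES = ("chord_length", "curved_length", "mean_radius",
                        "tortuosity", "node_radius", "slenderness",
                        "mean_ita", "theta", "phi")


@dataclass
class RegionInput:
    """One plate region: a volume file, a graph file, or a synthetic spec."""

    name: str
    kind: str  # "volume" | "graph" | "avizo" | "synthetic"
    path: str | None = None
    spec: dict | None = None
    subvolume: list | None = None  # [x, y, z, edge] µm

    def validate(self) -> None:
        if self.kind not in ("volume", "graph", "avizo", "synthetic"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.kind == "synthetic":
            if self.spec is None:
                self.spec = {}
        elif self.path is None:
            raise ValueError(f"region {self.name!r}: path required")


@dataclass
class RunConfig:
    regions: list[RegionInput] = field(default_factory=list)
    voxel_size: float = 3.0
    band: tuple[int, int] = DEFAULT_BAND
    min_size_vox: int = DEFAULT_MIN_SIZE
    connectivity: int = DEFAULT_CONNECTIVITY
    denoise: bool = True
    denoise_size_px: int = 3
    denoise_neighborhood: int = 26
    radius_correction: str = "midpoint"
    smooth_iterations: int = 2
    spur_length_vox: float = 2.0
    ita_bin_width: float = 5.0
    rose_bins: int = 36
    theta_bins: int = 18
    subsample_n: int = 300
    iterations: int = 10000
    seed: int = 17
    young_modulus: float = 1.0
    n_coeff: float = 4.0
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        regions = []
        for r in d.pop("regions", []):
            rknown = {f.name for f in dataclasses.fields(RegionInput)}
            runknown = set(r) - rknown
            if runknown:
                raise ValueError(f"unknown region keys: {sorted(runknown)}")
            regions.append(RegionInput(**r))
        cfg = cls(regions=regions, **d)
        if "band" in d:
            cfg.band = tuple(d["band"])
        for r in cfg.regions:
            r.validate()
        return cfg

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return d


def load_region_graph(region: RegionInput, config: RunConfig) -> SpatialGraph:
    """Produce the cleaned spatial graph for one region input."""
    if region.kind == "synthetic":
        spec = spec_from_dict(region.spec or {})
        if spec.seed is None:
            spec.seed = config.seed
        g, _ = generate_network(spec)
        return g
    if region.kind == "graph":
        return read_graph(region.path)
    if region.kind == "avizo":
        return deduplicate(read_avizo_spatialgraph(region.path))
    vol = read_volume(region.path, voxel_size=config.voxel_size)
    if region.subvolume is not None:
        x, y, z, edge = region.subvolume
        vol = extract_subvolume(vol, (x, y, z), edge)
    mask = preprocess(vol, band=config.band, min_size_vox=config.min_size_vox,
                      connectivity=config.connectivity, denoise=config.denoise,
                      denoise_size_px=config.denoise_size_px,
                      denoise_neighborhood=config.denoise_neighborhood)
    g = skeleton_to_graph(mask, radius_correction=config.radius_correction,
                          smooth_iterations=config.smooth_iterations,
                          spur_length_vox=config.spur_length_vox)
    return deduplicate(g)


def analyze_region(graph: SpatialGraph, config: RunConfig, name: str) -> dict:
    """Descriptor tables, summaries and distribution statistics for a region."""
    st = desc.segment_table(graph)
    st = mechanics.per_segment_buckling(st, E=config.young_modulus,
                                        n_coeff=config.n_coeff)
    nt = desc.node_table(graph)
    cfgtab = desc.node_configuration_table(graph, bin_width=config.ita_bin_width)
    summary = desc.summarize(
        st, ["chord_length", "curved_length", "tortuosity", "mean_radius",
             "slenderness", "theta", "phi"])
    node_summary = desc.summarize(nt, ["node_radius", "mean_ita"])

    theta_vals = st["theta"].dropna().to_numpy()
    phi_vals = st["phi"].dropna().to_numpy()
    dist: dict = {}
    if theta_vals.size >= 3 and np.ptp(theta_vals) > 0:
        dist["theta_shapiro"] = stats.shapiro_wilk(theta_vals, seed=config.seed).to_dict()
        dist["theta_skewness"] = stats.moment_skewness(theta_vals)
        dist["theta_kurtosis"] = stats.moment_kurtosis(theta_vals)
    if phi_vals.size >= config.rose_bins:
        dist["phi_chi_square"] = stats.chi_square_uniformity(
            phi_vals, config.rose_bins).to_dict()
    rose = stats.rose_bins(phi_vals, config.rose_bins) if phi_vals.size else \
        np.zeros(config.rose_bins, dtype=int)
    theta_hist, theta_edges = np.histogram(theta_vals, bins=config.theta_bins,
                                           range=(0.0, 90.0))
    return {
        "name": name,
        "n_nodes": graph.n_nodes,
        "n_segments": graph.n_segments,
        "segments": st,
        "nodes": nt,
        "node_configuration": cfgtab,
        "summary": summary.table,
        "node_summary": node_summary.table,
        "point_radius_summary": desc.point_radius_summary(graph),
        "distributions": dist,
        "rose_counts": rose,
        "theta_hist": {"counts": theta_hist, "edges": theta_edges},
    }


def compare_regions(a: dict, b: dict, config: RunConfig) -> list[dict]:
    """Subsampled rank-sum comparisons of descriptor distributions."""
    out = []
    for i, var in enumerate(COMPARISON_VARIABLES):
        src_a = a["nodes"] if var in ("node_radius", "mean_ita") else a["segments"]
        src_b = b["nodes"] if var in ("node_radius", "mean_ita") else b["segments"]
        col = "mean_ita" if var == "mean_ita" else var
        x = src_a[col].dropna().to_numpy()
        y = src_b[col].dropna().to_numpy()
        if x.size < 3 or y.size < 3:
            log.warning("comparison %s skipped: too few values", var)
            continue
        r = stats.subsampled_wilcoxon(
            x, y, n=config.subsample_n, iterations=config.iterations,
            seed=config.seed + 1000 + i,
            label_x=a["name"], label_y=b["name"])
        rec = r.to_dict()
        rec["variable"] = var
        out.append(rec)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for every region and all pairwise comparisons."""
    if not config.regions:
        raise ValueError("config defines no regions")
    regions = []
    for region in config.regions:
        log.info("processing region %s (%s)", region.name, region.kind)
        try:
            graph = load_region_graph(region, config)
            regions.append(analyze_region(graph, config, region.name))
        except Exception as e:
            raise RuntimeError(f"stage failed for region {region.name!r}: {e}") from e
    comparisons = []
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            comparisons.append({
                "pair": [regions[i]["name"], regions[j]["name"]],
                "tests": compare_regions(regions[i], regions[j], config),
            })
    bundle = {"config": config.to_dict(), "regions": regions,
              "comparisons": comparisons}
    if config.out_dir:
        render_report(bundle, config.out_dir)
    return bundle


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _fmt_summary(tab: pd.DataFrame) -> str:
    return tab.to_string(float_format=lambda v: f"{v:.2f}")


def render_text(bundle: dict) -> str:
    """Deterministic human-readable report of a pipeline bundle."""
    lines = []
    for reg in bundle["regions"]:
        lines.append(f"=== region: {reg['name']} "
                     f"({reg['n_segments']} segments, {reg['n_nodes']} nodes) ===")
        if len(reg["segments"]) == 0:
            lines.append("no data: region produced an empty segment table")
        else:
            lines.append("descriptor summary (median / mad / min / max / N):")
            lines.append(_fmt_summary(reg["summary"]))
            lines.append("node summary:")
            lines.append(_fmt_summary(reg["node_summary"]))
            lines.append("node configuration (ITA per valence class):")
            lines.append(reg["node_configuration"].to_string(
                index=False, float_format=lambda v: f"{v:.2f}"))
        for key, val in sorted(reg["distributions"].items()):
            lines.append(f"{key}: {json.dumps(val, sort_keys=True, default=float)}"
                         if isinstance(val, dict) else f"{key}: {val:.4f}")
        lines.append("")
    for comp in bundle["comparisons"]:
        lines.append(f"=== comparison: {comp['pair'][0]} vs {comp['pair'][1]} ===")
        if not comp["tests"]:
            lines.append("no data: no comparable variables")
        for t in comp["tests"]:
            lines.append(f"{t['variable']}: mean p = {t['mean_p']:.4f} "
                         f"(N = {t['subsample_size']}, "
                         f"iterations = {t['iterations']})")
        lines.append("")
    return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def render_report(bundle: dict, out_dir) -> None:
    """Write the JSON + text report and per-region CSV artifacts.

    The rose-sector and theta-histogram counts are sufficient to
    regenerate orientation plots.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(_jsonable(bundle), indent=1, sort_keys=True))
    (out / "report.txt").write_text(render_text(bundle))
    for reg in bundle["regions"]:
        name = reg["name"]
        reg["segments"].to_csv(out / f"segments_{name}.csv", index=False)
        reg["nodes"].to_csv(out / f"nodes_{name}.csv", index=False)
        pd.DataFrame({
            "sector_start_deg": np.arange(len(reg["rose_counts"])) *
            (360.0 / len(reg["rose_counts"])),
            "count": reg["rose_counts"],
        }).to_csv(out / f"rose_{name}.csv", index=False)
        th = reg["theta_hist"]
        pd.DataFrame({"bin_start_deg": th["edges"][:-1],
                      "bin_end_deg": th["edges"][1:],
                      "count": th["counts"]}).to_csv(
            out / f"theta_hist_{name}.csv", index=False)
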