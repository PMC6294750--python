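"""End-to-end orchestration: phantom (or input data) -> tensor fit -> FACT
and Gibbs tracking -> quantification -> clustering, with a machine-readable
report.

Configuration lives in a single TOML file mirroring the CLI flags (CLI
values override the file). Exactly one of ``[phantom]`` / ``[inputs]`` must
be present. All stage RNG seeds derive from the one global seed, and every
intermediate is written in a standard format, so any stage can be re-run
from its saved outputs.
"""

from __future__ import annotations

import csv
import json
import logging
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import __version__
from .cluster import cluster_purity, cluster_tracts, spectral_embed
from .fact import FactParams, fact_track, filter_by_length
from .gibbs import GibbsParams, anneal, extract_streamlines
from .io import load_dwi, load_gradient_table, load_mask, load_tracts, save_tracts
from .phantom import PhantomSpec, make_geometry, write_phantom
from .quant import fit_cosine_series, heading_histogram, heading_symmetry
from .scoring import (
    assign_bundle_labels,
    crossing_continuation_rate,
    mean_orientation_error,
    midline_crossing_fraction,
)
from .tensor import color_fa_map, fit_tensor

log = logging.getLogger("myotract.pipeline")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_report"]


@dataclass
class PipelineConfig:
    """One declarative description of a full run."""

    out_dir: Path
    phantom: PhantomSpec | None = None
    inputs: dict | None = None  # paths: dwi, bval, bvec, mask[, truth_tracts]
    fact: FactParams = field(default_factory=FactParams)
    gibbs: GibbsParams = field(default_factory=GibbsParams)
    min_length: float | None = None  # mm; default 0.25 x grid diagonal
    min_chain: int = 3
    cosine_order: int = 9
    bin_width: float = 10.0
    k_clusters: int = 2
    sigma: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if (self.phantom is None) == (self.inputs is None):
            raise ValueError("exactly one of phantom / inputs must be configured")

    @classmethod
    def from_toml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kw: dict = {}
        if "phantom" in raw:
            ph = dict(raw["phantom"])
            if "grid_shape" in ph:
                ph["grid_shape"] = tuple(ph["grid_shape"])
            if "voxel_size" in ph:
                ph["voxel_size"] = tuple(ph["voxel_size"])
            kw["phantom"] = PhantomSpec(**ph)
        if "inputs" in raw:
            kw["inputs"] = dict(raw["inputs"])
        if "fact" in raw:
            kw["fact"] = FactParams(**raw["fact"])
        if "gibbs" in raw:
            kw["gibbs"] = GibbsParams(**raw["gibbs"])
        for key in (
            "out_dir",
            "min_length",
            "min_chain",
            "cosine_order",
            "bin_width",
            "k_clusters",
            "sigma",
            "seed",
        ):
            if key in raw:
                kw[key] = raw[key]
        kw.update(overrides)
        return cls(**kw)


@dataclass
class RunReport:
    config_echo: dict
    stages: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config_echo,
            "stages": self.stages,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, Path):
        return str(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def validate_report(report: dict) -> None:
    """Check a run report against the shipped schema (required dotted keys)."""
    schema = json.loads(
        resources.files("myotract").joinpath("report_schema.json").read_text()
    )
    for dotted in schema["required"]:
        node = report
        for part in dotted.split("."):
            if not isinstance(node, dict) or part not in node:
                raise ValueError(f"report is missing required entry {dotted!r}")
            node = node[part]


def _grid_diagonal(dwi) -> float:
    return float(np.linalg.norm(np.asarray(dwi.shape) * dwi.voxel_size))


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute all stages in order; a stage failure halts downstream stages.

    Returns the report (also written to ``out_dir/report.json``) with
    per-stage metrics: tract counts before/after the length filter, the
    energy-trace summary, truth-based recovery rates when ground truth is
    available, the per-axis heading-symmetry statistic and cluster purity.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    report = RunReport(config_echo=_echo_config(cfg), stages=stages)

    try:
        dwi, mask, truth_tracts, spec = _stage_data(cfg, out, stages)
        tf = _stage_tensor(cfg, dwi, mask, out, stages)
        min_len = (
            cfg.min_length if cfg.min_length is not None else 0.25 * _grid_diagonal(dwi)
        )
        fact_ts = _stage_fact(cfg, tf, mask, min_len, out, stages)
        gibbs_ts, gibbs_cfg = _stage_gibbs(cfg, dwi, mask, min_len, out, stages)
        _stage_quant(cfg, gibbs_ts, out, stages)
        _stage_cluster(cfg, gibbs_ts, truth_tracts, out, stages)
        _stage_scoring(cfg, spec, truth_tracts, fact_ts, gibbs_ts, gibbs_cfg, stages)
    except Exception as exc:  # noqa: BLE001 - failure is part of the report
        stages["failure"] = {"error": f"{type(exc).__name__}: {exc}"}
        log.exception("pipeline stage failed; halting downstream stages")

    report.save(out / "report.json")
    return report


def _echo_config(cfg: PipelineConfig) -> dict:
    d = {
        "out_dir": str(cfg.out_dir),
        "seed": cfg.seed,
        "min_length": cfg.min_length,
        "min_chain": cfg.min_chain,
        "cosine_order": cfg.cosine_order,
        "bin_width": cfg.bin_width,
        "k_clusters": cfg.k_clusters,
        "sigma": cfg.sigma,
        "fact": vars(cfg.fact).copy(),
        "gibbs": {
            k: v for k, v in vars(cfg.gibbs).items() if not isinstance(v, np.ndarray)
        },
    }
    if cfg.phantom is not None:
        d["phantom"] = json.loads(cfg.phantom.to_json())
    if cfg.inputs is not None:
        d["inputs"] = {k: str(v) for k, v in cfg.inputs.items()}
    return d


def _stage_data(cfg, out, stages):
    spec = None
    truth_tracts = None
    if cfg.phantom is not None:
        spec = cfg.phantom
        log.info("generating %s phantom (seed %d)", spec.geometry_kind, spec.seed)
        paths = write_phantom(spec, out / "phantom")
        gtab = load_gradient_table(paths["bval"], paths["bvec"])
        dwi = load_dwi(paths["dwi"], gtab)
        mask = load_mask(paths["mask"], dwi)
        truth_tracts = load_tracts(paths["truth_tracts"])
        stages["data"] = {
            "source": "phantom",
            "kind": spec.geometry_kind,
            "n_truth_tracts": len(truth_tracts),
            "n_mask_voxels": int(mask.binary().sum()),
        }
    else:
        paths = cfg.inputs
        gtab = load_gradient_table(paths["bval"], paths["bvec"])
        dwi = load_dwi(paths["dwi"], gtab)
        mask = load_mask(paths["mask"], dwi)
        if "truth_tracts" in paths:
            truth_tracts = load_tracts(paths["truth_tracts"])
        stages["data"] = {
            "source": "files",
            "n_mask_voxels": int(mask.binary().sum()),
        }
    return dwi, mask, truth_tracts, spec


def _stage_tensor(cfg, dwi, mask, out, stages):
    import nibabel as nib

    tf = fit_tensor(dwi, mask)
    nib.save(nib.Nifti1Image(tf.fa_map.astype(np.float32), tf.affine), out / "fa.nii.gz")
    rgb = color_fa_map(tf)
    nib.save(nib.Nifti1Image(rgb.astype(np.float32), tf.affine), out / "color_fa.nii.gz")
    stages["tensor"] = {
        "n_valid_voxels": int(tf.valid_mask.sum()),
        "mean_fa_in_mask": float(tf.fa_map[mask.binary()].mean()),
        "n_clamped": int(tf.clamped_mask.sum()),
    }
    return tf


def _stage_fact(cfg, tf, mask, min_len, out, stages):
    kw = vars(cfg.fact).copy()
    kw["min_length"] = 1e-9  # track everything, filter explicitly below
    raw = fact_track(tf, mask, FactParams(**kw), seed=cfg.seed)
    ts = filter_by_length(raw, min_len)
    save_tracts(ts, out / "fact.tck")
    stages["fact"] = {
        "n_tracts_raw": len(raw),
        "n_tracts_after_length_filter": len(ts),
        "min_length_mm": min_len,
    }
    return ts


def _stage_gibbs(cfg, dwi, mask, min_len, out, stages):
    gp_kw = vars(cfg.gibbs).copy()
    gp_kw["rng_seed"] = cfg.seed
    gp = GibbsParams(**gp_kw)
    gcfg, trace = anneal(dwi, mask, gp)
    raw = extract_streamlines(
        gcfg, min_chain=cfg.min_chain, stitch_radius=4.0 * gp.segment_length
    )
    ts = filter_by_length(raw, min_len)
    save_tracts(ts, out / "gibbs.tck")
    with open(out / "gibbs_energy_trace.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(trace.dtype.names)
        for row in trace:
            wr.writerow(list(row))
    e_tot = trace["external"] + trace["internal"]
    n10 = max(1, len(e_tot) // 10)
    stages["gibbs"] = {
        "n_particles": gcfg.n_particles,
        "n_pairs": gcfg.n_pairs,
        "n_tracts_raw": len(raw),
        "n_tracts_after_length_filter": len(ts),
        "energy_first10pct_mean": float(e_tot[:n10].mean()),
        "energy_last10pct_mean": float(e_tot[-n10:].mean()),
        "min_length_mm": min_len,
    }
    return ts, gcfg


def _stage_quant(cfg, ts, out, stages):
    if len(ts) == 0:
        stages["quant"] = {"n_tracts": 0}
        return
    sym = heading_symmetry(ts)
    hists = {}
    for axis in "xyz":
        counts, edges = heading_histogram(ts, axis=axis, bin_width=cfg.bin_width)
        hists[axis] = {"counts": counts.tolist(), "edges": edges.tolist()}
    residuals = []
    for t in ts:
        if len(t) > cfg.cosine_order + 1:
            residuals.append(fit_cosine_series(t, cfg.cosine_order).residual_rmse)
    (out / "heading_histograms.json").write_text(json.dumps(hists))
    stages["quant"] = {
        "n_tracts": len(ts),
        "heading_symmetry_deg": sym.tolist(),
        "cosine_order": cfg.cosine_order,
        "cosine_rmse_mean": float(np.mean(residuals)) if residuals else None,
    }


def _stage_cluster(cfg, ts, truth_tracts, out, stages):
    if len(ts) < max(3, cfg.k_clusters):
        stages["cluster"] = {"n_tracts": len(ts), "skipped": True}
        return
    emb = spectral_embed(ts, sigma=cfg.sigma)
    labels = cluster_tracts(emb, k=cfg.k_clusters, seed=cfg.seed)
    entry = {
        "n_tracts": len(ts),
        "k": cfg.k_clusters,
        "cluster_sizes": np.bincount(labels, minlength=cfg.k_clusters).tolist(),
    }
    if truth_tracts is not None and all(
        t.bundle_label is not None for t in truth_tracts
    ):
        truth_labels = assign_bundle_labels(ts, truth_tracts)
        entry["purity_vs_truth"] = float(cluster_purity(labels, truth_labels))
    (out / "cluster_labels.json").write_text(json.dumps(labels.tolist()))
    np.savetxt(
        out / "embedding.csv",
        np.column_stack([emb.coordinates, labels]),
        delimiter=",",
        header="e1,e2,label",
        comments="",
    )
    stages["cluster"] = entry


def _stage_scoring(cfg, spec, truth_tracts, fact_ts, gibbs_ts, gibbs_cfg, stages):
    if spec is None or truth_tracts is None:
        return
    entry: dict = {}
    truth = make_geometry(spec)  # regenerate the per-voxel orientation map
    try:
        entry["gibbs_orientation_error_deg"] = mean_orientation_error(gibbs_cfg, truth)
    except ValueError:
        pass
    if spec.geometry_kind == "crossing":
        entry["fact_continuation_rate"] = crossing_continuation_rate(fact_ts, spec)
        entry["gibbs_continuation_rate"] = crossing_continuation_rate(gibbs_ts, spec)
    if spec.geometry_kind == "purse_string":
        entry["fact_midline_crossing_fraction"] = midline_crossing_fraction(fact_ts)
        entry["gibbs_midline_crossing_fraction"] = midline_crossing_fraction(gibbs_ts)
    stages["scoring"] = entry
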