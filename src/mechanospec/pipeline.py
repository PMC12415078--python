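"""End-to-end pipeline: simulate -> fit -> preprocess -> cluster -> stats.

``run_pipeline`` chains the stages deterministically under a fixed seed and
writes a report bundle (CSV tables with provenance headers plus a JSON test
summary) into the output directory.  A structured log records the number of
points entering and leaving every stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .brillouin import extract_brillouin_parameters
from .clustering import (discard_offtarget_cluster, kmeans_cluster,
                         select_cluster_count, silhouette_profile,
                         spectra_matrix)
from .io import config_hash, read_phantom, truth_frame, write_table
from .raman import area_normalize, baseline_correct, crop
from .stats import (build_histogram, cluster_medians, join_colocalized,
                    pairwise_comparisons, shift_width_correlation,
                    welch_omnibus)
from .synthetic import (generate_phantom_map, ht18584_line_config,
                        organoid_line_config, u87_line_config)

__all__ = ["PipelineConfig", "run_pipeline", "fit_map", "prep_raman_map",
           "PipelineError"]

_SIMULATE_KINDS = {
    "u87_line": u87_line_config,
    "ht18584_line": ht18584_line_config,
    "organoid_line": organoid_line_config,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending points."""


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Either ``input_path`` points at an existing phantom container, or
    ``simulate`` names a phantom kind ("u87_line", "ht18584_line",
    "organoid_line") to be generated on the fly (``n_maps`` line maps).
    """

    out_dir: str
    input_path: str | None = None
    simulate: str | None = "u87_line"
    n_maps: int = 10
    rayleigh_fwhm: float | None = None   # None: use the phantom's value
    reference_shift: float = 3.81
    crop_lo: float = 600.0
    crop_hi: float = 1800.0
    k_range: tuple = (2, 8)
    seed: int = 0
    baseline_lam: float = 1e7
    baseline_p: float = 0.001

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def __post_init__(self):
        if self.input_path is None and self.simulate is None:
            raise ValueError("either input_path or simulate is required")
        if self.simulate is not None and self.simulate not in _SIMULATE_KINDS:
            raise ValueError(f"unknown phantom kind {self.simulate!r}")


def fit_map(smap, rayleigh_fwhm=None) -> pd.DataFrame:
    """Fit every Brillouin spectrum of a map into a tidy table."""
    rows = []
    for i, spec in enumerate(smap.brillouin):
        fit = extract_brillouin_parameters(spec, rayleigh_fwhm=rayleigh_fwhm)
        rows.append({
            "point": i, "x_um": float(smap.x_um[i]),
            "y_um": float(smap.y_um[i]), "nu_B": fit.nu_B,
            "gamma_B": fit.gamma_B, "gamma_B_measured": fit.gamma_B_measured,
            "amplitude": fit.amplitude, "valid": fit.valid,
            "reason": fit.reason,
        })
    return pd.DataFrame(rows)


def prep_raman_map(spectra, crop_lo=600.0, crop_hi=1800.0,
                   lam=1e7, p=0.001):
    """Crop, baseline-correct and area-normalize a list of raw spectra."""
    out = []
    for s in spectra:
        s = crop(s, crop_lo, crop_hi)
        s = baseline_correct(s, lam=lam, p=p)
        s = area_normalize(s)
        out.append(s)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a report dict with the fitted tables, the cluster model
    selection, the per-cluster statistics and the stage log.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = []

    # -- stage: input ------------------------------------------------------
    if config.input_path is not None:
        maps = [read_phantom(config.input_path)]
        log.append({"stage": "load", "maps": 1,
                    "points": maps[0].n_points})
    else:
        factory = _SIMULATE_KINDS[config.simulate]
        maps = [factory(seed=(config.seed * 1000 + i) % (2 ** 31))
                for i in range(config.n_maps)]
        maps = [generate_phantom_map(c) for c in maps]
        log.append({"stage": "simulate", "maps": len(maps),
                    "points": sum(m.n_points for m in maps)})
    if sum(m.n_points for m in maps) == 0:
        raise PipelineError("input: no points to analyse")

    # -- stage: Brillouin fitting -----------------------------------------
    fits = []
    offset = 0
    truths = []
    for m in maps:
        f = fit_map(m, rayleigh_fwhm=config.rayleigh_fwhm)
        f["point"] = f["point"] + offset
        t = truth_frame(m)
        t["point"] = t["point"] + offset
        offset += m.n_points
        fits.append(f)
        truths.append(t)
    fits = pd.concat(fits, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    n_valid = int(fits["valid"].sum())
    log.append({"stage": "fit_brillouin", "points_in": len(fits),
                "points_out": n_valid,
                "invalid": int(len(fits) - n_valid)})
    if n_valid == 0:
        bad = fits.loc[~fits["valid"], "point"].tolist()[:10]
        raise PipelineError(f"fit_brillouin: all fits invalid (e.g. {bad})")

    # -- stage: Raman preprocessing ---------------------------------------
    raman_raw = [s for m in maps if m.raman is not None for s in m.raman]
    if not raman_raw:
        raise PipelineError("prep_raman: no Raman spectra in input")
    prepped = prep_raman_map(raman_raw, config.crop_lo, config.crop_hi,
                             lam=config.baseline_lam, p=config.baseline_p)
    n_blank = sum(s.quality != "ok" for s in prepped)
    log.append({"stage": "prep_raman", "points_in": len(raman_raw),
                "points_out": len(prepped), "flagged_blank": n_blank})

    # -- stage: clustering -------------------------------------------------
    mat, axis = spectra_matrix(prepped)
    k_lo, k_hi = config.k_range
    k_opt, criteria = select_cluster_count(
        mat, range(int(k_lo), int(k_hi) + 1), seed=config.seed)
    model = kmeans_cluster(mat, k_opt, seed=config.seed)
    model.wavenumber = axis
    sil_values, sil_means = silhouette_profile(model, mat)
    labels, n_discarded, discarded = discard_offtarget_cluster(model)
    log.append({"stage": "cluster", "k_opt": k_opt,
                "discarded_clusters": discarded,
                "points_discarded": n_discarded,
                "points_out": int((labels >= 0).sum())})

    # -- stage: statistics --------------------------------------------------
    label_df = pd.DataFrame({"point": np.arange(len(labels)),
                             "cluster": labels,
                             "silhouette": sil_values})
    joined = join_colocalized(
        fits[["point", "nu_B", "gamma_B", "valid"]],
        label_df[["point", "cluster"]])
    medians = cluster_medians(joined)
    tests = {}
    for var in ("nu_B", "gamma_B", "blt"):
        omnibus = welch_omnibus(joined, var)
        pw = pairwise_comparisons(joined, var)
        tests[var] = {
            "omnibus": dataclasses.asdict(omnibus),
            "pairwise": pw.to_dict(orient="records"),
        }
    corr = shift_width_correlation(joined, by_cluster=True)
    hist_nu = build_histogram(fits.loc[fits["valid"], "nu_B"])
    hist_ga = build_histogram(fits.loc[fits["valid"], "gamma_B"])
    log.append({"stage": "stats", "points_in": len(joined),
                "clusters": len(medians)})

    # -- report bundle ------------------------------------------------------
    seed, cfg = config.seed, config
    write_table(fits, out_dir / "fits.csv", seed, cfg)
    write_table(truth, out_dir / "truth.csv", seed, cfg)
    write_table(label_df, out_dir / "labels.csv", seed, cfg)
    write_table(criteria.reset_index(), out_dir / "criteria.csv", seed, cfg)
    write_table(medians.reset_index(), out_dir / "medians.csv", seed, cfg)
    write_table(corr, out_dir / "correlations.csv", seed, cfg)
    centroids = pd.DataFrame(model.centroids.T, columns=[
        f"cluster_{i}" for i in range(model.k)])
    centroids.insert(0, "wavenumber", axis)
    write_table(centroids, out_dir / "centroids.csv", seed, cfg)
    hist_df = pd.DataFrame({
        "bin_lo": hist_nu.bin_edges[:-1], "bin_hi": hist_nu.bin_edges[1:],
        "count": hist_nu.counts})
    write_table(hist_df, out_dir / "histogram_nu.csv", seed, cfg)
    with open(out_dir / "tests.json", "w") as fh:
        json.dump(tests, fh, indent=2, default=float)
    resolved = {**{k: v for k, v in vars(config).items()},
                "version": _version, "config_hash": config_hash(config)}
    resolved["k_range"] = list(resolved["k_range"])
    with open(out_dir / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh)
    with open(out_dir / "stage_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)

    return {
        "fits": fits, "truth": truth, "labels": label_df, "model": model,
        "k_opt": k_opt, "criteria": criteria, "medians": medians,
        "tests": tests, "correlations": corr,
        "histograms": {"nu_B": hist_nu, "gamma_B": hist_ga},
        "log": log, "discarded_clusters": discarded,
    }
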