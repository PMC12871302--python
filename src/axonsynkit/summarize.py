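"""Replicate-aware (SuperPlot) aggregation, tidy I/O and the pipeline runner.

Biological replicates — independent iNeuron inductions — are the unit of
inference: per-replicate means are computed over the measured units (axons,
fields, wells), the genotype grand mean is the unweighted mean of replicate
means, and dispersion is the SD across replicate means (n-1 denominator).
Pooling units across replicates for dispersion (pseudoreplication) is never
done here.

``run_pipeline`` wires the synthetic generators through the analysis stages
and writes tidy CSV tables plus a JSON manifest (seed, parameters, package
version) so every output is traceable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import comets as cm
from . import mea as mea_mod
from . import qpcr as qpcr_mod
from . import synthetic as syn
from . import transport as tp
from .config import PRESETS, coculture_params

__all__ = [
    "SuperPlotSummary",
    "superplot_summarize",
    "default_config",
    "run_pipeline",
    "write_kymograph_tiff",
    "read_kymograph_tiff",
]

log = logging.getLogger("axonsynkit")


@dataclass
class SuperPlotSummary:
    """Replicate means plus genotype-level mean and dispersion."""

    replicate_means: pd.DataFrame   # genotype, replicate_id, mean, n_units
    genotype_stats: pd.DataFrame    # genotype, grand_mean, sd_rep_means, n_reps


def superplot_summarize(data: pd.DataFrame) -> SuperPlotSummary:
    """SuperPlot aggregation of tidy measurements.

    ``data`` needs columns genotype, replicate_id, unit_id, value.  SD is
    undefined (NaN, with a warning) for genotypes with one replicate.
    """
    required = {"genotype", "replicate_id", "unit_id", "value"}
    if data is None or len(data) == 0:
        raise ValueError("empty measurement table")
    if not required.issubset(data.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    rep = (data.groupby(["genotype", "replicate_id"])["value"]
           .agg(mean="mean", n_units="count").reset_index())
    geno = (rep.groupby("genotype")["mean"]
            .agg(grand_mean="mean", sd_rep_means=lambda s: s.std(ddof=1),
                 n_reps="count").reset_index())
    singles = geno.loc[geno.n_reps < 2, "genotype"].tolist()
    if singles:
        warnings.warn(f"single replicate for {singles}: SD undefined")
    return SuperPlotSummary(replicate_means=rep, genotype_stats=geno)


# ---------------------------------------------------------------------------
# shared readers / writers
# ---------------------------------------------------------------------------

def write_kymograph_tiff(kymo: syn.Kymograph, path: str | Path) -> None:
    """Write a kymograph as float32 TIFF with a JSON calibration sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, kymo.values.astype(np.float32))
    sidecar = {"px_um": kymo.px_um, "dt_s": kymo.dt_s,
               "length_um": kymo.length_um, "duration_s": kymo.duration_s}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_kymograph_tiff(path: str | Path) -> syn.Kymograph:
    """Read a TIFF kymograph; calibration comes from the JSON sidecar."""
    import tifffile

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return syn.Kymograph(values=np.asarray(tifffile.imread(path), dtype=float),
                         **meta)


# ---------------------------------------------------------------------------
# pipeline runner
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Default run configuration; every stage at a desk-scale problem size."""
    return {
        "genotypes": list(PRESETS),
        "seed": 0,
        "stages": ["transport", "comets", "mea", "synapse", "qpcr"],
        "n_axons": 10,
        "n_replicates": 3,
        "axon_length_um": 100.0,
        "svp_duration_s": 300.0,
        "comet_duration_s": 300.0,
        "mea_duration_s": 300.0,
        "mea_with_traces": False,
        "n_wells": 2,
        "synapse_n_pre": 100,
        "synapse_apposed_frac": 0.5,
        "qpcr_noise_sd": 0.1,
        "qpcr_n_reps": 3,
    }


def _stage_transport(cfg: dict, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for g in cfg["genotypes"]:
        p = PRESETS[g]
        for rep in range(cfg["n_replicates"]):
            seed = int(rng.integers(2**31))
            axons = syn.gen_svp_tracks(p, cfg["n_axons"],
                                       cfg["svp_duration_s"],
                                       cfg["axon_length_um"], seed)
            for axon_id, tracks in axons.items():
                kymo = syn.render_kymograph(tracks, cfg["axon_length_um"],
                                            cfg["svp_duration_s"],
                                            noise_sd=10.0,
                                            seed=int(rng.integers(2**31)))
                traced = tp.trace_tracks(kymo)
                s = tp.summarize_axon(traced, cfg["svp_duration_s"],
                                      axon_id=axon_id, kymo=kymo)
                for metric, v in (
                    ("antero_flux_per_min", s.antero_flux),
                    ("retro_flux_per_min", s.retro_flux),
                    ("antero_vmax_um_s", s.antero_vmax),
                    ("retro_vmax_um_s", s.retro_vmax),
                ):
                    rows.append((g, f"rep{rep}", axon_id, metric, v))
    return pd.DataFrame(rows, columns=["genotype", "replicate_id", "unit_id",
                                       "metric", "value"])


def _stage_comets(cfg: dict, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for g in cfg["genotypes"]:
        p = PRESETS[g]
        for rep in range(cfg["n_replicates"]):
            for i in range(cfg["n_axons"]):
                seed = int(rng.integers(2**31))
                sites, comet_ev = syn.gen_comet_site_axon(
                    p, cfg["axon_length_um"], cfg["comet_duration_s"], seed)
                kymo = syn.render_comet_kymograph(
                    sites, comet_ev, cfg["axon_length_um"],
                    cfg["comet_duration_s"], seed=int(rng.integers(2**31)))
                det = cm.detect_svp_sites(kymo)
                s = cm.summarize_axon_comets(
                    f"axon{i:03d}", det, comet_ev, cfg["axon_length_um"],
                    cfg["comet_duration_s"])
                for metric, v in (
                    ("site_density_per_10um", s.site_density),
                    ("comet_density_per_um_min", s.comet_density),
                    ("frac_comets_assoc", s.frac_comets_assoc),
                    ("frac_sites_active", s.frac_sites_active),
                ):
                    rows.append((g, f"rep{rep}", f"axon{i:03d}", metric, v))
    return pd.DataFrame(rows, columns=["genotype", "replicate_id", "unit_id",
                                       "metric", "value"])


def _stage_mea(cfg: dict, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for g in cfg["genotypes"]:
        p = coculture_params(PRESETS[g])
        for rep in range(cfg["n_replicates"]):
            for w in range(cfg["n_wells"]):
                seed = int(rng.integers(2**31))
                well = syn.gen_mea_recording(
                    p, duration_s=cfg["mea_duration_s"], seed=seed,
                    with_traces=cfg["mea_with_traces"],
                    well_id=f"{g}_r{rep}w{w}")
                if cfg["mea_with_traces"]:
                    well = mea_mod.well_from_traces(
                        well.traces, well.fs_hz, well.duration_s,
                        well_id=well.well_id, div=well.div)
                s = mea_mod.summarize_well(well)
                for metric, v in (
                    ("n_active", s.n_active),
                    ("mfr_hz", s.mfr),
                    ("burst_freq_per_min", s.burst_freq),
                    ("burst_dur_s", s.burst_dur_mean),
                    ("nb_freq_per_min", s.nb_freq),
                    ("nb_dur_s", s.nb_dur_mean),
                ):
                    rows.append((g, f"rep{rep}", s.well_id, metric, v))
    return pd.DataFrame(rows, columns=["genotype", "replicate_id", "unit_id",
                                       "metric", "value"])


def _stage_synapse(cfg: dict, rng: np.random.Generator) -> pd.DataFrame:
    from . import synapse as sq
    rows = []
    for g in cfg["genotypes"]:
        frac = cfg["synapse_apposed_frac"] * (0.6 if g == "R350G" else 1.0)
        for rep in range(cfg["n_replicates"]):
            seed = int(rng.integers(2**31))
            fld = syn.gen_synapse_field(cfg["synapse_n_pre"], frac, seed=seed)
            pairs = sq.match_appositions(fld["pre"], fld["post"])
            rows.append((g, f"rep{rep}", f"field{rep}", "apposed_pct",
                         sq.apposed_percent(len(pairs), len(fld["pre"]))))
            rows.append((g, f"rep{rep}", f"field{rep}", "density_per_um2",
                         sq.synapse_density(len(pairs), fld["map2_area_um2"])))
    return pd.DataFrame(rows, columns=["genotype", "replicate_id", "unit_id",
                                       "metric", "value"])


def _stage_qpcr(cfg: dict, rng: np.random.Generator) -> pd.DataFrame:
    rel = {g: PRESETS[g].rel_expr for g in cfg["genotypes"]}
    table = syn.gen_ct_table(rel, noise_sd=cfg["qpcr_noise_sd"],
                             n_reps=cfg["qpcr_n_reps"],
                             seed=int(rng.integers(2**31)))
    est = qpcr_mod.delta_delta_ct(table)
    return pd.DataFrame({
        "genotype": est.index,
        "replicate_id": "pooled",
        "unit_id": "pooled",
        "metric": "rel_expr",
        "value": est.to_numpy(),
    })


_STAGES = {
    "transport": _stage_transport,
    "comets": _stage_comets,
    "mea": _stage_mea,
    "synapse": _stage_synapse,
    "qpcr": _stage_qpcr,
}


def run_pipeline(config: dict | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run synthetic generation -> stage analyses -> SuperPlot summaries.

    Returns a bundle {stage: measurements DataFrame, "superplots": {...},
    "manifest": {...}}; with ``out_dir`` every table is written as tidy CSV
    next to a JSON run manifest.
    """
    cfg = default_config()
    cfg.update(config or {})
    unknown = [s for s in cfg["stages"] if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; known: {sorted(_STAGES)}")
    rng = np.random.default_rng(cfg["seed"])
    bundle: dict = {"superplots": {}}
    for stage in cfg["stages"]:
        log.info("running stage %s", stage)
        df = _STAGES[stage](cfg, rng)
        bundle[stage] = df
        per_metric = {}
        for metric, sub in df.groupby("metric"):
            sub = sub.dropna(subset=["value"])
            if len(sub):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    per_metric[metric] = superplot_summarize(sub)
        bundle["superplots"][stage] = per_metric

    from importlib.metadata import PackageNotFoundError, version
    try:
        ver = version("axonsynkit")
    except PackageNotFoundError:
        ver = "unknown"
    manifest = {"seed": cfg["seed"], "stages": cfg["stages"],
                "config": {k: v for k, v in cfg.items()},
                "package_version": ver}
    bundle["manifest"] = manifest

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for stage in cfg["stages"]:
            bundle[stage].to_csv(out / f"{stage}_measurements.csv", index=False)
            for metric, sp in bundle["superplots"][stage].items():
                sp.genotype_stats.to_csv(
                    out / f"{stage}_{metric}_superplot.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
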