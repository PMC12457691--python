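"""End-to-end orchestration: simulate/ingest -> detect -> track -> classify
-> diffusion/shape -> report.

A run is described by a config object whose every parameter lands in a JSON
manifest next to the outputs, so any reported number regenerates
bit-identically from the manifest and seed. The SPT chain follows the
five-step scheme: preprocess the stack, detect and link foci, drop tracks
shorter than the minimum duration, classify by MSD, exclude the directed
subpopulation, estimate per-trajectory D by the CDF model, fit the
two-component log-normal mixture per replicate and take per-strain medians.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rodtrack._version import __version__ as _pkg_version
from rodtrack.diffusion import aggregate_replicates, estimate_dc_per_track, fit_lognormal_mixture
from rodtrack.errors import ConfigError
from rodtrack.imaging import preprocess_stack, read_stack
from rodtrack.motion import classify_tracks, compute_density, summarize_directed
from rodtrack.shape import contours_from_labels, descriptors_table
from rodtrack.synthetic import (
    MovieSimConfig,
    TrajectorySimConfig,
    simulate_movie,
    simulate_trajectories,
)
from rodtrack.tracking import detect_spots, filter_tracks, link_detections, read_trackmate_csv

log = logging.getLogger("rodtrack")


@dataclass
class CohortSpec:
    """One (strain, replicate) input: a simulation config, a movie file or a
    TrackMate track table."""

    strain: str
    replicate_id: str
    simulation: TrajectorySimConfig | MovieSimConfig | None = None
    movie_path: str | None = None
    track_csv: str | None = None

    def kind(self) -> str:
        n_sources = sum(x is not None for x in (self.simulation, self.movie_path, self.track_csv))
        if n_sources != 1:
            raise ConfigError(
                f"cohort {self.strain}/{self.replicate_id}: exactly one of "
                "simulation, movie_path, track_csv must be set"
            )
        if self.simulation is not None:
            return "sim_movie" if isinstance(self.simulation, MovieSimConfig) else "sim_tracks"
        return "movie" if self.movie_path else "csv"


@dataclass
class SPTRunConfig:
    """All parameters of an SPT run; defaults mirror the analysis settings
    (LoG radius 0.25 µm, link distance 0.4 µm, gap 0, 10-frame minimum,
    R²_dir 0.9, R²_diff 0.8, displacement lag 4 frames)."""

    cohorts: list[CohortSpec]
    seed: int = 0
    pixel_size: float | None = None  # required for movie inputs
    t_lag: float = 0.1
    detect_radius_um: float = 0.25
    detect_threshold: float = 100.0
    link_max_dist_um: float = 0.4
    min_frames: int = 10
    r2_dir: float = 0.9
    r2_diff: float = 0.8
    lag_frames: int = 4
    mixture_restarts: int = 5
    outdir: str | None = None


@dataclass
class RunReport:
    per_replicate: pd.DataFrame
    per_strain: pd.DataFrame
    stage_counts: pd.DataFrame
    summaries: dict
    manifest: dict

    def content_hash(self) -> str:
        """SHA-256 over the serialized report tables (determinism check)."""
        payload = json.dumps(
            {
                "per_replicate": self.per_replicate.round(12).to_dict("records"),
                "per_strain": self.per_strain.round(12).to_dict("records"),
                "summaries": self.summaries,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def _manifest(cfg) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "wkt"):
            return obj.wkt
        return obj

    return {"version": _pkg_version, "config": enc(cfg)}


def _tracks_for_cohort(spec: CohortSpec, cfg: SPTRunConfig, seed: int):
    """Track table + optional (mask, n_frames) for density, per input kind."""
    kind = spec.kind()
    density_ctx = None
    if kind == "sim_tracks":
        sim = dataclasses.replace(spec.simulation, seed=seed)
        tracks, _ = simulate_trajectories(sim)
        return tracks, sim.t_lag, density_ctx
    if kind == "sim_movie":
        sim = dataclasses.replace(spec.simulation, seed=seed)
        stack, _ = simulate_movie(sim)
        t_lag = sim.trajectory_config.t_lag
        pre = preprocess_stack(stack)
        dets = detect_spots(pre, cfg.detect_radius_um, cfg.detect_threshold)
        tracks = link_detections(dets, cfg.link_max_dist_um, 0, t_lag=t_lag)
        from shapely.ops import unary_union

        mask = unary_union(sim.cell_footprints)
        density_ctx = (mask, pre.n_frames)
        return tracks, t_lag, density_ctx
    if kind == "movie":
        if cfg.pixel_size is None:
            raise ConfigError("pixel_size is required for movie inputs")
        stack = read_stack(spec.movie_path, cfg.pixel_size, cfg.t_lag)
        pre = preprocess_stack(stack)
        dets = detect_spots(pre, cfg.detect_radius_um, cfg.detect_threshold)
        tracks = link_detections(dets, cfg.link_max_dist_um, 0, t_lag=cfg.t_lag)
        return tracks, cfg.t_lag, density_ctx
    tracks = read_trackmate_csv(spec.track_csv)
    return tracks, cfg.t_lag, density_ctx


def run_spt_pipeline(cfg: SPTRunConfig) -> RunReport:
    """Run the full SPT quantification for every cohort.

    Directed-classified trajectories contribute to the speed/density
    summary and are excluded from the diffusion analysis; the remaining
    tracks yield per-trajectory D values pooled per replicate for the
    mixture fit. Per-strain values are medians across replicates.
    """
    if not cfg.cohorts:
        raise ConfigError("cohorts must not be empty")
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    rep_rows, count_rows, summaries = [], [], {}
    for spec in cfg.cohorts:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        tracks, t_lag, density_ctx = _tracks_for_cohort(spec, cfg, sub_seed)
        kept, counts = filter_tracks(tracks, cfg.min_frames)
        cls = classify_tracks(kept, t_lag, cfg.r2_dir, cfg.r2_diff, cfg.min_frames)
        summary = summarize_directed(cls) if len(cls) else {}
        log.info(
            "%s/%s: %d tracks in, %d kept, %d directed",
            spec.strain,
            spec.replicate_id,
            counts["n_input"],
            counts["n_kept"],
            summary.get("n_directed", 0),
        )

        if density_ctx is not None:
            mask, n_frames = density_ctx
            dens = compute_density(cls, kept, mask, n_frames)
            summary["mean_density_um2"] = dens.mean_density if summary.get("n_directed") else None
            summary["sd_density_um2"] = dens.sd_density if summary.get("n_directed") else None
            summary["cell_area_um2"] = dens.cell_area_um2

        directed_ids = set(cls.loc[cls["label"] == "directed", "traj_id"])
        nondirected = kept[~kept["traj_id"].isin(directed_ids)]
        dc = estimate_dc_per_track(nondirected, t_lag, cfg.lag_frames, cfg.min_frames)
        fit = fit_lognormal_mixture(
            dc["d_um2_s"].to_numpy(), n_restarts=cfg.mixture_restarts, seed=sub_seed
        )
        rep_rows.append(
            {
                "strain": spec.strain,
                "replicate_id": spec.replicate_id,
                "w1": fit.w1,
                "d1_um2_s": fit.d1_um2_s,
                "d2_um2_s": fit.d2_um2_s,
                "sigma1": fit.sigma1,
                "sigma2": fit.sigma2,
                "converged": fit.converged,
                "n_trajectories": int(len(dc)),
            }
        )
        count_rows.append({"strain": spec.strain, "replicate_id": spec.replicate_id, **counts})
        summaries[f"{spec.strain}/{spec.replicate_id}"] = summary

        if outdir:
            tag = f"{spec.strain}_{spec.replicate_id}"
            kept.to_csv(outdir / f"tracks_{tag}.csv", index=False)
            cls.to_csv(outdir / f"classifications_{tag}.csv", index=False)
            dc.to_csv(outdir / f"dc_{tag}.csv", index=False)

    per_replicate = pd.DataFrame(rep_rows)
    per_strain = aggregate_replicates(per_replicate)
    stage_counts = pd.DataFrame(count_rows)
    manifest = _manifest(cfg)
    report = RunReport(per_replicate, per_strain, stage_counts, summaries, manifest)

    if outdir:
        per_replicate.to_csv(outdir / "mixture_per_replicate.csv", index=False)
        per_strain.to_csv(outdir / "mixture_per_strain.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        with open(outdir / "report.json", "w") as fh:
            json.dump(
                {
                    "summaries": summaries,
                    "per_strain": per_strain.to_dict("records"),
                    "hash": report.content_hash(),
                },
                fh,
                indent=2,
                default=str,
            )
    return report


def load_run_config(path) -> SPTRunConfig:
    """Build an :class:`SPTRunConfig` from a YAML file.

    Top-level keys are ``SPTRunConfig`` fields; each entry of ``cohorts``
    has ``strain``, ``replicate_id`` and one of ``simulation`` (a mapping of
    :class:`TrajectorySimConfig` fields) or ``track_csv``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "cohorts" not in raw:
        raise ConfigError("run config must define 'cohorts'")
    cohorts = []
    for i, entry in enumerate(raw.pop("cohorts")):
        entry = dict(entry)
        sim = entry.pop("simulation", None)
        if sim is not None:
            try:
                sim = TrajectorySimConfig(**sim)
            except TypeError as exc:
                raise ConfigError(f"cohorts[{i}].simulation: {exc}") from exc
        try:
            cohorts.append(CohortSpec(simulation=sim, **entry))
        except TypeError as exc:
            raise ConfigError(f"cohorts[{i}]: {exc}") from exc
    known = {f.name for f in dataclasses.fields(SPTRunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
    return SPTRunConfig(cohorts=cohorts, **raw)


@dataclass
class ShapeRunConfig:
    """Inputs for the morphometrics pipeline: per strain, label-mask TIFFs
    or ready-made contour polygons."""

    inputs: list  # (strain, path-to-label-tiff) or (strain, list[CellContour])
    pixel_size: float = 0.065
    spacing_um: float | None = None
    outdir: str | None = None


def run_shape_pipeline(cfg: ShapeRunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell shape descriptors plus per-strain medians.

    Unreadable masks or non-rod cells are logged and skipped; the run
    continues. Returns (per_cell, per_strain) tables.
    """
    import tifffile

    frames = []
    n_failed = 0
    for strain, source in cfg.inputs:
        if isinstance(source, (str, Path)):
            try:
                labels = tifffile.imread(source)
                contours = contours_from_labels(labels, cfg.pixel_size)
            except Exception as exc:  # per-file failure: log and continue
                log.warning("shape: skipping %s (%s)", source, exc)
                n_failed += 1
                continue
        else:
            contours = source
        rows = []
        for c in contours:
            try:
                tab = descriptors_table([c], cfg.spacing_um)
                rows.append(tab)
            except Exception as exc:
                log.warning("shape: cell %s of strain %s failed (%s)", c.cell_id, strain, exc)
                n_failed += 1
        if rows:
            df = pd.concat(rows, ignore_index=True)
            df.insert(0, "strain", strain)
            frames.append(df)

    cols = [
        "strain",
        "cell_id",
        "solidity",
        "lateral_asymmetry",
        "longitudinal_asymmetry",
        "width_variation_um",
        "mean_width_um",
        "length_um",
    ]
    per_cell = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)
    if len(per_cell):
        per_strain = per_cell.groupby("strain").median(numeric_only=True).reset_index()
    else:
        per_strain = pd.DataFrame(columns=cols[:1])
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        per_cell.to_csv(out / "shape_per_cell.csv", index=False)
        per_strain.to_csv(out / "shape_per_strain.csv", index=False)
    return per_cell, per_strain
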