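"""Run configuration and end-to-end pipeline orchestration.

A run is described by a :class:`RunConfig` (serializable to YAML and
back unchanged), executed into a flat run directory with stage-numbered
outputs and a log recording every parameter and derived seed, so that
identical config + seed reproduces identical summary tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .colocalization import (
    ColocalizationCriterion,
    aggregate_fields,
    classify_droplets,
    extract_centers,
)
from .registration import PlanarTransform, detect_beads, estimate_transform, match_points
from .segmentation import image_stats, segment_image
from .synthetic import (
    CompositionModel,
    ImagingConfig,
    render_bead_field,
    render_channels,
    sample_droplet_field,
)

__all__ = ["RunConfig", "run_pipeline", "run_synthetic_study"]

MODES = ("simulate", "segment", "register", "coloc", "stats", "run-all")


@dataclass
class RunConfig:
    """Parameters for every stage plus the master seed.

    Seeds for stochastic stages are derived deterministically from
    ``seed``; unset input paths are only required by the modes that read
    them.
    """

    mode: str = "run-all"
    seed: int = 0

    # -- simulation --
    n_fields: int = 6
    field_size_px: tuple[int, int] = (1024, 1024)
    pixel_size_nm: float = 114.17
    droplets_per_field: int = 420
    p_heterotypic: float = 0.447
    p_green_only: float = 0.122
    p_red_only: float = 0.431
    radius_log_median_nm: float = 500.0
    radius_log_sigma: float = 0.3
    psf_sigma_nm: float = 150.0
    background: float = 20.0
    read_noise_sd: float = 2.0
    channel_shift_nm: tuple[float, float] = (0.0, 0.0)
    channel_rotation_deg: float = 0.0
    channel_scale: float = 1.0
    n_beads: int = 40

    # -- segmentation --
    threshold_method: str = "otsu"
    min_area_px: int = 5
    connectivity: int = 8

    # -- registration --
    transform_model: str = "similarity"
    bead_min_separation_nm: float = 1000.0
    bead_match_max_nm: float = 1500.0

    # -- colocalization --
    max_distance_nm: float = 500.0
    circularity_min: float = 0.8
    exclude_overlapping: bool = False

    # -- external inputs (non-simulate modes) --
    input_images: list[str] = field(default_factory=list)
    bead_image_green: str = ""
    bead_image_red: str = ""
    transform_file: str = ""
    green_images: list[str] = field(default_factory=list)
    red_images: list[str] = field(default_factory=list)
    summary_csvs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    # -- (de)serialization: round-trips unchanged --

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["field_size_px"] = list(self.field_size_px)
        d["channel_shift_nm"] = list(self.channel_shift_nm)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("field_size_px", "channel_shift_nm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    # -- derived objects --

    def composition(self) -> CompositionModel:
        return CompositionModel(
            self.p_heterotypic,
            self.p_green_only,
            self.p_red_only,
            self.radius_log_median_nm,
            self.radius_log_sigma,
        )

    def imaging(self, seed: int) -> ImagingConfig:
        return ImagingConfig(
            pixel_size_nm=self.pixel_size_nm,
            psf_sigma_nm=self.psf_sigma_nm,
            background=self.background,
            read_noise_sd=self.read_noise_sd,
            channel_transform=self.true_channel_transform(),
            seed=seed,
        )

    def true_channel_transform(self) -> PlanarTransform:
        return PlanarTransform.from_similarity(
            self.channel_scale,
            np.deg2rad(self.channel_rotation_deg),
            *self.channel_shift_nm,
        )


def _child_seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2**31)]


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the configured stages into ``out_dir`` and return it.

    The run directory is flat with stage-numbered files; a ``run_log.json``
    records the full config and derived seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {"config": config.to_dict(), "derived_seeds": {}}

    if config.mode in ("simulate", "run-all"):
        _stage_simulate(config, out, log)
    if config.mode == "segment":
        _stage_segment_external(config, out)
    if config.mode in ("register", "run-all"):
        _stage_register(config, out, log)
    if config.mode in ("coloc", "run-all"):
        _stage_coloc(config, out)
    if config.mode == "stats":
        _stage_stats(config, out)

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    config.to_yaml(out / "config.yaml")
    return out


def run_synthetic_study(config: RunConfig, correct_registration: bool = True) -> dict:
    """Simulate one multi-field colocalization study and analyse it in memory.

    Renders ``config.n_fields`` two-channel droplet fields (red channel
    through the configured true misregistration) plus a bead calibration
    pair, estimates the red->green transform from the beads, extracts
    droplet centers per channel, classifies them with and without the
    estimated correction, and aggregates percentages across fields.

    Returns a dict with keys ``aggregate`` (corrected
    :class:`FieldAggregate` if ``correct_registration`` else raw),
    ``aggregate_uncorrected``, ``true_pct`` (realized ground-truth
    composition percentages pooled over fields), ``true_n``,
    ``transform`` (the estimated red->green transform) and
    ``bead_residual_rms_nm``.
    """
    seeds = _child_seeds(config.seed, config.n_fields + 1)
    px = config.pixel_size_nm
    field_nm = (config.field_size_px[0] * px, config.field_size_px[1] * px)
    criterion = ColocalizationCriterion(config.max_distance_nm)

    bead_g, bead_r, _ = render_bead_field(
        config.n_beads, config.true_channel_transform(), config.imaging(seed=seeds[-1]),
        seed=seeds[-1],
    )
    pts_g = detect_beads(bead_g, config.bead_min_separation_nm)
    pts_r = detect_beads(bead_r, config.bead_min_separation_nm)
    matches = match_points(pts_r, pts_g, config.bead_match_max_nm)
    est_tf = estimate_transform(matches, model=config.transform_model)

    results_cor, results_unc = [], []
    true_counts = {"heterotypic": 0, "greenOnly": 0, "redOnly": 0}
    for s in seeds[:-1]:
        truth = sample_droplet_field(
            config.composition(), config.droplets_per_field, field_nm, px, seed=s
        )
        for comp, c in truth.composition_counts().items():
            true_counts[comp] += c
        green, red = render_channels(truth, config.imaging(seed=s))
        pg = extract_centers(green, config.circularity_min, config.exclude_overlapping,
                             config.threshold_method, config.min_area_px)
        pr = extract_centers(red, config.circularity_min, config.exclude_overlapping,
                             config.threshold_method, config.min_area_px)
        cg = np.array([p.ellipse_center_nm for p in pg]).reshape(-1, 2)
        cr = np.array([p.ellipse_center_nm for p in pr]).reshape(-1, 2)
        results_unc.append(classify_droplets(cg, cr, criterion))
        cr_cor = est_tf(cr) if len(cr) else cr
        results_cor.append(classify_droplets(cg, cr_cor, criterion))

    n_true = sum(true_counts.values())
    true_pct = {k: 100.0 * v / n_true for k, v in true_counts.items()}
    agg_cor = aggregate_fields(results_cor)
    agg_unc = aggregate_fields(results_unc)
    return {
        "aggregate": agg_cor if correct_registration else agg_unc,
        "aggregate_corrected": agg_cor,
        "aggregate_uncorrected": agg_unc,
        "true_pct": true_pct,
        "true_n": n_true,
        "transform": est_tf,
        "bead_residual_rms_nm": matches.residual_rms_nm,
    }


def _stage_simulate(config: RunConfig, out: Path, log: dict) -> None:
    seeds = _child_seeds(config.seed, config.n_fields + 1)
    log["derived_seeds"]["fields"] = seeds[:-1]
    log["derived_seeds"]["beads"] = seeds[-1]
    px = config.pixel_size_nm
    field_nm = (config.field_size_px[0] * px, config.field_size_px[1] * px)
    for i, s in enumerate(seeds[:-1]):
        truth = sample_droplet_field(
            config.composition(), config.droplets_per_field, field_nm, px, seed=s
        )
        green, red = render_channels(truth, config.imaging(seed=s))
        dio.write_image(green, out / f"01_field{i:02d}_green.tif")
        dio.write_image(red, out / f"01_field{i:02d}_red.tif")
        truth.to_dataframe().to_csv(out / f"01_field{i:02d}_truth.csv", index=False)
    bead_g, bead_r, coords = render_bead_field(
        config.n_beads, config.true_channel_transform(), config.imaging(seed=seeds[-1]),
        seed=seeds[-1],
    )
    dio.write_image(bead_g, out / "01_beads_green.tif")
    dio.write_image(bead_r, out / "01_beads_red.tif")
    dio.write_centers_csv(coords, "bead_truth", out / "01_beads_truth.csv")


def _stage_segment_external(config: RunConfig, out: Path) -> None:
    rows = []
    for path in config.input_images:
        img = dio.read_image(path)
        particles = segment_image(
            img, config.threshold_method, config.min_area_px, config.connectivity
        )
        name = Path(path).stem
        dio.write_particles_csv(particles, out / f"02_{name}_particles.csv")
        rows.append(dio.stats_row(name, image_stats(particles)))
    pd.DataFrame(rows).to_csv(out / "02_summary.csv", index=False)


def _estimate_channel_transform(config: RunConfig, green, red) -> PlanarTransform:
    """Fit the red->green frame transform from a bead image pair."""
    if green.pixel_size_nm != red.pixel_size_nm:
        raise ValueError(
            f"inconsistent pixel sizes between channels: "
            f"{green.pixel_size_nm} vs {red.pixel_size_nm} nm"
        )
    pts_g = detect_beads(green, config.bead_min_separation_nm)
    pts_r = detect_beads(red, config.bead_min_separation_nm)
    matches = match_points(pts_r, pts_g, config.bead_match_max_nm)
    return estimate_transform(matches, model=config.transform_model)


def _stage_register(config: RunConfig, out: Path, log: dict) -> None:
    if config.mode == "register":
        green = dio.read_image(config.bead_image_green, channel="green")
        red = dio.read_image(config.bead_image_red, channel="red")
    else:  # run-all: use the simulated bead pair
        green = dio.read_image(out / "01_beads_green.tif")
        red = dio.read_image(out / "01_beads_red.tif")
    tf = _estimate_channel_transform(config, green, red)
    tf.to_json(out / "03_transform.json")
    log["registration_model"] = tf.model


def _field_image_pairs(config: RunConfig, out: Path):
    if config.mode == "coloc" and config.green_images:
        for g, r in zip(config.green_images, config.red_images):
            yield Path(g).stem, dio.read_image(g, channel="green"), dio.read_image(r, channel="red")
    else:  # run-all: the simulated fields
        for i in range(config.n_fields):
            yield (
                f"field{i:02d}",
                dio.read_image(out / f"01_field{i:02d}_green.tif"),
                dio.read_image(out / f"01_field{i:02d}_red.tif"),
            )


def _stage_coloc(config: RunConfig, out: Path) -> None:
    tf_path = Path(config.transform_file) if config.transform_file else out / "03_transform.json"
    transform = PlanarTransform.from_json(tf_path) if tf_path.exists() else None
    criterion = ColocalizationCriterion(config.max_distance_nm)
    results = []
    pair_rows, class_rows = [], []
    for name, green, red in _field_image_pairs(config, out):
        if green.pixel_size_nm != red.pixel_size_nm:
            raise ValueError(
                f"inconsistent pixel sizes for field {name}: "
                f"{green.pixel_size_nm} vs {red.pixel_size_nm} nm"
            )
        pg = extract_centers(green, config.circularity_min, config.exclude_overlapping,
                             config.threshold_method, config.min_area_px)
        pr = extract_centers(red, config.circularity_min, config.exclude_overlapping,
                             config.threshold_method, config.min_area_px)
        centers_g = np.array([p.ellipse_center_nm for p in pg]).reshape(-1, 2)
        centers_r = np.array([p.ellipse_center_nm for p in pr]).reshape(-1, 2)
        if transform is not None and len(centers_r):
            centers_r = transform(centers_r)
        res = classify_droplets(centers_g, centers_r, criterion)
        results.append(res)
        for g, r, d in res.heterotypic_pairs:
            pair_rows.append({"field": name, "green_id": g, "red_id": r, "distance_nm": d})
        class_rows.append(
            {
                "field": name,
                "n_total": res.n_total,
                "n_heterotypic": len(res.heterotypic_pairs),
                "n_green_only": len(res.green_only),
                "n_red_only": len(res.red_only),
                "pct_heterotypic": res.pct_heterotypic,
                "pct_green_only": res.pct_green_only,
                "pct_red_only": res.pct_red_only,
            }
        )
    pd.DataFrame(pair_rows).to_csv(out / "04_pairs.csv", index=False)
    pd.DataFrame(class_rows).to_csv(out / "04_classification.csv", index=False)
    agg = aggregate_fields(results)
    pd.DataFrame(
        [
            {
                "class": cls,
                "mean_pct": agg.mean_pct[cls],
                "sd_pct": agg.sd_pct[cls],
                "n_pooled": agg.n_pooled,
            }
            for cls in ("heterotypic", "greenOnly", "redOnly")
        ]
    ).to_csv(out / "05_aggregate.csv", index=False)


def _stage_stats(config: RunConfig, out: Path) -> None:
    from .stats import ConditionGroup, anova_bonferroni

    groups_counts, groups_vol = [], []
    for name, path in config.summary_csvs.items():
        df = pd.read_csv(path)
        groups_counts.append(ConditionGroup(name, df["particle_count"].astype(float).tolist()))
        vols = df["mean_volume_um3"].dropna().astype(float).tolist()
        groups_vol.append(ConditionGroup(name, vols))
    rows = []
    for quantity, groups in (("count", groups_counts), ("mean_volume_um3", groups_vol)):
        rep = anova_bonferroni(groups)
        for pw in rep.pairwise:
            rows.append(
                {
                    "quantity": quantity,
                    "group_a": pw.group_a,
                    "group_b": pw.group_b,
                    "mean_diff": pw.mean_diff,
                    "raw_p": pw.raw_p,
                    "adjusted_p": pw.adjusted_p,
                    "stars": pw.stars,
                    "anova_f": rep.f_statistic,
                    "anova_p": rep.overall_p,
                }
            )
    pd.DataFrame(rows).to_csv(out / "06_comparisons.csv", index=False)
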