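"""End-to-end orchestration: simulate -> morphometry -> intensity ->
expression -> stats, as one reproducible, seeded run.

A single top-level seed is fanned out to per-stage child seeds by a fixed
affine derivation (``child = (seed * 1_000_003 + k) mod 2^31``) so any
stage can be re-run in isolation and the whole run is deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import expression as expr
from . import intensity as inten
from . import morphometry as morph
from . import stats as st
from . import synthetic as syn

log = logging.getLogger("spindlemorph")

#: Default qPCR fold-change settings used for the synthetic Ct tables
#: (genes the study reported as unchanged are set to 1.0).
QPCR_FOLDS: dict[str, float] = {
    "Egr3": 3.5, "Myod1": 1.49, "Myf5": 1.0, "Myog": 1.0,
    "Myh1": 0.49, "Myh2": 0.51, "Myh3": 0.76, "Myh4": 2.17,
    "Myh6": 0.44, "Myh7": 0.58, "Myh8": 0.16, "Myh13": 1.0,
    "Myh7b/14": 1.0, "Etv4": 2.88, "Gdnf": 1.0, "Prph": 1.0, "Sstr2": 1.0,
}

#: Default western-blot adjusted-relative-density folds.
BLOT_FOLDS: dict[str, float] = {
    "MyHC3": 0.27, "MyHC8": 0.43, "MyHC6": 0.54, "Egr3": 2.24,
}

VIABILITY_FOLD = 1.15


def child_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2 ** 31)


@dataclass
class RunConfig:
    seed: int = 0
    n_fields: int = 9
    fov_shape: tuple[int, int] = (1024, 1024)
    conditions: tuple[str, ...] = ("control", "nrg1")
    thresholds_source: str = "summary"   # summary | train | file
    thresholds_file: str | None = None
    training_per_class: int = 10
    denominator: str = "all"
    ct_noise_sd: float = 0.15
    blot_noise_cv: float = 0.05
    assay_noise_cv: float = 0.03
    stages: tuple[str, ...] = ("simulate", "morpho", "intensity",
                               "expression", "stats")
    write_images: bool = False
    out_dir: str = "spindlemorph_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                if f.name in ("fov_shape", "conditions", "stages"):
                    v = tuple(v)
                kwargs[f.name] = v
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fov_shape"] = list(self.fov_shape)
        d["conditions"] = list(self.conditions)
        d["stages"] = list(self.stages)
        return d


def train_thresholds(seed: int, per_class: int = 10,
                     pixel_size: float = 0.65) -> morph.DdrThresholds:
    """Derive classification cutoffs from rendered training fibres.

    Mirrors the manual training procedure: ``per_class`` exemplars of each
    morphology are rendered in isolation, their DDR measured by the medial-
    axis profile, and the cutoffs derived from per-class mean +- sample SD.
    """
    rng = np.random.default_rng(seed)
    measured: dict[str, list[float]] = {syn.LINEAR: [], syn.BAG: []}
    params = syn.CONTROL
    for kind, mean, sd in ((syn.LINEAR, params.linear_ddr_mean, params.linear_ddr_sd),
                           (syn.BAG, params.bag_ddr_mean, params.bag_ddr_sd)):
        while len(measured[kind]) < per_class:
            ddr = syn._draw_truncated_normal(rng, mean, sd, low=1.05)
            mg, mask = syn.render_single_fibre(
                kind, ddr, w_min_um=rng.uniform(8, 12),
                theta=rng.uniform(0, np.pi / 8), pixel_size=pixel_size,
                fov_shape=(512, 768))
            inst = morph.MyotubeInstance(id=0, mask=mask, pixel_size=pixel_size,
                                         nuclei_count=3,
                                         area_um2=mask.sum() * pixel_size ** 2)
            try:
                morph.width_profile(inst)
                measured[kind].append(morph.compute_ddr(inst))
            except morph.UnmeasurableInstanceError:
                continue
    return morph.derive_thresholds(measured[syn.LINEAR], measured[syn.BAG])


def _resolve_thresholds(config: RunConfig) -> morph.DdrThresholds:
    if config.thresholds_source == "summary":
        return morph.PUBLISHED_THRESHOLDS
    if config.thresholds_source == "train":
        return train_thresholds(child_seed(config.seed, 17),
                                per_class=config.training_per_class)
    if config.thresholds_source == "file":
        if not config.thresholds_file:
            raise ValueError("thresholds_source 'file' needs thresholds_file")
        with open(config.thresholds_file) as fh:
            d = yaml.safe_load(fh)
        return morph.DdrThresholds(d["linear_mean"], d["linear_sd"],
                                   d["bag_mean"], d["bag_sd"])
    raise ValueError(f"unknown thresholds_source {config.thresholds_source!r}")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the enabled stages in order; fail fast on stage errors.

    Returns the run report (also written to ``<out_dir>/report.json``
    together with the serialised config and per-stage CSVs).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    (out / "config.yaml").write_text(cfg_yaml)
    report: dict[str, Any] = {
        "software_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16],
    }

    fields: dict[str, list[syn.SyntheticField]] = {}
    if "simulate" in config.stages:
        log.info("simulating %d fields per arm", config.n_fields)
        for arm_idx, name in enumerate(config.conditions):
            params = syn.CONDITIONS[name]
            fields[name] = [
                syn.generate_field(params, child_seed(config.seed, 100 * arm_idx + i),
                                   fov_shape=config.fov_shape)
                for i in range(config.n_fields)
            ]
            truth = pd.concat(
                [f.ground_truth.assign(field=i) for i, f in enumerate(fields[name])],
                ignore_index=True)
            truth.to_csv(out / f"ground_truth_{name}.csv", index=False)
            if config.write_images:
                for i, f in enumerate(fields[name]):
                    f.micrograph.to_tiff(out / "images", f"{name}_{i:03d}")
        report["simulate"] = {
            name: {"n_fields": len(fs),
                   "true_bag_fraction": _true_bag_fraction(fs)}
            for name, fs in fields.items()}

    analyses: dict[str, list] = {}
    if "morpho" in config.stages:
        if not fields:
            raise RuntimeError("morpho stage needs the simulate stage")
        thresholds = _resolve_thresholds(config)
        with open(out / "thresholds.yaml", "w") as fh:
            yaml.safe_dump(thresholds.to_dict(), fh)
        rows = []
        for name, fs in fields.items():
            analyses[name] = []
            for i, f in enumerate(fs):
                insts, summary, centroids = morph.analyze_field(
                    f.micrograph, thresholds, denominator=config.denominator)
                analyses[name].append((f, insts, summary, centroids))
                for inst in insts:
                    rows.append({"condition": name, "field": i, "id": inst.id,
                                 "d_max": inst.d_max, "d_min": inst.d_min,
                                 "ddr": inst.ddr, "class": inst.assigned_class,
                                 "nuclei": inst.nuclei_count,
                                 "area_um2": inst.area_um2})
        pd.DataFrame(rows).to_csv(out / "myotubes.csv", index=False)
        report["morpho"] = {
            "thresholds": thresholds.to_dict(),
            "field_summaries": {
                name: [dataclasses.asdict(s) for (_, _, s, _) in items]
                for name, items in analyses.items()},
        }
        report["bag_fraction_contrast"] = {
            name: float(np.mean([s.bag_pct for (_, _, s, _) in items]))
            for name, items in analyses.items()}

    if "intensity" in config.stages:
        if not analyses:
            raise RuntimeError("intensity stage needs the morpho stage")
        negative = syn.generate_primary_negative(child_seed(config.seed, 31))
        calib = inten.calibrate_background(negative)
        with open(out / "calibration.yaml", "w") as fh:
            yaml.safe_dump(calib.to_dict(), fh)
        per_field, per_myotube = [], []
        for name, items in analyses.items():
            for i, (f, insts, summary, centroids) in enumerate(items):
                corrected = inten.subtract_background(
                    f.micrograph.channel("marker"), calib)
                value, _ = inten.intensity_per_nucleus(corrected, len(centroids))
                per_field.append({"condition": name, "field": i,
                                  "coverage_pct": inten.coverage(corrected),
                                  "intensity_per_nucleus": value})
                for inst in insts:
                    per_myotube.append({
                        "condition": name, "field": i, "id": inst.id,
                        "class": inst.assigned_class,
                        "mean_intensity": inten.myotube_mean_intensity(
                            corrected, inst.mask),
                        "nuclei": inst.nuclei_count})
        pf = pd.DataFrame(per_field)
        pm = pd.DataFrame(per_myotube)
        control_mean = pf.loc[pf["condition"] == "control",
                              "intensity_per_nucleus"].mean()
        pf["fold_vs_control"] = pf["intensity_per_nucleus"] / control_mean
        pf.to_csv(out / "intensity_fields.csv", index=False)
        pm.to_csv(out / "intensity_myotubes.csv", index=False)
        report["intensity"] = {
            "background_threshold": calib.background_threshold,
            "coverage_pct": pf.groupby("condition")["coverage_pct"].mean().to_dict(),
            "intensity_per_nucleus_fold": pf.groupby("condition")[
                "fold_vs_control"].mean().to_dict(),
        }
        report["_per_myotube_intensity"] = pm

    if "expression" in config.stages:
        ct = syn.generate_ct_table(QPCR_FOLDS, n_samples=config.n_fields,
                                   ct_noise_sd=config.ct_noise_sd,
                                   seed=child_seed(config.seed, 41))
        records = expr.relative_expression(ct)
        folds = (records[records["condition"] == "treated"]
                 .groupby("gene")["fold_change"].mean())
        blot = syn.generate_blot_table(BLOT_FOLDS, seed=child_seed(config.seed, 43),
                                       noise_cv=config.blot_noise_cv)
        blot = expr.adjusted_relative_density(blot)
        blot_folds = (blot[blot["condition"] == "treated"]
                      .groupby("target")["adjusted_relative_density"].mean())
        assay = syn.generate_assay_table(VIABILITY_FOLD,
                                         noise_cv=config.assay_noise_cv,
                                         seed=child_seed(config.seed, 47))
        viability = expr.viability_fold(assay)
        records.to_csv(out / "expression.csv", index=False)
        blot.to_csv(out / "blot.csv", index=False)
        report["expression"] = {
            "qpcr_folds": {g: float(v) for g, v in folds.items()},
            "blot_folds": {t: float(v) for t, v in blot_folds.items()},
            "viability_fold": float(
                viability.set_index("condition")
                .loc["treated", "fold_vs_control"]),
        }

    if "stats" in config.stages:
        if not analyses:
            raise RuntimeError("stats stage needs the morpho stage")
        stats_report: dict[str, Any] = {}
        bag = {name: [s.bag_pct for (_, _, s, _) in items]
               for name, items in analyses.items()}
        res = st.gated_two_group_test(bag["control"], bag["nrg1"],
                                      labels=("control", "nrg1"))
        stats_report["bag_pct"] = _stat_result_dict(res)
        nuc = {name: [s.nuclei_per_fov for (_, _, s, _) in items]
               for name, items in analyses.items()}
        res = st.gated_two_group_test(nuc["control"], nuc["nrg1"],
                                      labels=("control", "nrg1"))
        stats_report["nuclei_per_fov"] = _stat_result_dict(res)

        counts = []
        for name, items in analyses.items():
            for _, insts, _, _ in items:
                for inst in insts:
                    if inst.assigned_class in (morph.LINEAR, morph.BAG):
                        counts.append({"treatment": name,
                                       "myotype": inst.assigned_class,
                                       "nuclei": inst.nuclei_count})
        counts_df = pd.DataFrame(counts)
        if len(counts_df) >= 10 and counts_df["myotype"].nunique() == 2:
            nb = st.nuclei_count_model(counts_df, "nuclei", "treatment", "myotype")
            stats_report["nuclei_count_model"] = {
                "rate_ratios": nb.rate_ratios, "p_values": nb.p_values,
                "dispersion_alpha": nb.dispersion_alpha}

        pm = report.pop("_per_myotube_intensity", None)
        if pm is not None:
            pm = pm[pm["class"].isin([morph.LINEAR, morph.BAG])]
            try:
                anova = st.two_way_anova_tukey(pm, "mean_intensity",
                                               "condition", "class",
                                               transform="sqrt")
                stats_report["egr3_intensity_anova"] = {
                    "treatment_p": anova.effect_p("condition"),
                    "type_p": anova.effect_p("class"),
                    "interaction_p": anova.effect_p(":"),
                    "transform": anova.transform,
                }
            except ValueError as e:
                stats_report["egr3_intensity_anova"] = {"skipped": str(e)}
        report["stats"] = stats_report

    report.pop("_per_myotube_intensity", None)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)
    return report


def _true_bag_fraction(fs: list[syn.SyntheticField]) -> float:
    total = sum(len(f.ground_truth) for f in fs)
    if total == 0:
        return float("nan")
    bags = sum((f.ground_truth["true_class"] == syn.BAG).sum() for f in fs)
    return float(bags / total)


def _stat_result_dict(res: st.StatResult) -> dict:
    return {"effect": res.effect, "estimate": res.estimate,
            "statistic": res.statistic, "p_value": res.p_value,
            "stars": res.stars, "group_means": res.group_means,
            "group_sems": res.group_sems, "n": res.n,
            "chosen_test": res.details.get("chosen_test")}


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(obj)}")
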