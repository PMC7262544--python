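"""Config-driven end-to-end runs.

A single YAML config describes a run: a seed, an output directory, a
significance level and an ordered list of stages (synthetic plate
generation, halo quantification, liquid-CAS calibration and quantification,
group comparisons, PCA, enrichment factors, MS annotation, profile
comparison).  Every output CSV carries the config hash and the seed as
comment lines, so a rerun with an identical config is byte-identical for
the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import halo, liquid, msannot, stats, synthetic

__all__ = ["ConfigError", "validate_config", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

STAGES = (
    "generate_plate",
    "quantify_halos",
    "cas_calibrate",
    "cas_quantify",
    "compare_groups",
    "pca",
    "enrichment",
    "ms_annotate",
    "profile_compare",
)

_DEFAULTS: dict[str, Any] = {"alpha": 0.05, "seed": 0, "outdir": "results", "stages": []}

# output-path keys (with defaults) each stage declares; later stages may
# reference these as inputs before they exist on disk
_OUTPUT_KEYS: dict[str, tuple[tuple[str, str], ...]] = {
    "generate_plate": (("image_out", "plate.png"), ("truth_out", "ground_truth.csv"),
                       ("crops_out", "crops.yaml")),
    "quantify_halos": (("out", "halo_measurements.csv"),
                       ("aggregates_out", "halo_aggregates.csv")),
    "cas_calibrate": (("out", "calibration.yaml"),),
    "cas_quantify": (("out", "dfob_equivalents.csv"),),
    "compare_groups": (),
    "pca": (),
    "enrichment": (("out", "enrichment_factors.csv"),),
    "ms_annotate": (("out", "annotations.csv"),),
    "profile_compare": (),
}

# input-path keys checked for existence per stage
_PATH_KEYS: dict[str, tuple[str, ...]] = {
    "quantify_halos": ("image",),
    "cas_calibrate": ("standards",),
    "cas_quantify": ("samples", "model"),
    "compare_groups": ("table",),
    "pca": ("table",),
    "enrichment": ("table",),
    "ms_annotate": ("features", "refs"),
    "profile_compare": ("profiles",),
}


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(["config must be a mapping"])
    return cfg


def validate_config(config: dict, base_dir: str | Path = ".") -> dict:
    """Fill defaults and collect every violation; raises ConfigError if any.

    Input paths must exist at validation time, except files that an earlier
    ``generate_plate`` stage of the same run will create.
    """
    base = Path(base_dir)
    cfg = dict(_DEFAULTS)
    cfg.update(config or {})
    errors: list[str] = []

    if not isinstance(cfg["alpha"], (int, float)) or not 0 < cfg["alpha"] < 1:
        errors.append(f"alpha: must be in (0, 1), got {cfg['alpha']!r}")
    if not isinstance(cfg["seed"], int):
        errors.append(f"seed: must be an integer, got {cfg['seed']!r}")
    if not isinstance(cfg["stages"], list):
        errors.append("stages: must be a list")
        cfg["stages"] = []

    outdir = base / str(cfg["outdir"])
    generated: set[str] = set()
    for i, stage in enumerate(cfg["stages"]):
        where = f"stages[{i}]"
        if not isinstance(stage, dict) or "stage" not in stage:
            errors.append(f"{where}: each stage needs a 'stage' key")
            continue
        name = stage["stage"]
        if name not in STAGES:
            errors.append(f"{where}: unknown stage {name!r}; known: {', '.join(STAGES)}")
            continue
        for key in _PATH_KEYS.get(name, ()):
            if key not in stage:
                errors.append(f"{where} ({name}): missing required input {key!r}")
                continue
            rel = str(stage[key])
            if rel in generated:
                continue
            if not (base / rel).exists() and not (outdir / rel).exists():
                errors.append(f"{where} ({name}): path not found: {rel}")
        generated.update(str(stage.get(k, d)) for k, d in _OUTPUT_KEYS.get(name, ()))
    if errors:
        raise ConfigError(errors)
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str, seed: int, **index_kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={cfg_hash}\n# seed={seed}\n")
        df.to_csv(fh, **index_kw)


def _resolve(rel: str, base: Path, outdir: Path) -> Path:
    p = base / rel
    if p.exists():
        return p
    return outdir / rel


def run_pipeline(config: dict, base_dir: str | Path = ".") -> dict:
    """Execute the configured stages in order; returns a run report dict.

    A stage failure halts the run with an error naming the stage.  All
    randomness flows through the single configured seed.
    """
    base = Path(base_dir)
    cfg = validate_config(config, base_dir=base)
    cfg_hash = _config_hash(cfg)
    seed = int(cfg["seed"])
    outdir = base / str(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config_sha256": cfg_hash, "seed": seed, "stages": []}

    handlers: dict[str, Callable[[dict], dict]] = {}

    def _stage_generate_plate(stage: dict) -> dict:
        rng = np.random.default_rng(seed)
        spec, crops = synthetic.random_plate_spec(
            rng,
            n_colonies=int(stage.get("n_colonies", 3)),
            noise_sd=float(stage.get("noise_sd", 0.0)),
        )
        image, truth = synthetic.generate_plate(spec)
        from PIL import Image

        image_out = outdir / stage.get("image_out", "plate.png")
        Image.fromarray(image, mode="L").save(image_out)
        truth_df = pd.DataFrame(
            {
                "colony": range(len(truth.colony_counts)),
                "n_colony_true": truth.colony_counts,
                "n_halo_true": truth.halo_counts,
                "ratio_true": [truth.ratio(i) for i in range(len(truth.colony_counts))],
            }
        )
        truth_out = outdir / stage.get("truth_out", "ground_truth.csv")
        _write_csv(truth_df, truth_out, cfg_hash, seed, index=False)
        crops_out = outdir / stage.get("crops_out", "crops.yaml")
        with open(crops_out, "w") as fh:
            yaml.safe_dump(
                {"crops": [{"crop": list(c), "id": f"crop{i}"} for i, c in enumerate(crops)],
                 "seed": seed},
                fh,
            )
        return {"image": str(image_out), "truth": str(truth_out), "crops": str(crops_out)}

    def _stage_quantify_halos(stage: dict) -> dict:
        image = halo.load_image(_resolve(stage["image"], base, outdir))
        if "crops" in stage:
            crop_defs = stage["crops"]
        else:
            with open(_resolve(stage["crops_file"], base, outdir)) as fh:
                crop_defs = yaml.safe_load(fh)["crops"]
        entries = []
        for i, cd in enumerate(crop_defs):
            r0, c0, r1, c1 = cd["crop"]
            thresholds = None
            if "tC" in cd and "tH" in cd:
                thresholds = halo.ThresholdPair(int(cd["tC"]), int(cd["tH"]))
            entries.append(
                halo.CropEntry(
                    region=halo.CropRegion(r0, c0, r1, c1),
                    thresholds=thresholds,
                    condition=cd.get("condition"),
                    crop_id=cd.get("id", f"crop{i}"),
                )
            )
        result = halo.quantify_plate(image, entries)
        for crop_id, reason in result.failures:
            logger.warning("WARN excluded crop %s: %s", crop_id, reason)
        meas_out = outdir / stage.get("out", "halo_measurements.csv")
        _write_csv(result.to_frame(), meas_out, cfg_hash, seed, index=False)
        agg_out = outdir / stage.get("aggregates_out", "halo_aggregates.csv")
        _write_csv(result.aggregates, agg_out, cfg_hash, seed, index=False)
        return {"measurements": str(meas_out), "aggregates": str(agg_out),
                "n_failures": len(result.failures)}

    def _stage_cas_calibrate(stage: dict) -> dict:
        standards = pd.read_csv(_resolve(stage["standards"], base, outdir), comment="#")
        model = liquid.fit_calibration(
            standards["conc_uM"], standards["response_pct"],
            free_ceiling=bool(stage.get("free_ceiling", False)),
        )
        out = outdir / stage.get("out", "calibration.yaml")
        with open(out, "w") as fh:
            yaml.safe_dump(
                {"model": model.to_dict(), "config_sha256": cfg_hash, "seed": seed}, fh
            )
        return {"model": str(out), "k_per_uM": model.k}

    def _stage_cas_quantify(stage: dict) -> dict:
        with open(_resolve(stage["model"], base, outdir)) as fh:
            model = liquid.CalibrationModel.from_dict(yaml.safe_load(fh)["model"])
        samples = pd.read_csv(_resolve(stage["samples"], base, outdir), comment="#")
        rows = []
        for _, row in samples.iterrows():
            dilution = float(row.get("dilution", 1.0))
            equiv = liquid.to_dfob_equivalents(float(row["response_pct"]), model, dilution)
            rows.append(
                {
                    "sample": row.get("sample"),
                    "response_pct": row["response_pct"],
                    "dilution": dilution,
                    "dfob_equivalents_uM": equiv,
                }
            )
        out = outdir / stage.get("out", "dfob_equivalents.csv")
        _write_csv(pd.DataFrame(rows), out, cfg_hash, seed, index=False)
        return {"results": str(out)}

    def _stage_compare_groups(stage: dict) -> dict:
        table = pd.read_csv(_resolve(stage["table"], base, outdir), comment="#")
        value_col = stage.get("value_col", "value")
        groups = {
            str(label): sub[value_col].to_numpy()
            for label, sub in table.groupby(stage.get("group_col", "group"), sort=False)
        }
        alpha = float(stage.get("alpha", cfg["alpha"]))
        test = stage.get("test", "kw")
        if test == "kw":
            result = stats.dunn_bonferroni(groups, alpha=alpha)
        elif test == "anova":
            result = stats.fisher_lsd(groups, alpha=alpha)
        else:
            raise ValueError(f"unknown test {test!r}; use 'kw' or 'anova'")
        out = outdir / stage.get("out", f"pairwise_{test}.csv")
        _write_csv(result.pairwise, out, cfg_hash, seed, index=False)
        letters_out = outdir / stage.get("letters_out", f"letters_{test}.txt")
        with open(letters_out, "w") as fh:
            fh.write(f"# config_sha256={cfg_hash}\n# seed={seed}\n")
            fh.write(f"# test={result.test} statistic={result.statistic:.6g} "
                     f"p={result.pvalue:.6g} alpha={alpha}\n")
            for label, letters in result.letters.items():
                fh.write(f"{label}\t{letters}\n")
        return {"pairwise": str(out), "letters": str(letters_out),
                "statistic": result.statistic, "pvalue": result.pvalue}

    def _stage_pca(stage: dict) -> dict:
        table = pd.read_csv(_resolve(stage["table"], base, outdir), comment="#")
        matrix = stats.pivot_elements(
            table,
            sample_col=stage.get("sample_col", "sample"),
            element_col=stage.get("element_col", "element"),
            value_col=stage.get("value_col", "concentration_ug_ml"),
        )
        result = stats.pca(matrix, standardize=bool(stage.get("standardize", True)))
        prefix = stage.get("out_prefix", "pca")
        scores_out = outdir / f"{prefix}_scores.csv"
        loadings_out = outdir / f"{prefix}_loadings.csv"
        var_out = outdir / f"{prefix}_variance.csv"
        _write_csv(result.scores, scores_out, cfg_hash, seed)
        _write_csv(result.loadings, loadings_out, cfg_hash, seed)
        _write_csv(
            pd.DataFrame(
                {
                    "component": result.scores.columns,
                    "variance_explained_pct": result.variance_explained_pct,
                }
            ),
            var_out, cfg_hash, seed, index=False,
        )
        return {"scores": str(scores_out), "loadings": str(loadings_out),
                "variance": str(var_out)}

    def _stage_enrichment(stage: dict) -> dict:
        table = pd.read_csv(_resolve(stage["table"], base, outdir), comment="#")
        factors = stats.enrichment_factors_from_summary(
            table, blank_label=stage.get("blank_label", "BlankTMOS")
        )
        out = outdir / stage.get("out", "enrichment_factors.csv")
        _write_csv(factors, out, cfg_hash, seed, index=False)
        return {"factors": str(out)}

    def _stage_ms_annotate(stage: dict) -> dict:
        feats_df = pd.read_csv(_resolve(stage["features"], base, outdir), comment="#")
        refs_df = pd.read_csv(_resolve(stage["refs"], base, outdir), comment="#")
        features = [
            msannot.MSFeature(
                mz=float(r["measured_mz"]),
                mode=str(r["mode"]),
                adduct=str(r["adduct"]),
                name=None if pd.isna(r.get("name")) else str(r["name"]),
                class_tag=None if pd.isna(r.get("class")) else str(r["class"]),
            )
            for _, r in feats_df.iterrows()
        ]
        refs = [
            msannot.ReferenceCompound(
                name=str(r["name"]),
                neutral_mass=float(r["neutral_mass"]),
                class_label=None if pd.isna(r.get("class")) else str(r["class"]),
            )
            for _, r in refs_df.iterrows()
        ]
        annotations = msannot.match_features(
            features, refs, tol_ppm=float(stage.get("tol_ppm", 10.0))
        )
        out = outdir / stage.get("out", "annotations.csv")
        _write_csv(annotations, out, cfg_hash, seed, index=False)
        return {"annotations": str(out), "n_features": len(annotations)}

    def _stage_profile_compare(stage: dict) -> dict:
        profiles = pd.read_csv(
            _resolve(stage["profiles"], base, outdir), comment="#", index_col=0
        )
        prefix = stage.get("out_prefix", "profiles")
        cos_out = outdir / f"{prefix}_cosine.csv"
        sum_out = outdir / f"{prefix}_summary.csv"
        _write_csv(msannot.cosine_matrix(profiles), cos_out, cfg_hash, seed)
        _write_csv(msannot.profile_summary(profiles), sum_out, cfg_hash, seed, index=False)
        return {"cosine": str(cos_out), "summary": str(sum_out)}

    handlers.update(
        generate_plate=_stage_generate_plate,
        quantify_halos=_stage_quantify_halos,
        cas_calibrate=_stage_cas_calibrate,
        cas_quantify=_stage_cas_quantify,
        compare_groups=_stage_compare_groups,
        pca=_stage_pca,
        enrichment=_stage_enrichment,
        ms_annotate=_stage_ms_annotate,
        profile_compare=_stage_profile_compare,
    )

    for i, stage in enumerate(cfg["stages"]):
        name = stage["stage"]
        try:
            outputs = handlers[name](stage)
        except Exception as exc:
            raise RuntimeError(f"stage {i} ({name}) failed: {exc}") from exc
        logger.info("stage %d (%s) done", i, name)
        report["stages"].append({"stage": name, "outputs": outputs})
    return report
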