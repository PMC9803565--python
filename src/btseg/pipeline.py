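"""End-to-end orchestration: image -> denoise -> segment -> mask ->
texture features -> (optional) classification -> quality metrics.

A run is fully described by a :class:`RunConfig`; the same config and
seed reproduce every artifact byte for byte.  Stage outputs are cached
on disk under a directory keyed by the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import classify as _classify
from . import clustering, denoise, metrics, phantoms, texture

__all__ = ["RunConfig", "run_pipeline", "make_texture_dataset", "save_image", "load_image"]

log = logging.getLogger("btseg")


@dataclass
class RunConfig:
    """Every knob of a pipeline run; serializable to/from YAML."""

    # input: a grayscale image path, or a generated phantom when None
    input_image: str | None = None
    truth_mask: str | None = None
    # phantom
    height: int = 96
    width: int = 96
    tissue_means: tuple = (20.0, 120.0, 230.0)
    tumour_radius: float = 10.0
    noise_sigma: float = 10.0
    block_quality: int | None = None
    # denoising
    denoise: bool = True
    wavelet: str = "bior4.4"
    levels: int = 2
    sigma_d: float = 1.8
    sigma_r_scale: float = 1.0
    window: int = 11
    threshold_rule: str = "soft"
    block: int = 8
    # clustering
    n_clusters: int = 3
    fuzzifier: float = 2.0
    population: int = 20
    max_generations: int = 60
    stagnation: int = 15
    refine_every: int = 1
    inner_fcm_iters: int = 2
    # texture / classification
    features: bool = True
    classify: bool = False
    kernel: str = "grbf"
    degree: int = 3
    kernel_sigma: float = 1.0
    C: float = 1.0
    train_per_class: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissue_means"] = list(self.tissue_means)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "tissue_means" in d:
            d["tissue_means"] = tuple(float(v) for v in d["tissue_means"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def save_image(img: np.ndarray, path) -> None:
    arr = np.clip(np.asarray(img, dtype=float), 0, 255).round().astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=float)


def _denoise_cfg(cfg: RunConfig) -> denoise.DenoiseConfig:
    return denoise.DenoiseConfig(
        wavelet=cfg.wavelet,
        levels=cfg.levels,
        sigma_d=cfg.sigma_d,
        sigma_r_scale=cfg.sigma_r_scale,
        window=cfg.window,
        threshold_rule=cfg.threshold_rule,
        block=cfg.block,
    )


def _cluster_cfg(cfg: RunConfig, seed: int) -> clustering.GCPSOFCMConfig:
    return clustering.GCPSOFCMConfig(
        population=cfg.population,
        max_generations=cfg.max_generations,
        stagnation=cfg.stagnation,
        refine_every=cfg.refine_every,
        inner_fcm_iters=cfg.inner_fcm_iters,
        m=cfg.fuzzifier,
        seed=seed,
    )


def make_texture_dataset(
    n_per_class: int = 40,
    seed: int = 0,
    size: int = 64,
    noise_sigma: float = 8.0,
    tissue_means: tuple = (20.0, 120.0, 230.0),
    tumour_radius: float = 7.0,
):
    """Two-class GLCM feature set: phantoms with vs without a tumour.

    Each sample is the flattened feature table of one noisy phantom
    (two level counts x four directions x four features = 32 features).
    Labels: 1 = tumour present, 0 = absent.  Returns (X, y).
    """
    X, y = [], []
    for k in range(2 * n_per_class):
        label = k % 2
        spec = phantoms.PhantomSpec(
            height=size,
            width=size,
            tissue_means=tissue_means,
            tumour_radius=tumour_radius,
            seed=seed * 100003 + k,
        )
        regions = phantoms.make_region_map(spec)
        means = np.asarray(spec.tissue_means)
        if label == 0:
            regions = np.where(regions == 2, 1, regions)
        img = means[regions]
        img = phantoms.add_noise(img, noise_sigma, seed=spec.seed + 1)
        table = texture.extract_feature_table(img)
        feats = table[["contrast", "correlation", "energy", "homogeneity"]].to_numpy()
        X.append(np.nan_to_num(feats.ravel()))
        y.append(label)
    return np.asarray(X), np.asarray(y)


def run_pipeline(cfg: RunConfig, outdir, use_cache: bool = True) -> dict:
    """Run every stage and return the machine-readable report.

    Artifacts (input/noisy/denoised PNGs, label map, tumour mask,
    feature CSV, report.json, config.yaml) land in a subdirectory of
    ``outdir`` keyed by the config hash.
    """
    outdir = Path(outdir)
    rundir = outdir / f"run-{cfg.digest()}"
    report_path = rundir / "report.json"
    if use_cache and report_path.exists():
        log.info("cache hit: %s", rundir)
        return json.loads(report_path.read_text())
    rundir.mkdir(parents=True, exist_ok=True)
    cfg.save(rundir / "config.yaml")
    report: dict = {"config_digest": cfg.digest(), "seed": cfg.seed, "stages": []}

    def stage(name):
        t0 = time.perf_counter()

        def done():
            log.info("stage %-10s %.2fs (seed=%d)", name, time.perf_counter() - t0, cfg.seed)
            report["stages"].append(name)

        return done

    # --- input -----------------------------------------------------------
    end = stage("input")
    clean = None
    truth = None
    try:
        if cfg.input_image is not None:
            img = load_image(cfg.input_image)
            if cfg.truth_mask is not None:
                truth = load_image(cfg.truth_mask) > 127
        else:
            spec = phantoms.PhantomSpec(
                height=cfg.height,
                width=cfg.width,
                tissue_means=tuple(cfg.tissue_means),
                tumour_radius=cfg.tumour_radius,
                noise_sigma=cfg.noise_sigma,
                block_quality=cfg.block_quality,
                seed=cfg.seed,
            )
            img, truth = phantoms.make_phantom(spec)
            clean_spec = phantoms.PhantomSpec(
                height=cfg.height,
                width=cfg.width,
                tissue_means=tuple(cfg.tissue_means),
                tumour_radius=cfg.tumour_radius,
                seed=cfg.seed,
            )
            clean, _ = phantoms.make_phantom(clean_spec)
        save_image(img, rundir / "input.png")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'input' failed: {exc}") from exc
    end()

    # --- denoise ---------------------------------------------------------
    end = stage("denoise")
    try:
        if cfg.denoise:
            work = denoise.adaptive_bilateral_multiresolution(img, _denoise_cfg(cfg))
            save_image(work, rundir / "denoised.png")
        else:
            work = img
            report["denoise_skipped"] = True
        if clean is not None:
            report["mse_noisy"] = metrics.mse(img, clean)
            report["mse_denoised"] = metrics.mse(work, clean)
            p = metrics.psnr(work, clean)
            report["psnr_denoised"] = "inf" if p == float("inf") else p
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'denoise' failed: {exc}") from exc
    end()

    # --- segment ---------------------------------------------------------
    end = stage("segment")
    try:
        labels = clustering.segment_image(
            work, cfg.n_clusters, _cluster_cfg(cfg, cfg.seed)
        )
        scale = 255 // max(cfg.n_clusters - 1, 1)
        save_image(labels * scale, rundir / "labels.png")
        mask = clustering.tumour_mask(labels)
        save_image(mask.astype(float) * 255, rundir / "tumour_mask.png")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'segment' failed: {exc}") from exc
    end()

    # --- metrics ---------------------------------------------------------
    end = stage("metrics")
    try:
        if truth is not None:
            rates = metrics.confusion_rates(mask, truth)
            report["confusion_rates"] = {
                "TPR": rates.tpr,
                "TNR": rates.tnr,
                "FPR": rates.fpr,
                "FNR": rates.fnr,
                "accuracy": rates.accuracy,
            }
            report["dice"] = metrics.dice(mask, truth)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'metrics' failed: {exc}") from exc
    end()

    # --- texture features ------------------------------------------------
    if cfg.features:
        end = stage("features")
        try:
            table = texture.extract_feature_table(np.round(work))
            table.to_csv(rundir / "features.csv", index=False)
            report["n_feature_rows"] = int(len(table))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'features' failed: {exc}") from exc
        end()

    # --- classification --------------------------------------------------
    if cfg.classify:
        end = stage("classify")
        try:
            X, y = make_texture_dataset(
                n_per_class=cfg.train_per_class,
                seed=cfg.seed + 7,
                size=min(cfg.height, cfg.width),
                tissue_means=tuple(cfg.tissue_means),
            )
            spec = _classify.KernelSpec(
                family=cfg.kernel, degree=cfg.degree, sigma=cfg.kernel_sigma
            )
            model = _classify.train_margin_classifier(X, y, spec, C=cfg.C)
            table = texture.extract_feature_table(np.round(work))
            feats = table[
                ["contrast", "correlation", "energy", "homogeneity"]
            ].to_numpy()
            pred = int(model.predict(np.nan_to_num(feats.ravel())[None, :])[0])
            report["predicted_class"] = "cancerous" if pred == 1 else "non-cancerous"
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'classify' failed: {exc}") from exc
        end()

    report_path.write_text(json.dumps(report, sort_keys=True, indent=2))
    return report
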