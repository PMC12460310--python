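"""End-to-end traceability and quality-evaluation orchestration.

The traceability track runs: synthetic (or loaded) reflectance spectra
-> per-sample synchronous 3DCOS images against the training-set mean
-> random 50/25/15 train/test/external split -> 12-layer residual CNN,
with a 2-LV PLS-DA baseline fitted on the raw spectra for comparison.

The quality track runs: coupled alkaloid/element panels -> PCA on the
element table -> element-alkaloid correlation analysis.

Every stage's seed and configuration are echoed into a YAML run
manifest so any artifact can be regenerated from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chemometrics import pca_scores, plsda_fit, plsda_predict, split_dataset
from .cnn import (ConfusionMatrix, ResNetConfig, TrainingCurves, build_resnet12,
                  evaluate, metrics, train)
from .cos3d import RenderSpec, render_map, sample_sync_map
from .quantification import correlate_panels
from .spectra_io import SpectraSet, write_spectra_csv
from .synthetic_data import (GeneratorConfig, PanelConfig, generate_panels,
                             generate_spectra_set)

__all__ = ["RunConfig", "Report", "images_from_spectra", "run_traceability", "run_quality"]

logger = logging.getLogger("fcbtrace")


@dataclass
class RunConfig:
    """Single configuration object driving both analysis tracks."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    panels: PanelConfig = field(default_factory=PanelConfig)
    split_sizes: tuple = (50, 25, 15)
    split_seed: int = 0
    image_size: tuple = (224, 224)
    resnet: ResNetConfig = field(default_factory=ResNetConfig)
    n_lv: int = 2
    scale_plsda: bool = True


def _stage(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.2fs", name, dt)
            else:
                logger.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)

    return _Timer()


def images_from_spectra(
    spectra: SpectraSet,
    reference: np.ndarray,
    size: tuple = (224, 224),
    bounds: tuple | None = None,
) -> tuple[np.ndarray, tuple]:
    """Per-sample rank-1 synchronous maps rendered as grayscale images.

    ``reference`` is the training-set mean spectrum.  ``bounds`` are
    the global intensity-normalisation (vmin, vmax); if None they are
    computed over this set's maps and returned for reuse, so test and
    external images share the training set's intensity scale.
    """
    maps = [sample_sync_map(spectra.spectrum(i), reference) for i in range(spectra.n_samples)]
    if bounds is None:
        vmin = min(float(m.phi.min()) for m in maps)
        vmax = max(float(m.phi.max()) for m in maps)
        bounds = (vmin, vmax)
    spec = RenderSpec(
        width_px=size[1], height_px=size[0], colormap=None,
        normalization="global", vmin=bounds[0], vmax=bounds[1],
    )
    images = np.stack([render_map(m, spec) for m in maps]).astype(np.float32)
    return images, bounds


@dataclass
class Report:
    """Artifacts of one traceability run."""

    classes: list
    split: object
    comparison: pd.DataFrame
    curves: TrainingCurves
    resnet_conf_test: ConfusionMatrix
    resnet_conf_external: ConfusionMatrix
    plsda_conf_external: ConfusionMatrix
    manifest: dict
    model: object = None


def _conf_from_pred(y_true, y_pred, classes) -> ConfusionMatrix:
    K = len(classes)
    lut = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((K, K), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[lut[t], lut[p]] += 1
    return ConfusionMatrix(counts, classes=list(classes))


def _summary_row(model_name, subset, conf) -> dict:
    m = metrics(conf)
    return {
        "model": model_name,
        "subset": subset,
        "accuracy": m["accuracy"],
        "macro_precision": m["macro_precision"],
        "macro_sensitivity": m["macro_sensitivity"],
        "macro_specificity": m["macro_specificity"],
    }


def run_traceability(config: RunConfig, output_dir=None, spectra: SpectraSet | None = None) -> Report:
    """Run the full ResNet-vs-PLS-DA traceability comparison."""
    if spectra is None:
        with _stage("simulate"):
            spectra = generate_spectra_set(config.generator)
    classes = [str(c) for c in dict.fromkeys(np.asarray(spectra.labels))]
    y = np.array([classes.index(l) for l in spectra.labels])

    with _stage("split"):
        split = split_dataset(spectra.n_samples, config.split_sizes, config.split_seed)

    with _stage("cos3d"):
        train_set = spectra.subset(split.train)
        reference = train_set.reflectance.mean(axis=0)
        imgs_train, bounds = images_from_spectra(train_set, reference, config.image_size)
        imgs_test, _ = images_from_spectra(
            spectra.subset(split.test), reference, config.image_size, bounds)
        imgs_ext, _ = images_from_spectra(
            spectra.subset(split.external), reference, config.image_size, bounds)

    with _stage("train"):
        rcfg = dataclasses.replace(config.resnet, n_classes=len(classes),
                                   input_size=tuple(config.image_size))
        model = build_resnet12(rcfg)
        curves = train(model, imgs_train, y[split.train], imgs_test, y[split.test])

    with _stage("evaluate"):
        conf_test = evaluate(model, imgs_test, y[split.test], classes)
        conf_ext = evaluate(model, imgs_ext, y[split.external], classes)

    with _stage("chemo"):
        pls = plsda_fit(train_set.reflectance, np.asarray(spectra.labels)[split.train],
                        n_lv=config.n_lv, scale=config.scale_plsda)
        pls_rows, pls_confs = [], {}
        for name, idx in (("train", split.train), ("test", split.test),
                          ("external", split.external)):
            pred, _ = plsda_predict(pls, spectra.reflectance[idx])
            conf = _conf_from_pred(np.asarray(spectra.labels)[idx], pred, classes)
            pls_confs[name] = conf
            pls_rows.append(_summary_row("PLS-DA", name, conf))

    comparison = pd.DataFrame(
        [
            _summary_row("ResNet-12", "train",
                         _conf_from_pred(y[split.train], model.predict(imgs_train),
                                         list(range(len(classes))))),
            _summary_row("ResNet-12", "test", conf_test),
            _summary_row("ResNet-12", "external", conf_ext),
            *pls_rows,
        ]
    )

    manifest = {
        "generator": _yamlable(config.generator),
        "split": {"sizes": list(config.split_sizes), "seed": config.split_seed},
        "image_size": list(config.image_size),
        "normalization_bounds": [float(b) for b in bounds],
        "resnet": _yamlable(rcfg),
        "plsda": {"n_lv": config.n_lv, "scale": config.scale_plsda},
        "classes": classes,
        "epochs_run": len(curves.train_acc),
    }
    report = Report(classes, split, comparison, curves, conf_test, conf_ext,
                    pls_confs["external"], manifest, model=model)
    if output_dir is not None:
        _write_report(report, spectra, Path(output_dir))
    return report


def run_quality(config: RunConfig, output_dir=None):
    """Panel generation, element PCA and element-alkaloid correlations."""
    with _stage("panels"):
        alk, elem = generate_panels(config.panels, config.generator.n_per_class)
    with _stage("pca"):
        scores, loadings, evr = pca_scores(elem.values.to_numpy(), k=2, scale=True)
    with _stage("correlate"):
        corr = correlate_panels(elem, alk)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        alk.values.assign(cls=alk.labels).to_csv(out / "alkaloid_panel.csv", index=False)
        elem.values.assign(cls=elem.labels).to_csv(out / "element_panel.csv", index=False)
        pd.DataFrame(scores, columns=["PC1", "PC2"]).assign(cls=elem.labels).to_csv(
            out / "element_pca_scores.csv", index=False)
        corr.r.to_csv(out / "correlation_r.csv")
        corr.p.to_csv(out / "correlation_p.csv")
        corr.stars.to_csv(out / "correlation_stars.csv")
    return alk, elem, (scores, loadings, evr), corr


def _yamlable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return {str(i): _yamlable(list(row)) for i, row in obj.iterrows()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_report(report: Report, spectra: SpectraSet, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_spectra_csv(spectra, out / "spectra.csv", out / "labels.csv")
    if report.model is not None:
        report.model.save(out / "model.npz")
    ref = spectra.subset(report.split.train).reflectance.mean(axis=0)
    pd.DataFrame({"wavelength_nm": spectra.wavelengths_nm, "reflectance": ref}).to_csv(
        out / "reference_spectrum.csv", index=False, float_format="%.12g")
    report.comparison.to_csv(out / "metrics_comparison.csv", index=False,
                             float_format="%.6f")
    report.resnet_conf_test.to_frame().to_csv(out / "confusion_test.csv")
    report.resnet_conf_external.to_frame().to_csv(out / "confusion_external.csv")
    report.plsda_conf_external.to_frame().to_csv(out / "confusion_external_plsda.csv")
    report.curves.to_frame().to_csv(out / "training_curves.csv", index=False,
                                    float_format="%.6f")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(report.manifest, fh, sort_keys=False)
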