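"""End-to-end pipeline orchestration and run configuration.

A :class:`RunConfig` bundles every stage's parameters — synthetic-data
spec (or an epochs file), filter band, feature extractor, selection
sweep, classifier and CV settings — plus one global seed.  The global
seed fans out to per-stage child seeds by a fixed derivation
(``SeedSequence(seed).spawn``-style keys), so each stage is independently
reproducible.  :func:`run_pipeline` executes

    data arrangement -> feature extraction -> in-fold t-test selection
    -> LRBSF (or baseline) -> Monte-Carlo CV report

and writes every intermediate artifact plus a provenance log.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .convnet import ConvNetSpec, extract_convnet_features, extract_raw_features, init_filters
from .epochs import EpochSet, ValidationError
from .evaluation import CVReport, monte_carlo_cv, pairwise_sweep
from .synthetic import SyntheticSpec, average_presentations, generate_epochs
from .wavelet import extract_wavelet_features

log = logging.getLogger("eegfuse")

_STAGE_KEYS = {"synthetic": 0, "convnet": 1, "cv": 2}


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Explicit, JSON-round-trippable configuration of a full run."""

    seed: int = 0
    epochs_path: str = None          # load instead of simulating when set
    synthetic: dict = field(default_factory=dict)
    average_presentations: bool = True
    feature_method: str = "convnet"  # convnet | wavelet | raw
    convnet: dict = field(default_factory=dict)
    wavelet_name: str = "db4"
    wavelet_levels: int = None
    selection_alpha: float = 0.05
    subset_sizes: list = field(default_factory=lambda: [50])
    classifier: str = "lrbsf"        # lrbsf | svm
    eta: float = 1.0
    tune_eta: bool = False
    mode: str = "pairwise"           # pairwise | multiclass
    n_reps: int = 100
    test_fraction: float = 0.10

    def to_json(self, path) -> None:
        full = asdict(self)
        # record every defaulted value explicitly, including nested specs
        full["synthetic"] = SyntheticSpec(
            **{**self.synthetic, "seed": self.synthetic.get("seed", child_seed(self.seed, "synthetic"))}
        ).to_dict() if self.epochs_path is None else self.synthetic
        with open(path, "w") as fh:
            json.dump(full, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


def _prepare_epochs(config: RunConfig) -> EpochSet:
    if config.epochs_path:
        epochs = EpochSet.load(config.epochs_path)
    else:
        syn = dict(config.synthetic)
        syn.setdefault("seed", child_seed(config.seed, "synthetic"))
        epochs = generate_epochs(SyntheticSpec.from_dict(syn))
    if config.average_presentations:
        epochs = average_presentations(epochs)
    return epochs


def _extract_features(epochs: EpochSet, config: RunConfig):
    if config.feature_method == "convnet":
        cn = dict(config.convnet)
        cn.setdefault("seed", child_seed(config.seed, "convnet"))
        spec = init_filters(ConvNetSpec(**cn))
        return extract_convnet_features(epochs, spec)
    if config.feature_method == "wavelet":
        return extract_wavelet_features(
            epochs, wavelet_name=config.wavelet_name, n_levels=config.wavelet_levels
        )
    if config.feature_method == "raw":
        return extract_raw_features(epochs)
    raise ValidationError(f"unknown feature_method {config.feature_method!r}")


def run_pipeline(config: RunConfig, outdir=None):
    """Execute the full pipeline; returns (report, features, epochs).

    ``report`` is a CVReport (mode='multiclass') or a dict mapping class
    pairs to CVReports (mode='pairwise').  When ``outdir`` is given,
    features, reports, the echoed config and a provenance log are written
    there.
    """
    t0 = time.time()
    stage = "arrange"
    try:
        epochs = _prepare_epochs(config)
        log.info(
            "epochs: %d trials x %d channels x %d samples @ %g Hz",
            epochs.n_trials, epochs.n_channels, epochs.n_samples, epochs.fs,
        )
        stage = "features"
        features = _extract_features(epochs, config)
        log.info("features (%s): %d x %d", features.method_tag, features.n_trials, features.n_features)
        stage = "evaluate"
        cv_seed = child_seed(config.seed, "cv")
        kwargs = dict(
            subset_sizes=config.subset_sizes,
            n_reps=config.n_reps,
            test_fraction=config.test_fraction,
            seed=cv_seed,
            alpha=config.selection_alpha,
            classifier=config.classifier,
            eta=config.eta,
            tune_eta=config.tune_eta,
        )
        if config.mode == "multiclass":
            report = monte_carlo_cv(features, epochs.labels, **kwargs)
        elif config.mode == "pairwise":
            cls_kwargs = {k: v for k, v in kwargs.items() if k != "seed"}
            report = pairwise_sweep(features, epochs.labels, seed=cv_seed, **cls_kwargs)
        else:
            raise ValidationError(f"unknown mode {config.mode!r}")
    except ValidationError as exc:
        raise ValidationError(
            f"[stage {stage}] {exc} (config: {asdict(config)})"
        ) from exc
    except Exception as exc:
        raise RuntimeError(
            f"[stage {stage}] {exc} (config: {asdict(config)})"
        ) from exc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        features.save(outdir / "features.npz")
        config.to_json(outdir / "config.json")
        if isinstance(report, CVReport):
            report.to_json(outdir / "report.json")
        else:
            for pair, rep in report.items():
                rep.to_json(outdir / f"report_pair_{pair[0]}_{pair[1]}.json")
            _write_pair_table(report, outdir / "pairwise_summary.tsv")
        _write_provenance(config, outdir / "provenance.json", time.time() - t0)
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return report, features, epochs


def _write_pair_table(report: dict, path) -> None:
    """Table-shaped pairwise summary: pair, accuracy, sensitivity, specificity."""
    import pandas as pd

    rows = []
    for pair, rep in report.items():
        s = rep.summary()
        rows.append(
            {
                "class_a": pair[0],
                "class_b": pair[1],
                "subset_size": s["subset_size"],
                "accuracy_pct": round(s["accuracy"], 2),
                "sensitivity_pct": round(s.get("sensitivity", float("nan")), 2),
                "specificity_pct": round(s.get("specificity", float("nan")), 2),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_provenance(config: RunConfig, path, elapsed_s: float) -> None:
    from importlib.metadata import version

    with open(path, "w") as fh:
        json.dump(
            {
                "config": asdict(config),
                "seed": config.seed,
                "elapsed_s": elapsed_s,
                "versions": {
                    pkg: version(pkg)
                    for pkg in ("numpy", "scipy", "scikit-learn", "pandas",
                                "PyWavelets", "click")
                },
            },
            fh,
            indent=2,
        )
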