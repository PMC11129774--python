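"""End-to-end orchestration of the published modelling procedure.

Stage order (the faithful default): validate -> dummy-encode -> bootstrap ->
70:30 split -> OLS regression (+ test MSE) -> possibilistic fuzzy regression
on the same split -> min-max scale -> an independent 70:30 split -> network
training (+ scaled test MSE) -> comparison report.

Two fidelity flags expose the statistically cleaner alternatives the
faithful order forgoes:

``split_before_bootstrap``
    The default bootstraps first and splits the enlarged pseudo-sample, so
    duplicated cases leak across train and test.  With the flag set, the
    original cases are partitioned 70:30 first and each part is bootstrapped
    separately, keeping train and test disjoint at the case level.
``scale_on_train_only``
    The default fits min-max scaling on the full bootstrapped table before
    the network split (as published); the flag refits it on the network's
    training part only.

Every random draw comes from a named substream of the single root seed, so
a report is reproducible from its own provenance block.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .data import Dataset, encode_dummies, validate
from .errors import ConfigError, QualinearError
from .flr import PossibilisticLinearModel
from .mlffnn import NeuralNetRegressor, min_max_scale, mse_net
from .mlr import LinearModel, mse
from .report import build_comparison, build_mse_table, to_markdown
from .resampling import SplitSpec, bootstrap_resample, split_train_test, substream
from .synthetic import SyntheticConfig, generate

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

log = logging.getLogger("qualinear.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    data_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    response: str = "effectiveness"
    numeric: tuple = ("age",)
    categorical: tuple = ("treatment",)
    reference: dict = field(default_factory=dict)  # variable -> reference level
    bootstrap_size: int = 10000
    train_fraction: float = 0.70
    seed: int = 0
    h_level: float = 0.0
    hidden_layers: tuple = (3, 2)
    learning_rate: float = 0.5
    max_epochs: int = 2000
    tol: float = 0.01
    split_before_bootstrap: bool = False
    scale_on_train_only: bool = False
    run_nn: bool = True

    def __post_init__(self):
        if (self.data_csv is None) == (self.synthetic is None):
            raise ConfigError("exactly one of data_csv or synthetic must be given")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.bootstrap_size < 2:
            raise ConfigError("bootstrap_size must be >= 2")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and d["synthetic"] is not None:
            syn = dict(d["synthetic"])
            if "age_range" in syn:
                syn["age_range"] = tuple(syn["age_range"])
            d["synthetic"] = SyntheticConfig(**syn)
        for key in ("numeric", "categorical", "hidden_layers"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"]["age_range"] = list(self.synthetic.age_range)
        for key in ("numeric", "categorical", "hidden_layers"):
            d[key] = list(d[key])
        return d


@dataclass
class PipelineReport:
    """All tables and provenance from one run."""

    config: dict
    provenance: dict
    mlr_results: object
    flr_results: object
    mse_lm: float
    comparison: object            # DataFrame of per-case predictions
    avg_absdiff_mlr: float
    avg_absdiff_flr: float
    mse_net_scaled: float | None = None
    mse_net_unscaled: float | None = None
    nn_results: object = None
    mse_table: object = None

    def to_markdown(self, max_rows: int = 20) -> str:
        parts = [
            "# Pipeline report",
            "",
            "## Provenance",
            "```json",
            json.dumps({"config": self.config, **self.provenance},
                       indent=2, sort_keys=True),
            "```",
            "",
            "## Linear regression (training fit)",
            "```",
            self.mlr_results.summary(),
            "```",
            f"Test MSE (raw units): {self.mse_lm:.6f}",
            "",
            "## Fuzzy linear regression",
            "```",
            self.flr_results.summary(),
            "```",
            "",
            "## Actual vs predicted (test set)",
            to_markdown(self.comparison.head(max_rows)),
            f"\n({len(self.comparison)} test cases; first {min(max_rows, len(self.comparison))} shown)",
            f"Average absolute difference: MLR {self.avg_absdiff_mlr:.6f}, "
            f"FLR {self.avg_absdiff_flr:.6f}",
        ]
        if self.mse_table is not None:
            parts += ["", "## Predicted mean square errors", to_markdown(self.mse_table)]
        return "\n".join(parts) + "\n"

    def to_json(self) -> str:
        out = {
            "config": self.config,
            "provenance": self.provenance,
            "mlr": self.mlr_results.to_dict(),
            "flr": self.flr_results.to_dict(),
            "mse_lm": self.mse_lm,
            "avg_absdiff_mlr": self.avg_absdiff_mlr,
            "avg_absdiff_flr": self.avg_absdiff_flr,
            "mse_net_scaled": self.mse_net_scaled,
            "mse_net_unscaled": self.mse_net_unscaled,
        }
        return json.dumps(out, indent=2, sort_keys=True)

    def write(self, outdir) -> None:
        """Write report.md, report.json and comparison.csv under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.md").write_text(self.to_markdown())
        (outdir / "report.json").write_text(self.to_json() + "\n")
        self.comparison.to_csv(outdir / "comparison.csv", index=False)


def _stage(name, fn, *args, **kw):
    """Run one stage, prefixing any package error with the stage name."""
    try:
        return fn(*args, **kw)
    except QualinearError as exc:
        exc.args = (f"[stage {name}] {exc}",)
        raise


def _load(config: PipelineConfig) -> Dataset:
    if config.synthetic is not None:
        return generate(config.synthetic)
    return Dataset.from_csv(config.data_csv, response=config.response,
                            numeric=config.numeric,
                            categorical=config.categorical)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    ds = _stage("load", _load, config)
    log.info("loaded %d cases", ds.n)
    _stage("validate", validate, ds)

    encodings = {}
    for var in list(ds.categorical):
        ds, enc = _stage("encode", encode_dummies, ds, var,
                         config.reference.get(var))
        encodings[var] = enc
        log.info("encoded %s: levels %s, reference %s",
                 var, list(enc.levels), enc.reference_level)

    boot_rng = substream(config.seed, "bootstrap")
    split_lm_rng = substream(config.seed, "split-lm")
    spec = SplitSpec(train_fraction=config.train_fraction, seed=config.seed)

    if config.split_before_bootstrap:
        base_train, base_test = _stage("split", split_train_test, ds, spec,
                                       rng=split_lm_rng)
        k = spec.train_size(config.bootstrap_size)
        train = _stage("bootstrap", bootstrap_resample, base_train, k, rng=boot_rng)
        test = _stage("bootstrap", bootstrap_resample, base_test,
                      config.bootstrap_size - k, rng=boot_rng)
        boot = None
    else:
        boot = _stage("bootstrap", bootstrap_resample, ds,
                      config.bootstrap_size, rng=boot_rng)
        train, test = _stage("split", split_train_test, boot, spec,
                             rng=split_lm_rng)
    log.info("train/test sizes: %d/%d", train.n, test.n)

    mlr_model = LinearModel.from_dataset(train)
    mlr_res = _stage("mlr", mlr_model.fit)
    X_test, _ = _design(test)
    mlr_pred = mlr_res.predict(X_test)
    mse_lm = mse(test.response_values, mlr_pred)
    log.info("MLR: R2=%.4f, test MSE=%.4f", mlr_res.rsquared, mse_lm)

    flr_model = PossibilisticLinearModel.from_dataset(train, h=config.h_level)
    flr_res = _stage("flr", flr_model.fit)
    flr_pred = flr_res.predict(X_test)
    log.info("FLR: total spread objective=%.4f", flr_res.total_spread)

    comparison, avg_mlr, avg_flr = _stage(
        "report", build_comparison, test.response_values, mlr_pred, flr_pred)

    mse_net_scaled = mse_net_unscaled = None
    nn_res = None
    if config.run_nn:
        if boot is not None:
            nn_frame = boot.frame
        else:  # cleaner order: the pseudo-sample is the two disjoint parts
            nn_frame = pd.concat([train.frame, test.frame], ignore_index=True)
        split_nn_rng = substream(config.seed, "split-nn")
        if config.scale_on_train_only:
            nn_train_raw, nn_test_raw = _stage(
                "split-nn", split_train_test, nn_frame, spec, rng=split_nn_rng)
            _, scaling = _stage("scale", min_max_scale, nn_train_raw)
            nn_train = scaling.transform(nn_train_raw)
            nn_test = scaling.transform(nn_test_raw).clip(0.0, 1.0)
        else:
            scaled, scaling = _stage("scale", min_max_scale, nn_frame)
            nn_train, nn_test = _stage("split-nn", split_train_test, scaled,
                                       spec, rng=split_nn_rng)
        nn_model = NeuralNetRegressor(nn_train, config.response,
                                      hidden=config.hidden_layers)
        nn_res = _stage("mlffnn", nn_model.fit,
                        rng=substream(config.seed, "nn-init"),
                        learning_rate=config.learning_rate,
                        max_epochs=config.max_epochs, tol=config.tol)
        mse_net_scaled = mse_net(nn_res.network, nn_test, config.response,
                                 feature_names=nn_res.model.feature_names)
        mse_net_unscaled = mse_net(nn_res.network, nn_test, config.response,
                                   feature_names=nn_res.model.feature_names,
                                   scaling=scaling)
        log.info("MLFFNN: stop=%s, scaled test MSE=%.6f",
                 nn_res.stop_reason, mse_net_scaled)

    mse_table = (build_mse_table(mse_lm, mse_net_scaled, mse_net_unscaled)
                 if mse_net_scaled is not None else None)

    provenance = {
        "package_version": __version__,
        "root_seed": config.seed,
        "substreams": ["bootstrap", "split-lm", "split-nn", "nn-init"],
        "encodings": {
            v: {"levels": list(e.levels), "reference": e.reference_level}
            for v, e in encodings.items()
        },
        "n_input": int(ds.n),
        "n_train": int(train.n),
        "n_test": int(test.n),
    }
    return PipelineReport(
        config=config.to_dict(),
        provenance=provenance,
        mlr_results=mlr_res,
        flr_results=flr_res,
        mse_lm=mse_lm,
        comparison=comparison,
        avg_absdiff_mlr=avg_mlr,
        avg_absdiff_flr=avg_flr,
        mse_net_scaled=mse_net_scaled,
        mse_net_unscaled=mse_net_unscaled,
        nn_results=nn_res,
        mse_table=mse_table,
    )


def _design(dataset: Dataset):
    from .data import design_matrix

    return design_matrix(dataset, add_intercept=True)
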