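"""End-to-end orchestration of the early-warning analysis.

Stages: simulate-or-load -> drop rows without counts -> impute factor gaps ->
cluster counts into warning levels -> score and select factors -> z-score
(training statistics only) -> stratified train/test split -> BP training ->
test-set evaluation.  Every stage is a pure function of (inputs, config,
seed); per-stage seeds are derived deterministically from the single global
seed so changing one stage cannot reshuffle another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, features, network, preprocessing, series, synthetic
from .exceptions import PestwarnError

log = logging.getLogger("pestwarn")

_STAGES = ("simulate", "impute", "levels", "features", "split", "train")


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed.

    ``input_csv = None`` generates synthetic data; otherwise the CSV is
    loaded in the documented dialect.
    """

    input_csv: str | None = None
    out_dir: str = "pestwarn_out"
    seed: int = 1
    # synthetic stage
    n_records: int = 2536
    missing_rate: float = 0.009
    # preprocessing
    window: int = 4
    k: int = 4
    # feature selection
    resolution: float = 0.5
    threshold: float = 0.5
    # classifier
    hidden: int = 13
    epochs: int = 10_000
    learning_rate: float = 0.1
    split_fraction: float = 0.7
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) derived from the global seed."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def stratified_split(levels: np.ndarray, fraction: float,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Single seeded split, stratified by level; returns (train, test) row
    indices.  Each level contributes ``round(fraction * n_level)`` rows to
    the training side."""
    rng = np.random.default_rng(seed)
    train, test = [], []
    for lv in np.unique(levels):
        idx = np.nonzero(levels == lv)[0]
        idx = rng.permutation(idx)
        cut = int(round(fraction * len(idx)))
        train.extend(idx[:cut])
        test.extend(idx[cut:])
    return np.sort(np.asarray(train, dtype=int)), np.sort(np.asarray(test, dtype=int))


def run_pipeline(config: PipelineConfig) -> evaluation.EvaluationReport:
    """Execute the full analysis; writes every intermediate artifact under
    ``config.out_dir`` and returns the test-set evaluation report.

    Identical (config, seed) produce byte-identical artifacts.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), "INFO"))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- data ------------------------------------------------------------
    if config.input_csv is None:
        gen_cfg = synthetic.GeneratorConfig(
            n_records=config.n_records,
            seed=stage_seed(config.seed, "simulate"),
            missing_rate=config.missing_rate)
        data = synthetic.generate_sensor_series(gen_cfg)
        log.info("simulated %d records (%d missing cells)", len(data),
                 len(data.attrs.get("missing_cells", [])))
    else:
        data = series.read_csv(config.input_csv)
        log.info("loaded %d records from %s", len(data), config.input_csv)
    series.write_csv(data, out / "data.csv")

    # --- preprocessing ---------------------------------------------------
    data = preprocessing.drop_missing_counts(data)
    imputed = preprocessing.impute_series(data, window=config.window)
    series.write_csv(imputed, out / "imputed.csv")
    counts = imputed[series.COUNT_COLUMN].to_numpy(dtype=float)
    scheme = preprocessing.kmeans_1d(counts, k=config.k,
                                     seed=stage_seed(config.seed, "levels"))
    scheme.to_json(out / "scheme.json")
    log.info("level cut points: %s", scheme.boundaries)
    levels = preprocessing.assign_levels(counts, scheme)

    # --- feature selection -----------------------------------------------
    scores = features.score_factors(imputed, scheme,
                                    resolution=config.resolution,
                                    threshold=config.threshold)
    features.scores_to_frame(scores).to_csv(out / "scores.csv", index=False)
    selected = [s.factor_name for s in scores if s.selected]
    if not selected:
        raise PestwarnError("no features selected: every impact factor fell "
                            f"below threshold {config.threshold}")
    log.info("selected factors: %s", selected)

    # --- split + normalization (training statistics only) ----------------
    X = imputed[selected].to_numpy(dtype=float)
    train_idx, test_idx = stratified_split(levels, config.split_fraction,
                                           stage_seed(config.seed, "split"))
    X_train, means, sds = preprocessing.zscore_normalize(X[train_idx], selected)
    X_test = preprocessing.zscore_apply(X[test_idx], means, sds)

    # --- training --------------------------------------------------------
    net = network.init_network(len(selected), config.hidden, config.k,
                               seed=stage_seed(config.seed, "train"))
    net.norm_means, net.norm_sds = means, sds
    targets = network.one_hot(levels[train_idx], config.k)
    cfg = network.TrainConfig(learning_rate=config.learning_rate,
                              max_epochs=config.epochs,
                              seed=stage_seed(config.seed, "train"),
                              split_fraction=config.split_fraction)
    net, history = network.train(net, X_train, targets, cfg)
    net.to_json(out / "model.json",
                extra={"selected_factors": selected,
                       "train_config": {"learning_rate": cfg.learning_rate,
                                        "max_epochs": cfg.max_epochs,
                                        "seed": cfg.seed}})
    if history:
        log.info("final training error E = %.4f after %d epochs",
                 history[-1], len(history))

    # --- evaluation ------------------------------------------------------
    predicted = network.predict_levels(net, X_test)
    report = evaluation.evaluate_predictions(levels[test_idx], predicted,
                                             config.k, scheme.labels)
    report.to_json(out / "report.json")
    log.info("test accuracy %.4f on %d held-out records",
             report.overall_accuracy, len(test_idx))
    return report
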