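"""Monte Carlo under-sampling benchmark of classifier configurations.

The class imbalance of the stimulus dataset (the real study counted
628 : 1488 : 35718 blocks for NaCl : H2SO4 : O3) is handled by repeated
random under-sampling: each draw takes the minority-class count from
every class, splits the balanced subset 50:50 into stratified train and
test halves, optionally refits PCA on the training half, fits every
registered classifier, and records the 3x3 test confusion matrix. All
classifiers see identical draws (common random numbers) so per-draw
comparisons between classifiers and feature spaces are paired.

:class:`MonteCarloBenchmark` is the modelling object: construct it from
a cleaned, normalized feature table, call :meth:`fit`, and read the
metric distributions, averaged confusion matrices and summary table off
the returned :class:`BenchmarkResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dimred, metrics as metrics_mod
from .classify import ClassifierSpec, confusion, fit_predict
from .features import FEATURE_NAMES
from .synth import STIMULI


@dataclass(frozen=True)
class ResampleConfig:
    """Monte Carlo design: number of draws R and the master seed.

    The train fraction is fixed at the 50:50 split of the benchmarked
    design.
    """

    R: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")


@dataclass(frozen=True)
class ConfusionEnsemble:
    """R stacked test-set confusion matrices for one (classifier, space)."""

    matrices: np.ndarray  # (R, K, K) integer counts

    def __post_init__(self) -> None:
        m = self.matrices
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError("expected an (R, K, K) stack")
        if np.any(m < 0):
            raise ValueError("negative counts")

    def __len__(self) -> int:
        return self.matrices.shape[0]


def balanced_undersample(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a balanced subset: n_min rows per class, without replacement.

    The minority class is taken in full; each majority class contributes
    a uniform random subset of the same size.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 3:
        raise ValueError("need at least 3 classes present")
    n_min = counts.min()
    if n_min < 4:
        raise ValueError("minority class has fewer than 4 members")
    picked = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        picked.append(idx)
    return np.concatenate(picked)


def split_half(indices: np.ndarray, labels: np.ndarray,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 50:50 split of a balanced index set.

    Per class, floor(n/2) indices go to train and the remainder to test;
    the halves are disjoint and cover the input.
    """
    indices = np.asarray(indices)
    labels = np.asarray(labels)
    train, test = [], []
    for cls in np.unique(labels[indices]):
        idx = indices[labels[indices] == cls]
        if idx.size < 2:
            raise ValueError("a class has fewer than 2 members to split")
        idx = rng.permutation(idx)
        half = idx.size // 2
        train.append(idx[:half])
        test.append(idx[half:])
    return np.concatenate(train), np.concatenate(test)


def _label_codes(table: pd.DataFrame) -> np.ndarray:
    order = {s: i for i, s in enumerate(STIMULI)}
    return table["stimulus"].map(order).to_numpy(int)


def _feature_matrix(table: pd.DataFrame) -> np.ndarray:
    cols = [c for c in FEATURE_NAMES if c in table.columns]
    if not cols:
        cols = [c for c in table.columns
                if c.startswith("pc") and c[2:].isdigit()]
    return table[cols].to_numpy(float)


def run_benchmark(table: pd.DataFrame, specs: list[ClassifierSpec],
                  cfg: ResampleConfig, spaces: tuple[str, ...] = ("15d",),
                  n_components: int = 7,
                  pca_global: bool = False) -> dict[tuple[str, str], ConfusionEnsemble]:
    """Monte Carlo under-sampling benchmark over classifiers and spaces.

    Returns one ConfusionEnsemble per (space, classifier-name) setting.
    ``spaces`` may contain ``"15d"`` (raw feature columns) and ``"7d"``
    (PCA scores, ``n_components`` kept). By default PCA is refit on each
    draw's training half only; ``pca_global=True`` fits it once on the
    whole table before resampling, mirroring a whole-dataset fit.
    """
    for s in spaces:
        if s not in ("15d", "7d"):
            raise ValueError("spaces entries must be '15d' or '7d'")
    labels = _label_codes(table)
    x_full = _feature_matrix(table)
    if not np.all(np.isfinite(x_full)):
        raise ValueError("feature table contains non-finite values; clean first")

    global_model = dimred.fit_pca(x_full) if ("7d" in spaces and pca_global) else None

    master = np.random.SeedSequence(cfg.seed)
    draw_seeds = master.spawn(cfg.R)
    stacks: dict[tuple[str, str], list[np.ndarray]] = {
        (space, spec.name): [] for space in spaces for spec in specs
    }
    for i in range(cfg.R):
        children = draw_seeds[i].spawn(2 + len(specs))
        rng_sample = np.random.default_rng(children[0])
        rng_split = np.random.default_rng(children[1])
        sub = balanced_undersample(labels, rng_sample)
        train_idx, test_idx = split_half(sub, labels, rng_split)
        y_train, y_test = labels[train_idx], labels[test_idx]
        views: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if "15d" in spaces:
            views["15d"] = (x_full[train_idx], x_full[test_idx])
        if "7d" in spaces:
            model = global_model or dimred.fit_pca(x_full[train_idx])
            views["7d"] = (
                dimred.transform(model, x_full[train_idx], n_components),
                dimred.transform(model, x_full[test_idx], n_components),
            )
        for j, spec in enumerate(specs):
            seeded = spec.with_seed(int(children[2 + j].generate_state(1)[0] % (2**31)))
            for space, (x_train, x_test) in views.items():
                pred = fit_predict(seeded, (x_train, y_train), x_test)
                stacks[(space, spec.name)].append(confusion(y_test, pred))
    return {
        key: ConfusionEnsemble(np.stack(mats)) for key, mats in stacks.items()
    }


def average_confusion(ensemble: ConfusionEnsemble) -> np.ndarray:
    """Row-normalize every matrix, then average element-wise.

    The result is the mean confusion matrix on a 0-1 scale; its rows sum
    to 1.
    """
    m = ensemble.matrices.astype(float)
    rows = m.sum(axis=2, keepdims=True)
    if np.any(rows == 0):
        raise ValueError("a confusion matrix has an empty row; cannot normalize")
    return (m / rows).mean(axis=0)


# ---------------------------------------------------------------------------
# Model / Results presentation
# ---------------------------------------------------------------------------

class MonteCarloBenchmark:
    """Benchmark model over a cleaned, normalized feature table.

    Parameters
    ----------
    table
        Feature table with a ``stimulus`` label column and the 15
        feature columns, already outlier-filtered and normalized.
    specs
        Classifier configurations; defaults to the full ten-model
        registry.
    spaces
        Feature spaces to benchmark: ``("15d",)``, ``("7d",)`` or both.
    """

    def __init__(self, table: pd.DataFrame,
                 specs: list[ClassifierSpec] | None = None,
                 spaces: tuple[str, ...] = ("15d", "7d"),
                 n_components: int = 7,
                 pca_global: bool = False):
        from .classify import CLASSIFIER_NAMES

        self.table = table
        self.specs = specs or [ClassifierSpec(n) for n in CLASSIFIER_NAMES]
        self.spaces = tuple(spaces)
        self.n_components = n_components
        self.pca_global = pca_global

    def fit(self, R: int = 1000, seed: int = 0) -> "BenchmarkResults":
        cfg = ResampleConfig(R=R, seed=seed)
        ensembles = run_benchmark(self.table, self.specs, cfg,
                                  spaces=self.spaces,
                                  n_components=self.n_components,
                                  pca_global=self.pca_global)
        return BenchmarkResults(self, cfg, ensembles)


@dataclass
class BenchmarkResults:
    """Fitted benchmark: ensembles, metric distributions, summaries."""

    model: MonteCarloBenchmark
    config: ResampleConfig
    ensembles: dict[tuple[str, str], ConfusionEnsemble]
    _distributions: dict = field(default_factory=dict, repr=False)

    def distribution(self, space: str, name: str) -> metrics_mod.MetricDistribution:
        key = (space, name)
        if key not in self._distributions:
            self._distributions[key] = metrics_mod.metric_distributions(
                self.ensembles[key]
            )
        return self._distributions[key]

    def average_confusion(self, space: str, name: str) -> np.ndarray:
        return average_confusion(self.ensembles[(space, name)])

    def metrics_frame(self) -> pd.DataFrame:
        """Long table: draw, classifier, space, acc, bal_acc, f1, mcc."""
        parts = []
        for (space, name) in self.ensembles:
            values = self.distribution(space, name).values.copy()
            values.insert(0, "draw", np.arange(len(values)))
            values.insert(1, "classifier", name)
            values.insert(2, "space", space)
            parts.append(values)
        return pd.concat(parts, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        """Mean and sd of every metric per (classifier, space)."""
        rows = []
        for (space, name) in sorted(self.ensembles):
            dist = self.distribution(space, name)
            row = {"classifier": name, "space": space}
            for m in metrics_mod.METRIC_NAMES:
                row[f"{m}_mean"] = dist.mean[m]
                row[f"{m}_sd"] = dist.std[m]
            rows.append(row)
        return pd.DataFrame(rows)

    def save_ensembles(self, path: str | Path) -> None:
        payload = {
            f"{space}/{name}": ens.matrices.tolist()
            for (space, name), ens in self.ensembles.items()
        }
        payload["seed"] = self.config.seed
        Path(path).write_text(json.dumps(payload))
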