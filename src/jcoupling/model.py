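"""Per-coupling-type gradient-boosted regression of scalar coupling constants.

The modelling surface follows the familiar Model/Results pattern: a
:class:`ScalarCouplingModel` is built from a structure map and a coupling
table, and :meth:`ScalarCouplingModel.fit` returns a
:class:`ScalarCouplingResults` carrying one trained LightGBM booster per
coupling type together with held-out metrics (r², RMSE, RRMSE), variable
importances and a text ``summary()``.

Data are split at the molecule level (all records of a molecule fall in the
same partition) so that no structural information leaks between training and
test sets.  Near-constant toolkit descriptors are removed with a
most-frequent-value filter computed on the training partition only.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import lightgbm as lgb
import numpy as np
import pandas as pd

from . import descriptors as desc
from .graph import perceive_bonds
from .io import CouplingTable, MolecularStructure

__all__ = [
    "BoostingParams",
    "ModelBundle",
    "MetricsReport",
    "split_by_molecule",
    "train",
    "predict",
    "evaluate",
    "importance",
    "ScalarCouplingModel",
    "ScalarCouplingResults",
    "run_per_type_pipeline",
    "plot_parity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoostingParams:
    """LightGBM hyperparameters; the defaults are the reference configuration."""

    num_leaves: int = 128
    min_child_samples: int = 79
    bagging_seed: int = 11
    learning_rate: float = 0.2
    reg_lambda: float = 0.3
    boosting_type: str = "gbdt"
    subsample_freq: int = 1
    subsample: float = 0.9
    objective: str = "regression"
    metric: str = "mae"
    verbosity: int = -1
    reg_alpha: float = 0.1
    max_depth: int = 13
    colsample_bytree: float = 1.0
    # round count and threading are artifact choices, not part of the
    # reference table; single-threaded deterministic training is the default
    n_rounds: int = 1000
    num_threads: int = 1

    def to_lightgbm(self) -> Dict[str, object]:
        return {
            "num_leaves": self.num_leaves,
            "min_child_samples": self.min_child_samples,
            "bagging_seed": self.bagging_seed,
            "learning_rate": self.learning_rate,
            "reg_lambda": self.reg_lambda,
            "boosting_type": self.boosting_type,
            "subsample_freq": self.subsample_freq,
            "subsample": self.subsample,
            "objective": self.objective,
            "metric": self.metric,
            "verbosity": self.verbosity,
            "reg_alpha": self.reg_alpha,
            "max_depth": self.max_depth,
            "colsample_bytree": self.colsample_bytree,
            "num_threads": self.num_threads,
            "deterministic": True,
            "force_row_wise": True,
            "seed": self.bagging_seed,
        }


@dataclass
class ModelBundle:
    """One trained booster with everything needed to apply it later."""

    coupling_type: str
    booster: lgb.Booster
    feature_names: Tuple[str, ...]  # after variance filtering
    filter_mask: Optional[pd.Series]  # keep mask over the unfiltered columns
    params: BoostingParams
    split_seed: Optional[int] = None
    mode: str = "proposed"


@dataclass(frozen=True)
class MetricsReport:
    """Held-out regression metrics for one coupling type."""

    r2: float
    rmse: float  # Hz
    rrmse: float  # dimensionless, rmse / population std of y_true
    n: int


def split_by_molecule(
    molecule_ids: Sequence[str], train_fraction: float = 0.7, seed: int = 42
) -> Tuple[List[str], List[str]]:
    """Randomly partition molecule ids into train/test at the molecule level.

    ``|train| = floor(train_fraction * n)``; partitions are disjoint,
    exhaustive and deterministic given the seed.
    """
    ids = list(molecule_ids)
    if not ids:
        raise ValueError("cannot split an empty molecule-id list")
    if len(set(ids)) != len(ids):
        raise ValueError("molecule ids must be unique")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = math.floor(train_fraction * len(ids))
    train_ids = sorted(ids[k] for k in order[:n_train])
    test_ids = sorted(ids[k] for k in order[n_train:])
    return train_ids, test_ids


def train(
    features: pd.DataFrame,
    y: np.ndarray,
    params: Optional[BoostingParams] = None,
    coupling_type: str = "",
    mode: str = "proposed",
) -> ModelBundle:
    """Train one booster on a named feature matrix.

    ``features`` must contain descriptor columns only (no meta columns).
    """
    params = params or BoostingParams()
    y = np.asarray(y, dtype=float)
    if features.shape[0] != y.shape[0] or y.shape[0] < 2:
        raise ValueError("features and y must have equal length >= 2")
    if not np.all(np.isfinite(y)):
        raise ValueError("training targets must be finite")
    if y.shape[0] < params.min_child_samples:
        warnings.warn(
            f"only {y.shape[0]} rows < min_child_samples={params.min_child_samples}; "
            "the model may degenerate to a constant",
            stacklevel=2,
        )
    dataset = lgb.Dataset(
        features.to_numpy(dtype=float), label=y,
        feature_name=list(features.columns), free_raw_data=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        booster = lgb.train(params.to_lightgbm(), dataset, num_boost_round=params.n_rounds)
    return ModelBundle(
        coupling_type=coupling_type,
        booster=booster,
        feature_names=tuple(features.columns),
        filter_mask=None,
        params=params,
        mode=mode,
    )


def predict(bundle: ModelBundle, features: pd.DataFrame) -> np.ndarray:
    """Predict coupling constants (Hz) for a named feature matrix.

    Extra columns are allowed (the stored feature list is selected from
    them); missing columns raise with their names.
    """
    missing = [c for c in bundle.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature matrix is missing columns {missing}")
    x = features[list(bundle.feature_names)]
    if x.shape[0] == 0:
        return np.empty(0)
    return np.asarray(bundle.booster.predict(x.to_numpy(dtype=float)))


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """r², RMSE and RRMSE of predictions against true values.

    r² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²; RRMSE divides RMSE by the population standard
    deviation of the true values, so r² = 1 − RRMSE² holds exactly.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must have equal nonzero length")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y_true has zero variance; r2 and rrmse are undefined")
    rmse = math.sqrt(ss_res / y_true.size)
    rrmse = math.sqrt(ss_res / ss_tot)  # == rmse / population std
    # derive r2 from rrmse so the identity r2 = 1 - rrmse^2 is exact
    return MetricsReport(r2=1.0 - rrmse * rrmse, rmse=rmse, rrmse=rrmse, n=y_true.size)


def importance(bundle: ModelBundle, top_n: int = 3) -> List[Tuple[str, float]]:
    """Top descriptors by the booster's split-gain importance, descending."""
    gains = bundle.booster.feature_importance(importance_type="gain")
    names = bundle.feature_names
    order = sorted(range(len(names)), key=lambda k: (-gains[k], names[k]))
    return [(names[k], float(gains[k])) for k in order[: min(top_n, len(names))]]


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class ScalarCouplingModel:
    """Scalar-coupling regression over a structure map and a coupling table.

    Parameters
    ----------
    structures
        Map of molecule_id to :class:`~jcoupling.io.MolecularStructure`.
    couplings
        Coupling records with constants (Hz) for training.
    mode
        ``"proposed"`` (full atom-pair featurization) or ``"traditional"``
        (molecular descriptors + pair distance only).
    coupling_types
        Optional subset of types to model; defaults to every type present.
    """

    def __init__(
        self,
        structures: Dict[str, MolecularStructure],
        couplings: CouplingTable,
        mode: str = "proposed",
        coupling_types: Optional[Iterable[str]] = None,
    ):
        if mode not in ("proposed", "traditional"):
            raise ValueError(f"unknown mode {mode!r}")
        self.structures = structures
        self.couplings = couplings
        self.mode = mode
        present = couplings.coupling_types
        if coupling_types is None:
            self.coupling_types = present
        else:
            requested = [t for t in coupling_types]
            self.coupling_types = [t for t in present if t in requested]

    @classmethod
    def from_csv(cls, structures_path, couplings_path, **kwargs) -> "ScalarCouplingModel":
        from .io import read_couplings_csv, read_structures_csv

        return cls(
            read_structures_csv(structures_path),
            read_couplings_csv(couplings_path),
            **kwargs,
        )

    def fit(
        self,
        train_fraction: float = 0.7,
        seed: int = 42,
        params: Optional[BoostingParams] = None,
        variance_threshold: float = 0.95,
        top_n_importance: int = 3,
    ) -> "ScalarCouplingResults":
        """Split at molecule level, then featurize/filter/train/evaluate per type."""
        params = params or BoostingParams()
        mol_ids = self.couplings.molecule_ids()
        train_ids, test_ids = split_by_molecule(mol_ids, train_fraction, seed)
        train_set, test_set = set(train_ids), set(test_ids)
        assert not train_set & test_set, "molecule-level split leaked"

        graphs = {}
        metrics: Dict[str, MetricsReport] = {}
        bundles: Dict[str, ModelBundle] = {}
        importances: Dict[str, List[Tuple[str, float]]] = {}
        predictions: Dict[str, pd.DataFrame] = {}
        for ctype in self.coupling_types:
            table = self.couplings.by_type(ctype)
            if len(table) == 0:
                logger.warning("coupling type %s has zero records; skipped", ctype)
                continue
            for mid in table.molecule_ids():
                if mid not in graphs:
                    graphs[mid] = perceive_bonds(self.structures[mid])
            frame = desc.featurize_table(self.structures, table, mode=self.mode, graphs=graphs)
            if "y" not in frame.columns or frame["y"].isna().any():
                raise ValueError(f"type {ctype}: training requires constants on every record")
            in_train = frame["molecule_name"].isin(train_set)
            feature_cols = [c for c in frame.columns if c not in desc._META_COLUMNS + ["y"]]
            x_train = frame.loc[in_train, feature_cols]
            x_test = frame.loc[~in_train, feature_cols]
            if x_train.shape[0] < 2 or x_test.shape[0] == 0:
                logger.warning("coupling type %s: too few records to train/evaluate; skipped", ctype)
                continue
            mask = desc.variance_filter(x_train, threshold=variance_threshold)
            kept = [c for c in feature_cols if mask[c]]
            bundle = train(
                x_train[kept], frame.loc[in_train, "y"].to_numpy(),
                params=params, coupling_type=ctype, mode=self.mode,
            )
            bundle.filter_mask = mask
            bundle.split_seed = seed
            y_pred = predict(bundle, x_test)
            y_true = frame.loc[~in_train, "y"].to_numpy()
            metrics[ctype] = evaluate(y_true, y_pred)
            bundles[ctype] = bundle
            importances[ctype] = importance(bundle, top_n_importance)
            predictions[ctype] = pd.DataFrame(
                {
                    "molecule_name": frame.loc[~in_train, "molecule_name"].to_numpy(),
                    "y_true": y_true,
                    "y_pred": y_pred,
                }
            )
        return ScalarCouplingResults(
            mode=self.mode,
            metrics=metrics,
            bundles=bundles,
            importances=importances,
            train_ids=train_ids,
            test_ids=test_ids,
            predictions=predictions,
        )


@dataclass
class ScalarCouplingResults:
    """Fit results: per-type boosters, held-out metrics and importances."""

    mode: str
    metrics: Dict[str, MetricsReport]
    bundles: Dict[str, ModelBundle]
    importances: Dict[str, List[Tuple[str, float]]]
    train_ids: List[str]
    test_ids: List[str]
    predictions: Dict[str, pd.DataFrame] = field(default_factory=dict)

    def metrics_frame(self) -> pd.DataFrame:
        """Per-type metrics table: type, mode, r2, rmse, rrmse, n_test."""
        rows = [
            (t, self.mode, m.r2, m.rmse, m.rrmse, m.n)
            for t, m in self.metrics.items()
        ]
        return pd.DataFrame(rows, columns=["type", "mode", "r2", "rmse", "rrmse", "n_test"])

    def importance_frame(self) -> pd.DataFrame:
        """Per-type top descriptors: type, rank, descriptor, importance."""
        rows = []
        for t, pairs in self.importances.items():
            for rank, (name, gain) in enumerate(pairs, start=1):
                rows.append((t, rank, name, gain))
        return pd.DataFrame(rows, columns=["type", "rank", "descriptor", "importance"])

    def predict_table(
        self,
        structures: Dict[str, MolecularStructure],
        couplings: CouplingTable,
    ) -> CouplingTable:
        """Predict constants for new records; every type needs a fitted bundle."""
        needed = couplings.coupling_types
        missing = [t for t in needed if t not in self.bundles]
        if missing:
            raise ValueError(f"no trained bundle for coupling type(s) {missing}")
        out = []
        for ctype in needed:
            table = couplings.by_type(ctype)
            frame = desc.featurize_table(structures, table, mode=self.mode)
            values = predict(self.bundles[ctype], frame)
            for rec, v in zip(table, values):
                out.append(rec.with_constant(float(v)))
        return CouplingTable(out)

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Scalar coupling regression (LightGBM, molecule-level split)",
            f"mode: {self.mode}   train molecules: {len(self.train_ids)}   "
            f"test molecules: {len(self.test_ids)}",
            "",
            f"{'type':<6}{'n_test':>8}{'r2':>9}{'RMSE/Hz':>10}{'RRMSE':>8}",
        ]
        for t, m in self.metrics.items():
            lines.append(f"{t:<6}{m.n:>8}{m.r2:>9.3f}{m.rmse:>10.3f}{m.rrmse:>8.3f}")
        lines.append("")
        lines.append("top descriptors by split gain:")
        for t, pairs in self.importances.items():
            for rank, (name, gain) in enumerate(pairs, start=1):
                lines.append(f"  {t} #{rank}: {name} ({gain:.1f})")
        return "\n".join(lines)


def run_per_type_pipeline(
    structures: Dict[str, MolecularStructure],
    couplings: CouplingTable,
    mode: str = "proposed",
    train_fraction: float = 0.7,
    seed: int = 42,
    params: Optional[BoostingParams] = None,
    variance_threshold: float = 0.95,
    coupling_types: Optional[Iterable[str]] = None,
    top_n_importance: int = 3,
) -> ScalarCouplingResults:
    """Functional wrapper: build a :class:`ScalarCouplingModel` and fit it."""
    model = ScalarCouplingModel(structures, couplings, mode=mode, coupling_types=coupling_types)
    return model.fit(
        train_fraction=train_fraction,
        seed=seed,
        params=params,
        variance_threshold=variance_threshold,
        top_n_importance=top_n_importance,
    )


def plot_parity(results: ScalarCouplingResults, coupling_type: str, ax=None):
    """Parity plot (actual vs predicted, Hz) for one coupling type's test set."""
    import matplotlib.pyplot as plt

    frame = results.predictions[coupling_type]
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(frame["y_true"], frame["y_pred"], s=4, alpha=0.4)
    lims = [
        min(frame["y_true"].min(), frame["y_pred"].min()),
        max(frame["y_true"].max(), frame["y_pred"].max()),
    ]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("actual J / Hz")
    ax.set_ylabel("predicted J / Hz")
    ax.set_title(f"{coupling_type} ({results.mode})")
    return ax
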