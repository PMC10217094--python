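"""Single-layer perceptron temperature regression over k channel features.

The model is one linear layer (identity activation by default) mapping a
standardised feature vector of k hyperspectral channel values — optionally
plus a key-day feature — to temperature in deg C, trained by full-batch
gradient descent on the mean-squared error with early stopping.  The
reported loss is the pooled multi-day RMSE

    RMSE = sqrt( sum_j sum_{m in M_j} (py_jm - y_jm)^2 / n ),

where py_jm is the prediction for the m-th mask pixel of key day j and n
is the total pixel count over all day masks — i.e. plain RMSE over the
pooled rows, never an unweighted mean of per-day RMSEs.

The default learning rate is "auto": each descent step uses the exact
line-search length for the quadratic objective (g.g / g'Hg), which is
stable and monotone for any feature collinearity — hyperspectral
channels are strongly collinear, so a fixed step that is safe for k = 1
can diverge or stall at k = 204.  A numeric learning rate is applied
verbatim as a fixed step instead.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .types import PointCloud


class DivergenceError(RuntimeError):
    """Training loss became non-finite (learning rate too high)."""


@dataclass
class SLPConfig:
    """Training hyper-parameters for the perceptron regressor.

    learning_rate : "auto" (exact line-search step, always stable) or a
        float step size applied to the MSE gradient on standardised
        features.
    max_epochs, patience : early-stopping budget — training stops when the
        monitored RMSE has not improved by > min_delta for `patience`
        consecutive epochs.
    batch_size : None for full-batch descent (default), else a seeded
        mini-batch shuffle per epoch.
    output_activation : "identity" (default) or "sigmoid" — the latter
        squashes the linear output through a sigmoid rescaled to the
        training target range (experimentation hook).
    """

    learning_rate: float | str = "auto"
    max_epochs: int = 500
    patience: int = 20
    min_delta: float = 1e-6
    batch_size: int | None = None
    val_fraction: float = 0.1
    seed: int = 0
    output_activation: str = "identity"

    def __post_init__(self) -> None:
        if self.learning_rate != "auto" and not float(self.learning_rate) > 0:
            raise ValueError("learning_rate must be 'auto' or > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.output_activation not in ("identity", "sigmoid"):
            raise ValueError("output_activation must be 'identity' or 'sigmoid'")


@dataclass
class FeatureMatrix:
    """Masked pixels pooled over key days, as rows of channel features.

    ``x`` holds the raw (unstandardised) feature columns: one per channel
    in ``channels`` plus, iff ``include_day``, a trailing key-day column
    min-max scaled to [0, 1] over the days present.  Per-column mean/std
    (population) are computed from these rows; a model trained on a
    matrix applies *its* training statistics to any matrix it predicts on.
    """

    x: np.ndarray                 # (n, p) raw features
    y: np.ndarray                 # (n,) deg C targets
    day: np.ndarray               # (n,) key-day ordinal per row
    channels: tuple[int, ...]
    include_day: bool = False
    means: np.ndarray = field(init=False)
    stds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=np.float64))
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.day = np.asarray(self.day, dtype=int).ravel()
        self.channels = tuple(int(c) for c in self.channels)
        p_expected = len(self.channels) + (1 if self.include_day else 0)
        if self.x.shape[1] != p_expected:
            raise ValueError(
                f"feature matrix has {self.x.shape[1]} columns, expected {p_expected}"
            )
        if not (self.x.shape[0] == self.y.size == self.day.size):
            raise ValueError("rows, targets and day labels must align")
        self.means = self.x.mean(axis=0) if self.x.size else np.zeros(self.x.shape[1])
        self.stds = self.x.std(axis=0) if self.x.size else np.ones(self.x.shape[1])
        for j in range(len(self.channels)):
            if self.x.shape[0] > 1 and self.stds[j] <= 1e-12 * (1.0 + abs(self.means[j])):
                raise ValueError(
                    f"channel {self.channels[j]} has zero variance; cannot standardise"
                )

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def p(self) -> int:
        return self.x.shape[1]

    @property
    def column_names(self) -> tuple[str, ...]:
        names = tuple(f"ch{c}" for c in self.channels)
        return names + (("day",) if self.include_day else ())

    def rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.x[idx], self.y[idx], self.day[idx], self.channels, self.include_day
        )


def assemble_features(
    clouds: Sequence[PointCloud],
    channels: Sequence[int],
    include_day: bool = False,
) -> FeatureMatrix:
    """Pool per-day clouds into one feature matrix.

    All clouds must have been sampled with (at least) the requested
    channels.  With ``include_day``, the key-day ordinal is appended
    min-max scaled to [0, 1] over the days present (the earliest day maps
    to 0, the latest to 1).
    """
    channels = [int(c) for c in channels]
    if not channels:
        raise ValueError("channel list must be non-empty")
    if not clouds:
        raise ValueError("need at least one cloud")
    xs, ys, ds = [], [], []
    for cloud in clouds:
        sub = cloud.select_channels(channels)
        xs.append(sub.x)
        ys.append(sub.y)
        ds.append(np.full(sub.n, cloud.day, dtype=int))
    x = np.vstack(xs)
    y = np.concatenate(ys)
    day = np.concatenate(ds)
    if include_day:
        lo, hi = day.min(), day.max()
        scaled = (day - lo) / (hi - lo) if hi > lo else np.zeros_like(day, dtype=float)
        x = np.column_stack([x, scaled])
    return FeatureMatrix(x, y, day, tuple(channels), include_day)


def _step_size(xs: np.ndarray, gw: np.ndarray, gb: float, fixed: float | None) -> float:
    """Step length for one descent update.

    ``fixed`` (a numeric learning rate) is used verbatim.  Otherwise the
    exact line-search step for the quadratic objective is returned,
    ``g.g / (g^T H g)`` with H the Gauss-Newton Hessian of the MSE — the
    steepest-descent step that minimises the loss along the gradient and
    can never increase it.
    """
    if fixed is not None:
        return fixed
    num = float(gw @ gw) + gb * gb
    if num == 0.0:
        return 0.0
    ag = xs @ gw + gb
    denom = (2.0 / xs.shape[0]) * float(ag @ ag)
    if denom == 0.0:
        return 0.0
    return num / denom


class SLPRegressor:
    """Single-layer perceptron model: linear layer over standardised features.

    Parameters
    ----------
    train : FeatureMatrix
    val : FeatureMatrix, optional
        Held-out rows monitored for early stopping (the pot-level test
        split, when available).  If omitted, a seeded `val_fraction` row
        split is carved out of ``train``; with ``val_fraction = 0`` early
        stopping monitors the training loss itself.
    config : SLPConfig
    """

    def __init__(
        self,
        train: FeatureMatrix,
        val: FeatureMatrix | None = None,
        config: SLPConfig | None = None,
    ) -> None:
        self.config = config or SLPConfig()
        if val is None and self.config.val_fraction > 0 and train.n >= 20:
            rng = np.random.default_rng(self.config.seed)
            perm = rng.permutation(train.n)
            n_val = max(1, int(round(train.n * self.config.val_fraction)))
            val = train.rows(perm[:n_val])
            train = train.rows(perm[n_val:])
        self.train_data = train
        self.val_data = val
        if train.n < 10:
            raise ValueError(f"need >= 10 training rows, got {train.n}")
        tiny = train.stds <= 1e-12 * (1.0 + np.abs(train.means))
        if np.any(tiny):
            j = int(np.argmax(tiny))
            raise ValueError(
                f"training feature column {train.column_names[j]!r} has zero variance"
            )

    def fit(self) -> "SLPResults":
        cfg = self.config
        tr = self.train_data
        xs = (tr.x - tr.means) / tr.stds
        y = tr.y
        n, p = xs.shape

        line_search = cfg.learning_rate == "auto"
        step = None if line_search else float(cfg.learning_rate)

        if self.val_data is not None and self.val_data.n > 0:
            xv = (self.val_data.x - tr.means) / tr.stds
            yv = self.val_data.y
        else:
            xv = yv = None

        rng = np.random.default_rng(cfg.seed)
        w = np.zeros(p)
        b = float(y.mean())
        y_lo, y_hi = float(y.min()), float(y.max())
        act = cfg.output_activation

        def forward(xmat, wv, bv):
            z = xmat @ wv + bv
            if act == "sigmoid":
                return y_lo + (y_hi - y_lo) / (1.0 + np.exp(-z))
            return z

        history_train: list[float] = []
        history_val: list[float] = []
        best = np.inf
        best_w, best_b = w.copy(), b
        stale = 0
        t0 = time.perf_counter()

        for epoch in range(cfg.max_epochs):
            pred = forward(xs, w, b)
            resid = pred - y
            train_rmse = float(np.sqrt(np.mean(resid**2)))
            if not np.isfinite(train_rmse):
                raise DivergenceError(
                    f"training loss became non-finite at epoch {epoch}; lower the learning rate"
                )
            history_train.append(train_rmse)
            if xv is not None:
                vres = forward(xv, w, b) - yv
                monitored = float(np.sqrt(np.mean(vres**2)))
                history_val.append(monitored)
            else:
                monitored = train_rmse
            if monitored < best - cfg.min_delta:
                best = monitored
                best_w, best_b = w.copy(), b
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
            # gradient step (full batch or seeded mini-batches)
            if cfg.batch_size is None:
                grad_w = (2.0 / n) * (xs.T @ resid)
                grad_b = 2.0 * float(resid.mean())
                s = _step_size(xs, grad_w, grad_b, step)
                w = w - s * grad_w
                b = b - s * grad_b
            else:
                order = rng.permutation(n)
                for start in range(0, n, cfg.batch_size):
                    idx = order[start:start + cfg.batch_size]
                    r = forward(xs[idx], w, b) - y[idx]
                    gw = (2.0 / idx.size) * (xs[idx].T @ r)
                    gb = 2.0 * float(r.mean())
                    s = _step_size(xs[idx], gw, gb, step)
                    w = w - s * gw
                    b = b - s * gb

        wall = time.perf_counter() - t0
        return SLPResults(
            weights=best_w,
            bias=best_b,
            means=tr.means.copy(),
            stds=tr.stds.copy(),
            channels=tr.channels,
            include_day=tr.include_day,
            config=cfg,
            history_train=history_train,
            history_val=history_val,
            epochs_run=len(history_train),
            wall_seconds=wall,
            y_lo=y_lo,
            y_hi=y_hi,
        )


@dataclass
class SLPResults:
    """Trained perceptron: weights, standardisation, training history."""

    weights: np.ndarray
    bias: float
    means: np.ndarray
    stds: np.ndarray
    channels: tuple[int, ...]
    include_day: bool
    config: SLPConfig
    history_train: list[float]
    history_val: list[float]
    epochs_run: int
    wall_seconds: float = 0.0
    y_lo: float = float("nan")    # training target range; used by the sigmoid output hook
    y_hi: float = float("nan")

    def predict(self, features: FeatureMatrix) -> np.ndarray:
        """deg C per row; features are standardised with the training statistics."""
        if features.channels != self.channels or features.include_day != self.include_day:
            raise ValueError(
                f"feature columns {features.column_names} do not match the model's "
                f"({tuple(f'ch{c}' for c in self.channels)}"
                f"{' + day' if self.include_day else ''})"
            )
        xs = (features.x - self.means) / self.stds
        z = xs @ self.weights + self.bias
        if self.config.output_activation == "sigmoid":
            return self.y_lo + (self.y_hi - self.y_lo) / (1.0 + np.exp(-z))
        return z

    def evaluate(self, features: FeatureMatrix) -> tuple[float, dict[int, float]]:
        """Pooled RMSE (deg C) over all rows plus a per-day RMSE breakdown."""
        if features.n == 0:
            raise ValueError("cannot evaluate on an empty feature matrix")
        pred = self.predict(features)
        err = pred - features.y
        pooled = float(np.sqrt(np.mean(err**2)))
        per_day: dict[int, float] = {}
        for d in np.unique(features.day):
            sel = features.day == d
            per_day[int(d)] = float(np.sqrt(np.mean(err[sel] ** 2)))
        return pooled, per_day

    def summary(self) -> str:
        k = len(self.channels)
        lines = [
            "SLP temperature regressor",
            "-------------------------",
            f"features          {k} channel(s)" + (" + key day" if self.include_day else ""),
            f"channels          {list(self.channels)}",
            f"epochs run        {self.epochs_run} (max {self.config.max_epochs})",
            f"final train RMSE  {self.history_train[-1]:.4g} degC",
        ]
        if self.history_val:
            lines.append(f"best val RMSE     {min(self.history_val):.4g} degC")
        lines.append(f"bias              {self.bias:.4g} degC")
        order = np.argsort(-np.abs(self.weights))[: min(8, len(self.weights))]
        names = tuple(f"ch{c}" for c in self.channels) + (
            ("day",) if self.include_day else ()
        )
        lines.append("largest weights (degC per sd):")
        for j in order:
            lines.append(f"  {names[j]:<8} {self.weights[j]:+.4g}")
        return "\n".join(lines)

    # -- JSON round-trip -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
            "channels": list(self.channels),
            "include_day": self.include_day,
            "config": {
                "learning_rate": self.config.learning_rate,
                "max_epochs": self.config.max_epochs,
                "patience": self.config.patience,
                "min_delta": self.config.min_delta,
                "batch_size": self.config.batch_size,
                "val_fraction": self.config.val_fraction,
                "seed": self.config.seed,
                "output_activation": self.config.output_activation,
            },
            "history_train": self.history_train,
            "history_val": self.history_val,
            "epochs_run": self.epochs_run,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SLPResults":
        doc = json.loads(Path(path).read_text())
        return cls(
            weights=np.array(doc["weights"]),
            bias=float(doc["bias"]),
            means=np.array(doc["means"]),
            stds=np.array(doc["stds"]),
            channels=tuple(doc["channels"]),
            include_day=bool(doc["include_day"]),
            config=SLPConfig(**doc["config"]),
            history_train=list(doc["history_train"]),
            history_val=list(doc["history_val"]),
            epochs_run=int(doc["epochs_run"]),
        )


@dataclass
class TrainReport:
    """One row of the channel-study report (mirrors the study tables' columns)."""

    label: str
    k: int
    thr: float
    a: float
    b: float
    train_mask_pix: int
    test_mask_pix: int
    train_rmse_c: float
    test_rmse_c: float
    epochs: int
    wall_seconds: float = 0.0

    def as_row(self, with_time: bool = False) -> dict:
        row = {
            "label": self.label, "k": self.k, "thr": self.thr, "a": self.a,
            "b": self.b, "train_mask_pix": self.train_mask_pix,
            "test_mask_pix": self.test_mask_pix,
            "train_rmse_c": self.train_rmse_c, "test_rmse_c": self.test_rmse_c,
            "epochs": self.epochs,
        }
        if with_time:
            row["wall_seconds"] = self.wall_seconds
        return row


def train_slp(
    train: FeatureMatrix,
    val: FeatureMatrix | None = None,
    config: SLPConfig | None = None,
) -> SLPResults:
    """Convenience wrapper: build and fit an :class:`SLPRegressor`."""
    return SLPRegressor(train, val, config).fit()
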