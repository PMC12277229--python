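"""Feed-forward surrogate for per-sample safe-intake limits.

A small fully connected network learns the mapping from encoded tubewell
features to the (log) safe water-intake limit, trained by mini-batch
gradient descent with an L2 penalty applied through the update

    w  <-  w - eta * ( alpha * dR(w)/dw + dLoss/dw ),    R(w) = 0.5 ||w||^2

i.e. the regularization strength ``alpha`` scales the penalty gradient
inside the step (biases are not penalized).  Validation follows the study
protocol: a stratified 90/10 train-test split plus tenfold cross-validation
over a half-decade alpha grid.  Interpretation uses exact Shapley values by
coalition enumeration under the interventional convention (absent features
are drawn from the background table), which satisfies the efficiency axiom
to machine precision; a seeded permutation-sampling estimator covers wider
feature sets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import Dataset, GuidelineRule, UNIONS

__all__ = [
    "UNION_CODES",
    "FEATURE_ORDER",
    "SurrogateConfig",
    "SurrogateModel",
    "FitReport",
    "CvResult",
    "Attribution",
    "AlphaClusterReport",
    "encode_features",
    "decode_union",
    "train_surrogate",
    "cross_validate",
    "shapley_attribution",
    "alpha_cluster_report",
    "save_model",
    "load_model",
]

# ---------------------------------------------------------------------------
# Feature encoding

#: Codebook for the categorical union feature (alphabetical, documented).
UNION_CODES: dict[str, int] = {u: i for i, u in enumerate(sorted(UNIONS))}
_CODE_TO_UNION = {v: k for k, v in UNION_CODES.items()}

#: Fixed feature column order of the encoded design matrix.
FEATURE_ORDER: tuple[str, ...] = (
    "union_code", "depth", "fe", "as", "ph", "ec", "tds",
    "fe_who", "fe_bdws", "as_who", "as_bdws",
)

_FLAG_RULES = {  # flag column -> (authority, parameter)
    "fe_who": ("WHO", "fe"),
    "fe_bdws": ("BDWS", "fe"),
    "as_who": ("WHO", "as"),
    "as_bdws": ("BDWS", "as"),
}


def decode_union(code: int) -> str:
    """Inverse of the union codebook."""
    return _CODE_TO_UNION[int(code)]


def encode_features(dataset: Dataset, registry: Sequence[GuidelineRule]) -> pd.DataFrame:
    """Numeric design matrix: union code, physicochemistry, and binary
    guideline-exceedance flags per analyte; column order is fixed."""
    df = dataset.df
    mandatory = ["depth", "fe", "as", "ph", "ec", "tds"]
    for col in mandatory:
        if df[col].isna().any():
            raise ValueError(f"missing mandatory feature values in column {col!r}")
    rules = {(r.authority, r.parameter): r for r in registry}
    out = pd.DataFrame(index=df.index)
    out["union_code"] = df["union"].map(UNION_CODES).astype(float)
    for col in mandatory:
        out[col] = df[col].astype(float)
    for flag, key in _FLAG_RULES.items():
        rule = rules.get(key)
        if rule is None:
            raise ValueError(f"registry lacks rule for {key}")
        out[flag] = df[key[1]].map(lambda v, r=rule: float(r.exceeded_by(v)))
    return out.loc[:, list(FEATURE_ORDER)]


# ---------------------------------------------------------------------------
# Model

@dataclass(frozen=True)
class SurrogateConfig:
    hidden_layers: tuple[int, ...] = (16, 8)
    activation: str = "relu"                 # relu | tanh
    eta: float = 0.02                        # learning rate
    alpha: float = 0.001                     # L2 strength in the update
    alpha_sweep: tuple[float, ...] = (0.10, 0.3162, 1.0, 3.1623, 10.0)
    loss: str = "squared_error"
    epochs: int = 400
    batch_size: int = 32
    seed: int = 0
    split_fraction: float = 0.9
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must be in (0, 1)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.activation not in ("relu", "tanh"):
            raise ValueError("activation must be relu or tanh")
        if self.loss != "squared_error":
            raise ValueError("only squared_error loss is supported")


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(x, 0.0) if kind == "relu" else np.tanh(x)


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    # expressed through the activation output
    return (a > 0).astype(a.dtype) if kind == "relu" else 1.0 - a ** 2


class SurrogateModel:
    """Fully connected regression network with explicit weight storage.

    ``weights`` is a list of (W, b) pairs; prediction is deterministic given
    the weights and input.  Feature scaling (center/scale learned from the
    training split) is stored on the model so raw feature rows can be fed
    directly.
    """

    def __init__(self, config: SurrogateConfig, n_features: int,
                 feature_names: Sequence[str] | None = None):
        self.config = config
        self.feature_names = tuple(feature_names) if feature_names is not None \
            else tuple(f"x{i}" for i in range(n_features))
        self.x_center = np.zeros(n_features)
        self.x_scale = np.ones(n_features)
        self.y_center = 0.0
        self.y_scale = 1.0
        self.fitted = False
        rng = np.random.default_rng(config.seed)
        sizes = [n_features, *config.hidden_layers, 1]
        self.weights: list[tuple[np.ndarray, np.ndarray]] = []
        for fan_in, fan_out in zip(sizes, sizes[1:]):
            if config.activation == "relu":
                w = rng.standard_normal((fan_in, fan_out)) * math.sqrt(2.0 / fan_in)
            else:
                limit = math.sqrt(6.0 / (fan_in + fan_out))
                w = rng.uniform(-limit, limit, (fan_in, fan_out))
            self.weights.append((w, np.zeros(fan_out)))

    # -- scaled-space forward/backward ------------------------------------

    def _forward(self, xs: np.ndarray) -> list[np.ndarray]:
        acts = [xs]
        a = xs
        for i, (w, b) in enumerate(self.weights):
            z = a @ w + b
            a = z if i == len(self.weights) - 1 else _act(z, self.config.activation)
            acts.append(a)
        return acts

    def loss_gradients(
        self, xs: np.ndarray, ys: np.ndarray
    ) -> tuple[float, list[tuple[np.ndarray, np.ndarray]]]:
        """Mean squared-error loss (0.5*mean residual^2) and its gradients.

        Overflow is tolerated here; the training loop turns a non-finite
        loss into a divergence error."""
        n = len(xs)
        with np.errstate(over="ignore", invalid="ignore"):
            return self._loss_gradients_impl(xs, ys, n)

    def _loss_gradients_impl(self, xs, ys, n):
        acts = self._forward(xs)
        resid = acts[-1][:, 0] - ys
        loss = 0.5 * float(resid @ resid) / n
        delta = (resid / n)[:, None]
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.weights)
        for i in range(len(self.weights) - 1, -1, -1):
            a_prev = acts[i]
            grads[i] = (a_prev.T @ delta, delta.sum(axis=0))
            if i > 0:
                w, _ = self.weights[i]
                delta = (delta @ w.T) * _act_grad(acts[i], self.config.activation)
        return loss, grads

    def apply_update(self, grads, eta: float, alpha: float) -> None:
        """One regularized gradient step; biases carry no penalty."""
        for i, ((w, b), (gw, gb)) in enumerate(zip(self.weights, grads)):
            self.weights[i] = (w - eta * (alpha * w + gw), b - eta * gb)

    # -- public prediction --------------------------------------------------

    def _scale_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_center) / self.x_scale

    def predict(self, X) -> np.ndarray:
        """Predict on raw (unscaled) feature rows."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        ys = self._forward(self._scale_x(X))[-1][:, 0]
        return ys * self.y_scale + self.y_center


@dataclass
class FitReport:
    train_r2: float | None
    test_r2: float | None
    n_train: int
    n_test: int
    final_loss: float
    constant_target: bool = False
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float | None:
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        return None
    return 1.0 - float(((y_true - y_pred) ** 2).sum()) / ss_tot


def _stratified_split(features: pd.DataFrame, frac: float, seed: int):
    """Deterministic train/test indices, stratified by union when present."""
    rng = np.random.default_rng(seed)
    idx = np.arange(len(features))
    groups = (features["union_code"].to_numpy() if "union_code" in features
              else np.zeros(len(features)))
    train, test = [], []
    for g in np.unique(groups):
        members = idx[groups == g]
        members = members[rng.permutation(len(members))]
        k = int(round(frac * len(members)))
        k = min(max(k, 1), len(members) - 1) if len(members) > 1 else len(members)
        train.extend(members[:k])
        test.extend(members[k:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))


def _fit_on(model: SurrogateModel, X: np.ndarray, y: np.ndarray,
            cfg: SurrogateConfig, rng: np.random.Generator) -> float:
    """Run the SGD loop on raw arrays; scaling is learned here."""
    model.x_center = X.mean(axis=0)
    scale = X.std(axis=0)
    model.x_scale = np.where(scale > 0, scale, 1.0)
    model.y_center = float(y.mean())
    y_sd = float(y.std())
    model.y_scale = y_sd if y_sd > 0 else 1.0

    xs = model._scale_x(X)
    ys = (y - model.y_center) / model.y_scale
    n = len(xs)
    loss = float("nan")
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            loss, grads = model.loss_gradients(xs[batch], ys[batch])
            if not math.isfinite(loss):
                raise ValueError(
                    "training diverged (non-finite loss); try a smaller eta")
            model.apply_update(grads, cfg.eta, cfg.alpha)
    model.fitted = True
    return loss


def train_surrogate(
    features: pd.DataFrame,
    target: Sequence[float],
    cfg: SurrogateConfig,
) -> tuple[SurrogateModel, FitReport]:
    """Train with a stratified split; returns the model and fit quality.

    A constant target yields a constant predictor and an undefined (None)
    R^2, reported as such rather than raising.
    """
    y = np.asarray(target, dtype=float)
    if len(features) < 20:
        raise ValueError("train_surrogate needs at least 20 rows")
    if len(features) != len(y):
        raise ValueError("features/target length mismatch")
    if not np.isfinite(y).all():
        raise ValueError("target must be finite (filter or cap unbounded limits first)")

    X = features.to_numpy(dtype=float)
    train_idx, test_idx = _stratified_split(features, cfg.split_fraction, cfg.seed)
    model = SurrogateModel(cfg, X.shape[1], feature_names=features.columns)
    rng = np.random.default_rng(cfg.seed + 1)

    constant = float(y[train_idx].std()) == 0.0
    if constant:
        # Nothing to learn: predict the constant exactly.
        model.x_center = X[train_idx].mean(axis=0)
        scale = X[train_idx].std(axis=0)
        model.x_scale = np.where(scale > 0, scale, 1.0)
        model.y_center = float(y[train_idx].mean())
        model.y_scale = 1.0
        w_last, b_last = model.weights[-1]
        model.weights[-1] = (np.zeros_like(w_last), np.zeros_like(b_last))
        model.fitted = True
        final_loss = 0.0
    else:
        final_loss = _fit_on(model, X[train_idx], y[train_idx], cfg, rng)
    pred_train = model.predict(X[train_idx])
    pred_test = model.predict(X[test_idx]) if len(test_idx) else np.array([])
    report = FitReport(
        train_r2=_r2(y[train_idx], pred_train),
        test_r2=_r2(y[test_idx], pred_test) if len(test_idx) else None,
        n_train=len(train_idx), n_test=len(test_idx),
        final_loss=final_loss, constant_target=constant,
        train_idx=train_idx, test_idx=test_idx,
    )
    return model, report


# ---------------------------------------------------------------------------
# Cross-validation and the alpha sweep

@dataclass
class CvResult:
    folds: pd.DataFrame          # columns: alpha, fold, n_val, r2
    summary: pd.DataFrame        # index alpha; columns mean_r2, sd_r2
    predictions: dict[float, np.ndarray]   # alpha -> out-of-fold predictions
    y: np.ndarray
    fold_of: np.ndarray          # row -> fold id


def cross_validate(
    features: pd.DataFrame,
    target: Sequence[float],
    cfg: SurrogateConfig,
) -> CvResult:
    """K-fold CV over the alpha sweep; every row validated exactly once per
    alpha, fold assignment fixed by the seed."""
    y = np.asarray(target, dtype=float)
    n = len(y)
    if cfg.cv_folds > n:
        raise ValueError(f"cv_folds {cfg.cv_folds} > rows {n}")
    X = features.to_numpy(dtype=float)
    rng_assign = np.random.default_rng(cfg.seed)
    fold_of = np.empty(n, dtype=int)
    perm = rng_assign.permutation(n)
    for k, chunk in enumerate(np.array_split(perm, cfg.cv_folds)):
        fold_of[chunk] = k

    rows = []
    predictions: dict[float, np.ndarray] = {}
    for alpha in cfg.alpha_sweep:
        acfg = SurrogateConfig(**{**cfg.__dict__, "alpha": alpha})
        oof = np.empty(n)
        for k in range(cfg.cv_folds):
            val = fold_of == k
            model = SurrogateModel(acfg, X.shape[1], feature_names=features.columns)
            rng = np.random.default_rng(acfg.seed + 1)
            _fit_on(model, X[~val], y[~val], acfg, rng)
            oof[val] = model.predict(X[val])
            rows.append({"alpha": alpha, "fold": k, "n_val": int(val.sum()),
                         "r2": _r2(y[val], oof[val])})
        predictions[alpha] = oof
    folds = pd.DataFrame(rows)
    summary = folds.groupby("alpha")["r2"].agg(mean_r2="mean", sd_r2="std")
    return CvResult(folds=folds, summary=summary, predictions=predictions,
                    y=y, fold_of=fold_of)


# ---------------------------------------------------------------------------
# Shapley attribution

@dataclass
class Attribution:
    sample_id: str
    baseline: float
    shap: dict[str, float]
    prediction: float
    mode: str                                # exact | sampling
    stderr: dict[str, float] | None = None   # Monte-Carlo SE (sampling mode)


def _coalition_value(model: SurrogateModel, x: np.ndarray,
                     background: np.ndarray, members: np.ndarray) -> float:
    """v(S): mean prediction with features in S fixed to x, rest from the
    background rows (interventional convention)."""
    grid = background.copy()
    grid[:, members] = x[members]
    return float(model.predict(grid).mean())


def shapley_attribution(
    model: SurrogateModel,
    x: Sequence[float] | pd.Series,
    background: pd.DataFrame | np.ndarray,
    *,
    sample_id: str = "",
    n_permutations: int = 256,
    max_exact_features: int = 12,
) -> Attribution:
    """Exact Shapley values by coalition enumeration (<= 12 features);
    seeded permutation sampling beyond that.

    The baseline is the mean model prediction over the background table;
    baseline + sum(shap) equals the prediction at ``x`` (efficiency axiom)
    to numerical precision in exact mode.
    """
    if not model.fitted:
        raise ValueError("model is not fitted")
    bg = np.asarray(background, dtype=float)
    if bg.ndim == 1:
        bg = bg[None, :]
    if len(bg) == 0:
        raise ValueError("background set is empty")
    xv = np.asarray(x, dtype=float).ravel()
    p = len(xv)

    if p <= max_exact_features:
        # Batch all 2^p coalition grids through the network at once.
        n_masks = 1 << p
        masks = np.arange(n_masks)
        bits = ((masks[:, None] >> np.arange(p)) & 1).astype(bool)  # (masks, p)
        grid = np.where(bits[:, None, :], xv[None, None, :], bg[None, :, :])
        preds = model.predict(grid.reshape(-1, p))
        values = preds.reshape(n_masks, len(bg)).mean(axis=1)

        sizes = bits.sum(axis=1)
        fact = np.array([math.factorial(k) for k in range(p + 1)], dtype=float)
        weight_of_size = fact[:p] * fact[p - 1 - np.arange(p)] / fact[p]
        phi = np.zeros(p)
        for i in range(p):
            bit = 1 << i
            without = masks[~bits[:, i]]
            phi[i] = float(np.sum(weight_of_size[sizes[without]]
                                  * (values[without | bit] - values[without])))
        baseline = values[0]
        prediction = values[n_masks - 1]
        mode = "exact"
    else:
        rng = np.random.default_rng(model.config.seed)
        contrib = np.empty((n_permutations, p))
        baseline = float(model.predict(bg).mean())
        prediction = float(model.predict(xv[None, :])[0])
        for t in range(n_permutations):
            order = rng.permutation(p)
            members: list[int] = []
            prev = baseline
            for i in order:
                members.append(i)
                cur = _coalition_value(model, xv, bg, np.array(members))
                contrib[t, i] = cur - prev
                prev = cur
        phi = contrib.mean(axis=0)
        se = contrib.std(axis=0, ddof=1) / math.sqrt(n_permutations)
        mode = "sampling"

    names = model.feature_names if len(model.feature_names) == p \
        else tuple(f"x{i}" for i in range(p))
    return Attribution(sample_id=sample_id, baseline=baseline,
                       shap=dict(zip(names, phi.tolist())),
                       prediction=prediction, mode=mode,
                       stderr=dict(zip(names, se.tolist())) if mode == "sampling"
                       else None)


# ---------------------------------------------------------------------------
# Alpha-sweep clustering diagnostic

@dataclass
class AlphaClusterReport:
    """Descriptive two-group diagnostic of the CV predictions per alpha.

    For each alpha, samples are split by a seeded two-means on standardized
    (prediction, residual) pairs; ``agreement_pct`` is co-assignment with the
    reference partition (smallest alpha), maximized over label swap."""

    table: pd.DataFrame          # index alpha; group sizes + agreement_pct
    degenerate: bool


def _two_means(points: np.ndarray, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    return km.fit_predict(points)


def alpha_cluster_report(cv: CvResult, *, seed: int = 0) -> AlphaClusterReport:
    """Two-group structure of predictions/residuals across the alpha sweep."""
    n = len(cv.y)
    if n < 4:
        raise ValueError("alpha_cluster_report needs n >= 4")
    if len(cv.predictions) < 2:
        raise ValueError("need cv results for >= 2 alpha values")

    labels: dict[float, np.ndarray] = {}
    degenerate = False
    for alpha, pred in sorted(cv.predictions.items()):
        pts = np.column_stack([pred, cv.y - pred])
        sd = pts.std(axis=0)
        if (sd == 0).all():
            degenerate = True
            labels[alpha] = np.zeros(n, dtype=int)
            continue
        pts = (pts - pts.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        labels[alpha] = _two_means(pts, seed)

    alphas = sorted(labels)
    ref = labels[alphas[0]]
    rows = []
    for alpha in alphas:
        lab = labels[alpha]
        same = float((lab == ref).mean())
        agreement = 100.0 * max(same, 1.0 - same) if len(set(ref)) > 1 else 100.0
        rows.append({"alpha": alpha,
                     "n_group0": int((lab == 0).sum()),
                     "n_group1": int((lab == 1).sum()),
                     "agreement_pct": agreement})
    table = pd.DataFrame(rows).set_index("alpha")
    return AlphaClusterReport(table=table, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Persistence (structured text artifact)

def save_model(model: SurrogateModel, path: str | Path) -> None:
    """Persist architecture + weights + scaling + feature names as JSON."""
    payload = {
        "config": {**model.config.__dict__,
                   "hidden_layers": list(model.config.hidden_layers),
                   "alpha_sweep": list(model.config.alpha_sweep)},
        "feature_names": list(model.feature_names),
        "x_center": model.x_center.tolist(),
        "x_scale": model.x_scale.tolist(),
        "y_center": model.y_center,
        "y_scale": model.y_scale,
        "fitted": model.fitted,
        "weights": [[w.tolist(), b.tolist()] for w, b in model.weights],
        "union_codes": UNION_CODES,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> SurrogateModel:
    """Exact reload of a persisted surrogate."""
    payload = json.loads(Path(path).read_text())
    raw = payload["config"]
    cfg = SurrogateConfig(**{**raw,
                             "hidden_layers": tuple(raw["hidden_layers"]),
                             "alpha_sweep": tuple(raw["alpha_sweep"])})
    n_features = len(payload["feature_names"])
    model = SurrogateModel(cfg, n_features, feature_names=payload["feature_names"])
    model.x_center = np.array(payload["x_center"])
    model.x_scale = np.array(payload["x_scale"])
    model.y_center = payload["y_center"]
    model.y_scale = payload["y_scale"]
    model.fitted = payload["fitted"]
    model.weights = [(np.array(w), np.array(b)) for w, b in payload["weights"]]
    return model
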