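"""The three-block network, its training loop, and evaluation.

Each block is an RGIN convolution followed by TopK pooling and a
readout; the three block summaries are concatenated and mapped to a
scalar score by a single affine head.  Defaults follow the reference
recipe for 53-ROI connectivity graphs: layer widths 32/128/256, K = 7
clusters, sum aggregation with the SERO readout, 100 % of edges kept,
lambda1 = 0.1, learning rate 0.001 halved every 30 epochs, and metrics
averaged over four seeds.

Targets are residualised before training: nuisance covariates (e.g. age
and acquisition site) are regressed out of the scores by ordinary least
squares fitted on the training subjects only, and the model is trained
and evaluated on the residuals.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import autodiff as ad
from .autodiff import Tensor
from .losses import LossConfig, smooth_l1, tpk_loss, total_loss, unit_loss
from .optim import Adam, step_lr
from .pooling import PoolingParams, init_pooling_params, topk_pool
from .readout import (
    GAROParams,
    SEROParams,
    concat_blocks,
    garo,
    init_garo_params,
    init_sero_params,
    meanmax_readout,
    sero,
)
from .rgin_conv import RGINLayerParams, init_rgin_params, rgin_forward

__all__ = [
    "ModelConfig",
    "GraphBatch",
    "SplitDataset",
    "EvalMetrics",
    "ForwardResult",
    "BrainRGIN",
    "residualize_scores",
    "train",
    "evaluate",
    "run_seeds",
    "save_checkpoint",
    "load_checkpoint",
]

_READOUTS = ("sero", "garo", "meanmax")


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters."""

    n_rois: int = 53
    layer_dims: tuple[int, ...] = (32, 128, 256)
    n_clusters: int = 7
    pooling_ratio: float = 0.38  # 0.38 fluid / 0.46 crystallized / 0.78 total
    aggregation: str = "sum"
    readout: str = "sero"
    keep_percent: float = 100.0
    lambda1: float = 0.1
    unit_norm_mode: str = "squared"
    lr_init: float = 1e-3
    lr_step: int = 30
    lr_factor: float = 0.5
    epochs: int = 100
    batch_size: int = 64
    patience: int = 0  # early stop on validation MSE; <=0 trains the full schedule
    seeds: tuple[int, ...] = (0, 1, 2, 3)

    def __post_init__(self):
        if len(self.layer_dims) != 3:
            raise ValueError("the architecture uses exactly 3 blocks")
        if self.readout not in _READOUTS:
            raise ValueError(f"readout must be one of {_READOUTS}")
        if not (0.0 < self.pooling_ratio <= 1.0):
            raise ValueError("pooling_ratio must lie in (0, 1]")
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")

    def node_counts(self) -> list[int]:
        """Node count entering each block plus the final survivor count."""
        counts = [self.n_rois]
        for _ in self.layer_dims:
            counts.append(max(1, math.ceil(self.pooling_ratio * counts[-1])))
        return counts

    def embedding_width(self) -> int:
        per_block = [2 * d if self.readout == "meanmax" else d for d in self.layer_dims]
        return int(sum(per_block))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["layer_dims"] = list(self.layer_dims)
        d["seeds"] = list(self.seeds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "layer_dims" in d:
            d["layer_dims"] = tuple(d["layer_dims"])
        if "seeds" in d:
            d["seeds"] = tuple(d["seeds"])
        return cls(**d)


@dataclass
class GraphBatch:
    """A stack of same-size FNC graphs ready for the network."""

    adjacency: np.ndarray  # (n, N, N)
    features: np.ndarray  # (n, N, N0)
    roi_index: np.ndarray  # (n, N)
    scores: np.ndarray  # (n,) residualised targets
    subject_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.adjacency.shape[0]

    def subset(self, idx: np.ndarray) -> "GraphBatch":
        ids = [self.subject_ids[i] for i in idx] if self.subject_ids else []
        return GraphBatch(
            self.adjacency[idx], self.features[idx], self.roi_index[idx],
            self.scores[idx], ids,
        )

    @classmethod
    def from_graphs(cls, graphs, scores) -> "GraphBatch":
        return cls(
            adjacency=np.stack([g.adjacency for g in graphs]),
            features=np.stack([g.node_features for g in graphs]),
            roi_index=np.stack([g.roi_index for g in graphs]),
            scores=np.asarray(scores, dtype=np.float64),
            subject_ids=[g.subject_id for g in graphs],
        )


@dataclass
class SplitDataset:
    """Disjoint train/validation/test graph batches."""

    train: GraphBatch
    val: GraphBatch
    test: GraphBatch


@dataclass
class EvalMetrics:
    mse: float
    pearson_r: float
    degenerate: bool = False  # constant predictions: r reported as 0


@dataclass
class ForwardResult:
    """Predictions plus the per-block pooling byproducts the losses and
    the interpretation stage need."""

    pred: Tensor  # (B,)
    scores_norm: list[Tensor]  # per block, (B, N_l) pre-pooling
    selected_roi: list[np.ndarray]  # per block, (B, k_l) original ROI ids
    ks: list[int]


class BrainRGIN:
    """Three RGIN blocks with pooling and attention readouts, then an
    affine head to a scalar score."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        counts = cfg.node_counts()
        self.convs: list[RGINLayerParams] = []
        self.pools: list[PoolingParams] = []
        self.readouts: list[GAROParams | SEROParams | None] = []
        d_in = cfg.n_rois
        for l, d_out in enumerate(cfg.layer_dims):
            self.convs.append(
                init_rgin_params(
                    rng, cfg.n_clusters, cfg.n_rois, d_in, d_out, cfg.aggregation
                )
            )
            self.pools.append(init_pooling_params(rng, d_out, cfg.pooling_ratio))
            if cfg.readout == "sero":
                self.readouts.append(init_sero_params(rng, d_out, counts[l + 1]))
            elif cfg.readout == "garo":
                self.readouts.append(init_garo_params(rng, d_out))
            else:
                self.readouts.append(None)
            d_in = d_out
        width = cfg.embedding_width()
        self.head_w = ad.parameter(rng.normal(0.0, 1.0 / np.sqrt(width), size=width))
        self.head_b = ad.parameter(0.0)

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for l in range(len(self.cfg.layer_dims)):
            out.update(self.convs[l].parameters(f"block{l}.conv"))
            out.update(self.pools[l].parameters(f"block{l}.pool"))
            if self.readouts[l] is not None:
                out.update(self.readouts[l].parameters(f"block{l}.readout"))
        out["head.w"] = self.head_w
        out["head.b"] = self.head_b
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(state) != set(params):
            raise ValueError("checkpoint does not match the model's parameters")
        for k, p in params.items():
            p.data = np.array(state[k], dtype=np.float64)

    def forward(self, batch: GraphBatch) -> ForwardResult:
        cfg = self.cfg
        if batch.features.shape[1] != cfg.n_rois:
            raise ValueError(
                f"model expects {cfg.n_rois} nodes, got {batch.features.shape[1]}"
            )
        adj = batch.adjacency
        roi = batch.roi_index
        h: Tensor | np.ndarray = batch.features
        summaries, scores_norm, selected, ks = [], [], [], []
        for l in range(len(cfg.layer_dims)):
            h = rgin_forward(adj, roi, h, self.convs[l])
            pooled = topk_pool(adj, roi, h, self.pools[l])
            if cfg.readout == "sero":
                summaries.append(sero(pooled.h, self.readouts[l]))
            elif cfg.readout == "garo":
                summaries.append(garo(pooled.h, self.readouts[l]))
            else:
                summaries.append(meanmax_readout(pooled.h))
            scores_norm.append(pooled.scores_norm)
            selected.append(pooled.roi_index)
            ks.append(pooled.k)
            h, adj, roi = pooled.h, pooled.adjacency, pooled.roi_index
        z = concat_blocks(summaries)
        proj = ad.matmul(z, ad.reshape(self.head_w, (self.head_w.shape[0], 1)))
        pred = ad.reshape(proj, (z.shape[0],)) + self.head_b
        return ForwardResult(pred=pred, scores_norm=scores_norm,
                             selected_roi=selected, ks=ks)

    def predict(self, batch: GraphBatch, chunk: int = 256) -> np.ndarray:
        """Scores for a batch, evaluated in chunks without a tape."""
        out = []
        for start in range(0, len(batch), chunk):
            idx = np.arange(start, min(start + chunk, len(batch)))
            out.append(self.forward(batch.subset(idx)).pred.data)
        return np.concatenate(out)


# -- covariate residualisation -------------------------------------------

def residualize_scores(
    scores,
    covariates: pd.DataFrame,
    fit_subset,
) -> np.ndarray:
    """OLS residuals of score on covariates, fitted on ``fit_subset``.

    Categorical covariate columns are one-hot encoded (first level
    dropped); an intercept is always included, so residuals of the fit
    subset are centred.  A rank-deficient design triggers a warning and
    falls back to the minimum-norm least-squares fit, which is
    prediction-equivalent to dropping the collinear columns.
    """
    y = np.asarray(scores, dtype=np.float64)
    fit_idx = np.asarray(fit_subset)
    if fit_idx.dtype == bool:
        fit_idx = np.flatnonzero(fit_idx)
    if fit_idx.size == 0:
        raise ValueError("fit_subset must be nonempty")

    cat_cols = [
        c for c in covariates.columns
        if covariates[c].dtype == object
        or isinstance(covariates[c].dtype, pd.CategoricalDtype)
    ]
    design = pd.get_dummies(covariates, columns=cat_cols, drop_first=True)
    x = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=np.float64)])

    x_fit = x[fit_idx]
    rank = np.linalg.matrix_rank(x_fit)
    if rank < x_fit.shape[1]:
        warnings.warn(
            "covariate design is rank deficient; collinear columns are "
            "effectively dropped (minimum-norm OLS)",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(x_fit, y[fit_idx], rcond=None)
    return y - x @ beta


# -- training & evaluation -----------------------------------------------

def _batch_loss(model: BrainRGIN, batch: GraphBatch, loss_cfg: LossConfig):
    res = model.forward(batch)
    reg = smooth_l1(res.pred, batch.scores)
    units, tpks = [], []
    for l, s_norm in enumerate(res.scores_norm):
        units.append(unit_loss(model.pools[l].omega, mode=loss_cfg.unit_norm_mode))
        sig = ad.sigmoid(s_norm)
        order = np.argsort(-sig.data, axis=1, kind="stable")
        sorted_sig = ad.take_along(sig, order, axis=1)
        tpks.append(tpk_loss(sorted_sig, res.ks[l], clamp_eps=loss_cfg.clamp_eps))
    return total_loss(reg, units, tpks, loss_cfg), res


def train(
    dataset: SplitDataset,
    cfg: ModelConfig,
    seed: int = 0,
    verbose: bool = False,
) -> tuple[BrainRGIN, pd.DataFrame]:
    """Minimise the composite loss; return the best-validation model.

    Deterministic given ``(cfg, seed)``: the same seed drives parameter
    initialisation and minibatch shuffling.  Training aborts with a
    diagnostic if the loss becomes non-finite.  The returned history has
    one row per epoch (loss components, validation MSE, learning rate).
    """
    if len(dataset.train) == 0:
        raise ValueError("training split is empty")
    model = BrainRGIN(cfg, seed=seed)
    loss_cfg = LossConfig(lambda1=cfg.lambda1, unit_norm_mode=cfg.unit_norm_mode)
    opt = Adam(model.parameters(), lr=cfg.lr_init)
    rng = np.random.default_rng(seed + 1)

    best_state = model.state_dict()
    best_val = np.inf
    best_epoch = -1
    rows = []
    n = len(dataset.train)
    for epoch in range(cfg.epochs):
        opt.lr = step_lr(cfg.lr_init, epoch, cfg.lr_step, cfg.lr_factor)
        perm = rng.permutation(n)
        epoch_parts: dict[str, float] = {}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            batch = dataset.train.subset(perm[start : start + cfg.batch_size])
            report, _ = _batch_loss(model, batch, loss_cfg)
            if not np.isfinite(report.total.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {report.as_dict()}"
                )
            opt.zero_grad()
            report.total.backward()
            opt.step()
            for key, val in report.as_dict().items():
                epoch_parts[key] = epoch_parts.get(key, 0.0) + val
            n_batches += 1
        row = {k: v / n_batches for k, v in epoch_parts.items()}
        row["epoch"] = epoch
        row["lr"] = opt.lr

        if len(dataset.val):
            val_pred = model.predict(dataset.val)
            val_mse = float(np.mean((val_pred - dataset.val.scores) ** 2))
        else:
            val_mse = row["total"]
        row["val_mse"] = val_mse
        rows.append(row)
        if verbose:
            print(
                f"epoch {epoch:3d}  total {row['total']:.4f}  "
                f"val_mse {val_mse:.4f}  lr {opt.lr:.2e}"
            )
        if val_mse < best_val:
            best_val = val_mse
            best_state = model.state_dict()
            best_epoch = epoch
        elif cfg.patience > 0 and epoch - best_epoch >= cfg.patience:
            break

    model.load_state_dict(best_state)
    return model, pd.DataFrame(rows)


def evaluate(model: BrainRGIN, subset: GraphBatch) -> EvalMetrics:
    """MSE and Pearson r between predictions and residualised targets.

    Zero-variance predictions make r undefined; that degenerate case is
    reported as ``r = 0`` with the ``degenerate`` flag set.
    """
    if len(subset) == 0:
        raise ValueError("evaluation subset is empty")
    pred = model.predict(subset)
    mse = float(np.mean((pred - subset.scores) ** 2))
    if np.std(pred) == 0.0 or np.std(subset.scores) == 0.0:
        warnings.warn("constant predictions or targets: Pearson r reported as 0",
                      stacklevel=2)
        return EvalMetrics(mse=mse, pearson_r=0.0, degenerate=True)
    r = float(stats.pearsonr(pred, subset.scores).statistic)
    return EvalMetrics(mse=mse, pearson_r=r)


def run_seeds(
    dataset: SplitDataset,
    cfg: ModelConfig,
    seeds: tuple[int, ...] | None = None,
    verbose: bool = False,
):
    """Train once per seed and average test metrics (mean and s.d.).

    The summary also records each run's best validation MSE, so callers
    can select one model across seeds without touching the test split.
    """
    seeds = tuple(seeds if seeds is not None else cfg.seeds)
    models, metrics, val_mses = [], [], []
    for s in seeds:
        model, history = train(dataset, cfg, seed=s, verbose=verbose)
        models.append(model)
        metrics.append(evaluate(model, dataset.test))
        val_mses.append(float(history["val_mse"].min()))
    mses = np.array([m.mse for m in metrics])
    rs = np.array([m.pearson_r for m in metrics])
    summary = {
        "mse_mean": float(mses.mean()),
        "mse_sd": float(mses.std()),
        "pearson_r_mean": float(rs.mean()),
        "pearson_r_sd": float(rs.std()),
        "val_mse_per_seed": val_mses,
        "best_seed_index": int(np.argmin(val_mses)),
        "seeds": list(seeds),
    }
    return models, metrics, summary


# -- checkpoints ----------------------------------------------------------

def save_checkpoint(model: BrainRGIN, path) -> None:
    """Weights + config + seed in one ``.npz`` container."""
    meta = json.dumps({"config": model.cfg.to_dict(), "seed": model.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> BrainRGIN:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = BrainRGIN(ModelConfig.from_dict(meta["config"]), seed=meta["seed"])
    model.load_state_dict(state)
    return model
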