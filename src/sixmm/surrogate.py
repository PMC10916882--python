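"""Inverse surrogate: a convolutional-recurrent network that maps observed
vocal-fold edge trajectories to the 14 six-mass-model scaling parameters.

Pipeline: truncate the 75 ms transient, cut a 512-step (128 ms) window
(random per epoch in training, first window in evaluation), corrupt with
10% relative Gaussian noise, zero-truncate so left rows stay negative and
right rows positive; compress each trajectory with a shared two-stage
conv/max-pool stack into a 21-step sequence, iterate a two-layer
bidirectional GRU whose initial hidden state is derived from the
trajectory means, combine an attention readout over the sequence with the
final hidden state through fully connected layers, and emit 14 strictly
positive predictions.  Training minimizes the root mean square
logarithmic error (RMSLE), the natural loss for positive multiplicative
targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .autodiff import Adam, Parameter, Tensor, use_dtype
from .sampling import LabeledDataset

__all__ = [
    "SurrogateConfig",
    "TrainConfig",
    "TrainingRunResult",
    "preprocess",
    "compressed_length",
    "CRNN",
    "rmsle",
    "train_surrogate",
    "exclude_subperformant",
]


@dataclass(frozen=True)
class SurrogateConfig:
    """Architecture and preprocessing hyperparameters.

    The convolution arithmetic (kernel 3 / stride 3 / 10 channels, pool 2,
    kernel 3 / stride 2 / 5 channels, pool 2) compresses a 512-step window
    to a 21 x (5*6) sequence.  ``positivity`` selects the output head:
    ``exp`` (log-space regression, default), ``softplus``, or the literal
    ``softmax`` (which normalizes the 14 outputs to sum 1 and is kept only
    for comparison).
    """

    window_len: int = 512
    transient_cut_ms: float = 75.0
    noise_level: float = 0.10
    conv1_channels: int = 10
    conv1_kernel: int = 3
    conv1_stride: int = 3
    conv2_channels: int = 5
    conv2_kernel: int = 3
    conv2_stride: int = 2
    pool_kernel: int = 2
    gru_layers: int = 2
    gru_hidden: int = 256
    bidirectional: bool = True
    attention_width: int = 16
    head_width: int = 32
    output_dim: int = 14
    positivity: str = "exp"
    shared_subcnn: bool = True

    def __post_init__(self):
        if self.output_dim != 14:
            raise ValueError("the 6MM scaling space has 14 dimensions")
        if self.positivity not in ("exp", "softplus", "softmax"):
            raise ValueError("positivity must be exp, softplus or softmax")
        compressed_length(self.window_len, self)  # raises if too short


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (adaptive momentum, exponential LR
    decay with base 0.9, early stopping with patience 5)."""

    lr_init: float = 5e-3
    lr_decay_base: float = 0.9
    batch_size: int = 512
    early_stop_patience: int = 5
    val_fraction: float = 0.10
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainingRunResult:
    """Loss curves, the best model, and the per-parameter validation MAE."""

    train_curve: list
    val_curve: list
    best_val_loss: float
    epochs_trained: int
    model: "CRNN"
    val_mae: np.ndarray  # (14,)
    seed: int


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _clamp_signs(windows: np.ndarray) -> np.ndarray:
    windows[:, :3] = np.minimum(windows[:, :3], 0.0)
    windows[:, 3:] = np.maximum(windows[:, 3:], 0.0)
    return windows


def preprocess_batch(
    values: np.ndarray,
    dt_ms: float,
    cfg: SurrogateConfig,
    rng: np.random.Generator | None,
    training: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized preprocessing of (N, 6, n) trajectory arrays (mm).

    Returns (windows (N, 6, window_len), means (N, 6)); the means are the
    pre-noise window averages used to initialize the GRU hidden state.
    """
    values = np.asarray(values, float)
    N, rows, n = values.shape
    cut = int(round(cfg.transient_cut_ms / dt_ms))
    max_offset = n - cut - cfg.window_len
    if max_offset < 0:
        raise ValueError(
            f"need at least {cut + cfg.window_len} steps, got {n}"
        )
    if training:
        if rng is None:
            raise ValueError("training-mode preprocessing needs an rng")
        offsets = cut + rng.integers(0, max_offset + 1, size=N)
    else:
        offsets = np.full(N, cut)
    idx = offsets[:, None] + np.arange(cfg.window_len)[None, :]
    windows = np.take_along_axis(values, idx[:, None, :], axis=2).copy()
    means = windows.mean(axis=2)
    if training and cfg.noise_level > 0:
        stds = windows.std(axis=2, keepdims=True)
        windows += rng.standard_normal(windows.shape) * (cfg.noise_level * stds)
    return _clamp_signs(windows), means


def preprocess(
    T,
    cfg: SurrogateConfig | None = None,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess one :class:`~sixmm.model.TrajectorySet`.

    Returns (6 x window_len input, 6 trajectory means).  Training mode
    picks a uniformly random post-transient window and adds Gaussian
    noise with per-trajectory std = noise_level x the window's own std;
    evaluation mode uses the first eligible window, noise-free.  In both
    modes left rows are clamped to <= 0 and right rows to >= 0.
    """
    cfg = cfg or SurrogateConfig()
    w, m = preprocess_batch(T.values[None], T.dt, cfg, rng, training)
    return w[0], m[0]


def compressed_length(n_in: int, cfg: SurrogateConfig | None = None) -> int:
    """Sequence length after conv1 -> pool -> conv2 -> pool.

    Convolutions follow floor((L - k)/stride) + 1; pools floor(L/2).
    """
    cfg = cfg or SurrogateConfig()
    L = n_in
    # max pooling with kernel == stride == 2 obeys the same arithmetic as a
    # width-2 stride-2 convolution: floor((L - 2)/2) + 1 == floor(L/2)
    for k, s in (
        (cfg.conv1_kernel, cfg.conv1_stride),
        (cfg.pool_kernel, cfg.pool_kernel),
        (cfg.conv2_kernel, cfg.conv2_stride),
        (cfg.pool_kernel, cfg.pool_kernel),
    ):
        L = (L - k) // s + 1
    if L < 1:
        raise ValueError(f"input of {n_in} steps is too short for the conv stack")
    return L


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class CRNN:
    """The convolutional-recurrent inverse surrogate.

    A shared sub-CNN compresses each of the six trajectories, the joint
    21 x 30 sequence runs through a two-layer bidirectional GRU (hidden
    256) initialized from the trajectory means via FC + ReLU, and an
    attention branch (per-step FC to width 16, flattened, FC to 16) is
    merged with the final-hidden-state branch (FC to 16) into the
    positive 14-dimensional prediction head.
    """

    def __init__(self, config: SurrogateConfig | None = None, seed: int = 0):
        self.config = config or SurrogateConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: dict[str, Parameter] = {}
        self._build(rng)

    # -- parameter helpers ---------------------------------------------
    def _param(self, name: str, shape: tuple[int, ...], fan_in: int, rng):
        bound = 1.0 / np.sqrt(fan_in)
        self.params[name] = Parameter(rng.uniform(-bound, bound, size=shape))
        return self.params[name]

    def _build(self, rng):
        c = self.config
        n_rows = 6
        n_cnn = 1 if c.shared_subcnn else n_rows
        for i in range(n_cnn):
            tag = "" if c.shared_subcnn else f"_r{i}"
            self._param(f"conv1_w{tag}", (c.conv1_channels, 1, c.conv1_kernel),
                        c.conv1_kernel, rng)
            self._param(f"conv1_b{tag}", (c.conv1_channels,), c.conv1_kernel, rng)
            self._param(f"conv2_w{tag}",
                        (c.conv2_channels, c.conv1_channels, c.conv2_kernel),
                        c.conv1_channels * c.conv2_kernel, rng)
            self._param(f"conv2_b{tag}", (c.conv2_channels,),
                        c.conv1_channels * c.conv2_kernel, rng)
        H = c.gru_hidden
        D = 2 if c.bidirectional else 1
        feat = c.conv2_channels * n_rows
        for layer in range(c.gru_layers):
            in_dim = feat if layer == 0 else H * D
            for d in range(D):
                tag = f"_l{layer}d{d}"
                self._param(f"gru_wih{tag}", (in_dim, 3 * H), in_dim, rng)
                self._param(f"gru_whh{tag}", (H, 3 * H), H, rng)
                self._param(f"gru_bih{tag}", (3 * H,), H, rng)
                self._param(f"gru_bhh{tag}", (3 * H,), H, rng)
        # trajectory means -> initial hidden states of all layers/directions
        self._param("h0_w", (n_rows, c.gru_layers * D * H), n_rows, rng)
        self._param("h0_b", (c.gru_layers * D * H,), n_rows, rng)
        A = c.attention_width
        self.seq_len = compressed_length(c.window_len, c)
        self._param("att_step_w", (H * D, A), H * D, rng)
        self._param("att_step_b", (A,), H * D, rng)
        self._param("att_flat_w", (A * self.seq_len, A), A * self.seq_len, rng)
        self._param("att_flat_b", (A,), A * self.seq_len, rng)
        self._param("hid_w", (H * D, A), H * D, rng)
        self._param("hid_b", (A,), H * D, rng)
        W = c.head_width
        self._param("head1_w", (2 * A, W), 2 * A, rng)
        self._param("head1_b", (W,), 2 * A, rng)
        self._param("head2_w", (W, c.output_dim), W, rng)
        self._param("head2_b", (c.output_dim,), W, rng)

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    # -- forward passes ------------------------------------------------
    def _subcnn(self, x: Tensor) -> Tensor:
        """(B*6, 1, L) -> (B*6, conv2_channels, seq_len)."""
        c, p = self.config, self.params
        h = x.conv1d(p["conv1_w"], p["conv1_b"], c.conv1_stride).relu()
        h = h.max_pool1d(c.pool_kernel)
        h = h.conv1d(p["conv2_w"], p["conv2_b"], c.conv2_stride).relu()
        return h.max_pool1d(c.pool_kernel)

    def _subcnn_per_row(self, x: Tensor, row: int) -> Tensor:
        c, p = self.config, self.params
        h = x.conv1d(p[f"conv1_w_r{row}"], p[f"conv1_b_r{row}"], c.conv1_stride).relu()
        h = h.max_pool1d(c.pool_kernel)
        h = h.conv1d(p[f"conv2_w_r{row}"], p[f"conv2_b_r{row}"], c.conv2_stride).relu()
        return h.max_pool1d(c.pool_kernel)

    def _gru_direction(self, feat: Tensor, h0: Tensor, layer: int, d: int):
        """Run one GRU direction over a (B, T, F) sequence tensor.

        The input-side gate projections for all steps are batched into a
        single matmul; only the hidden-side projection stays per step.
        """
        H = self.config.gru_hidden
        p = self.params
        tag = f"_l{layer}d{d}"
        B, T, F = feat.shape
        gi_all = (feat.reshape(B * T, F) @ p[f"gru_wih{tag}"]
                  + p[f"gru_bih{tag}"]).reshape(B, T, 3 * H)
        whh, bhh = p[f"gru_whh{tag}"], p[f"gru_bhh{tag}"]
        order = range(T) if d == 0 else range(T - 1, -1, -1)
        h = h0
        out: list[Tensor | None] = [None] * T
        for t in order:
            gi = gi_all[:, t, :]
            gh = h @ whh + bhh
            r = (gi[:, :H] + gh[:, :H]).sigmoid()
            z = (gi[:, H : 2 * H] + gh[:, H : 2 * H]).sigmoid()
            n = (gi[:, 2 * H :] + r * gh[:, 2 * H :]).tanh()
            h = (1.0 - z) * n + z * h
            out[t] = h
        return out, h

    def forward(self, batch: np.ndarray, trajectory_means: np.ndarray) -> Tensor:
        """(B, 6, window_len) inputs + (B, 6) means -> (B, 14) positive."""
        c = self.config
        batch = np.asarray(batch, float)
        B, rows, L = batch.shape
        if rows != 6:
            raise ValueError("expected 6 trajectory rows")
        x = Tensor(batch)
        if c.shared_subcnn:
            feat = self._subcnn(x.reshape(B * rows, 1, L))
            feat = feat.reshape(B, rows, c.conv2_channels, self.seq_len)
        else:
            per_row = [
                self._subcnn_per_row(x[:, r : r + 1, :], r) for r in range(rows)
            ]
            feat = Tensor.concat(
                [f.reshape(B, 1, c.conv2_channels, self.seq_len) for f in per_row],
                axis=1,
            )
        # (B, rows, C, T) -> per-step feature vectors (B, T, rows*C)
        T = self.seq_len
        feat = feat.transpose(0, 3, 1, 2).reshape(B, T, rows * c.conv2_channels)

        H = c.gru_hidden
        D = 2 if c.bidirectional else 1
        h0_all = (Tensor(np.asarray(trajectory_means, float)) @ self.params["h0_w"]
                  + self.params["h0_b"]).relu()
        h0_all = h0_all.reshape(B, c.gru_layers * D, H)
        last_h = None
        for layer in range(c.gru_layers):
            outs = []
            for d in range(D):
                h0 = h0_all[:, layer * D + d, :]
                out_d, h_final = self._gru_direction(feat, h0, layer, d)
                outs.append(out_d)
                if layer == c.gru_layers - 1:
                    last_h = h_final if d == 0 else Tensor.concat([last_h, h_final], axis=1)
            if D == 2:
                steps = [Tensor.concat([outs[0][t], outs[1][t]], axis=1).reshape(B, 1, D * H)
                         for t in range(T)]
            else:
                steps = [outs[0][t].reshape(B, 1, H) for t in range(T)]
            feat = Tensor.concat(steps, axis=1)  # (B, T, D*H)

        p = self.params
        # attention branch: per-step FC, flatten over the sequence, FC
        att = ((feat.reshape(B * T, D * H) @ p["att_step_w"]) + p["att_step_b"]).relu()
        att = att.reshape(B, T * c.attention_width)
        att = ((att @ p["att_flat_w"]) + p["att_flat_b"]).relu()
        hid = ((last_h @ p["hid_w"]) + p["hid_b"]).relu()
        merged = Tensor.concat([att, hid], axis=1)
        h = ((merged @ p["head1_w"]) + p["head1_b"]).relu()
        out = (h @ p["head2_w"]) + p["head2_b"]
        if c.positivity == "exp":
            return out.exp()
        if c.positivity == "softplus":
            return out.softplus()
        # literal softmax: positive but sum-normalized
        e = (out - Tensor(out.data.max(axis=1, keepdims=True))).exp()
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, batch: np.ndarray, trajectory_means: np.ndarray) -> np.ndarray:
        """Forward pass without gradient bookkeeping, returns numpy."""
        return self.forward(batch, trajectory_means).data

    # -- (de)serialization helpers -------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unexpected parameter {k}")
            if self.params[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            self.params[k].data = np.asarray(v, float).copy()


# ---------------------------------------------------------------------------
# Loss and training
# ---------------------------------------------------------------------------

def rmsle(q_true: np.ndarray, q_pred: np.ndarray) -> float:
    """Root mean square logarithmic error, natural log.

    ``sqrt(mean((log q - log q_hat)^2))`` over all components; scale
    invariant and symmetric in over-/under-prediction ratios.
    """
    q_true = np.asarray(q_true, float)
    q_pred = np.asarray(q_pred, float)
    if np.any(q_true <= 0) or np.any(q_pred <= 0):
        raise ValueError("RMSLE requires strictly positive inputs")
    d = np.log(q_true) - np.log(q_pred)
    return float(np.sqrt(np.mean(d * d)))


def _rmsle_loss(pred: Tensor, q_true: np.ndarray) -> Tensor:
    d = pred.log() - Tensor(np.log(q_true))
    return (d * d).mean().sqrt()


def train_surrogate(
    data: LabeledDataset,
    scfg: SurrogateConfig | None = None,
    tcfg: TrainConfig | None = None,
    progress: Callable[[str], None] | None = None,
) -> TrainingRunResult:
    """Train the CRNN on a labeled dataset and report validation metrics.

    A seeded 90/10 train/validation split, Adam with exponentially
    decaying learning rate, RMSLE loss, windows re-rolled every epoch,
    early stopping after ``early_stop_patience`` epochs without
    validation improvement.  Returns the best-validation model together
    with loss curves and the per-parameter validation MAE.
    """
    scfg = scfg or SurrogateConfig()
    tcfg = tcfg or TrainConfig()
    if len(data) == 0:
        raise ValueError("dataset is empty after the oscillation filter")
    rng = np.random.default_rng(tcfg.seed)
    n = len(data)
    perm = rng.permutation(n)
    n_val = max(1, int(round(tcfg.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    traj = np.asarray(data.trajectories, float)
    labels = np.asarray(data.q, float)

    val_x, val_means = preprocess_batch(traj[val_idx], data.dt, scfg, None, False)
    val_q = labels[val_idx]

    train_curve, val_curve = [], []
    best_val, best_state = np.inf, None
    since_best = 0
    # the network trains single precision; the ODE path stays double
    with use_dtype(np.float32):
        model = CRNN(scfg, seed=int(rng.integers(2**31)))
        opt = Adam(model.parameters(), lr=tcfg.lr_init)
        for epoch in range(tcfg.max_epochs):
            opt.lr = tcfg.lr_init * tcfg.lr_decay_base**epoch
            order = rng.permutation(len(train_idx))
            epoch_losses = []
            for start in range(0, len(order), tcfg.batch_size):
                sel = train_idx[order[start : start + tcfg.batch_size]]
                x, means = preprocess_batch(traj[sel], data.dt, scfg, rng, True)
                pred = model.forward(x, means)
                loss = _rmsle_loss(pred, labels[sel])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch} (loss={loss.data})"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
            val_pred = model.predict(val_x, val_means)
            v = rmsle(val_q, val_pred)
            train_curve.append(float(np.mean(epoch_losses)))
            val_curve.append(v)
            if progress:
                progress(
                    f"epoch {epoch}: train {train_curve[-1]:.4f} val {v:.4f} lr {opt.lr:.2e}"
                )
            if v < best_val:
                best_val, best_state = v, model.state_dict()
                since_best = 0
            else:
                since_best += 1
                if since_best >= tcfg.early_stop_patience:
                    break

    model.load_state_dict(best_state)
    val_pred = model.predict(val_x, val_means)
    val_mae = np.abs(val_pred - val_q).mean(axis=0)
    return TrainingRunResult(
        train_curve=train_curve,
        val_curve=val_curve,
        best_val_loss=float(best_val),
        epochs_trained=len(val_curve),
        model=model,
        val_mae=val_mae,
        seed=tcfg.seed,
    )


def exclude_subperformant(
    runs: list[TrainingRunResult], tolerance: float = 0.10
) -> list[TrainingRunResult]:
    """Keep runs whose validation loss is within 10% of the best run."""
    if not runs:
        raise ValueError("need at least one run")
    best = min(r.best_val_loss for r in runs)
    return [r for r in runs if r.best_val_loss <= (1 + tolerance) * best]
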