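"""Gated-attention multiple-instance survival network.

A case (patient) is a bag of patch embeddings per magnification scale.
Each scale has its own gated-attention pooling module producing a
case-level embedding; embeddings are concatenated across scales (plus
optional clinical covariates) and fed to a fully connected layer with
one neuron per discrete time interval.  Neuron ``t`` outputs, through a
sigmoid, the discrete hazard ``p_t`` — the probability of death in
interval ``t`` given survival to its start.  The survival function is
``S_t = prod_{tau<=t} (1 - p_tau)`` and the scalar risk score (the
digital pathology signature, DPS) is ``-sum_t S_t``: higher means worse
prognosis, bounded in ``[-n, 0]``.

The network is small enough that it is implemented directly on numpy
arrays with analytic gradients (see :meth:`MILSurvivalModel.loss_and_grads`)
and trained with Adam; a finite-difference check in the test suite
guards the backward pass.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SCALE_ORDER",
    "MILConfig",
    "AttentionParams",
    "AttentionWeights",
    "SurvivalHeadParams",
    "TimeGrid",
    "SurvivalLabel",
    "RiskOutput",
    "gated_attention",
    "aggregate_case",
    "fuse",
    "survival_head",
    "survival_function",
    "dps",
    "nll_loss",
    "make_time_grid",
    "MILSurvivalModel",
    "Adam",
]

#: Canonical magnification order used for multi-scale fusion.
SCALE_ORDER = ("5x", "10x", "20x")

_EPS = 1e-7


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MILConfig:
    """Model shape and initialisation settings.

    Parameters
    ----------
    scales:
        Magnification scales the model consumes, in canonical order
        (subset of ``("5x", "10x", "20x")``).
    input_dim:
        Dimensionality of the patch embeddings (1024).
    attn_dim:
        Hidden width ``L`` of the gated-attention module.
    dropout:
        Dropout rate applied to the attention-module inputs during
        training (the aggregation path sees the clean features).
    n_bins:
        Number of discrete time intervals ``n``.
    use_clinical:
        Append ``(sex_code, z-scored age)`` to the fused embedding.
    reduce_dim:
        Optional learned linear reduction of instance features before
        attention (e.g. 512); ``None`` disables it.
    seed:
        Seed for parameter initialisation and dropout.
    """

    scales: Sequence[str] = ("20x",)
    input_dim: int = 1024
    attn_dim: int = 256
    dropout: float = 0.25
    n_bins: int = 4
    use_clinical: bool = True
    reduce_dim: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [s for s in self.scales if s not in SCALE_ORDER]
        if bad:
            raise ValueError(f"unknown scales {bad}; expected subset of {SCALE_ORDER}")
        ordered = tuple(s for s in SCALE_ORDER if s in self.scales)
        object.__setattr__(self, "scales", ordered)

    @property
    def feature_dim(self) -> int:
        """Per-scale embedding width after the optional reduction."""
        return self.reduce_dim if self.reduce_dim else self.input_dim

    @property
    def fused_dim(self) -> int:
        return len(self.scales) * self.feature_dim + (2 if self.use_clinical else 0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class AttentionParams:
    """Learnable gated-attention parameters for one magnification."""

    V: np.ndarray  # (L, D)
    U: np.ndarray  # (L, D)
    w: np.ndarray  # (L,)

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.w = np.asarray(self.w, dtype=float).ravel()
        if self.V.shape != self.U.shape or self.V.shape[0] != self.w.shape[0]:
            raise ValueError("inconsistent attention parameter shapes")
        if not (np.isfinite(self.V).all() and np.isfinite(self.U).all()
                and np.isfinite(self.w).all()):
            raise ValueError("attention parameters must be finite")


@dataclass
class AttentionWeights:
    """Per-instance attention: softmax weights and raw (pre-softmax) logits."""

    a: np.ndarray
    logits: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float).ravel()
        self.logits = np.asarray(self.logits, dtype=float).ravel()


@dataclass
class SurvivalHeadParams:
    """Fully connected discrete-hazard head: one neuron per time bin."""

    W: np.ndarray  # (n_bins, fused_dim)
    b: np.ndarray  # (n_bins,)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.W.shape[0] != self.b.shape[0]:
            raise ValueError("head weight/bias shapes disagree")


# ---------------------------------------------------------------------------
# time discretisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeGrid:
    """Partition of follow-up time into ``n`` intervals.

    ``cut_points`` are the interior boundaries ``a_1 < ... < a_{n-1}``;
    the intervals are ``[0, a_1), [a_1, a_2), ..., [a_{n-1}, inf)``.
    """

    cut_points: np.ndarray

    def __post_init__(self) -> None:
        cp = np.asarray(self.cut_points, dtype=float).ravel()
        if cp.size < 1 or not np.all(np.diff(cp) > 0):
            raise ValueError("cut points must be strictly increasing, length >= 1")
        object.__setattr__(self, "cut_points", cp)

    @property
    def n(self) -> int:
        return self.cut_points.size + 1

    def bin_of(self, time) -> np.ndarray:
        """1-based interval index containing ``time`` (scalar or array)."""
        t = np.asarray(time, dtype=float)
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        return np.searchsorted(self.cut_points, t, side="right") + 1


def make_time_grid(times, events, n: int = 4) -> TimeGrid:
    """Quantile-based time grid over the uncensored event times.

    Cut points are the empirical quantiles of event times at levels
    ``1/n, ..., (n-1)/n`` (linear interpolation), so every bin contains
    at least one event.

    Raises
    ------
    ValueError
        If there are fewer than ``n`` distinct event times, or the
        quantiles collapse (suggesting a smaller ``n``).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if n < 2:
        raise ValueError("n must be >= 2")
    ev = times[events.astype(bool)]
    if np.unique(ev).size < n:
        raise ValueError(
            f"only {np.unique(ev).size} distinct event times; "
            f"use a smaller number of bins than n={n}"
        )
    cuts = np.quantile(ev, np.arange(1, n) / n)
    if not np.all(np.diff(cuts) > 0):
        raise ValueError(f"degenerate quantile cut points; use a smaller n than {n}")
    grid = TimeGrid(cuts)
    counts = np.bincount(grid.bin_of(ev) - 1, minlength=n)
    if np.any(counts == 0):
        raise ValueError(f"empty event bin with n={n}; use a smaller n")
    return grid


@dataclass(frozen=True)
class SurvivalLabel:
    """Right-censored follow-up mapped onto a :class:`TimeGrid`."""

    time: float
    event: int
    bin: int  # 1-based interval index containing `time`

    def __post_init__(self) -> None:
        if self.event not in (0, 1):
            raise ValueError("event must be 0 (censored) or 1 (death)")
        if self.bin < 1:
            raise ValueError("bin is a 1-based interval index")

    @staticmethod
    def from_grid(time: float, event: int, grid: TimeGrid) -> "SurvivalLabel":
        return SurvivalLabel(float(time), int(event), int(grid.bin_of(time)))


# ---------------------------------------------------------------------------
# elementary operations (the printed forward pass)
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max()
    e = np.exp(z)
    return e / e.sum()


def _check_features(features: np.ndarray) -> np.ndarray:
    f = np.asarray(features, dtype=float)
    if f.ndim != 2 or f.shape[0] < 1:
        raise ValueError("features must be a (B, D) matrix with B >= 1")
    if not np.isfinite(f).all():
        raise ValueError("features contain non-finite values")
    return f


def gated_attention(features: np.ndarray, params: AttentionParams) -> AttentionWeights:
    """Gated-attention score per instance.

    ``a_k = softmax_k( w^T ( tanh(V f_k) * sigmoid(U f_k) ) )`` with the
    softmax normalising over the whole bag, so the weights are in
    ``(0, 1]`` and sum to 1.
    """
    f = _check_features(features)
    if f.shape[1] != params.V.shape[1]:
        raise ValueError(
            f"feature dim {f.shape[1]} != attention input dim {params.V.shape[1]}"
        )
    gate = np.tanh(f @ params.V.T) * _sigmoid(f @ params.U.T)  # (B, L)
    logits = gate @ params.w  # (B,)
    return AttentionWeights(a=_softmax(logits), logits=logits)


def aggregate_case(weights: AttentionWeights | np.ndarray, features: np.ndarray) -> np.ndarray:
    """Attention-weighted sum of instance embeddings: ``h = sum_k a_k f_k``."""
    a = weights.a if isinstance(weights, AttentionWeights) else np.asarray(weights, float)
    f = _check_features(features)
    if a.shape[0] != f.shape[0]:
        raise ValueError("attention weights and features disagree on bag size")
    return f.T @ a


def fuse(
    case_embeddings: Mapping[str, np.ndarray],
    clinical: Optional[tuple] = None,
    scale_order: Sequence[str] = SCALE_ORDER,
) -> np.ndarray:
    """Concatenate per-scale case embeddings (fixed 5x, 10x, 20x order),
    appending ``(sex_code, normalized_age)`` last when provided."""
    ordered = [s for s in scale_order if s in case_embeddings]
    if len(ordered) != len(case_embeddings):
        missing = set(case_embeddings) - set(scale_order)
        raise ValueError(f"unknown scales in embeddings: {sorted(missing)}")
    parts = [np.asarray(case_embeddings[s], dtype=float).ravel() for s in ordered]
    if clinical is not None:
        parts.append(np.asarray(clinical, dtype=float).ravel())
    return np.concatenate(parts)


def survival_head(fused: np.ndarray, params: SurvivalHeadParams) -> np.ndarray:
    """Discrete hazards ``p_t = sigmoid(W_c h + b)_t``, one per time bin."""
    h = np.asarray(fused, dtype=float).ravel()
    if h.shape[0] != params.W.shape[1]:
        raise ValueError(f"fused dim {h.shape[0]} != head input dim {params.W.shape[1]}")
    return _sigmoid(params.W @ h + params.b)


def survival_function(p: np.ndarray) -> np.ndarray:
    """``S_t = prod_{tau<=t} (1 - p_tau)`` — non-increasing, in [0, 1]."""
    p = np.asarray(p, dtype=float).ravel()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("hazards must lie in [0, 1]")
    return np.cumprod(1.0 - p)


def dps(S: np.ndarray) -> float:
    """Digital pathology signature: ``-sum_t S_t``; in ``[-n, 0]``,
    strictly increasing in every hazard."""
    S = np.asarray(S, dtype=float).ravel()
    return float(-S.sum())


def nll_loss(p: np.ndarray, label: SurvivalLabel, event_weight: float = 1.0) -> float:
    """Discrete-time survival negative log-likelihood for one case.

    For an event in bin ``t``: ``-log p_t - sum_{tau<t} log(1-p_tau)``;
    for a case censored in bin ``t``: ``-sum_{tau<=t} log(1-p_tau)``.
    Hazards are clamped to ``[eps, 1-eps]`` (eps=1e-7) before the logs.
    ``event_weight`` optionally up-weights uncensored cases.
    """
    p = np.clip(np.asarray(p, dtype=float).ravel(), _EPS, 1.0 - _EPS)
    n = p.size
    t = label.bin
    if not 1 <= t <= n:
        raise ValueError(f"label bin {t} outside 1..{n}")
    i = t - 1
    if label.event:
        loss = -np.log(p[i]) - np.log(1.0 - p[:i]).sum()
        loss *= event_weight
    else:
        loss = -np.log(1.0 - p[: i + 1]).sum()
    return float(loss)


@dataclass
class RiskOutput:
    """Per-case model output: hazards, survival function, scalar DPS."""

    p: np.ndarray
    S: np.ndarray
    dps: float

    @staticmethod
    def from_hazards(p: np.ndarray) -> "RiskOutput":
        S = survival_function(p)
        return RiskOutput(p=np.asarray(p, float).ravel(), S=S, dps=dps(S))


# ---------------------------------------------------------------------------
# the trainable model
# ---------------------------------------------------------------------------

class MILSurvivalModel:
    """Multi-scale gated-attention MIL model with a discrete-hazard head.

    Parameters are plain numpy arrays in :attr:`params` keyed as
    ``V_<scale>``, ``U_<scale>``, ``w_<scale>``, ``R_<scale>`` (optional
    reduction), ``W_head``, ``b_head``.  The head is zero-initialised
    (all hazards start at 0.5); attention parameters are Gaussian.
    """

    def __init__(self, config: MILConfig, time_grid: Optional[TimeGrid] = None):
        self.config = config
        self.time_grid = time_grid
        self.age_mean: float = 0.0
        self.age_sd: float = 1.0
        # per-scale instance-feature centering (training-fold mean);
        # decouples hazard calibration from the discriminative direction
        self.feature_center: dict[str, np.ndarray] = {
            s: np.zeros(config.input_dim) for s in config.scales
        }
        self.params: dict[str, np.ndarray] = {}
        self.init_params(np.random.default_rng(config.seed))

    # -- parameters ---------------------------------------------------------
    def init_params(self, rng: np.random.Generator) -> None:
        c = self.config
        D, L, K = c.input_dim, c.attn_dim, c.feature_dim
        p: dict[str, np.ndarray] = {}
        for s in c.scales:
            if c.reduce_dim:
                p[f"R_{s}"] = rng.normal(0.0, 1.0 / np.sqrt(D), size=(K, D))
            p[f"V_{s}"] = rng.normal(0.0, 1.0 / np.sqrt(K), size=(L, K))
            p[f"U_{s}"] = rng.normal(0.0, 1.0 / np.sqrt(K), size=(L, K))
            p[f"w_{s}"] = rng.normal(0.0, 1.0 / np.sqrt(L), size=L)
        p["W_head"] = np.zeros((c.n_bins, c.fused_dim))
        p["b_head"] = np.zeros(c.n_bins)
        self.params = p

    def attention_params(self, scale: str) -> AttentionParams:
        return AttentionParams(
            V=self.params[f"V_{scale}"],
            U=self.params[f"U_{scale}"],
            w=self.params[f"w_{scale}"],
        )

    def head_params(self) -> SurvivalHeadParams:
        return SurvivalHeadParams(W=self.params["W_head"], b=self.params["b_head"])

    # -- clinical normalisation --------------------------------------------
    def set_age_norm(self, mean: float, sd: float) -> None:
        self.age_mean, self.age_sd = float(mean), float(sd) if sd > 0 else 1.0

    def set_feature_center(self, centers: Mapping[str, np.ndarray]) -> None:
        for s in self.config.scales:
            if s in centers:
                self.feature_center[s] = np.asarray(centers[s], dtype=float).ravel()

    def encode_clinical(self, sex, age_years: float) -> tuple:
        """(sex_code, z-scored age); sex female=1, male=0 (codes accepted)."""
        if isinstance(sex, str):
            sex_code = 1.0 if sex.lower().startswith("f") else 0.0
        else:
            sex_code = float(sex)
        return (sex_code, (float(age_years) - self.age_mean) / self.age_sd)

    # -- forward ------------------------------------------------------------
    @staticmethod
    def _bag_features(bag) -> np.ndarray:
        feats = getattr(bag, "features", bag)
        return np.asarray(feats, dtype=float)

    def _forward(self, bags: Mapping[str, object], clinical: Optional[tuple],
                 train: bool = False, rng: Optional[np.random.Generator] = None):
        c = self.config
        missing = [s for s in c.scales if s not in bags]
        if missing:
            raise ValueError(f"bags missing for configured scales: {missing}")
        cache: dict = {"scales": {}}
        embeds: dict[str, np.ndarray] = {}
        weights: dict[str, AttentionWeights] = {}
        for s in c.scales:
            f_raw = _check_features(self._bag_features(bags[s]))
            if f_raw.shape[1] != c.input_dim:
                raise ValueError(
                    f"scale {s}: feature dim {f_raw.shape[1]} != {c.input_dim}"
                )
            f_raw = f_raw - self.feature_center[s]
            if c.reduce_dim:
                f = f_raw @ self.params[f"R_{s}"].T
            else:
                f = f_raw
            if train and c.dropout > 0:
                if rng is None:
                    raise ValueError("training forward needs an rng for dropout")
                keep = 1.0 - c.dropout
                mask = (rng.random(f.shape) < keep) / keep
                fa = f * mask
            else:
                mask = None
                fa = f
            V, U, w = (self.params[f"V_{s}"], self.params[f"U_{s}"],
                       self.params[f"w_{s}"])
            preV = fa @ V.T
            preU = fa @ U.T
            t = np.tanh(preV)
            sg = _sigmoid(preU)
            g = t * sg
            logits = g @ w
            a = _softmax(logits)
            h = f.T @ a
            embeds[s] = h
            weights[s] = AttentionWeights(a=a, logits=logits)
            cache["scales"][s] = dict(f_raw=f_raw, f=f, fa=fa, mask=mask,
                                      t=t, sg=sg, g=g, a=a, h=h)
        clin_vec = None
        if c.use_clinical:
            if clinical is None:
                raise ValueError("model configured with clinical fusion but none given")
            clin_vec = np.asarray(clinical, dtype=float).ravel()
            if clin_vec.shape[0] != 2:
                raise ValueError("clinical must be (sex_code, normalized_age)")
        fused = fuse(embeds, clin_vec, scale_order=c.scales)
        z = self.params["W_head"] @ fused + self.params["b_head"]
        p = _sigmoid(z)
        cache.update(fused=fused, z=z, p=p, weights=weights)
        return cache

    def infer_case(self, bags: Mapping[str, object], clinical: Optional[tuple] = None):
        """Deterministic forward pass.

        Returns ``(RiskOutput, {scale: AttentionWeights})``.  ``clinical``
        is ``(sex, age_years)`` in raw units; the stored training-fold
        normalisation is applied.
        """
        clin = None
        if self.config.use_clinical:
            if clinical is None:
                raise ValueError("clinical covariates required by this config")
            clin = self.encode_clinical(*clinical)
        cache = self._forward(bags, clin, train=False)
        return RiskOutput.from_hazards(cache["p"]), cache["weights"]

    # -- loss and analytic gradients ----------------------------------------
    def loss_and_grads(self, bags: Mapping[str, object], clinical: Optional[tuple],
                       label: SurvivalLabel, rng: Optional[np.random.Generator] = None,
                       train: bool = True, event_weight: float = 1.0):
        """Negative log-likelihood of one case and gradients w.r.t. all
        parameters (backprop written out by hand).

        The loss is evaluated on the head logits (log-sigmoid form), which
        is the clamped-hazard likelihood up to epsilon and numerically
        stable; its gradient w.r.t. logit ``z_tau`` is ``p_tau`` for bins
        before the label bin (``<=`` when censored), ``p_t - 1`` at an
        event bin, zero after.
        """
        clin = clinical
        if self.config.use_clinical and clinical is not None and len(clinical) == 2:
            clin = tuple(float(v) for v in clinical)
        cache = self._forward(bags, clin, train=train, rng=rng)
        z, p, fused = cache["z"], cache["p"], cache["fused"]
        n = z.size
        i = label.bin - 1
        if not 0 <= i < n:
            raise ValueError(f"label bin {label.bin} outside 1..{n}")

        # stable log-sigmoid losses
        def log_sig(x):
            return -np.logaddexp(0.0, -x)

        if label.event:
            loss = -(log_sig(z[i]) + log_sig(-z[:i]).sum())
        else:
            loss = -log_sig(-z[: i + 1]).sum()
        dz = np.zeros(n)
        if label.event:
            dz[:i] = p[:i]
            dz[i] = p[i] - 1.0
        else:
            dz[: i + 1] = p[: i + 1]
        wgt = event_weight if label.event else 1.0
        loss *= wgt
        dz *= wgt

        grads: dict[str, np.ndarray] = {
            "W_head": np.outer(dz, fused),
            "b_head": dz,
        }
        dfused = self.params["W_head"].T @ dz
        K = self.config.feature_dim
        for idx, s in enumerate(self.config.scales):
            sc = cache["scales"][s]
            dh = dfused[idx * K: (idx + 1) * K]
            f, fa, a = sc["f"], sc["fa"], sc["a"]
            t, sg, g = sc["t"], sc["sg"], sc["g"]
            da = f @ dh                       # (B,)
            de = a * (da - float(a @ da))     # softmax backward
            w = self.params[f"w_{s}"]
            grads[f"w_{s}"] = g.T @ de
            dg = np.outer(de, w)              # (B, L)
            dpreV = dg * sg * (1.0 - t * t)
            dpreU = dg * t * sg * (1.0 - sg)
            V, U = self.params[f"V_{s}"], self.params[f"U_{s}"]
            grads[f"V_{s}"] = dpreV.T @ fa
            grads[f"U_{s}"] = dpreU.T @ fa
            if self.config.reduce_dim:
                df = np.outer(a, dh)          # aggregation path
                dfa = dpreV @ V + dpreU @ U   # attention path (pre-dropout)
                if sc["mask"] is not None:
                    dfa = dfa * sc["mask"]
                grads[f"R_{s}"] = (df + dfa).T @ sc["f_raw"]
        return float(loss), grads, cache

    # -- persistence ---------------------------------------------------------
    def save(self, path: str) -> None:
        """Single ``.npz`` checkpoint plus a ``.json`` metadata sidecar."""
        arrays = dict(self.params)
        if self.time_grid is not None:
            arrays["cut_points"] = self.time_grid.cut_points
        arrays["age_norm"] = np.array([self.age_mean, self.age_sd])
        for s, c in self.feature_center.items():
            arrays[f"center_{s}"] = c
        np.savez(path, **arrays)
        meta = {
            "config": self.config.to_dict(),
            "scale_order": list(self.config.scales),
            "config_hash": self.config.config_hash(),
            "format": "milsurv-checkpoint-v1",
        }
        sidecar = str(path)
        sidecar = sidecar[:-4] if sidecar.endswith(".npz") else sidecar
        with open(sidecar + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "MILSurvivalModel":
        sidecar = str(path)
        sidecar = sidecar[:-4] if sidecar.endswith(".npz") else sidecar
        with open(sidecar + ".json") as fh:
            meta = json.load(fh)
        cfg_dict = meta["config"]
        cfg_dict["scales"] = tuple(cfg_dict["scales"])
        config = MILConfig(**cfg_dict)
        data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        grid = TimeGrid(data["cut_points"]) if "cut_points" in data else None
        model = cls(config, time_grid=grid)
        for k in model.params:
            model.params[k] = np.array(data[k])
        if "age_norm" in data:
            model.set_age_norm(*data["age_norm"])
        for s in config.scales:
            if f"center_{s}" in data:
                model.feature_center[s] = np.array(data[f"center_{s}"])
        return model

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: Mapping[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.array(params[k])


class Adam:
    """Adam with decoupled weight decay, operating on a parameter dict."""

    def __init__(self, params: Mapping[str, np.ndarray], lr: float = 2e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Mapping[str, np.ndarray], grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            if self.wd:
                params[k] *= 1.0 - self.lr * self.wd
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
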