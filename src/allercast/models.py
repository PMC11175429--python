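"""Forecasting models over the disease network.

The multivariable spatiotemporal graph-convolutional forecaster (MST-GCN)
applies a stack of graph convolutions to every day of the history window,
feeds the resulting per-region embedding sequence to a gated recurrent unit
shared across regions, and emits all future days at once through an affine
readout (direct multi-step forecasting).  Three neural baselines isolate its
ingredients — graph convolution only, recurrence only, and the univariate
temporal-GCN combination — and a seasonal ARIMA fitted per region provides
the classical reference.

The graph convolution is H' = sigma(A_norm H theta) with the self-loop
normalised adjacency from :mod:`allercast.network`; layers inside a stack
use ReLU, the last layer of a stack is linear.  In the multivariable model
each layer additionally carries a root (self) transform, H theta_r, letting
node-specific attributes bypass the neighbourhood averaging.  The GRU uses
the standard reset/update gating:

    z = logistic(W_z [x, h] + b_z)
    r = logistic(W_r [x, h] + b_r)
    h~ = tanh(W_h [x, r * h] + b_h)
    h' = (1 - z) * h + z * h~
"""

from __future__ import annotations

import re
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .network import DiseaseNetwork

MODEL_KINDS = ("mstgcn", "tgcn", "gru", "gcn", "sarima")


@dataclass
class ModelConfig:
    """Architecture settings shared by the neural forecasters."""

    model_kind: str = "mstgcn"
    n_gcn_layers: int = 2
    gcn_hidden: int = 64
    gru_hidden: int = 128
    n_gru_layers: int = 1
    l_h: int = 14
    l_p: int = 1
    d_out: int = 1
    seed: int = 0
    dtype: str = "float64"  # float32 roughly halves CPU training time

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.l_h < 1 or self.l_p < 1:
            raise ValueError("l_h and l_p must be >= 1")
        if self.model_kind in ("mstgcn", "tgcn", "gru") and self.gru_hidden <= 0:
            raise ValueError("recurrent models need gru_hidden > 0")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, (fan_in, fan_out))


class NeuralForecaster:
    """Shared machinery: parameter store, GCN stack, GRU stack, readout."""

    def __init__(self, config: ModelConfig, n_features: int, network: DiseaseNetwork | None):
        self.config = config
        self.n_features = n_features
        self.network = network
        self.params: dict[str, Tensor] = {}
        self._weight_names: list[str] = []  # L2-penalised (biases excluded)
        self.dtype = np.dtype(config.dtype)
        if network is not None:
            self._a_norm = Tensor(network.normalized_adjacency.astype(self.dtype))
        self._build()

    # -- parameter plumbing ------------------------------------------------
    def _rng(self, name: str) -> np.random.Generator:
        # one deterministic stream per parameter: models that share a layer
        # (e.g. ablation arms with different input widths) share its init
        return np.random.default_rng([self.config.seed, zlib.crc32(name.encode())])

    def _add(self, name: str, array: np.ndarray, is_weight: bool = True) -> None:
        self.params[name] = Tensor(array.astype(self.dtype), requires_grad=True)
        if is_weight:
            self._weight_names.append(name)

    def weight_tensors(self) -> list:
        return [self.params[n] for n in self._weight_names]

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def get_state(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_state(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = v.astype(self.dtype)

    def save(self, path) -> None:
        np.savez(path, **self.get_state())

    def load(self, path) -> None:
        archive = np.load(path)
        self.set_state({k: archive[k] for k in archive.files})

    # -- building blocks ---------------------------------------------------
    def _build_gcn(
        self, n_layers: int, f_in: int, f_out: int, prefix: str = "gcn",
        root_weights: bool = False,
    ) -> None:
        dims = [f_in] + [f_out] * n_layers
        for i in range(n_layers):
            name = f"{prefix}{i}_w"
            self._add(name, _glorot(self._rng(name), dims[i], dims[i + 1]))
            if root_weights:
                name = f"{prefix}{i}_r"
                self._add(name, _glorot(self._rng(name), dims[i], dims[i + 1]))

    def _gcn_stack(self, h: Tensor, n_layers: int, prefix: str = "gcn") -> Tensor:
        """Graph convolutions; layers are H' = act(A_norm H theta [+ H theta_r]).

        The optional root term is a separate transform of the node's own
        features: neighbourhood averaging smooths node-specific attributes
        away, and the root path lets them bypass it (used by the
        multivariable model; the plain temporal-GCN baseline omits it).

        Operands are reshaped so every product is one large matrix product
        (batched small products are slow on CPU): the node axis is brought
        first for the adjacency multiply, and the batch/node axes are fused
        for the feature transforms.
        """
        b, n = h.shape[0], h.shape[1]
        for i in range(n_layers):
            f_in = h.shape[2]
            mixed = (
                self._a_norm @ h.transpose(1, 0, 2).reshape(n, b * f_in)
            ).reshape(n, b, f_in).transpose(1, 0, 2)
            flat = mixed.reshape(b * n, f_in)
            out = flat @ self.params[f"{prefix}{i}_w"]
            root = self.params.get(f"{prefix}{i}_r")
            if root is not None:
                out = out + h.reshape(b * n, f_in) @ root
            out = out.reshape(b, n, out.shape[-1])
            h = out.relu() if i < n_layers - 1 else out  # last layer linear
        return h

    def _build_gru(self, n_layers: int, f_in: int, hidden: int) -> None:
        # gate weights are stored fused ([z | r | c] along the output axis)
        # but initialised per gate so the Glorot scale matches the unfused form
        dims = [f_in] + [hidden] * n_layers
        for i in range(n_layers):
            rng = self._rng(f"gru{i}_wx")
            self._add(
                f"gru{i}_wx",
                np.concatenate(
                    [_glorot(rng, dims[i], hidden) for _ in range(3)], axis=1
                ),
            )
            rng = self._rng(f"gru{i}_uzr")
            self._add(
                f"gru{i}_uzr",
                np.concatenate(
                    [_glorot(rng, hidden, hidden) for _ in range(2)], axis=1
                ),
            )
            self._add(f"gru{i}_uc", _glorot(self._rng(f"gru{i}_uc"), hidden, hidden))
            self._add(f"gru{i}_b", np.zeros(3 * hidden), is_weight=False)

    def _gru_stack(self, seq: Tensor, n_layers: int, hidden: int) -> Tensor:
        """Run stacked GRUs over a (l_h, B, F) sequence; return the last hidden.

        The input projections of all gates and time steps are computed in one
        matrix product per layer; only the recurrent products stay inside the
        step loop.  The gating is the standard
        z = logistic(W_z x + U_z h + b_z), r = logistic(W_r x + U_r h + b_r),
        c = tanh(W_c x + U_c (r * h) + b_c), h' = (1 - z) * h + z * c.
        """
        p = self.params
        l_h, batch = seq.shape[0], seq.shape[1]
        for layer in range(n_layers):
            f_in = seq.shape[2]
            xproj = (
                seq.reshape(l_h * batch, f_in) @ p[f"gru{layer}_wx"]
                + p[f"gru{layer}_b"]
            ).reshape(l_h, batch, 3 * hidden)
            h = Tensor(np.zeros((batch, hidden), dtype=self.dtype))
            outputs = []
            for t in range(l_h):
                xp = xproj[t]
                hzr = h @ p[f"gru{layer}_uzr"]
                z = (xp[:, :hidden] + hzr[:, :hidden]).sigmoid()
                r = (xp[:, hidden : 2 * hidden] + hzr[:, hidden:]).sigmoid()
                cand = (xp[:, 2 * hidden :] + (r * h) @ p[f"gru{layer}_uc"]).tanh()
                h = (1.0 - z) * h + z * cand
                if layer < n_layers - 1:
                    outputs.append(h.reshape(1, batch, hidden))
            if layer < n_layers - 1:
                seq = Tensor.concat(outputs, axis=0)
        return h

    def _build_readout(self, f_in: int) -> None:
        c = self.config
        self._add("readout_w", _glorot(self._rng("readout_w"), f_in, c.l_p * c.d_out))
        self._add("readout_b", np.zeros(c.l_p * c.d_out), is_weight=False)

    def _readout(self, h: Tensor) -> Tensor:
        return h @ self.params["readout_w"] + self.params["readout_b"]

    # -- public API --------------------------------------------------------
    def forward(self, histories) -> Tensor:
        raise NotImplementedError

    def predict(self, histories: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(histories)).data

    def _prepare_history(self, histories) -> Tensor:
        t = Tensor._wrap(histories)
        if t.data.dtype != self.dtype and not t.requires_grad:
            t = Tensor(t.data.astype(self.dtype))
        self._check_history(t)
        return t

    def _check_history(self, histories: Tensor) -> None:
        s, l_h, n, f = histories.shape
        if l_h != self.config.l_h:
            raise ValueError(f"history length {l_h} != configured l_h {self.config.l_h}")
        if f != self.n_features:
            raise ValueError(f"feature count {f} != configured {self.n_features}")
        if self.network is not None and n != self.network.n_regions:
            raise ValueError("region axis does not match the network")


class MSTGCNForecaster(NeuralForecaster):
    """Per-day GCN stack -> per-region shared GRU -> direct multi-step readout."""

    def _build(self) -> None:
        c = self.config
        self._build_gcn(
            c.n_gcn_layers, self.n_features, c.gcn_hidden,
            root_weights=self.config.model_kind == "mstgcn",
        )
        self._build_gru(c.n_gru_layers, c.gcn_hidden, c.gru_hidden)
        self._build_readout(c.gru_hidden)

    def forward(self, histories) -> Tensor:
        histories = self._prepare_history(histories)
        c = self.config
        s, l_h, n, _ = histories.shape
        flat = histories.reshape(s * l_h, n, self.n_features)
        emb = self._gcn_stack(flat, c.n_gcn_layers)  # (S*l_h, N, g)
        seq = emb.reshape(s, l_h, n, c.gcn_hidden).transpose(1, 0, 2, 3).reshape(
            l_h, s * n, c.gcn_hidden
        )
        h = self._gru_stack(seq, c.n_gru_layers, c.gru_hidden)  # (S*N, H)
        out = self._readout(h)  # (S*N, l_p*D)
        return out.reshape(s, n, c.l_p, c.d_out).transpose(0, 2, 1, 3)


class TGCNForecaster(MSTGCNForecaster):
    """Temporal GCN baseline: the same pipeline fixed at two GCN layers, one GRU."""

    def __init__(self, config: ModelConfig, n_features: int, network: DiseaseNetwork):
        config = ModelConfig(**{**config.__dict__, "model_kind": "tgcn",
                                "n_gcn_layers": 2, "n_gru_layers": 1})
        super().__init__(config, n_features, network)


class GRUForecaster(NeuralForecaster):
    """Recurrence-only baseline: a stacked GRU run independently per region."""

    def __init__(self, config: ModelConfig, n_features: int, network=None):
        super().__init__(config, n_features, None)

    def _build(self) -> None:
        c = self.config
        self._build_gru(c.n_gru_layers, self.n_features, c.gru_hidden)
        self._build_readout(c.gru_hidden)

    def forward(self, histories) -> Tensor:
        histories = self._prepare_history(histories)
        c = self.config
        s, l_h, n, f = histories.shape
        seq = histories.transpose(1, 0, 2, 3).reshape(l_h, s * n, f)
        h = self._gru_stack(seq, c.n_gru_layers, c.gru_hidden)
        out = self._readout(h)
        return out.reshape(s, n, c.l_p, c.d_out).transpose(0, 2, 1, 3)


class GCNForecaster(NeuralForecaster):
    """Spatial-only baseline: history steps averaged (temporal order discarded),
    then two graph convolutions and an affine readout."""

    def _build(self) -> None:
        c = self.config
        self._build_gcn(c.n_gcn_layers, self.n_features, c.gcn_hidden)
        self._build_readout(c.gcn_hidden)

    def forward(self, histories) -> Tensor:
        histories = self._prepare_history(histories)
        c = self.config
        s, l_h, n, f = histories.shape
        # mean over the history axis discards temporal order by construction
        summed = histories[:, 0]
        for t in range(1, l_h):
            summed = summed + histories[:, t]
        pooled = summed * (1.0 / l_h)  # (S, N, F)
        emb = self._gcn_stack(pooled, c.n_gcn_layers)
        out = self._readout(emb)  # (S, N, l_p*D)
        return out.reshape(s, n, c.l_p, c.d_out).transpose(0, 2, 1, 3)


def make_model(config: ModelConfig, n_features: int, network: DiseaseNetwork | None):
    kind = config.model_kind
    if kind == "mstgcn":
        return MSTGCNForecaster(config, n_features, network)
    if kind == "tgcn":
        return TGCNForecaster(config, n_features, network)
    if kind == "gru":
        return GRUForecaster(config, n_features)
    if kind == "gcn":
        return GCNForecaster(config, n_features, network)
    raise ValueError(f"no neural forecaster for kind {kind!r}")


# ---------------------------------------------------------------------------
# standalone layer/cell entry points (used directly in tests and docs)
# ---------------------------------------------------------------------------

def gcn_layer(h: np.ndarray, normalized_adjacency: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """One graph convolution ReLU(A_norm H theta); no bias term."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != np.asarray(theta).shape[0]:
        raise ValueError("feature dimension of H does not match theta")
    return np.maximum(normalized_adjacency @ h @ theta, 0.0)


def gru_cell(x: np.ndarray, h: np.ndarray, params: dict) -> np.ndarray:
    """One GRU step on plain arrays; params keys w_z, b_z, w_r, b_r, w_h, b_h."""
    x, h = np.atleast_1d(np.asarray(x, float)), np.atleast_1d(np.asarray(h, float))
    xh = np.concatenate([x, h], axis=-1)
    sigmoid = lambda v: 1.0 / (1.0 + np.exp(-v))
    z = sigmoid(xh @ params["w_z"] + params["b_z"])
    r = sigmoid(xh @ params["w_r"] + params["b_r"])
    xrh = np.concatenate([x, r * h], axis=-1)
    h_cand = np.tanh(xrh @ params["w_h"] + params["b_h"])
    return (1.0 - z) * h + z * h_cand


# ---------------------------------------------------------------------------
# SARIMA baseline
# ---------------------------------------------------------------------------

@dataclass
class SarimaSpec:
    """Seasonal ARIMA orders (p, d, q)(P, D, Q)_s."""

    order: tuple = (1, 0, 1)
    seasonal_order: tuple = (0, 1, 1)
    s: int = 14

    def __post_init__(self) -> None:
        if any(v < 0 for v in (*self.order, *self.seasonal_order)) or self.s < 1:
            raise ValueError("orders must be >= 0 and s >= 1")

    def __str__(self) -> str:
        p, d, q = self.order
        sp, sd, sq = self.seasonal_order
        return f"({p},{d},{q})({sp},{sd},{sq})_{self.s}"

    @classmethod
    def from_string(cls, text: str) -> "SarimaSpec":
        m = re.fullmatch(
            r"\s*\((\d+),\s*(\d+),\s*(\d+)\)\s*\((\d+),\s*(\d+),\s*(\d+)\)_(\d+)\s*", text
        )
        if not m:
            raise ValueError(f"cannot parse SARIMA spec {text!r}")
        v = [int(g) for g in m.groups()]
        return cls(order=tuple(v[:3]), seasonal_order=tuple(v[3:6]), s=v[6])


def sarima_fit_forecast(
    series: np.ndarray, spec: SarimaSpec, horizon: int
) -> np.ndarray:
    """Maximum-likelihood fit of one region's series; direct multi-step forecast."""
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    series = np.asarray(series, dtype=float)
    p, _, q = spec.order
    _, sd, _ = spec.seasonal_order
    if len(series) <= spec.s * (sd + 1) + max(p, q):
        raise ValueError("series too short for the requested seasonal orders")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(
            series,
            order=spec.order,
            seasonal_order=(*spec.seasonal_order, spec.s),
            enforce_stationarity=False,
            enforce_invertibility=False,
        )
        res = model.fit(disp=False, maxiter=100)
        return np.asarray(res.forecast(steps=horizon))


def sarima_rolling_forecast(
    train_series: np.ndarray,
    test_series: np.ndarray,
    spec: SarimaSpec,
    horizon: int,
) -> np.ndarray:
    """Forecast the test span in blocks of ``horizon`` days.

    The model is fitted once on the training series; after each block the
    true observations are appended (parameters kept fixed) before the next
    block is forecast.
    """
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    train_series = np.asarray(train_series, dtype=float)
    test_series = np.asarray(test_series, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(
            train_series,
            order=spec.order,
            seasonal_order=(*spec.seasonal_order, spec.s),
            enforce_stationarity=False,
            enforce_invertibility=False,
        )
        res = model.fit(disp=False, maxiter=100)
        preds = []
        pos = 0
        while pos < len(test_series):
            step = min(horizon, len(test_series) - pos)
            preds.append(np.asarray(res.forecast(steps=step)))
            res = res.append(test_series[pos : pos + step], refit=False)
            pos += step
    return np.concatenate(preds)
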