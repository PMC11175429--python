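"""Forecaster forward contracts, reductions between architectures, SARIMA."""

import numpy as np
import pandas as pd
import pytest

from allercast.autodiff import Tensor
from allercast.models import (
    GRUForecaster,
    MSTGCNForecaster,
    ModelConfig,
    SarimaSpec,
    TGCNForecaster,
    gcn_layer,
    gru_cell,
    make_model,
    sarima_fit_forecast,
)
from allercast.network import DiseaseNetwork, build_knn_graph


def _zero_gru_params(f, h):
    return {
        f"{w}_{g}": np.zeros((f + h, h)) if w == "w" else np.zeros(h)
        for g in ("z", "r", "h")
        for w in ("w", "b")
    }


class TestGcnLayer:
    def test_two_node_complete_graph_by_hand(self):
        a_norm = np.full((2, 2), 0.5)
        out = gcn_layer(np.array([[1.0], [3.0]]), a_norm, np.array([[1.0]]))
        np.testing.assert_allclose(out, [[2.0], [2.0]])

    def test_relu_clips_negative_preactivation(self):
        out = gcn_layer(-np.ones((3, 2)), np.eye(3), np.eye(2))
        np.testing.assert_array_equal(out, 0.0)

    def test_identity_propagation_on_edgeless_graph(self):
        h = np.array([[1.0, -2.0], [0.5, 3.0]])
        out = gcn_layer(h, np.eye(2), np.eye(2))
        np.testing.assert_array_equal(out, np.maximum(h, 0.0))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            gcn_layer(np.ones((2, 3)), np.eye(2), np.ones((2, 1)))


class TestGruCell:
    def test_zero_weights_halve_hidden(self):
        params = _zero_gru_params(2, 3)
        h = np.array([1.0, -2.0, 4.0])
        out = gru_cell(np.array([5.0, 5.0]), h, params)
        np.testing.assert_allclose(out, 0.5 * h)

    def test_zero_state_fixed_point(self):
        params = _zero_gru_params(2, 3)
        out = gru_cell(np.zeros(2), np.zeros(3), params)
        np.testing.assert_array_equal(out, 0.0)

    def test_output_bounded_by_convex_combination(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            params = {
                f"{w}_{g}": rng.normal(size=(5 + 4, 4)) if w == "w" else rng.normal(size=4)
                for g in ("z", "r", "h")
                for w in ("w", "b")
            }
            h = rng.normal(size=4) * 3
            out = gru_cell(rng.normal(size=5), h, params)
            assert np.all(np.abs(out) <= np.maximum(np.abs(h), 1.0) + 1e-12)


@pytest.fixture(scope="module")
def random_history():
    rng = np.random.default_rng(7)
    return rng.random((4, 6, 8, 5))  # (S, l_h, N, F) in [0, 1]


@pytest.fixture(scope="module")
def module_network():
    rng = np.random.default_rng(1)
    regions = pd.DataFrame(
        {"region_id": range(8), "lon": rng.uniform(127, 129, 8),
         "lat": rng.uniform(35, 37, 8)}
    )
    return build_knn_graph(regions, k=2)


BASE = dict(n_gcn_layers=2, gcn_hidden=6, gru_hidden=5, l_h=6, l_p=2, d_out=3, seed=3)


class TestForwardContracts:
    @pytest.mark.parametrize("kind", ["mstgcn", "tgcn", "gru", "gcn"])
    def test_output_shape(self, kind, random_history, module_network):
        model = make_model(ModelConfig(model_kind=kind, **BASE), 5, module_network)
        out = model.predict(random_history)
        assert out.shape == (4, 2, 8, 3)

    @pytest.mark.parametrize("kind", ["mstgcn", "tgcn", "gru", "gcn"])
    def test_deterministic_forward(self, kind, random_history, module_network):
        cfg = ModelConfig(model_kind=kind, **BASE)
        m1 = make_model(cfg, 5, module_network)
        m2 = make_model(cfg, 5, module_network)
        np.testing.assert_array_equal(
            m1.predict(random_history), m2.predict(random_history)
        )

    @pytest.mark.parametrize("kind", ["mstgcn", "tgcn", "gcn"])
    def test_permutation_equivariance(self, kind, random_history, module_network):
        cfg = ModelConfig(model_kind=kind, **BASE)
        model = make_model(cfg, 5, module_network)
        out = model.predict(random_history)
        perm = np.random.default_rng(5).permutation(8)
        permuted_net = DiseaseNetwork(
            region_ids=[module_network.region_ids[i] for i in perm],
            adjacency=module_network.adjacency[np.ix_(perm, perm)],
            k=module_network.k,
        )
        model_p = make_model(cfg, 5, permuted_net)
        model_p.set_state(model.get_state())  # identical weights
        out_p = model_p.predict(random_history[:, :, perm, :])
        np.testing.assert_allclose(out_p, out[:, :, perm, :], atol=1e-10)

    def test_gcn_only_invariant_to_history_shuffling(self, random_history, module_network):
        model = make_model(ModelConfig(model_kind="gcn", **BASE), 5, module_network)
        out = model.predict(random_history)
        shuffled = random_history[:, ::-1].copy()
        np.testing.assert_allclose(model.predict(shuffled), out, atol=1e-12)

    def test_gru_regions_independent(self, random_history):
        model = make_model(ModelConfig(model_kind="gru", **BASE), 5, None)
        full = model.predict(random_history)
        per_region = np.concatenate(
            [model.predict(random_history[:, :, [i], :]) for i in range(8)], axis=2
        )
        np.testing.assert_allclose(per_region, full, atol=1e-12)

    def test_history_length_mismatch(self, random_history, module_network):
        cfg = ModelConfig(model_kind="mstgcn", **{**BASE, "l_h": 4})
        model = make_model(cfg, 5, module_network)
        with pytest.raises(ValueError):
            model.predict(random_history)


class TestReductions:
    def test_single_region_mstgcn_equals_gru(self, single_region_network):
        """With identity GCN weights on one region, the spatiotemporal model
        collapses to the per-node GRU with the same recurrent weights."""
        rng = np.random.default_rng(11)
        f = 4
        cfg = ModelConfig(model_kind="mstgcn", n_gcn_layers=2, gcn_hidden=f,
                          gru_hidden=6, l_h=5, l_p=2, d_out=1, seed=0)
        mst = MSTGCNForecaster(cfg, f, single_region_network)
        mst.params["gcn0_w"].data = np.eye(f)
        mst.params["gcn1_w"].data = np.eye(f)
        mst.params["gcn0_r"].data = np.zeros((f, f))
        mst.params["gcn1_r"].data = np.zeros((f, f))
        gru = GRUForecaster(ModelConfig(**{**cfg.__dict__, "model_kind": "gru"}), f)
        gru.set_state({k: v for k, v in mst.get_state().items() if not k.startswith("gcn")})
        hist = rng.random((6, 5, 1, f))  # non-negative: ReLU is pass-through
        np.testing.assert_allclose(mst.predict(hist), gru.predict(hist), atol=1e-6)

    def test_tgcn_equals_mstgcn_same_configuration(self, random_history, module_network):
        # the temporal-GCN baseline is the multivariable model with the
        # per-layer root (self) transforms removed
        cfg = ModelConfig(model_kind="mstgcn", **BASE)
        mst = MSTGCNForecaster(cfg, 5, module_network)
        for name in ("gcn0_r", "gcn1_r"):
            mst.params[name].data[:] = 0.0
        tgcn = TGCNForecaster(ModelConfig(model_kind="tgcn", **BASE), 5, module_network)
        tgcn.set_state(
            {k: v for k, v in mst.get_state().items() if not k.endswith("_r")}
        )
        np.testing.assert_allclose(
            tgcn.predict(random_history), mst.predict(random_history), atol=1e-12
        )

    def test_parameter_counts_match_formula(self, module_network):
        cfg = ModelConfig(model_kind="mstgcn", **BASE)
        model = MSTGCNForecaster(cfg, 5, module_network)
        g, h, lp, d = cfg.gcn_hidden, cfg.gru_hidden, cfg.l_p, cfg.d_out
        expected = (
            2 * (5 * g + g * g)  # two GCN layers, conv + root transforms
            + 3 * ((g + h) * h + h)  # GRU gates
            + h * lp * d + lp * d  # readout
        )
        assert model.n_parameters == expected


class TestGradients:
    def test_autodiff_matches_numeric_gradient(self, module_network):
        cfg = ModelConfig(model_kind="mstgcn", n_gcn_layers=2, gcn_hidden=3,
                          gru_hidden=3, l_h=3, l_p=1, d_out=1, seed=2)
        model = MSTGCNForecaster(cfg, 2, module_network)
        rng = np.random.default_rng(3)
        hist = rng.random((2, 3, 8, 2))
        target = rng.random((2, 1, 8, 1))

        def loss_value():
            pred = model.forward(Tensor(hist))
            return float(((pred.data - target) ** 2).sum())

        pred = model.forward(Tensor(hist))
        loss = ((pred - Tensor(target)) * (pred - Tensor(target))).sum()
        for p in model.params.values():
            p.zero_grad()
        loss.backward()
        eps = 1e-6
        for name in ["gcn0_w", "gcn1_r", "gru0_wx", "gru0_uzr", "gru0_uc", "readout_w", "gru0_b"]:
            param = model.params[name]
            idx = tuple(0 for _ in param.shape)
            orig = param.data[idx]
            param.data[idx] = orig + eps
            up = loss_value()
            param.data[idx] = orig - eps
            down = loss_value()
            param.data[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert param.grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestSarima:
    def test_spec_round_trips_through_text(self):
        spec = SarimaSpec.from_string("(1,0,1)(0,1,1)_14")
        assert spec.order == (1, 0, 1)
        assert spec.seasonal_order == (0, 1, 1)
        assert spec.s == 14
        assert SarimaSpec.from_string(str(spec)) == spec

    def test_invalid_spec_strings(self):
        with pytest.raises(ValueError):
            SarimaSpec.from_string("(1,0)(0,1,1)_14")

    def test_constant_series_forecast_constant(self):
        forecast = sarima_fit_forecast(np.full(120, 5.0), SarimaSpec(), horizon=14)
        np.testing.assert_allclose(forecast, 5.0, atol=1e-6)

    def test_seasonal_sinusoid_continued(self):
        t = np.arange(200)
        series = 10.0 + 3.0 * np.sin(2 * np.pi * t / 14.0)
        forecast = sarima_fit_forecast(series[:186], SarimaSpec(), horizon=14)
        truth = series[186:]
        r2 = 1 - np.sum((truth - forecast) ** 2) / np.sum((truth - truth.mean()) ** 2)
        assert r2 >= 0.9

    def test_series_too_short(self):
        with pytest.raises(ValueError):
            sarima_fit_forecast(np.ones(10), SarimaSpec(), horizon=3)
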