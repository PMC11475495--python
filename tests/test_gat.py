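"""GAT-Cox network: closed-form attention values, oracles, training behavior."""

import numpy as np
import pytest

from gatsurv.cohort import CohortConfig, SurvivalOutcome, generate_cohort
from gatsurv.coxph import cox_loss_and_grad
from gatsurv.exceptions import ConfigurationError
from gatsurv.gat import (
    GATConfig,
    GATCoxSurvival,
    GATLayerParams,
    TrainConfig,
    _init_params,
    _net_backward,
    _net_forward,
    attention_logit,
    attention_normalize,
    gat_layer_forward,
)
from gatsurv.graphs import SampleGraph, build_sample_graph


def scalar_params(w=1.0, a=(1.0, 1.0), slope=0.2):
    return GATLayerParams(
        W=np.array([[[w]]]), a=np.array([list(a)]), leaky_slope=slope
    )


def naive_gat_layer(X, adj, params: GATLayerParams, merge="concat", activation="elu"):
    """Loop-and-formula reference: e_ij, softmax over N_i, aggregation, merge."""
    H, Fo, _ = params.W.shape
    n = X.shape[0]
    heads = []
    for k in range(H):
        pk = GATLayerParams(params.W[k:k + 1], params.a[k:k + 1], params.leaky_slope)
        out = np.zeros((n, Fo))
        for i in range(n):
            nbrs = np.nonzero(adj[i])[0]
            logits = [attention_logit(X[i], X[j], pk) for j in nbrs]
            alpha = attention_normalize(logits)
            for w_ij, j in zip(alpha, nbrs):
                out[i] += w_ij * (params.W[k] @ X[j])
        heads.append(out)
    merged = np.concatenate(heads, axis=1) if merge == "concat" else np.mean(heads, axis=0)
    if activation == "elu":
        merged = np.where(merged > 0, merged, np.expm1(np.minimum(merged, 0)))
    return merged


# --- attention primitives -------------------------------------------------------

def test_attention_logit_scalar_cases():
    p = scalar_params(w=1.0, a=(1.0, 1.0))
    assert attention_logit([1.0], [2.0], p) == pytest.approx(3.0)
    p_neg = scalar_params(w=1.0, a=(-1.0, -1.0), slope=0.2)
    assert attention_logit([1.0], [2.0], p_neg) == pytest.approx(-0.6)
    p_zero = scalar_params(w=1.0, a=(0.0, 0.0))
    assert attention_logit([5.0], [-3.0], p_zero) == 0.0


def test_attention_logit_asymmetric():
    p = GATLayerParams(W=np.array([[[1.0]]]), a=np.array([[2.0, 1.0]]))
    assert attention_logit([1.0], [2.0], p) != attention_logit([2.0], [1.0], p)


def test_attention_logit_dim_mismatch_raises():
    p = scalar_params()
    with pytest.raises(ConfigurationError):
        attention_logit([1.0, 2.0], [1.0], p)


def test_attention_normalize_cases():
    np.testing.assert_allclose(attention_normalize([3.7]), [1.0])
    np.testing.assert_allclose(attention_normalize([2.0, 2.0, 2.0]), np.ones(3) / 3)
    np.testing.assert_allclose(attention_normalize([0.0, np.log(3)]), [0.25, 0.75])
    with pytest.raises(ConfigurationError):
        attention_normalize([])


def test_attention_normalize_overflow_safe():
    alpha = attention_normalize([1000.0, 1000.0])
    np.testing.assert_allclose(alpha, [0.5, 0.5])


# --- layer forward --------------------------------------------------------------

def test_isolated_node_with_identity_weights_returns_own_features():
    graph = SampleGraph(n_nodes=3, edges=frozenset(), self_loops=True)
    X = np.array([[1.0, 2.0], [3.0, 4.0], [-1.0, 0.5]])
    params = GATLayerParams(
        W=np.eye(2)[None, :, :], a=np.zeros((1, 4)), leaky_slope=0.2
    )
    out = gat_layer_forward(X, graph, params, merge="concat", activation="identity")
    np.testing.assert_allclose(out, X)  # alpha_ii = 1 for isolated nodes


def test_neighbor_order_permutation_invariance(rng):
    """Relabeling nodes permutes the outputs but never mixes them."""
    X = rng.normal(size=(8, 3))
    adj = rng.random((8, 8)) < 0.5
    adj = adj | adj.T
    np.fill_diagonal(adj, True)
    params = GATLayerParams(
        W=rng.normal(size=(2, 4, 3)), a=rng.normal(size=(2, 8)), leaky_slope=0.2
    )
    out = naive_gat_layer(X, adj, params)
    perm = rng.permutation(8)
    out_perm = naive_gat_layer(X[perm], adj[np.ix_(perm, perm)], params)
    np.testing.assert_allclose(out_perm, out[perm], atol=1e-12)


def test_two_node_path_hand_computed():
    """2-node path, scalar weights: hand evaluation of softmax + aggregation."""
    X = np.array([[1.0], [2.0]])
    adj = np.ones((2, 2), dtype=bool)
    p = scalar_params(w=2.0, a=(1.0, 0.5))
    # z = (2, 4); e_1j = 2 + 0.5*z_j -> e_11 = 3, e_12 = 4
    a11, a12 = np.exp([3.0, 4.0]) / np.exp([3.0, 4.0]).sum()
    expected_node1 = a11 * 2.0 + a12 * 4.0
    out = naive_gat_layer(X, adj, p, merge="concat", activation="identity")
    assert out[0, 0] == pytest.approx(expected_node1, rel=1e-12)
    graph = SampleGraph(n_nodes=2, edges=frozenset({(0, 1)}), self_loops=True)
    dense = gat_layer_forward(X, graph, p, merge="concat", activation="identity")
    np.testing.assert_allclose(dense, out, atol=1e-12)


def test_dense_forward_matches_naive_oracle_on_random_graphs(rng):
    """Vectorized masked attention == loop-and-formula oracle, 10-node graphs."""
    for trial in range(15):
        n, Fi, Fo, H = 10, 5, 3, 4
        X = rng.normal(size=(n, Fi))
        adj = rng.random((n, n)) < 0.3
        adj = adj | adj.T
        np.fill_diagonal(adj, True)
        params = GATLayerParams(
            W=rng.normal(size=(H, Fo, Fi)), a=rng.normal(size=(H, 2 * Fo)),
            leaky_slope=0.2,
        )
        edges = frozenset(
            (i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]
        )
        graph = SampleGraph(n_nodes=n, edges=edges, self_loops=True)
        for merge in ("concat", "mean"):
            dense = gat_layer_forward(X, graph, params, merge=merge)
            naive = naive_gat_layer(X, adj, params, merge=merge)
            np.testing.assert_allclose(dense, naive, atol=1e-10)


def test_attention_rows_sum_to_one(rng):
    from gatsurv.gat import _layer_forward

    n = 12
    X = rng.normal(size=(n, 4))
    adj = rng.random((n, n)) < 0.4
    adj = adj | adj.T
    np.fill_diagonal(adj, True)
    params = GATLayerParams(
        W=rng.normal(size=(3, 2, 4)), a=rng.normal(size=(3, 4)), leaky_slope=0.2
    )
    _, cache = _layer_forward(X, adj, params, "concat", "elu")
    sums = cache["alphas"].sum(axis=2)
    np.testing.assert_allclose(sums, 1.0, atol=1e-6)
    # attention support never leaves the neighborhood
    assert (cache["alphas"][:, ~adj] == 0).all()


# --- full network ---------------------------------------------------------------

def _toy_net(rng, n=9, Fi=4, dropout=0.0, batch_norm=True, heads=2, hidden=3):
    X = rng.normal(size=(n, Fi))
    adj = rng.random((n, n)) < 0.4
    adj = adj | adj.T
    np.fill_diagonal(adj, True)
    cfg = GATConfig(hidden_dim=hidden, num_heads=heads, dropout=dropout,
                    batch_norm=batch_norm)
    params = _init_params(rng, Fi, cfg)
    D = hidden * heads
    bn = {"mean": np.zeros(D), "var": np.ones(D)}
    return X, adj, cfg, params, bn


def test_zero_weight_model_gives_constant_risk(rng):
    X, adj, cfg, params, bn = _toy_net(rng)
    for k in ("l1.W", "l1.a", "l2.W", "l2.a"):
        params[k] = np.zeros_like(params[k])
    risk, _ = _net_forward(params, X, adj, cfg, bn, training=False)
    assert np.ptp(risk) == pytest.approx(0.0, abs=1e-12)


def test_eval_mode_is_deterministic(rng):
    X, adj, cfg, params, bn = _toy_net(rng, dropout=0.6)
    r1, _ = _net_forward(params, X, adj, cfg, dict(bn), training=False)
    r2, _ = _net_forward(params, X, adj, cfg, dict(bn), training=False)
    np.testing.assert_array_equal(r1, r2)


def test_full_network_gradient_matches_finite_differences(rng):
    """Analytic backprop vs central differences on a 5-node toy, rel err < 1e-4."""
    n = 5
    X = rng.normal(size=(n, 3))
    adj = np.ones((n, n), dtype=bool)
    cfg = GATConfig(hidden_dim=2, num_heads=2, dropout=0.0, batch_norm=True)
    params = _init_params(rng, 3, cfg)
    bn = {"mean": np.zeros(4), "var": np.ones(4)}
    time = rng.exponential(1, n)
    event = np.array([1, 0, 1, 1, 0])
    mask = np.ones(n, bool)

    def loss_at(p):
        bn_local = {k: v.copy() for k, v in bn.items()}
        risk, _ = _net_forward(p, X, adj, cfg, bn_local, training=True)
        return cox_loss_and_grad(risk, time, event, mask)[0]

    bn_run = {k: v.copy() for k, v in bn.items()}
    risk, caches = _net_forward(params, X, adj, cfg, bn_run, training=True)
    _, dg = cox_loss_and_grad(risk, time, event, mask)
    grads, _ = _net_backward(dg, params, caches, cfg)

    h = 1e-6
    for name in grads:
        flat = params[name].ravel()
        for idx in range(0, flat.size, max(1, flat.size // 6)):
            p2 = {k: v.copy() for k, v in params.items()}
            p2[name].ravel()[idx] += h
            lp = loss_at(p2)
            p2[name].ravel()[idx] -= 2 * h
            lm = loss_at(p2)
            num = (lp - lm) / (2 * h)
            ana = grads[name].ravel()[idx]
            assert ana == pytest.approx(num, rel=1e-4, abs=1e-9), name


def test_fit_is_seed_reproducible(small_cohort):
    ds = small_cohort
    model = GATCoxSurvival.from_dataset(
        ds, config=GATConfig(hidden_dim=4, num_heads=2)
    )
    tc = TrainConfig(max_epochs=8, patience=8, seed=5)
    r1 = model.fit(train_config=tc)
    r2 = model.fit(train_config=tc)
    np.testing.assert_array_equal(r1.risk_scores, r2.risk_scores)
    assert r1.concordance() == r2.concordance()


def test_best_checkpoint_loss_is_monotone(small_cohort):
    model = GATCoxSurvival.from_dataset(
        small_cohort, config=GATConfig(hidden_dim=4, num_heads=2, dropout=0.3)
    )
    res = model.fit(train_config=TrainConfig(max_epochs=25, patience=25, seed=2))
    best_so_far = np.minimum.accumulate(res.history["monitor_loss"])
    assert (np.diff(best_so_far) <= 1e-12).all()


def test_training_separates_strong_toy_hazard():
    """With huge effect sizes the trained risk approaches the true-hazard
    ranking (oracle C of the generating linear predictor is 0.983 here)."""
    cfg = CohortConfig(
        n_samples=60,
        block_sizes={"mrna": 12},
        n_informative={"mrna": 3},
        effect_sizes=(6.0, 8.0),
        censoring_fraction_target=0.0,
        n_clusters=2,
        seed=13,
    )
    ds = generate_cohort(cfg)
    sd = ds.X.std(0)
    eta = ((ds.X - ds.X.mean(0)) / np.where(sd > 0, sd, 1.0))[
        :, ds.truth.indices
    ] @ ds.truth.beta
    from gatsurv.survival import concordance_index

    oracle = concordance_index(eta, ds.outcome)
    model = GATCoxSurvival.from_dataset(
        ds, config=GATConfig(hidden_dim=8, num_heads=2, dropout=0.0)
    )
    res = model.fit(
        train_config=TrainConfig(learning_rate=0.01, max_epochs=500, patience=500,
                                 seed=3, val_fraction=0.0)
    )
    assert res.concordance() >= 0.95
    assert res.concordance() >= oracle - 0.03


def test_feature_importance_zero_except_one_column(rng):
    X, adj, cfg, params, bn = _toy_net(rng, n=12, Fi=5)
    W = np.zeros_like(params["l1.W"])
    W[:, :, 2] = 1.0
    params["l1.W"] = W
    graph = SampleGraph(
        n_nodes=12,
        edges=frozenset(
            (i, j) for i in range(12) for j in range(i + 1, 12) if adj[i, j]
        ),
        self_loops=True,
    )
    model = GATCoxSurvival(
        X, (np.arange(12) + 1.0, np.ones(12, dtype=int)), graph=graph, config=cfg
    )
    from gatsurv.gat import GATCoxResults
    import pandas as pd

    res = GATCoxResults(
        model=model, params=params, bn_state=bn,
        risk_scores=np.zeros(12), history=pd.DataFrame(),
        train_mask=np.ones(12, bool), val_mask=np.zeros(12, bool),
        best_epoch=0, train_config=TrainConfig(),
    )
    imp = res.feature_importance()
    assert imp.iloc[0]["feature"] == "x2"
    assert imp.iloc[0]["importance"] == 1.0
    assert (imp["importance"].iloc[1:] == 0).all()


@pytest.mark.parametrize("kind", ["weight", "grad_input"])
def test_feature_importance_ranks_informative_above_null(kind):
    cfg = CohortConfig(
        n_samples=120,
        block_sizes={"mrna": 40},
        n_informative={"mrna": 6},
        effect_sizes=(1.5, 2.0),
        n_clusters=3,
        seed=17,
    )
    ds = generate_cohort(cfg)
    model = GATCoxSurvival.from_dataset(
        ds, config=GATConfig(hidden_dim=8, num_heads=2, dropout=0.2)
    )
    res = model.fit(
        train_config=TrainConfig(learning_rate=0.01, max_epochs=200, patience=200,
                                 seed=4)
    )
    scores = res.feature_importance(kind).set_index("feature")["importance"]
    inf_ids = set(ds.feature_ids[ds.truth.indices])
    inf_scores = scores[[f for f in scores.index if f in inf_ids]]
    null_scores = scores[[f for f in scores.index if f not in inf_ids]]
    assert inf_scores.mean() > null_scores.mean() + 0.1


def test_train_mask_without_events_raises(small_cohort):
    model = GATCoxSurvival.from_dataset(small_cohort)
    mask = small_cohort.outcome.event == 0
    with pytest.raises(ConfigurationError):
        model.fit(train_mask=mask)
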