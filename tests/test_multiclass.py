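import numpy as np
import pytest

from conftest import FAST_SVM, tiny_spec
from mitool.multiclass import (
    MulticlassModel,
    evaluate,
    predict_all,
    predict_dag,
    predict_epoch,
    predict_ovo,
    predict_ovr,
    predict_two_layer,
    train_multiclass,
)
from mitool.signal_io import EpochSet
from mitool.synthetic import generate


class StubNode:
    """Decision unit with fixed decision values, for topology-rule tests."""

    def __init__(self, pair, value):
        self.pair = pair
        self.role = str(pair)
        self._value = value

    def decision(self, epoch):
        return self._value


def stub_model(scheme, classes, decisions):
    nodes = [StubNode(pair, d) for pair, d in decisions.items()]
    grouping = None
    if scheme == "two_layer":
        grouping = nodes[0].pair
    return MulticlassModel(scheme=scheme, classes=classes, nodes=nodes, grouping=grouping)


EPOCH = np.zeros((4, 10))


@pytest.fixture(scope="module")
def data():
    return generate(tiny_spec(K=4, seed=21))


class TestTraining:
    @pytest.mark.parametrize("scheme,n_svms", [("ovr", 4), ("ovo", 6), ("dag", 6), ("two_layer", 3)])
    def test_four_class_node_counts(self, data, scheme, n_svms):
        model = train_multiclass(data[0], scheme=scheme, csp_m=1, svm_config=FAST_SVM)
        assert model.n_svms == n_svms

    @pytest.mark.parametrize("K", [3, 5])
    def test_pairwise_node_counts_scale_as_k_choose_2(self, K):
        train, _ = generate(tiny_spec(K=K, seed=22))
        model = train_multiclass(train, scheme="ovo", csp_m=1, svm_config=FAST_SVM)
        assert model.n_svms == K * (K - 1) // 2
        model = train_multiclass(train, scheme="ovr", csp_m=1, svm_config=FAST_SVM)
        assert model.n_svms == K

    def test_pairwise_nodes_see_only_their_classes(self, data):
        model = train_multiclass(data[0], scheme="ovo", csp_m=1, svm_config=FAST_SVM)
        assert [n.pair for n in model.nodes] == [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]

    def test_two_layer_requires_grouping_for_k3(self):
        train, _ = generate(tiny_spec(K=3, seed=23))
        with pytest.raises(ValueError, match="grouping"):
            train_multiclass(train, scheme="two_layer", csp_m=1, svm_config=FAST_SVM)
        model = train_multiclass(
            train, scheme="two_layer", csp_m=1, svm_config=FAST_SVM, grouping=((1, 2), (3,))
        )
        assert model.n_svms == 2  # singleton group skips layer 2

    def test_unknown_scheme_rejected(self, data):
        with pytest.raises(ValueError):
            train_multiclass(data[0], scheme="tournament")


class TestOvrRule:
    def test_single_positive_is_unambiguous(self):
        model = stub_model("ovr", [1, 2, 3, 4],
                           {(1, "rest"): 0.8, (2, "rest"): -0.5, (3, "rest"): -1.0, (4, "rest"): -2.0})
        k, diag = predict_ovr(model, EPOCH)
        assert k == 1 and diag["ambiguous"] is False

    def test_multiple_positives_fall_back_to_argmax(self):
        model = stub_model("ovr", [1, 2, 3, 4],
                           {(1, "rest"): 0.9, (2, "rest"): 0.3, (3, "rest"): -1.0, (4, "rest"): -1.0})
        k, diag = predict_ovr(model, EPOCH)
        assert k == 1 and diag["ambiguous"] is True

    def test_all_negative_falls_back_to_argmax(self):
        model = stub_model("ovr", [1, 2, 3, 4],
                           {(1, "rest"): -0.2, (2, "rest"): -0.9, (3, "rest"): -1.1, (4, "rest"): -3.0})
        k, diag = predict_ovr(model, EPOCH)
        assert k == 1 and diag["ambiguous"] is True


class TestOvoRule:
    def test_unanimous_winner_collects_all_its_votes(self):
        decisions = {(1, 2): -1.0, (1, 3): 1.0, (1, 4): 1.0,
                     (2, 3): 1.0, (2, 4): 1.0, (3, 4): 1.0}
        model = stub_model("ovo", [1, 2, 3, 4], decisions)
        k, diag = predict_ovo(model, EPOCH)
        assert k == 2 and diag["votes"][2] == 3
        assert sum(diag["votes"].values()) == 6  # one vote per pair

    def test_three_way_tie_resolved_by_decision_margins(self):
        # votes: 1→2, 2→2, 3→2, 4→0; margins favor class 3
        decisions = {(1, 2): 0.1, (1, 3): -2.0, (1, 4): 0.1,
                     (2, 3): 0.1, (2, 4): 0.1, (3, 4): 2.0}
        model = stub_model("ovo", [1, 2, 3, 4], decisions)
        k, diag = predict_ovo(model, EPOCH)
        votes = diag["votes"]
        assert (votes[1], votes[2], votes[3], votes[4]) == (2, 2, 2, 0)
        margins = {c: sum((d if a == c else -d if b == c else 0.0)
                          for (a, b), d in decisions.items()) for c in [1, 2, 3, 4]}
        assert max(margins, key=margins.get) == 3
        assert k == 3

    def test_full_tie_breaks_to_smallest_class_id(self):
        decisions = {(1, 2): 1.0, (1, 3): -1.0, (1, 4): 1.0,
                     (2, 3): 1.0, (2, 4): -1.0, (3, 4): 1.0}
        model = stub_model("ovo", [1, 2, 3, 4], decisions)
        k, diag = predict_ovo(model, EPOCH)
        assert sorted(diag["votes"].values()) == [1, 1, 2, 2]


class TestDagRule:
    def test_path_length_is_k_minus_one(self):
        decisions = {(a, b): 1.0 for a in range(1, 5) for b in range(a + 1, 5)}
        model = stub_model("dag", [1, 2, 3, 4], decisions)
        k, diag = predict_dag(model, EPOCH)
        assert len(diag["path"]) == 3
        assert k == 1

    def test_unanimous_pairwise_favorite_always_wins(self):
        # every pairwise decision favors class 3
        decisions = {}
        for a in range(1, 5):
            for b in range(a + 1, 5):
                if a == 3:
                    decisions[(a, b)] = 1.0
                elif b == 3:
                    decisions[(a, b)] = -1.0
                else:
                    decisions[(a, b)] = 1.0
        model = stub_model("dag", [1, 2, 3, 4], decisions)
        assert predict_dag(model, EPOCH)[0] == 3
        model.scheme = "ovo"
        assert predict_ovo(model, EPOCH)[0] == 3  # agrees with voting

    def test_root_error_accumulates(self):
        # true class 1: both remaining 1-pairs favor it, but the root (1 vs 4)
        # eliminates class 1, so no later node can recover it
        decisions = {(1, 4): -0.1, (1, 2): 1.0, (1, 3): 1.0,
                     (2, 4): 0.5, (2, 3): 0.5, (3, 4): 0.5}
        model = stub_model("dag", [1, 2, 3, 4], decisions)
        k, diag = predict_dag(model, EPOCH)
        assert diag["path"][0] == {"pair": (1, 4), "decision": -0.1, "eliminated": 1}
        assert k != 1
        model.scheme = "ovo"
        assert predict_ovo(model, EPOCH)[0] == 1  # voting still recovers it


class TestTwoLayerRule:
    def test_tree_traversal(self):
        decisions = {((1, 2), (3, 4)): -0.4, (1, 2): 1.0, (3, 4): -0.9}
        model = stub_model("two_layer", [1, 2, 3, 4], decisions)
        k, diag = predict_two_layer(model, EPOCH)
        assert diag["group"] == (3, 4)
        assert k == 4
        assert "layer2" in diag  # exactly two evaluations

    def test_singleton_group_skips_layer_two(self):
        decisions = {((1, 2), (3,)): -0.4, (1, 2): 1.0}
        model = stub_model("two_layer", [1, 2, 3], decisions)
        k, diag = predict_two_layer(model, EPOCH)
        assert k == 3 and "layer2" not in diag


@pytest.fixture(scope="module")
def trained():
    train, test = generate(tiny_spec(K=4, seed=24))
    model = train_multiclass(train, scheme="two_layer", csp_m=1, svm_config=FAST_SVM)
    return model, test


class TestEvaluate:
    def test_confusion_counts_conserve_epochs(self, trained):
        model, test = trained
        acc, confusion = evaluate(model, test)
        assert confusion.sum() == test.n_epochs
        assert acc == pytest.approx(100.0 * np.trace(confusion) / test.n_epochs)

    def test_perfect_predictions_give_diagonal_confusion(self, trained):
        model, test = trained
        pred = predict_all(model, test)
        oracle = EpochSet(test.data, pred, test.fs, test.channel_names)
        acc, confusion = evaluate(model, oracle)
        assert acc == 100.0
        assert np.all(confusion == np.diag(np.diag(confusion)))

    def test_prediction_is_deterministic(self, trained):
        model, test = trained
        a = predict_epoch(model, test.data[0])
        b = predict_epoch(model, test.data[0])
        assert a == b

    def test_shuffled_labels_score_near_chance(self, trained):
        model, test = trained
        rng = np.random.default_rng(0)
        chance = EpochSet(test.data, rng.permutation(test.labels), test.fs, test.channel_names)
        acc, _ = evaluate(model, chance)
        assert 10.0 < acc < 45.0  # K=4 chance level is 25%

    def test_empty_test_set_rejected(self, trained):
        model, test = trained
        with pytest.raises(ValueError):
            evaluate(model, test.select(np.zeros(test.n_epochs, dtype=bool)))
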