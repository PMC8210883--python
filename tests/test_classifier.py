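import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

import spikestate as ss
from spikestate import DataError
from spikestate.classifier import STATE_ORDER, parse_gate

from conftest import ACCEPT_SEED, derive_pc1_gates


class TestSelectDifferentialGenes:
    def small(self):
        cells = [f"c{i}" for i in range(6)]
        ann = pd.DataFrame({"condition": ["control"] * 3 + ["PAC16"] * 3},
                           index=cells)
        E = pd.DataFrame(
            {
                "flat": [2.0] * 6,
                "boundary": [2.0] * 3 + [2.0 + np.log2(1.5)] * 3,
                "strong": [2.0] * 3 + [4.0] * 3,
            },
            index=cells,
        ).T
        return E, ann

    def test_flat_gene_not_selected(self):
        E, ann = self.small()
        genes, _ = ss.select_differential_genes(E, ann)
        assert "flat" not in genes

    def test_boundary_inclusive(self):
        E, ann = self.small()
        genes, _ = ss.select_differential_genes(E, ann)
        assert "boundary" in genes

    def test_control_normalization(self):
        E, ann = self.small()
        _, norm = ss.select_differential_genes(E, ann)
        ctrl = ann.index[ann.condition == "control"]
        np.testing.assert_allclose(norm[ctrl].mean(axis=1), 0.0, atol=1e-12)

    def test_no_control_errors(self):
        E, ann = self.small()
        ann["condition"] = "PAC16"
        with pytest.raises(DataError):
            ss.select_differential_genes(E, ann)

    def test_planted_cluster_genes_selected(self, sc_data):
        """Well-expressed planted genes exceed the threshold by construction;
        near the E-value floor the log2(N/10+1) transform compresses folds."""
        truth = sc_data["truth"]
        E = sc_data["evalues"].E
        ann = sc_data["annotation"]
        ctrl_mean = E[ann.index[ann.condition == "control"]].mean(axis=1)
        planted = set(truth.true_cluster.index[truth.true_cluster != "none"])
        present = {g for g in planted if g in E.index and ctrl_mean[g] >= 3.0}
        selected = set(sc_data["de_genes"])
        assert len(present & selected) / len(present) > 0.95


class TestPca:
    def test_rank_one_matrix(self):
        gene = np.array([1.0, 2.0, 3.0, 4.0])
        m = pd.DataFrame(np.outer([1.0, 2.0, 0.5], gene),
                         index=["g1", "g2", "g3"],
                         columns=[f"c{i}" for i in range(4)])
        res = ss.run_pca(m)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_duplicated_cell_identical_scores(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(10, 5)),
                         index=[f"g{i}" for i in range(10)],
                         columns=[f"c{i}" for i in range(5)])
        m["dup"] = m["c0"]
        res = ss.run_pca(m)
        np.testing.assert_allclose(res.scores.loc["c0"], res.scores.loc["dup"],
                                   atol=1e-9)

    def test_too_few_cells(self):
        m = pd.DataFrame(np.ones((5, 2)), index=list("abcde"), columns=["x", "y"])
        with pytest.raises(DataError):
            ss.run_pca(m)

    def test_orientation(self, sc_data):
        ann = sc_data["annotation"]
        ctrl = ann.index[ann.condition == "control"].tolist()
        cele = ann.index[ann.condition == "CELE16"].tolist()
        res = ss.run_pca(sc_data["norm"], orient={"PC1": cele, "PC2": ctrl})
        assert res.scores.loc[cele, "PC1"].mean() > 0
        assert res.scores.loc[ctrl, "PC2"].mean() > 0

    def test_states_separable_silhouette(self, sc_data):
        res = ss.run_pca(sc_data["norm"])
        truth = sc_data["truth"].true_state.loc[res.scores.index]
        sil = silhouette_score(res.scores[["PC1", "PC2"]], truth)
        assert sil > 0.3

    def test_variance_fractions_non_increasing(self, sc_data):
        res = ss.run_pca(sc_data["norm"])
        vf = res.variance_fraction
        assert (np.diff(vf) <= 1e-12).all()
        assert ((vf >= 0) & (vf <= 1)).all()


class TestOobConditionError:
    def test_separated_conditions_low_error(self):
        """Cleanly separated conditions (small per-cell content jitter)."""
        for seed in range(3):
            cfg = ss.SyntheticConfig.three_state(50, seed=seed,
                                                 content_jitter_cv=0.05)
            tpm, _, ann, truth = ss.simulate_single_cell_experiment(cfg)
            spk = ss.SpikeInSet(truth.spikein_ids)
            ev = ss.spikein_normalize_evalues(tpm, spk)
            _, norm = ss.select_differential_genes(ev.E, ann,
                                                   exclude=spk.spikein_ids)
            err = ss.oob_condition_error(norm, ann["condition"], ntree=200,
                                         seed=seed)
            assert (err < 0.1).all(), err.to_dict()

    def test_permuted_labels_chance_error(self, sc_data):
        rng = np.random.default_rng(0)
        cond = sc_data["annotation"]["condition"]
        permuted = pd.Series(rng.permutation(cond.to_numpy()), index=cond.index)
        err = ss.oob_condition_error(sc_data["norm"], permuted, ntree=200, seed=1)
        assert err.mean() == pytest.approx(1 - 1 / 3, abs=0.1)

    def test_single_condition_errors(self, sc_data):
        labels = pd.Series("only", index=sc_data["norm"].columns)
        with pytest.raises(DataError):
            ss.oob_condition_error(sc_data["norm"], labels)

    def test_small_class_errors(self, sc_data):
        cond = sc_data["annotation"]["condition"].copy()
        cond.iloc[:3] = "tiny"
        cond.iloc[3:] = "big"
        with pytest.raises(DataError, match="tiny"):
            ss.oob_condition_error(sc_data["norm"], cond)


class TestTrainClassifier:
    def test_strong_data_high_auc(self, trained):
        assert min(trained["aucs"].values()) > 0.95

    def test_shuffled_labels_chance_auc(self, sc_data):
        aucs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            labels = sc_data["labels"]
            shuffled = pd.Series(rng.permutation(labels.to_numpy()),
                                 index=labels.index)
            _, a = ss.train_state_classifier(sc_data["norm"], shuffled,
                                             seed=seed, compute_mda=False,
                                             cv_folds=0)
            aucs.extend(a.values())
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_two_states_errors(self, sc_data):
        labels = sc_data["labels"]
        two = labels[labels != "amplification"]
        with pytest.raises(DataError):
            ss.train_state_classifier(sc_data["norm"], two)

    def test_small_state_errors(self, sc_data):
        labels = sc_data["labels"].copy()
        keep = labels.index[labels == "repression"][:3].tolist() + \
            labels.index[labels != "repression"].tolist()
        with pytest.raises(DataError, match="repression"):
            ss.train_state_classifier(sc_data["norm"][keep], labels.loc[keep])

    def test_mda_ranks_planted_signature_genes(self):
        """With no global-scale confound, the planted cluster genes are the
        only state signal and must rank in the top MDA decile."""
        flat = {"control_like": 1.0, "repression": 1.0, "amplification": 1.0}
        de = {cl: {"n": 8, "fold": 4.0} for cl in ("I", "II", "III")}
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = ss.SyntheticConfig.three_state(
                30, seed=seed, n_genes=600, state_scaling=flat, de_effects=de,
                dropout_rate=0.1)
            tpm, _, ann, truth = ss.simulate_single_cell_experiment(cfg)
            spk = ss.SpikeInSet(truth.spikein_ids)
            ev = ss.spikein_normalize_evalues(tpm, spk)
            E = ev.E.drop(index=truth.spikein_ids)
            ctrl = ann.index[ann.condition == "control"]
            norm = E.sub(E[ctrl].mean(axis=1), axis=0)
            model, _ = ss.train_state_classifier(
                norm, ss.reference_state_labels(ann), seed=seed, cv_folds=0)
            sig = truth.true_cluster.index[truth.true_cluster != "none"]
            ranks = model.mda.rank(pct=True)
            hits += (ranks[sig] > 0.9).mean() >= 0.8
        assert hits >= 0.8 * n_seeds


class _FakeForest:
    classes_ = np.array(["amplification", "control_like", "repression"])

    def predict_proba(self, X):
        return np.full((X.shape[0], 3), 1 / 3)


class TestClassifyCells:
    def test_p_triples_sum_to_one(self, trained, sc_data):
        probs = trained["states"][[f"p_{s}" for s in STATE_ORDER]]
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert ((probs >= 0) & (probs <= 1)).all().all()

    def test_decided_is_argmax(self, trained):
        states = trained["states"]
        probs = states[[f"p_{s}" for s in STATE_ORDER]]
        argmax = probs.to_numpy().argmax(axis=1)
        expected = [STATE_ORDER[i] for i in argmax]
        # idxmax picks the first max, so plain argmax agrees except on ties
        ties = (probs.to_numpy() == probs.to_numpy().max(axis=1, keepdims=True)).sum(axis=1) > 1
        agree = states["decided_state"].to_numpy() == np.array(expected)
        assert (agree | ties).all()

    def test_training_cell_duplicate_classified_consistently(self, trained, sc_data):
        labels = sc_data["labels"]
        ctrl_cell = [c for c in trained["model"].training_cells
                     if labels.get(c) == "control_like"][0]
        dup = sc_data["norm"][[ctrl_cell]].rename(columns={ctrl_cell: "dup"})
        out = ss.classify_cells(trained["model"], dup)
        assert out.loc["dup", "decided_state"] == "control_like"

    def test_tie_broken_by_fixed_order(self, trained):
        model = ss.StateModel(
            feature_genes=["g1", "g2"], forest=_FakeForest(),
            training_matrix=pd.DataFrame(), training_cells=[], test_cells=[],
            mda=None, ntree=1, cv_scores=None, seed=0)
        m = pd.DataFrame({"c": [0.0, 0.0]}, index=["g1", "g2"])
        out = ss.classify_cells(model, m)
        assert out.loc["c", "decided_state"] == "repression"

    def test_missing_features_error(self, trained, sc_data):
        with pytest.raises(DataError):
            ss.classify_cells(trained["model"], sc_data["norm"].iloc[5:])

    def test_matches_planted_states(self, trained, sc_data):
        truth = sc_data["truth"].true_state
        decided = trained["states"]["decided_state"]
        assert (decided == truth.loc[decided.index]).mean() > 0.95


class TestGates:
    def fake_pca(self, rows):
        scores = pd.DataFrame(rows, columns=["PC1", "PC2", "PC3"])
        scores.index = [f"c{i}" for i in range(len(rows))]
        return ss.PcaResult(scores=scores, variance_fraction=np.array([0.5, 0.3, 0.2]))

    def test_parse_gate(self):
        assert parse_gate(["PC1 > 15", "PC2 < -3.5"]) == \
            [("PC1", ">", 15.0), ("PC2", "<", -3.5)]
        with pytest.raises(DataError):
            parse_gate(["PC1 >= 15"])

    def test_example_cell_in_repression_pool(self):
        pca = self.fake_pca([(20.0, -5.0, 6.0)])
        pools = ss.pca_gate_training_selection(pca, n_per_group=1, seed=0,
                                               allow_small=True)
        assert pools["repression"] == ["c0"]
        assert pools["control_like"] == []

    def test_pc2_gate_control_like(self):
        pca = self.fake_pca([(0.0, 20.0, 0.0)])
        pools = ss.pca_gate_training_selection(pca, n_per_group=1, seed=0,
                                               allow_small=True)
        assert pools["control_like"] == ["c0"]

    def test_cell_in_no_gate_excluded(self):
        pca = self.fake_pca([(0.0, 0.0, 0.0)])
        pools = ss.pca_gate_training_selection(pca, n_per_group=1, seed=0,
                                               allow_small=True)
        assert all(len(v) == 0 for v in pools.values())

    def test_small_pool_errors_unless_allowed(self):
        pca = self.fake_pca([(20.0, -5.0, 6.0)])
        with pytest.raises(DataError, match="pool for state"):
            ss.pca_gate_training_selection(pca, n_per_group=2, seed=0)

    def test_sampling_without_replacement_and_deterministic(self):
        rows = [(20.0, -5.0, 6.0)] * 40
        pca = self.fake_pca(rows)
        a = ss.pca_gate_training_selection(pca, n_per_group=10, seed=3,
                                           allow_small=True)
        b = ss.pca_gate_training_selection(pca, n_per_group=10, seed=3,
                                           allow_small=True)
        assert a == b
        assert len(set(a["repression"])) == 10

    def test_unavailable_component_errors(self):
        pca = self.fake_pca([(1.0, 1.0, 1.0)])
        with pytest.raises(DataError):
            ss.pca_gate_training_selection(
                pca, gates={"repression": ["PC9 > 0"]}, n_per_group=1,
                allow_small=True)


class TestConsistency:
    def test_strong_data_consistent(self):
        """Well-separated states (small content jitter): gate-trained and
        label-trained classifiers agree on > 90% of cells."""
        cfg = ss.SyntheticConfig.three_state(50, seed=ACCEPT_SEED,
                                             content_jitter_cv=0.05)
        tpm, _, ann, truth = ss.simulate_single_cell_experiment(cfg)
        spk = ss.SpikeInSet(truth.spikein_ids)
        ev = ss.spikein_normalize_evalues(tpm, spk)
        _, norm = ss.select_differential_genes(ev.E, ann,
                                               exclude=spk.spikein_ids)
        labels = ss.reference_state_labels(ann)
        model, _ = ss.train_state_classifier(norm, labels, seed=ACCEPT_SEED,
                                             compute_mda=False, cv_folds=0)
        reference = ss.classify_cells(model, norm)["decided_state"]
        pca = ss.run_pca(norm)
        gates = derive_pc1_gates(pca, labels)
        median, (lo, hi) = ss.classification_consistency(
            norm, reference, gates, reps=60, seed=ACCEPT_SEED, pca=pca)
        assert median > 0.9
        assert lo <= median <= hi

    def test_random_reference_chance_level(self, sc_data):
        pca = ss.run_pca(sc_data["norm"])
        gates = derive_pc1_gates(pca, sc_data["labels"])
        rng = np.random.default_rng(1)
        random_ref = pd.Series(
            rng.choice(list(STATE_ORDER), size=sc_data["norm"].shape[1]),
            index=sc_data["norm"].columns)
        median, _ = ss.classification_consistency(
            sc_data["norm"], random_ref, gates, reps=10, seed=2, pca=pca)
        assert median == pytest.approx(1 / 3, abs=0.1)

    def test_impossible_gates_error(self, sc_data, trained):
        gates = {"repression": ["PC1 > 1e9"]}
        with pytest.raises(DataError):
            ss.classification_consistency(
                sc_data["norm"], trained["states"]["decided_state"], gates,
                reps=4, seed=0)
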