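import numpy as np
import pandas as pd
import pytest

from bcrpsvm.chem_io import NON_SUBSTRATE, SUBSTRATE
from bcrpsvm.experiment import (
    ExperimentError,
    RunRecord,
    SplitSpec,
    overlap_matrix,
    predict_compound,
    random_split,
    run_protocol,
    select_best_model,
)
from bcrpsvm.svm_engine import save_model
from bcrpsvm.synthetic import SyntheticSpec, make_descriptor_dataset, make_split_fixture

# small grids keep the multi-run tests quick without touching the defaults
FAST = dict(
    C_grid=(0.25, 4.0),
    gamma_grid=(0.03125, 0.5),
    grid_folds=3,
    max_candidates=10,
)


def small_dataset(delta=3.0, seed=0, n_noise=15):
    dm, labels, informative = make_descriptor_dataset(
        SyntheticSpec(n_pos=60, n_neg=40, n_informative=3, n_noise=n_noise,
                      delta=delta, seed=seed)
    )
    modelling, external = make_split_fixture(
        n_total=100, n_external=20, labels=labels, n_external_pos=12, seed=seed
    )
    return (
        dm.select_rows(modelling), labels.loc[modelling],
        dm.select_rows(external), labels.loc[external],
    )


class TestRandomSplit:
    def test_reported_set_sizes(self):
        ids = [f"c{i}" for i in range(223)]
        train, test = random_split(ids, SplitSpec(fraction=0.75, seed=0))
        assert (len(train), len(test)) == (167, 56)

    def test_same_seed_same_partition(self):
        ids = [f"c{i}" for i in range(50)]
        s = SplitSpec(fraction=0.7, seed=11)
        assert random_split(ids, s) == random_split(ids, s)

    def test_half_split(self):
        train, test = random_split([f"c{i}" for i in range(10)], SplitSpec(fraction=0.5, seed=1))
        assert len(train) == len(test) == 5
        assert set(train).isdisjoint(test)
        assert sorted(train + test) == sorted(f"c{i}" for i in range(10))

    def test_stratified_preserves_class_ratio(self):
        labels = pd.Series(
            [SUBSTRATE] * 60 + [NON_SUBSTRATE] * 40,
            index=[f"c{i}" for i in range(100)],
        )
        train, test = random_split(
            list(labels.index), SplitSpec(fraction=0.75, seed=2, stratified=True), labels
        )
        assert len(train) == 75
        n_pos = sum(labels[i] == SUBSTRATE for i in train)
        assert abs(n_pos - 45) <= 1

    def test_degenerate_fraction_errors(self):
        with pytest.raises(ExperimentError):
            random_split(["a", "b"], SplitSpec(fraction=0.2, seed=0))


class TestProtocol:
    def test_single_run_on_separable_data_trains_perfectly(self):
        args = small_dataset(delta=6.0, seed=1)
        res = run_protocol(*args, n_runs=1, base_seed=0, **FAST)
        assert res.records[0].reports["training"].acc == 100.0

    def test_same_base_seed_byte_identical_report(self):
        args = small_dataset(seed=2)
        r1 = run_protocol(*args, n_runs=2, base_seed=5, **FAST)
        r2 = run_protocol(*args, n_runs=2, base_seed=5, **FAST)
        assert r1.report_text() == r2.report_text()

    def test_informative_features_beat_pure_noise(self):
        signal = small_dataset(delta=3.0, seed=3)
        noise = small_dataset(delta=0.0, seed=3)
        rs = run_protocol(*signal, n_runs=4, base_seed=1, **FAST)
        rn = run_protocol(*noise, n_runs=4, base_seed=1, **FAST)
        assert rs.mean_reports()["test"]["acc"] > rn.mean_reports()["test"]["acc"]

    def test_overlapping_external_set_rejected(self):
        dm, labels, ext_dm, ext_labels = small_dataset()
        with pytest.raises(ExperimentError):
            run_protocol(dm, labels, dm, labels, n_runs=1, **FAST)

    def test_scrambled_external_labels_change_only_external_reports(self):
        dm, labels, ext_dm, ext_labels = small_dataset(seed=4)
        r1 = run_protocol(dm, labels, ext_dm, ext_labels, n_runs=2, base_seed=9, **FAST)
        scrambled = ext_labels.copy()
        scrambled[:] = ext_labels.iloc[::-1].to_numpy()
        r2 = run_protocol(dm, labels, ext_dm, scrambled, n_runs=2, base_seed=9, **FAST)
        for a, b in zip(r1.records, r2.records):
            assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
            assert a.selected_features == b.selected_features
            assert (a.grid.best_C, a.grid.best_gamma) == (b.grid.best_C, b.grid.best_gamma)
            assert a.reports["training"].counts == b.reports["training"].counts
            assert a.reports["test"].counts == b.reports["test"].counts
        assert any(
            a.reports["external"].counts != b.reports["external"].counts
            for a, b in zip(r1.records, r2.records)
        )

    def test_selected_model_recovers_planted_features(self):
        """With a few informative columns among noise, the gap-selected
        best model keeps most of the planted signal."""
        hits = 0
        for seed in range(6):
            dm, labels, informative = make_descriptor_dataset(
                SyntheticSpec(n_pos=90, n_neg=45, n_informative=5, n_noise=45,
                              delta=3.0, seed=50 + seed)
            )
            modelling, external = make_split_fixture(
                n_total=135, n_external=20, labels=labels, n_external_pos=12,
                seed=seed,
            )
            res = run_protocol(
                dm.select_rows(modelling), labels.loc[modelling],
                dm.select_rows(external), labels.loc[external],
                n_runs=2, base_seed=seed, **FAST,
            )
            best = select_best_model(res.records)[0]
            found = len(set(best.selected_features) & set(informative))
            if found >= 4:
                hits += 1
        assert hits >= 4


class TestSelectBestModel:
    def _fake_run(self, index, acc_train, acc_test, n_features):
        # minimal stand-in record: only the fields the ranking uses
        class _Rep:
            def __init__(self, acc):
                self.acc = acc

        r = RunRecord(
            index=index, seed=0, split=SplitSpec(), train_ids=[], test_ids=[],
            selected_features=[f"f{k}" for k in range(n_features)],
            grid=None, model=None,
            reports={"training": _Rep(acc_train), "test": _Rep(acc_test)},
            trace=None,
        )
        return r

    def test_rule_gap_then_feature_count(self):
        runs = [
            self._fake_run(0, 90.0, 81.0, 5),  # gap 9.0
            self._fake_run(1, 80.0, 78.5, 8),  # gap 1.5
            self._fake_run(2, 80.0, 78.5, 4),  # gap 1.5, fewer features
        ]
        assert select_best_model(runs)[0].index == 2

    def test_single_run_selects_itself(self):
        runs = [self._fake_run(0, 80.0, 75.0, 3)]
        assert select_best_model(runs)[0].index == 0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        runs = [
            self._fake_run(k, float(rng.integers(70, 95)),
                           float(rng.integers(60, 90)), int(rng.integers(1, 12)))
            for k in range(10)
        ]
        ranked = select_best_model(runs)
        def key(r):
            return (abs(r.reports["training"].acc - r.reports["test"].acc),
                    len(r.selected_features), r.index)
        best = min(runs, key=key)
        assert ranked[0].index == best.index
        assert [r.index for r in ranked] == [r.index for r in sorted(runs, key=key)]

    def test_permutation_invariant_winner(self):
        rng = np.random.default_rng(8)
        runs = [
            self._fake_run(k, 85.0, 80.0, int(rng.integers(2, 9))) for k in range(5)
        ]
        winner = select_best_model(runs)[0].index
        shuffled = [runs[i] for i in rng.permutation(5)]
        assert select_best_model(shuffled)[0].index == winner


class TestOverlap:
    def test_duplicated_model_full_overlap_and_diagonal(self):
        args = small_dataset(delta=5.0, seed=6)
        res = run_protocol(*args, n_runs=2, base_seed=2, **FAST)
        m = res.records[0].model
        om = overlap_matrix([m, m], args[0])
        assert np.allclose(om.matrix, 100.0)

    def test_models_on_separable_data_agree(self):
        args = small_dataset(delta=6.0, seed=7)
        res = run_protocol(*args, n_runs=3, base_seed=3, **FAST)
        om = overlap_matrix([r.model for r in res.records], args[0])
        assert np.allclose(np.diag(om.matrix), 100.0)
        assert np.allclose(om.matrix, om.matrix.T)
        assert om.summary()["min"] >= 95.0

    def test_fewer_than_two_models_errors(self):
        with pytest.raises(ExperimentError):
            overlap_matrix([], None)


class TestPredictCompound:
    def test_training_compound_round_trip(self, tmp_path, toys):
        from bcrpsvm.descriptors import compute_descriptor_matrix
        from bcrpsvm.preprocess import fit_scaling, apply_scaling
        from bcrpsvm.svm_engine import KernelSpec, SVMConfig, train
        from bcrpsvm.synthetic import toy_molecules

        cs = toy_molecules()
        dm = compute_descriptor_matrix(cs)
        scaling = fit_scaling(dm, dm.ids)
        scaled = apply_scaling(dm, scaling)
        labels = list(cs.labels)
        model = train(
            scaled.frame, labels,
            SVMConfig(C=10.0, kernel=KernelSpec("rbf", gamma=0.5)),
            scaling=scaling,
        )
        path = tmp_path / "toy_model.txt"
        save_model(model, path)
        in_train, _ = model.predict(scaled)
        for comp, expected in zip(cs, in_train):
            (row,) = predict_compound(path, comp.structure)
            assert row["label"] == expected
            assert set(row["descriptors"]) == set(model.feature_names)

    def test_2d_only_input_refused(self, tmp_path, toys):
        from bcrpsvm.descriptors import compute_descriptor_matrix
        from bcrpsvm.preprocess import fit_scaling, apply_scaling
        from bcrpsvm.svm_engine import KernelSpec, SVMConfig, train
        from bcrpsvm.synthetic import toy_molecules

        cs = toy_molecules()
        dm = compute_descriptor_matrix(cs)
        scaling = fit_scaling(dm, dm.ids)
        model = train(apply_scaling(dm, scaling).frame, list(cs.labels),
                      SVMConfig(), scaling=scaling)
        with pytest.raises(ExperimentError, match="2D-only"):
            predict_compound(model, "CCO")

    def test_malformed_smiles_errors(self, toys):
        from bcrpsvm.chem_io import ChemIOError
        from bcrpsvm.descriptors import compute_descriptor_matrix
        from bcrpsvm.preprocess import fit_scaling, apply_scaling
        from bcrpsvm.svm_engine import SVMConfig, train
        from bcrpsvm.synthetic import toy_molecules

        cs = toy_molecules()
        dm = compute_descriptor_matrix(cs)
        scaling = fit_scaling(dm, dm.ids)
        model = train(apply_scaling(dm, scaling).frame, list(cs.labels),
                      SVMConfig(), scaling=scaling)
        with pytest.raises(ChemIOError):
            predict_compound(model, "xx((bad")
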