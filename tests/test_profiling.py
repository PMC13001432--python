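"""Bioprofile construction, MI scoring, training-set sampling and gap filling."""

import math

import numpy as np
import pytest

from chemprofiler import profiling
from chemprofiler.profiling import (
    Bioprofile,
    GapFillTrainingSet,
    MIScore,
    TrainingSetRejected,
    binary_mutual_information,
    build_initial_bioprofile,
    compute_mi_scores,
    compute_overall_labels,
    export_heatmap,
    fill_gaps,
    sample_training_set,
    select_assays,
    train_gapfill_model,
)
from chemprofiler.synthetic import (
    InformativeAssay,
    WorldSpec,
    generate_bioassay_world,
    generate_chemical_library,
    matches_rule,
)


def brute_force_mi(x, y):
    """Independent plug-in MI oracle: explicit sum over the 2x2 joint table."""
    n = len(x)
    mi = 0.0
    for a in (0, 1):
        for b in (0, 1):
            nab = sum(1 for xi, yi in zip(x, y) if xi == a and yi == b)
            if nab == 0:
                continue
            pab = nab / n
            pa = sum(1 for xi in x if xi == a) / n
            pb = sum(1 for yi in y if yi == b) / n
            mi += pab * math.log(pab / (pa * pb))
    return mi


class TestBioprofileType:
    def test_rejects_bad_entries(self):
        with pytest.raises(ValueError):
            Bioprofile(["c1"], ["A"], np.array([[2]]))

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            Bioprofile(["c1", "c2"], ["A"], np.array([[1]]))


class TestBuildInitialBioprofile:
    def test_encoding_rule(self, small_db):
        profile, _ = build_initial_bioprofile(["C1", "C2"], small_db)
        col = profile.column("A1")
        assert list(col) == [1, -1]

    def test_assay_without_actives_dropped(self, small_db):
        # A3 has only inactive outcomes -> filtered out
        profile, _ = build_initial_bioprofile(["C1", "C2", "C4"], small_db)
        assert "A3" not in profile.assays
        assert set(profile.assays) == {"A1", "A2"}

    def test_untested_chemical_encoded_zero(self, small_db):
        profile, _ = build_initial_bioprofile(["C1", "C4"], small_db)
        # C4 was never tested in A1/A2
        row = profile.matrix[profile.chemicals.index("C4")]
        assert set(row) <= {0}

    def test_probe_encoded_active(self, small_db):
        profile, _ = build_initial_bioprofile(["C3"], small_db)
        assert profile.column("A2")[0] == 1

    def test_unresolved_reported_and_excluded(self, small_db):
        profile, unresolved = build_initial_bioprofile(["C1", "NOPE"], small_db)
        assert unresolved == ["NOPE"]
        assert profile.chemicals == ["C1"]

    def test_smiles_input_resolves_via_inchikey(self, small_db):
        p1, _ = build_initial_bioprofile(["C2"], small_db)
        p2, _ = build_initial_bioprofile(["c1ccccc1"], small_db)
        assert p1.chemicals == p2.chemicals == ["C2"]

    def test_nothing_resolvable_is_error(self, small_db):
        with pytest.raises(ValueError):
            build_initial_bioprofile(["NOPE"], small_db)

    def test_columns_all_have_an_active(self, small_db):
        profile, _ = build_initial_bioprofile(["C1", "C2", "C3", "C4"], small_db)
        assert (profile.matrix == 1).any(axis=0).all()


class TestOverallLabels:
    @pytest.mark.parametrize("row,label", [
        ([1, -1, 0], 1),
        ([-1, 0, 0], 0),
        ([0, 0, 0], 0),
    ])
    def test_active_in_at_least_one_assay(self, row, label):
        profile = Bioprofile(["c", "d"], ["A", "B", "C"],
                             np.array([row, [1, 1, 1]]))
        assert compute_overall_labels(profile)[0] == label


class TestMutualInformation:
    def test_identical_split_gives_ln2(self):
        profile = Bioprofile(["a", "b", "c", "d"], ["A"],
                             np.array([[1], [1], [-1], [-1]]))
        labels = np.array([1, 1, 0, 0])
        scores = compute_mi_scores(profile, labels)
        assert scores[0].mi == pytest.approx(math.log(2), abs=1e-12)

    def test_hand_derived_asymmetric_table(self):
        # joint table (0.25, 0, 0.25, 0.5) -> 0.2157 nats
        profile = Bioprofile(["a", "b", "c", "d"], ["A"],
                             np.array([[1], [-1], [-1], [-1]]))
        labels = np.array([1, 1, 0, 0])
        scores = compute_mi_scores(profile, labels)
        expected = brute_force_mi([1, 0, 0, 0], [1, 1, 0, 0])
        assert expected == pytest.approx(0.2157, abs=1e-4)
        assert scores[0].mi == pytest.approx(expected, abs=1e-12)

    def test_constant_column_zero(self):
        profile = Bioprofile(["a", "b", "c"], ["A"], np.array([[1], [1], [1]]))
        scores = compute_mi_scores(profile, np.array([1, 0, 1]))
        assert scores[0].mi == 0.0

    def test_minus_one_and_zero_binarize_identically(self):
        labels = np.array([1, 1, 0, 0])
        p1 = Bioprofile(list("abcd"), ["A"], np.array([[1], [1], [-1], [-1]]))
        p2 = Bioprofile(list("abcd"), ["A"], np.array([[1], [1], [0], [0]]))
        assert compute_mi_scores(p1, labels)[0].mi == compute_mi_scores(p2, labels)[0].mi

    def test_matches_brute_force_and_sklearn_on_random_profiles(self):
        from sklearn.metrics import mutual_info_score

        rng = np.random.default_rng(0)
        for _ in range(30):
            col = rng.choice([1, -1, 0], size=20)
            labels = rng.integers(0, 2, size=20)
            profile = Bioprofile([f"c{i}" for i in range(20)], ["A"], col[:, None])
            mi = compute_mi_scores(profile, labels)[0].mi
            x = (col == 1).astype(int)
            assert mi == pytest.approx(brute_force_mi(x, labels), abs=1e-9)
            assert mi == pytest.approx(mutual_info_score(x, labels), abs=1e-9)

    def test_mi_bounded_by_label_entropy(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=50)
        p = labels.mean()
        h = -(p * math.log(p) + (1 - p) * math.log(1 - p))
        for _ in range(20):
            col = rng.choice([1, -1, 0], size=50)
            profile = Bioprofile([f"c{i}" for i in range(50)], ["A"], col[:, None])
            assert compute_mi_scores(profile, labels)[0].mi <= h + 1e-12


class TestSelectAssays:
    def test_top_n(self):
        scores = [MIScore("A", 0.7), MIScore("B", 0.2), MIScore("C", 0.0)]
        assert select_assays(scores, 2) == ["A", "B"]

    def test_tie_broken_by_aid(self):
        assert select_assays([MIScore("B", 0.5), MIScore("A", 0.5)], 1) == ["A"]

    def test_n_exceeding_assay_count(self):
        scores = [MIScore("A", 0.1), MIScore("B", 0.2), MIScore("C", 0.3)]
        assert select_assays(scores, 10) == ["C", "B", "A"]


@pytest.fixture(scope="module")
def gapfill_world():
    spec = WorldSpec(
        n_chemicals=400, n_assays=2,
        informative_assays=[InformativeAssay("A_N", "nitro", 0.0)],
        background_active_rate=0.05, missing_rate=0.0, seed=5,
    )
    return generate_bioassay_world(spec)


class TestSampleTrainingSet:
    def test_capping(self, gapfill_world):
        db, _ = gapfill_world
        ts = sample_training_set("A_N", db, cap=50, min_per_class=30, seed=1)
        assert len(ts.actives) == 50 and len(ts.inactives) == 50

    def test_below_minimum_rejected(self, gapfill_world):
        db, _ = gapfill_world
        with pytest.raises(TrainingSetRejected):
            sample_training_set("A_N", db, cap=500, min_per_class=200, seed=1)

    def test_below_cap_all_used(self, gapfill_world):
        db, truth = gapfill_world
        n_active = int((truth.truth[:, 0] == 1).sum())
        ts = sample_training_set("A_N", db, cap=10_000, min_per_class=10, seed=1)
        assert len(ts.actives) == n_active

    def test_seed_reproducibility(self, gapfill_world):
        db, _ = gapfill_world
        a = sample_training_set("A_N", db, cap=60, min_per_class=10, seed=9)
        b = sample_training_set("A_N", db, cap=60, min_per_class=10, seed=9)
        c = sample_training_set("A_N", db, cap=60, min_per_class=10, seed=10)
        assert a.actives == b.actives and a.inactives == b.inactives
        assert a.actives != c.actives or a.inactives != c.inactives

    def test_unknown_assay(self, gapfill_world):
        db, _ = gapfill_world
        with pytest.raises(KeyError):
            sample_training_set("A_MISSING", db, seed=0)


class TestGapFillModel:
    def test_planted_rule_recovered(self):
        lib = generate_chemical_library(300, seed=21)
        actives = [s for s in lib if matches_rule(s, "nitro")][:100]
        inactives = [s for s in lib if not matches_rule(s, "nitro")][:100]
        ts = GapFillTrainingSet("A", actives, inactives, cap=500,
                                min_per_class=50, seed=2)
        model = train_gapfill_model(ts, n_trees=100)
        mean_auc = float(model.metrics[model.metrics["fold"] == "mean"]["roc_auc"].iloc[0])
        assert mean_auc >= 0.95

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(3)
        lib = generate_chemical_library(200, seed=22)
        shuffled = [lib[i] for i in rng.permutation(200)]
        ts = GapFillTrainingSet("A", shuffled[:100], shuffled[100:], cap=500,
                                min_per_class=50, seed=3)
        model = train_gapfill_model(ts, n_trees=100)
        mean_auc = float(model.metrics[model.metrics["fold"] == "mean"]["roc_auc"].iloc[0])
        assert 0.4 <= mean_auc <= 0.6

    def test_predict_classes_and_threshold(self):
        lib = generate_chemical_library(150, seed=23)
        actives = [s for s in lib if matches_rule(s, "nitro")][:50]
        inactives = [s for s in lib if not matches_rule(s, "nitro")][:50]
        ts = GapFillTrainingSet("A", actives, inactives, cap=500,
                                min_per_class=20, seed=4)
        model = train_gapfill_model(ts, n_trees=100, cv_metrics=False)
        classes, proba, kept = model.predict(actives[:5] + ["not-a-smiles"])
        assert len(kept) == 5
        assert ((proba >= 0.5) == (classes == 1)).all()
        assert set(classes) <= {1, -1}


class TestFillGaps:
    @pytest.fixture()
    def filled(self, gapfill_world):
        db, truth = gapfill_world
        spec = WorldSpec(
            n_chemicals=400, n_assays=2,
            informative_assays=[InformativeAssay("A_N", "nitro", 0.0)],
            background_active_rate=0.05, missing_rate=0.3, seed=5,
        )
        db_sparse, truth_sparse = generate_bioassay_world(spec)
        profile, _ = build_initial_bioprofile(truth_sparse.chemicals, db_sparse)
        ts = sample_training_set("A_N", db_sparse, seed=5, min_per_class=50)
        model = train_gapfill_model(ts, n_trees=100, cv_metrics=False)
        complete, mask = fill_gaps(profile, {"A_N": model}, ["A_N"],
                                   structures=truth_sparse.structures)
        return profile, complete, mask, truth_sparse

    def test_observed_entries_preserved(self, filled):
        profile, complete, mask, _ = filled
        j = profile.assays.index("A_N")
        observed = profile.matrix[:, j] != 0
        assert (complete.matrix[observed, 0] == profile.matrix[observed, j]).all()
        assert (mask[observed, 0] == "observed").all()

    def test_no_zeros_remain(self, filled):
        _, complete, mask, _ = filled
        predictable = mask[:, 0] != "unpredictable"
        assert (complete.matrix[predictable, 0] != 0).all()

    def test_imputation_matches_truth_on_noise_free_rule(self, filled):
        profile, complete, mask, truth = filled
        jt = truth.assays.index("A_N")
        imputed = mask[:, 0] == "imputed"
        ti = {c: i for i, c in enumerate(truth.chemicals)}
        agree = [
            complete.matrix[i, 0] == truth.truth[ti[c], jt]
            for i, c in enumerate(complete.chemicals) if imputed[i]
        ]
        assert np.mean(agree) >= 0.9

    def test_missing_model_is_error(self, filled):
        profile, *_ = filled
        with pytest.raises(ValueError, match="no model"):
            fill_gaps(profile, {}, ["A_N"], structures={})


class TestHeatmapExport:
    def test_files_written_and_order_complete(self, tmp_path):
        profile = Bioprofile(["c1", "c2", "c3"], ["A", "B", "C"],
                             np.array([[1, -1, 0], [1, -1, 0], [-1, 1, 1]]))
        png, order = export_heatmap(profile, tmp_path / "heat.png")
        assert png.exists() and order.exists()
        lines = order.read_text().splitlines()
        assert lines.count("# rows") == 1 and lines.count("# columns") == 1
        assert {"c1", "c2", "c3"} <= set(lines)

    def test_identical_rows_adjacent(self, tmp_path):
        profile = Bioprofile(["dup1", "far", "dup2"], ["A", "B"],
                             np.array([[1, -1], [-1, 1], [1, -1]]))
        _, order = export_heatmap(profile, tmp_path / "heat.png")
        lines = order.read_text().splitlines()
        rows = lines[1:lines.index("# columns")]
        assert abs(rows.index("dup1") - rows.index("dup2")) == 1

    def test_degenerate_single_cell(self, tmp_path):
        profile = Bioprofile(["c1"], ["A"], np.array([[1]]))
        png, order = export_heatmap(profile, tmp_path / "one.png")
        assert png.exists() and order.exists()
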