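"""Architecture-model identification: knowledge base, centres, assignment,
growth-habit retrieval and Gaussian divergence summaries."""

import numpy as np
import pandas as pd
import pytest

from crownarch import (
    assign_ham,
    gaussian_summary,
    habits_for,
    load_knowledge,
    species_center,
)


@pytest.fixture(scope="module")
def knowledge():
    return load_knowledge()


def test_knowledge_base_complete_and_distinct(knowledge):
    assert set(knowledge.names) == {"Massart", "Rauh", "Roux", "Attim"}
    centres = knowledge.centers()
    assert len({tuple(c) for c in centres.tolist()}) == 4
    assert knowledge.feature_pair == ("P4", "P7")
    # both species->model readings are on record, unreconciled
    assert knowledge.species_links["narrative"]["PA"] == "Massart"
    assert knowledge.species_links["habit_table"]["PA"] == "Attim"


class TestSpeciesCenter:
    def _table(self):
        return pd.DataFrame(
            {
                "tree_id": ["a", "b", "c"],
                "species": ["X", "X", "Y"],
                "P4": [0.1, 0.3, 0.9],
                "P7": [0.2, 0.4, 0.8],
            }
        )

    def test_mean_of_two_trees(self):
        assert species_center(self._table(), "X", ("P4", "P7")) == (
            pytest.approx(0.2),
            pytest.approx(0.3),
        )

    def test_single_tree_center_is_itself(self):
        assert species_center(self._table(), "Y", ("P4", "P7")) == (0.9, 0.8)

    def test_matches_brute_force_mean_with_predictions(self, rng):
        n = 50
        table = pd.DataFrame(
            {
                "tree_id": [f"t{i}" for i in range(n)],
                "species": rng.choice(["X", "Y"], n),
                "P4": rng.uniform(0, 1, n),
                "P7": rng.uniform(0, 1, n),
            }
        )
        preds = pd.Series(rng.choice(["X", "Y"], n), index=table["tree_id"])
        c = species_center(table, "X", ("P4", "P7"), predictions=preds)
        mask = (preds.to_numpy() == "X")
        assert c[0] == pytest.approx(table["P4"].to_numpy()[mask].mean())
        assert c[1] == pytest.approx(table["P7"].to_numpy()[mask].mean())

    def test_correct_only_scope(self):
        table = self._table()
        preds = pd.Series(["X", "Y", "Y"], index=table["tree_id"])
        c = species_center(table, "Y", ("P4", "P7"), scope="correct_only",
                           predictions=preds)
        assert c == (0.9, 0.8)  # tree 'b' predicted Y but truly X: excluded

    def test_empty_scope_raises(self):
        with pytest.raises(ValueError, match="no trees"):
            species_center(self._table(), "Z", ("P4", "P7"))


class TestAssign:
    def test_exact_prototype_hit(self, knowledge):
        m = knowledge.models["Massart"]
        a = assign_ham(m.center, knowledge, species="PA")
        assert a.assigned == "Massart"
        assert a.margin > 0

    def test_quadrant_rule_constructed_mapping(self, knowledge):
        qmap = {("high", "low"): "Rauh", ("low", "low"): "Massart",
                ("low", "high"): "Roux", ("high", "high"): "Attim"}
        a = assign_ham((0.9, 0.1), knowledge, rule="quadrant",
                       thresholds=(0.5, 0.5), quadrant_map=qmap)
        assert a.assigned == "Rauh"

    def test_quadrant_tie_breaks_to_lower_with_warning(self, knowledge):
        with pytest.warns(UserWarning, match="lower"):
            a = assign_ham((0.5, 0.1), knowledge, rule="quadrant",
                           thresholds=(0.5, 0.5))
        assert a.assigned == knowledge.quadrant_map[("low", "low")]

    def test_nearest_center_invariant_to_affine_axis_rescaling(self, knowledge):
        rng = np.random.default_rng(6)
        for _ in range(25):
            centre = tuple(rng.uniform(0.0, 0.3, 2))
            base = assign_ham(centre, knowledge).assigned
            # rescale both axes affinely: knowledge centres and the query
            a1, b1, a2, b2 = 3.0, -1.0, 0.25, 2.0
            import copy
            import dataclasses

            scaled_models = {}
            for name, m in knowledge.models.items():
                c = (a1 * m.center[0] + b1, a2 * m.center[1] + b2)
                scaled_models[name] = dataclasses.replace(m, center=c)
            scaled_kn = dataclasses.replace(knowledge, models=scaled_models)
            q = (a1 * centre[0] + b1, a2 * centre[1] + b2)
            assert assign_ham(q, scaled_kn).assigned == base

    def test_cluster_recovery_on_generated_data(self, knowledge):
        rng = np.random.default_rng(6)
        for name, model in knowledge.models.items():
            pts = rng.normal(model.center, [0.01, 0.005], size=(30, 2))
            centre = tuple(pts.mean(axis=0))
            assert assign_ham(centre, knowledge).assigned == name

    def test_unknown_rule(self, knowledge):
        with pytest.raises(ValueError, match="rule"):
            assign_ham((0.1, 0.1), knowledge, rule="nope")


class TestHabits:
    def test_roux_texts(self, knowledge):
        h = habits_for("Roux", knowledge)
        assert h["branches"] == "plagiotropic, monopodial, non-phyllomorphic"
        assert h["growth"] == "continuous"

    def test_attim_growth(self, knowledge):
        assert habits_for("Attim", knowledge)["growth"] == "more or less continuous"

    def test_unknown_model_lists_valid_names(self, knowledge):
        with pytest.raises(ValueError, match="Massart"):
            habits_for("Foo", knowledge)


class TestGaussianSummary:
    def _table(self, rng, n=40):
        species = rng.choice(["PA", "PS"], n)
        return pd.DataFrame(
            {
                "tree_id": [f"t{i}" for i in range(n)],
                "species": species,
                "P4": rng.normal(np.where(species == "PA", 0.1, 0.2), 0.02),
                "P7": rng.normal(np.where(species == "PA", 0.03, 0.08), 0.01),
            }
        )

    def test_perfect_predictions_zero_divergence(self, rng):
        table = self._table(rng)
        preds = pd.Series(table["species"].to_numpy(), index=table["tree_id"])
        summary = gaussian_summary(table, preds, ["P4", "P7"])
        assert (summary["delta_mu_pct"] == 0).all()
        assert (summary["delta_sigma_pct"] == 0).all()

    def test_hand_built_mislabel(self):
        table = pd.DataFrame(
            {
                "tree_id": list("abcdef"),
                "species": ["X", "X", "X", "Y", "Y", "Y"],
                "v": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
            }
        )
        preds = pd.Series(["X", "X", "Y", "Y", "Y", "Y"], index=table["tree_id"])
        s = gaussian_summary(table, preds, ["v"])
        # X group DP = {1, 2}: mu 1.5, sigma 0.5 (population)
        row = s.loc[("X", "v")]
        assert row["mu_dp"] == pytest.approx(1.5)
        assert row["sigma_dp"] == pytest.approx(0.5)
        assert row["mu_gt"] == pytest.approx(2.0)
        assert row["delta_mu_pct"] == pytest.approx((2.0 - 1.5) / 2.0 * 100)
        # Y group DP = {3, 10, 11, 12}
        rowy = s.loc[("Y", "v")]
        assert rowy["mu_dp"] == pytest.approx(9.0)
        assert rowy["mu_gt"] == pytest.approx(11.0)

    def test_mislabelled_stand_matches_direct_recomputation(self, rng):
        table = self._table(rng, n=40)
        labels = table["species"].to_numpy().copy()
        flip = rng.choice(len(labels), size=6, replace=False)
        labels[flip] = np.where(labels[flip] == "PA", "PS", "PA")
        preds = pd.Series(labels, index=table["tree_id"])
        s = gaussian_summary(table, preds, ["P4", "P7"])
        for sp in ("PA", "PS"):
            for par in ("P4", "P7"):
                vals = table[par].to_numpy()
                mu_dp = vals[labels == sp].mean()
                mu_gt = vals[table["species"].to_numpy() == sp].mean()
                expect = (mu_gt - mu_dp) / mu_gt * 100
                assert s.loc[(sp, par), "delta_mu_pct"] == pytest.approx(expect)

    def test_missing_predictions_raise(self, rng):
        table = self._table(rng, n=10)
        preds = pd.Series(["PA"] * 9, index=table["tree_id"][:-1])
        with pytest.raises(ValueError, match="missing"):
            gaussian_summary(table, preds, ["P4"])

    def test_tiny_group_sigma_zero_with_warning(self):
        table = pd.DataFrame(
            {"tree_id": list("abc"), "species": ["X", "X", "Y"], "v": [1.0, 2.0, 5.0]}
        )
        preds = pd.Series(["X", "X", "Y"], index=table["tree_id"])
        with pytest.warns(UserWarning, match="<2"):
            s = gaussian_summary(table, preds, ["v"])
        assert s.loc[("Y", "v"), "sigma_dp"] == 0.0
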