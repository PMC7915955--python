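"""Blinded scenario construction and subjective-rate scoring."""

import json

import numpy as np
import pandas as pd
import pytest

from adaptseg.turing import (audit_blinding, build_scenarios,
                             score_discrimination, score_preference, score_qa,
                             write_scenarios)

METHODS = ["manual", "dlsm", "dlsu", "dir"]
STRUCTURES = [f"oar{i}" for i in range(9)]
PAIRS = [("manual", "dlsm"), ("dlsm", "dlsu"), ("dlsu", "dir")]


def make_sources(methods=METHODS, structures=STRUCTURES):
    return {m: {s: f"{m}/{s}.nii.gz" for s in structures} for m in methods}


@pytest.fixture(scope="module")
def standard_setup():
    scenarios, truth = build_scenarios(make_sources(), STRUCTURES, n_per_cell=2,
                                       seed=13, pairs=PAIRS)
    return scenarios, truth


class TestBuildScenarios:
    def test_default_configuration_totals_198_scenarios(self, standard_setup):
        scenarios, truth = standard_setup
        # 4 methods x 9 structures x 2 (discrimination) + 3 pairs x 9 x 2
        # (preference) + 4 x 9 x 2 (qa) = 72 + 54 + 72
        assert len(scenarios) == 198
        counts = pd.Series([s["question_type"] for s in scenarios]).value_counts()
        assert counts["discrimination"] == 72
        assert counts["preference"] == 54
        assert counts["qa"] == 72

    def test_seeded_reproducibility(self):
        a = build_scenarios(make_sources(), STRUCTURES, 2, seed=13, pairs=PAIRS)
        b = build_scenarios(make_sources(), STRUCTURES, 2, seed=13, pairs=PAIRS)
        assert a[0] == b[0] and a[1] == b[1]
        c = build_scenarios(make_sources(), STRUCTURES, 2, seed=14, pairs=PAIRS)
        assert a[0] != c[0]

    def test_presentation_file_is_blinded(self, standard_setup, tmp_path):
        scenarios, truth = standard_setup
        audit_blinding(scenarios, METHODS)
        write_scenarios(scenarios, truth, tmp_path / "p.json", tmp_path / "t.json")
        payload = (tmp_path / "p.json").read_text().lower()
        for m in METHODS:
            assert m not in payload
        truth_payload = json.loads((tmp_path / "t.json").read_text())
        assert all("methods" in v for v in truth_payload["scenarios"].values())

    def test_balanced_counts_per_cell(self, standard_setup):
        _, truth = standard_setup
        cells = pd.Series([
            (v["question_type"], v["structure"], tuple(sorted(v["methods"])))
            for v in truth["scenarios"].values()
        ]).value_counts()
        assert set(cells) == {2}

    def test_structure_missing_from_method_rejected(self):
        sources = make_sources()
        del sources["dir"]["oar3"]
        with pytest.raises(ValueError, match="oar3"):
            build_scenarios(sources, STRUCTURES, 1, seed=0)


def respond(truth, qtype, answer_fn, observers=("o1",)):
    rows = []
    for sid, info in truth["scenarios"].items():
        if info["question_type"] != qtype:
            continue
        for obs in observers:
            rows.append({"observer_id": obs, "scenario_id": sid,
                         "answer": answer_fn(info)})
    return pd.DataFrame(rows)


class TestScoreDiscrimination:
    def test_everything_judged_human_gives_100_percent(self, standard_setup):
        _, truth = standard_setup
        responses = respond(truth, "discrimination", lambda info: "human")
        rates = score_discrimination(responses, truth)
        assert (rates.rate_pct == 100.0).all()

    def test_known_proportion(self):
        sources = make_sources(["manual", "dlsm"], ["oar0"])
        _, truth = build_scenarios(sources, ["oar0"], n_per_cell=25, seed=0,
                                   pairs=[("manual", "dlsm")])
        responses = respond(truth, "discrimination", lambda info: "human",
                            observers=["o1", "o2"])
        # overwrite: first 27 of dlsm's 50 presentations judged human
        dlsm_rows = [i for i, r in responses.iterrows()
                     if truth["scenarios"][r.scenario_id]["methods"][0] == "dlsm"]
        responses.loc[dlsm_rows[27:], "answer"] = "computer"
        rates = score_discrimination(responses, truth)
        row = rates[(rates.method == "dlsm") & (rates.structure == "")].iloc[0]
        assert row.n_presented == 50
        assert row.rate_pct == pytest.approx(54.0)
        assert row.ci95_low_pct < 54.0 < row.ci95_high_pct

    def test_rates_invariant_to_observer_order(self, standard_setup):
        _, truth = standard_setup
        rng = np.random.default_rng(2)
        responses = respond(truth, "discrimination",
                            lambda info: rng.choice(["human", "computer"]),
                            observers=["o1", "o2", "o3"])
        shuffled = responses.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = score_discrimination(responses, truth).sort_values(
            ["method", "structure"]).reset_index(drop=True)
        b = score_discrimination(shuffled, truth).sort_values(
            ["method", "structure"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_answers_rejected(self, standard_setup):
        _, truth = standard_setup
        responses = respond(truth, "discrimination", lambda info: "robot")
        with pytest.raises(ValueError, match="invalid"):
            score_discrimination(responses, truth)

    def test_unknown_scenario_rejected(self, standard_setup):
        _, truth = standard_setup
        bad = pd.DataFrame([{"observer_id": "o", "scenario_id": "S9999",
                             "answer": "human"}])
        with pytest.raises(ValueError, match="unknown"):
            score_discrimination(bad, truth)

    def test_duplicate_response_rejected(self, standard_setup):
        _, truth = standard_setup
        responses = respond(truth, "discrimination", lambda info: "human")
        dup = pd.concat([responses, responses.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            score_discrimination(dup, truth)


class TestScorePreference:
    def test_pair_rates_sum_to_100(self, standard_setup):
        _, truth = standard_setup
        rng = np.random.default_rng(3)
        responses = respond(truth, "preference",
                            lambda info: rng.choice(["first", "second"]))
        rates = score_preference(responses, truth)
        assert np.allclose(rates.rate_a_pct + rates.rate_b_pct, 100.0)

    def test_known_win_ratio(self):
        sources = make_sources(["dlsm", "dlsu"], ["oar0"])
        _, truth = build_scenarios(sources, ["oar0"], n_per_cell=30, seed=5,
                                   pairs=[("dlsm", "dlsu")])
        responses = respond(
            truth, "preference",
            lambda info: "first" if info["methods"][0] == "dlsm" else "second",
            observers=["o1", "o2"])
        # flip 20 of the 60 dlsm wins to dlsu
        flip = responses.index[:20]
        responses.loc[flip, "answer"] = responses.loc[flip].apply(
            lambda r: "second"
            if truth["scenarios"][r.scenario_id]["methods"][0] == "dlsm"
            else "first", axis=1)
        rates = score_preference(responses, truth)
        row = rates[(rates.structure == "")].iloc[0]
        assert row.method_a == "dlsm"
        assert row.wins_a + row.wins_b == 60
        assert row.rate_a_pct == pytest.approx(100 * row.wins_a / 60)

    def test_always_prefer_first_converges_to_even_split(self):
        """Presentation order is randomized, so a position-biased observer
        produces ~50/50 method rates."""
        sources = make_sources(["dlsm", "dlsu"], ["oar0"])
        _, truth = build_scenarios(sources, ["oar0"], n_per_cell=200, seed=8,
                                   pairs=[("dlsm", "dlsu")])
        responses = respond(truth, "preference", lambda info: "first")
        rates = score_preference(responses, truth)
        row = rates[rates.structure == ""].iloc[0]
        assert 40.0 < row.rate_a_pct < 60.0


class TestScoreQa:
    def test_all_no_revision(self, standard_setup):
        _, truth = standard_setup
        responses = respond(truth, "qa", lambda info: "no-revision")
        rates = score_qa(responses, truth)
        overall = rates[rates.structure == ""]
        assert (overall.no_revision_pct == 100.0).all()
        assert (overall.major_revision_pct == 0.0).all()

    def test_known_split_and_normalization(self):
        sources = make_sources(["dlsm"], ["oar0"])

        _, truth = build_scenarios({**sources, "dlsu": sources["dlsm"]},
                                   ["oar0"], n_per_cell=50, seed=2)
        answers = (["no-revision"] * 35 + ["minor-revision"] * 11
                   + ["major-revision"] * 4)
        it = iter(answers)

        def answer(info):
            return next(it) if info["methods"][0] == "dlsm" else "no-revision"

        responses = respond(truth, "qa", answer)
        rates = score_qa(responses, truth)
        row = rates[(rates.method == "dlsm") & (rates.structure == "")].iloc[0]
        assert row.n_responses == 50
        triple = (row.no_revision_pct, row.minor_revision_pct, row.major_revision_pct)
        assert triple == (pytest.approx(70.0), pytest.approx(22.0), pytest.approx(8.0))
        assert sum(triple) == pytest.approx(100.0)
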