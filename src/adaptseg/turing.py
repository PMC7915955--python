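"""Blinded subjective evaluation (segmentation Turing test).

Three question types are supported: *discrimination* (was this single
contour drawn by a human or a computer?), *preference* (which of two
contours is better?), and *qa* (would this contour need no, minor, or
major revision? — a major error meaning a subjective difference of more
than 10% of the contour).  The module builds blinded, order-randomized
scenario files plus a separate truth key, and scores observer response
tables into discrimination, preference and quality-assurance rates.

Rendering and observer recruitment are out of scope: scenarios carry
opaque item references; any viewer can present them.
"""

from __future__ import annotations

import json
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

QUESTION_TYPES = ("discrimination", "preference", "qa")
DISCRIMINATION_ANSWERS = ("human", "computer")
PREFERENCE_ANSWERS = ("first", "second")
QA_ANSWERS = ("no-revision", "minor-revision", "major-revision")


def build_scenarios(sources: Mapping[str, Mapping[str, str]],
                    structures: Sequence[str], n_per_cell: int, seed: int,
                    pairs: Optional[Sequence[Tuple[str, str]]] = None,
                    human_methods: Sequence[str] = ("manual",)):
    """Balanced blinded scenario assignment.

    Parameters
    ----------
    sources : mapping
        method -> structure -> opaque contour reference (e.g. a mask path).
    structures : sequence
        Structures to present; must exist for every method.
    n_per_cell : int
        Scenarios per (question type x structure x method or method-pair).
    pairs : sequence of (method, method), optional
        Head-to-head pairs for preference questions; defaults to
        consecutive pairs in the order methods appear in ``sources``.
    human_methods : sequence
        Methods whose contours are human-drawn (ground truth for
        discrimination scoring).

    Returns ``(scenarios, truth_key)``.  The scenario list is blinded: it
    carries only scenario ids, question types, structures and opaque item
    ids, never method names.  The truth key maps scenario id to the
    presented methods in presentation order.  Deterministic given ``seed``.
    """
    methods = list(sources)
    if len(methods) < 2:
        raise ValueError("need at least two methods")
    for m in methods:
        for s in structures:
            if s not in sources[m]:
                raise ValueError(f"structure {s!r} missing from method {m!r}")
    if pairs is None:
        pairs = list(zip(methods[:-1], methods[1:]))
    for a, b in pairs:
        if a == b or a not in methods or b not in methods:
            raise ValueError(f"invalid preference pair ({a}, {b})")

    rng = np.random.default_rng(seed)
    scenarios: List[dict] = []
    truth: Dict[str, dict] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"S{counter:04d}"

    for qtype in ("discrimination", "qa"):
        for struct in structures:
            for method in methods:
                for _ in range(n_per_cell):
                    sid = new_id()
                    scenarios.append({"scenario_id": sid, "question_type": qtype,
                                      "structure": struct,
                                      "item_ids": [f"{sid}-item1"]})
                    truth[sid] = {"question_type": qtype, "structure": struct,
                                  "methods": [method],
                                  "refs": [sources[method][struct]],
                                  "is_human": [method in human_methods]}
    for struct in structures:
        for a, b in pairs:
            for _ in range(n_per_cell):
                sid = new_id()
                order = [a, b] if rng.random() < 0.5 else [b, a]
                scenarios.append({"scenario_id": sid, "question_type": "preference",
                                  "structure": struct,
                                  "item_ids": [f"{sid}-item1", f"{sid}-item2"]})
                truth[sid] = {"question_type": "preference", "structure": struct,
                              "methods": order,
                              "refs": [sources[m][struct] for m in order],
                              "is_human": [m in human_methods for m in order]}
    rng.shuffle(scenarios)
    truth_key = {"pairs": [list(p) for p in pairs], "scenarios": truth}
    return scenarios, truth_key


def write_scenarios(scenarios, truth_key, scenario_path, truth_path) -> None:
    """Write the blinded presentation file and the truth key separately."""
    with open(scenario_path, "w") as fh:
        json.dump(scenarios, fh, indent=2)
    with open(truth_path, "w") as fh:
        json.dump(truth_key, fh, indent=2)


def _check_responses(responses: pd.DataFrame, truth_key: Mapping, qtype: str,
                     answers: Tuple[str, ...]) -> pd.DataFrame:
    required = {"observer_id", "scenario_id", "answer"}
    if required - set(responses.columns):
        raise ValueError(f"response table needs columns {sorted(required)}")
    truth = truth_key["scenarios"]
    unknown = set(responses["scenario_id"]) - set(truth)
    if unknown:
        raise ValueError(f"responses reference unknown scenarios: {sorted(unknown)[:5]}")
    sel = responses[responses["scenario_id"].map(
        lambda s: truth[s]["question_type"] == qtype)].copy()
    bad = set(sel["answer"]) - set(answers)
    if bad:
        raise ValueError(f"invalid {qtype} answers {sorted(bad)}; allowed {answers}")
    dup = sel.duplicated(subset=["observer_id", "scenario_id"])
    if dup.any():
        raise ValueError("duplicate (observer, scenario) responses")
    return sel


def score_discrimination(responses: pd.DataFrame, truth_key: Mapping) -> pd.DataFrame:
    """Per-method (and per-structure) fraction of contours judged 'human'.

    Rates are percentages with Wilson 95% binomial intervals.
    """
    sel = _check_responses(responses, truth_key, "discrimination", DISCRIMINATION_ANSWERS)
    truth = truth_key["scenarios"]
    sel["method"] = sel["scenario_id"].map(lambda s: truth[s]["methods"][0])
    sel["structure"] = sel["scenario_id"].map(lambda s: truth[s]["structure"])
    sel["judged_human"] = sel["answer"] == "human"

    rows = []
    for keys, grp in list(sel.groupby("method")) + list(sel.groupby(["method", "structure"])):
        method, structure = (keys, "") if isinstance(keys, str) else keys
        n, k = len(grp), int(grp["judged_human"].sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append({"method": method, "structure": structure, "n_presented": n,
                     "n_judged_human": k, "rate_pct": 100.0 * k / n,
                     "ci95_low_pct": 100.0 * lo, "ci95_high_pct": 100.0 * hi})
    return pd.DataFrame(rows)


def score_preference(responses: pd.DataFrame, truth_key: Mapping) -> pd.DataFrame:
    """Head-to-head win rates per method pair; each pair's two rates sum
    to 100%."""
    sel = _check_responses(responses, truth_key, "preference", PREFERENCE_ANSWERS)
    truth = truth_key["scenarios"]
    sel["winner"] = [
        truth[s]["methods"][0 if a == "first" else 1]
        for s, a in zip(sel["scenario_id"], sel["answer"])
    ]
    sel["structure"] = sel["scenario_id"].map(lambda s: truth[s]["structure"])
    sel["pair"] = sel["scenario_id"].map(lambda s: tuple(sorted(truth[s]["methods"])))

    canonical = {tuple(sorted(p)): tuple(p) for p in truth_key.get("pairs", [])}
    rows = []
    for keys, grp in list(sel.groupby("pair")) + list(sel.groupby(["pair", "structure"])):
        pair, structure = (keys, "") if isinstance(keys[0], str) else keys
        a, b = canonical.get(tuple(pair), tuple(pair))
        n = len(grp)
        wins_a = int((grp["winner"] == a).sum())
        rows.append({"method_a": a, "method_b": b, "structure": structure,
                     "n_presentations": n, "wins_a": wins_a, "wins_b": n - wins_a,
                     "rate_a_pct": 100.0 * wins_a / n,
                     "rate_b_pct": 100.0 * (n - wins_a) / n})
    return pd.DataFrame(rows)


def score_qa(responses: pd.DataFrame, truth_key: Mapping) -> pd.DataFrame:
    """No-/minor-/major-revision rates per method (summing to 100%), with a
    per-structure breakdown."""
    sel = _check_responses(responses, truth_key, "qa", QA_ANSWERS)
    truth = truth_key["scenarios"]
    sel["method"] = sel["scenario_id"].map(lambda s: truth[s]["methods"][0])
    sel["structure"] = sel["scenario_id"].map(lambda s: truth[s]["structure"])

    rows = []
    for keys, grp in list(sel.groupby("method")) + list(sel.groupby(["method", "structure"])):
        method, structure = (keys, "") if isinstance(keys, str) else keys
        n = len(grp)
        row = {"method": method, "structure": structure, "n_responses": n}
        for answer, label in zip(QA_ANSWERS, ("no_revision", "minor_revision", "major_revision")):
            row[f"{label}_pct"] = 100.0 * (grp["answer"] == answer).sum() / n
        rows.append(row)
    return pd.DataFrame(rows)


def audit_blinding(scenarios, methods: Sequence[str]) -> None:
    """Raise if any method identifier appears in the presentation payload."""
    payload = json.dumps(scenarios).lower()
    leaked = [m for m in methods if m.lower() in payload]
    if leaked:
        raise AssertionError(f"presentation file leaks method names: {leaked}")
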