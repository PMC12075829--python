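"""Multi-criteria screening: filters, normalization, Pareto front, ranking."""

import numpy as np
import pandas as pd
import pytest

from cdftscreen import Criterion, default_config, pareto_front, screen
from cdftscreen.screening import HardFilter, apply_hard_filters, normalize_scores


def _criteria(*specs):
    return [Criterion(name=n, direction=d, weight=1.0) for n, d in specs]


def test_pgp_hard_filter_keeps_non_substrates(candidates):
    kept, excluded = apply_hard_filters(
        candidates, [HardFilter(name="pgp", field="pgp_substrate", equals=False)]
    )
    assert sorted(kept.index) == ["01", "02", "04"]
    assert sorted(pose for pose, _ in excluded) == ["03", "05", "06"]
    assert all(name == "pgp" for _, name in excluded)


def test_no_filters_keep_everything(candidates):
    kept, excluded = apply_hard_filters(candidates, [])
    assert len(kept) == 6 and excluded == []


def test_unsatisfiable_filter_excludes_everything(candidates):
    kept, excluded = apply_hard_filters(
        candidates, [HardFilter(name="impossible", field="pgp_substrate", equals="x")]
    )
    assert kept.empty and len(excluded) == 6


def test_missing_filter_field_is_a_configuration_error(candidates):
    with pytest.raises(KeyError, match="no_such_field"):
        apply_hard_filters(
            candidates, [HardFilter(name="bad", field="no_such_field", equals=1)]
        )


def test_normalize_two_candidates_span_unit_interval():
    frame = pd.DataFrame({"x": [1.0, 3.0]}, index=["a", "b"])
    scores = normalize_scores(frame, _criteria(("x", "higher_better")))
    assert scores["x"].tolist() == [0.0, 1.0]
    reversed_scores = normalize_scores(frame, _criteria(("x", "lower_better")))
    assert reversed_scores["x"].tolist() == [1.0, 0.0]


def test_constant_column_normalizes_to_half():
    frame = pd.DataFrame({"x": [2.0, 2.0, 2.0]}, index=list("abc"))
    scores = normalize_scores(frame, _criteria(("x", "higher_better")))
    assert (scores["x"] == 0.5).all()


def test_kept_set_gap_normalization(candidates):
    """Over the kept poses, the largest gap scores exactly 1."""
    kept = candidates.loc[["01", "02", "04"]]
    scores = normalize_scores(kept, _criteria(("gap", "higher_better")))
    assert scores.loc["02", "gap"] == pytest.approx(1.0)
    assert scores.loc["04", "gap"] == pytest.approx(0.0)


def test_pareto_front_edge_cases():
    criteria = _criteria(("x", "higher_better"), ("y", "lower_better"))
    single = pd.DataFrame({"x": [1.0], "y": [1.0]}, index=["only"])
    assert pareto_front(single, criteria) == ["only"]
    pair = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]}, index=["worse", "better"])
    assert pareto_front(pair, criteria) == ["better"]


def test_reference_front_contains_both_winners(bundle, candidates):
    kept = candidates.loc[["01", "02", "04"]]
    front = pareto_front(kept, default_config().criteria)
    assert {"02", "04"} <= set(front)


@pytest.mark.parametrize("seed", range(5))
def test_pareto_front_equals_brute_force_oracle(seed):
    """Dominance soundness against an independent O(n^2) enumeration."""
    rng = np.random.default_rng(seed)
    n = 50
    frame = pd.DataFrame(
        {"a": rng.normal(size=n), "b": rng.normal(size=n),
         "c": rng.integers(0, 3, size=n).astype(float)},
        index=[f"c{i:02d}" for i in range(n)],
    )
    criteria = _criteria(("a", "higher_better"), ("b", "lower_better"),
                         ("c", "higher_better"))
    # oracle: direct definition, written independently of the implementation
    signs = {"a": 1.0, "b": -1.0, "c": 1.0}
    expected = []
    for i in frame.index:
        dominated = False
        for j in frame.index:
            if i == j:
                continue
            geq = all(signs[k] * frame.loc[j, k] >= signs[k] * frame.loc[i, k]
                      for k in signs)
            gt = any(signs[k] * frame.loc[j, k] > signs[k] * frame.loc[i, k]
                     for k in signs)
            if geq and gt:
                dominated = True
                break
        if not dominated:
            expected.append(i)
    assert pareto_front(frame, criteria) == expected


def test_default_screen_selects_the_published_winners(candidates):
    report = screen(candidates, default_config())
    assert sorted(pose for pose, _ in report.excluded) == ["03", "05", "06"]
    assert report.selected == ["04", "02"]
    assert {"02", "04"} <= set(report.pareto_front)
    for pose_scores in report.scores.values():
        assert all(0.0 <= s <= 1.0 for s in pose_scores.values())


def test_single_criterion_ranking_is_a_sort(candidates):
    config = default_config()
    config.criteria = [Criterion(name="gap", direction="higher_better", weight=1.0)]
    config.hard_filters = []
    report = screen(candidates, config)
    by_gap = candidates["gap"].sort_values(ascending=False).index.tolist()
    assert report.ranking == by_gap


def test_screen_is_order_invariant_and_deterministic(candidates):
    config = default_config()
    report = screen(candidates, config)
    shuffled = candidates.sample(frac=1.0, random_state=123)
    assert screen(shuffled, config) == report
    assert screen(candidates, config).model_dump_json() == report.model_dump_json()


def test_ranking_invariant_under_affine_transforms(candidates):
    """Min-max normalization makes positive affine column rescaling a no-op."""
    config = default_config()
    baseline = screen(candidates, config)
    transformed = candidates.copy()
    transformed["gap"] = 100.0 * transformed["gap"] + 7.0
    transformed["entropy"] = 0.5 * transformed["entropy"] - 3.0
    report = screen(transformed, config)
    assert report.ranking == baseline.ranking
    assert report.pareto_front == baseline.pareto_front


def test_everything_filtered_gives_empty_report(candidates):
    config = default_config()
    config.hard_filters = [HardFilter(name="nope", field="pgp_substrate", equals="x")]
    report = screen(candidates, config)
    assert report.ranking == [] and report.selected == []
    assert len(report.excluded) == 6


def test_report_round_trip(tmp_path, candidates):
    from cdftscreen import read_report, write_report

    report = screen(candidates, default_config())
    path = tmp_path / "report.json"
    write_report(report, path, format="json")
    assert read_report(path) == report
    tsv = tmp_path / "report.tsv"
    write_report(report, tsv, format="tsv")
    lines = tsv.read_text().splitlines()
    assert len([l for l in lines[1:] if not l.split("\t")[1] == "excluded"]) == 3
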