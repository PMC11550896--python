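"""Confirmation logic and the five-way taxonomy.

The partition test enumerates every response log the experimental procedure
can produce (identification plus a confirmation loop that stops at the
first positive report, in one or both stimulus blocks) and checks the four
confirmed categories against an independent rule-by-rule oracle.
"""

import itertools

import pytest

from thermospot.classification import (
    ContractError,
    ResponseLog,
    TrialReport,
    classify_spot,
    is_confirmed,
    round_percent,
    summarize_categories,
)
from thermospot.spot_model import SpotTable, StudyRegion


def log_from(block_seqs: dict[str, list[str]]) -> ResponseLog:
    """Build a log from {block: [id_report, confirm1, ...]}."""
    trials = [
        TrialReport(block, sweep, report)
        for block, seq in block_seqs.items()
        for sweep, report in enumerate(seq)
    ]
    return ResponseLog("t", trials)


# --- confirmation -----------------------------------------------------------

def test_unconfirmed_when_all_confirmations_silent():
    log = log_from({"cold": ["cold", "none", "none", "none", "none"]})
    assert is_confirmed(log) is False


def test_any_positive_confirmation_confirms_even_if_quality_differs():
    log = log_from({"cold": ["cold", "none", "warm"]})
    assert is_confirmed(log) is True


def test_positive_first_confirmation_confirms():
    assert is_confirmed(log_from({"warm": ["warm", "warm"]})) is True


def test_confirmation_requires_positive_identification():
    with pytest.raises(ContractError):
        is_confirmed(log_from({"cold": ["none", "cold"]}))


def test_classify_requires_confirmed_log():
    with pytest.raises(ContractError):
        classify_spot(log_from({"cold": ["cold", "none", "none", "none", "none"]}))


# --- taxonomy ---------------------------------------------------------------

@pytest.mark.parametrize(
    "seqs,expected",
    [
        ({"cold": ["cold", "cold"]}, "cold"),
        ({"cold": ["cold", "warm"]}, "inconsistent"),
        ({"cold": ["warm", "warm"]}, "incongruous"),
        ({"warm": ["warm", "warm"]}, "warm"),
        ({"warm": ["cold", "cold"]}, "incongruous"),
        # responsive in both blocks, each internally consistent
        ({"cold": ["cold", "cold"], "warm": ["warm", "warm"]}, "inconsistent"),
    ],
)
def test_classify_examples(seqs, expected):
    assert classify_spot(log_from(seqs)) == expected


def _enumerate_block_sequences():
    """All sequences one block can produce under the stopping rule."""
    for id_report in ("cold", "warm", "none"):
        yield [id_report] + ["none"] * 4  # never confirmed in this block
        for k in range(4):  # k silent sweeps then a positive, then stop
            for positive in ("cold", "warm"):
                yield [id_report] + ["none"] * k + [positive]


def _enumerate_logs():
    seqs = list(_enumerate_block_sequences())
    for s in seqs:
        yield log_from({"cold": s})
        yield log_from({"warm": s})
    for s_cold, s_warm in itertools.product(seqs, seqs):
        yield log_from({"cold": s_cold, "warm": s_warm})


def _positives(log, block):
    return [t.report for t in log.block_trials(block) if t.report != "none"]


def _oracle_rules(log):
    """Independent truth table: which category definitions a log satisfies."""
    pos = {b: _positives(log, b) for b in log.blocks()}
    pos = {b: r for b, r in pos.items() if r}
    both_blocks = len(pos) == 2
    within_disagree = any(len(set(r)) > 1 for r in pos.values())
    all_reports = [r for rs in pos.values() for r in rs]
    agree = len(set(all_reports)) == 1
    rules = {
        "inconsistent": both_blocks or within_disagree,
        "cold": (not both_blocks and agree and "cold" in pos
                 and all_reports[0] == "cold"),
        "warm": (not both_blocks and agree and "warm" in pos
                 and all_reports[0] == "warm"),
        "incongruous": (not both_blocks and agree
                        and list(pos)[0] != all_reports[0]),
    }
    return rules


def test_taxonomy_is_exhaustive_and_mutually_exclusive():
    """Every enumerable confirmed log satisfies exactly one category rule."""
    n_checked = 0
    for log in _enumerate_logs():
        log.validate()
        has_positive_id = any(
            t.sweep_index == 0 and t.report != "none" for t in log.trials
        )
        if not has_positive_id:
            with pytest.raises(ContractError):
                is_confirmed(log)
            continue
        if not is_confirmed(log):
            continue
        rules = _oracle_rules(log)
        assert sum(rules.values()) == 1, f"rules {rules} for {log.trials}"
        (expected,) = [c for c, v in rules.items() if v]
        assert classify_spot(log) == expected
        n_checked += 1
    assert n_checked > 500  # the enumeration really covered the space


def _swap(report):
    return {"cold": "warm", "warm": "cold", "none": "none"}[report]


def test_relabelling_symmetry():
    """Swapping cold<->warm everywhere swaps cold/warm, fixes the rest."""
    expected_map = {
        "cold": "warm", "warm": "cold",
        "inconsistent": "inconsistent", "incongruous": "incongruous",
    }
    for log in _enumerate_logs():
        if not any(t.sweep_index == 0 and t.report != "none" for t in log.trials):
            continue
        if not is_confirmed(log):
            continue
        swapped = ResponseLog(
            "s",
            [TrialReport(_swap(t.block), t.sweep_index, _swap(t.report))
             for t in log.trials],
        )
        assert classify_spot(swapped) == expected_map[classify_spot(log)]


def test_classification_invariant_to_confirmation_position():
    """Where the terminating positive lands among sweeps 1-4 is irrelevant."""
    for k in range(4):
        log = log_from({"cold": ["cold"] + ["none"] * k + ["warm"]})
        assert classify_spot(log) == "inconsistent"
        log2 = log_from({"cold": ["cold"] + ["none"] * k + ["cold"]})
        assert classify_spot(log2) == "cold"


# --- summaries --------------------------------------------------------------

def test_summary_empty_table():
    s = summarize_categories(SpotTable([], StudyRegion()))
    assert s.n_total == 0 and s.n_confirmed == 0
    assert all(v == 0 for v in s.counts.values())


def test_summary_single_participant_degenerate_sd():
    from thermospot.spot_model import SpotRecord

    table = SpotTable(
        [
            SpotRecord("P1", 1, float(i), 10.0, frozenset(["cold"]), 2.0,
                       "cold", f"log-{i}")
            for i in range(8)
        ],
        StudyRegion(),
    )
    s = summarize_categories(table)
    mean, sd = s.per_participant_mean_sd["cold"]
    assert mean == 8.0 and sd == 0.0 and s.sd_degenerate


@pytest.mark.parametrize(
    "fraction,expected", [(165 / 334, 49), (112 / 334, 34), (41 / 334, 12),
                          (0.125, 13), (0.4940, 49)]
)
def test_percent_rounding_half_away_from_zero(fraction, expected):
    assert round_percent(fraction) == expected
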