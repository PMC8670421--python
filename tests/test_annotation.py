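"""Consensus CAZyme classifier and the peptidase/transporter/marker mappings."""

import numpy as np
import pandas as pd
import pytest

from stratiscope.annotation import (
    assign_markers,
    classify_peptidases,
    classify_transporters,
    combine_assignments,
    consensus_cazyme,
    split_tp_family,
)
from stratiscope.io_model import StratiscopeError

from oracles import brute_force_consensus, consensus_boundary_grid


def rec(orf, tool, family, **metrics):
    base = dict(orf_id=orf, tool=tool, family=family, percent_identity=np.nan,
                coverage=np.nan, hits=np.nan, frequency=np.nan)
    base.update(metrics)
    return base


def run_consensus(records):
    out = consensus_cazyme(pd.DataFrame(records))
    return dict(zip(out["orf_id"], out["family"]))


def test_single_alignment_below_identity_threshold_dropped():
    assert run_consensus([rec("a", "alignment", "GH16", percent_identity=45.0)]) == {}


def test_single_profile_above_coverage_threshold_kept():
    got = run_consensus([rec("a", "profile", "GH16", coverage=0.6)])
    assert got == {"a": "GH16"}


@pytest.mark.parametrize(
    "tool, metrics, kept",
    [
        ("alignment", dict(percent_identity=50.0), True),
        ("alignment", dict(percent_identity=49.999), False),
        ("profile", dict(coverage=0.5), True),
        ("profile", dict(coverage=0.499), False),
        ("pattern", dict(hits=10, frequency=0.1), True),
        ("pattern", dict(hits=9, frequency=9.9), False),
    ],
)
def test_exact_threshold_boundaries_are_retained(tool, metrics, kept):
    got = run_consensus([rec("a", tool, "GT4", **metrics)])
    assert (got == {"a": "GT4"}) is kept


def test_majority_vote_beats_single_strong_tool():
    got = run_consensus([
        rec("a", "alignment", "GH16", percent_identity=80.0),
        rec("a", "pattern", "GH13", hits=12, frequency=0.3),
        rec("a", "profile", "GH16", coverage=0.9),
    ])
    assert got == {"a": "GH16"}


def test_equal_votes_resolved_by_quality_then_lexicographic():
    # quality: GH13 coverage 0.6 beats GH16 identity 60/100 = 0.6? equal ->
    # lexicographic tie-break picks GH13
    got = run_consensus([
        rec("a", "alignment", "GH16", percent_identity=60.0),
        rec("a", "profile", "GH13", coverage=0.6),
    ])
    assert got == {"a": "GH13"}
    # now GH16's quality is higher
    got = run_consensus([
        rec("b", "alignment", "GH16", percent_identity=75.0),
        rec("b", "profile", "GH13", coverage=0.6),
    ])
    assert got == {"b": "GH16"}


def test_wrong_tool_metrics_and_unknown_tool_are_fatal():
    with pytest.raises(StratiscopeError, match="foreign metric"):
        consensus_cazyme(pd.DataFrame([
            rec("a", "alignment", "GH16", percent_identity=60.0, coverage=0.5)
        ]))
    with pytest.raises(StratiscopeError, match="lacks its metric"):
        consensus_cazyme(pd.DataFrame([rec("a", "profile", "GH16")]))
    bad = rec("a", "alignment", "GH16", percent_identity=60.0)
    bad["tool"] = "blastx"
    with pytest.raises(StratiscopeError, match="unknown tool"):
        consensus_cazyme(pd.DataFrame([bad]))


def test_consensus_matches_brute_force_oracle_on_boundary_grid():
    grid = consensus_boundary_grid()
    got = consensus_cazyme(grid)
    got_map = dict(zip(got["orf_id"], got["family"]))
    expected = brute_force_consensus(grid.to_dict("records"))
    for orf, fam in expected.items():
        assert got_map.get(orf) == fam, orf
    assert set(got_map) == {o for o, f in expected.items() if f is not None}


def test_consensus_never_emits_two_families_per_orf(default_dataset):
    from stratiscope.synthetic_data import SyntheticConfig, generate_cazyme_predictions

    cfg = SyntheticConfig(seed=42)
    preds = generate_cazyme_predictions(default_dataset.truth.orf_roles, cfg)
    out = consensus_cazyme(preds)
    assert not out["orf_id"].duplicated().any()
    assert (out["system"] == "CAZyme").all()


# ---------------------------------------------------------------------------
# Peptidases
# ---------------------------------------------------------------------------

MEROPS = pd.DataFrame({"pfam": ["PF00089", "PF01433"],
                       "merops_family": ["S01A", "M01"]})


def test_peptidase_single_mapped_hit():
    hits = pd.DataFrame([{"orf_id": "a", "pfam": "PF00089", "score": 50.0}])
    asg, unmapped = classify_peptidases(hits, MEROPS)
    assert asg.iloc[0]["family"] == "S01A" and asg.iloc[0]["system"] == "PEP"
    assert unmapped.empty


def test_peptidase_argmax_score_wins():
    hits = pd.DataFrame([
        {"orf_id": "a", "pfam": "PF00089", "score": 40.0},
        {"orf_id": "a", "pfam": "PF01433", "score": 90.0},
    ])
    asg, _ = classify_peptidases(hits, MEROPS)
    assert len(asg) == 1 and asg.iloc[0]["family"] == "M01"


def test_peptidase_unmapped_accession_side_report():
    hits = pd.DataFrame([{"orf_id": "a", "pfam": "PF99999", "score": 30.0}])
    asg, unmapped = classify_peptidases(hits, MEROPS)
    assert asg.empty
    assert list(unmapped["pfam"]) == ["PF99999"]


# ---------------------------------------------------------------------------
# Transporters
# ---------------------------------------------------------------------------

def tp_hit(orf, profile, family, tc, score=100.0):
    return dict(orf_id=orf, profile=profile, tcdb_family=family,
                tc_number=tc, score=score, gathering_pass=True)


def test_amt_override_corrects_wrong_database_family():
    hits = pd.DataFrame([
        tp_hit("a", "PF00909", "The Nitrate/Nitrite Porter (NNP) Family", "2.A.1.8")
    ])
    asg = classify_transporters(hits)
    name, tc = split_tp_family(asg.iloc[0]["family"])
    assert name == "The Ammonium Channel Transporter (Amt) Family"
    assert tc == "1.A.11"


def test_clc_override():
    hits = pd.DataFrame([
        tp_hit("a", "PF00654", "The Voltage-gated Ion Channel (VIC) Superfamily",
               "1.A.1.13")
    ])
    asg = classify_transporters(hits)
    name, tc = split_tp_family(asg.iloc[0]["family"])
    assert name == "The Chloride Carrier/Channel (ClC) Family"
    assert tc == "2.A.49"


def test_ordinary_transporter_hit_unchanged_and_argmax():
    hits = pd.DataFrame([
        tp_hit("a", "PF00005", "The ATP-binding Cassette (ABC) Superfamily",
               "3.A.1.1", score=80.0),
        tp_hit("a", "PF00593", "The Outer Membrane Receptor (OMR) Family",
               "1.B.14.1", score=120.0),
    ])
    asg = classify_transporters(hits)
    assert len(asg) == 1
    assert split_tp_family(asg.iloc[0]["family"])[0].startswith("The Outer Membrane")


def test_malformed_tc_number_is_fatal():
    hits = pd.DataFrame([tp_hit("a", "PF00005", "ABC", "not-a-tc")])
    with pytest.raises(StratiscopeError, match="malformed TC"):
        classify_transporters(hits)


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------

def test_marker_gathering_score_gate():
    hits = pd.DataFrame([
        {"orf_id": "a", "marker": "amoA", "score": 300.0, "gathering_pass": True},
        {"orf_id": "b", "marker": "amoA", "score": 10.0, "gathering_pass": False},
        {"orf_id": "c", "marker": "hcd", "score": 5.0, "gathering_pass": False},
    ])
    asg = assign_markers(hits)
    assert set(asg["orf_id"]) == {"a", "c"}  # hcd passes through regardless
    assert asg.loc[asg["orf_id"] == "c", "provenance"].iloc[0] == "placement (external)"


def test_unknown_marker_label_is_fatal():
    hits = pd.DataFrame([
        {"orf_id": "a", "marker": "nifH", "score": 300.0, "gathering_pass": True}
    ])
    with pytest.raises(StratiscopeError, match="unknown marker"):
        assign_markers(hits)


def test_combine_allows_multi_system_but_not_multi_cazyme():
    tp = pd.DataFrame([["a", "TP", "Amt|1.A.11", "tcdb"]],
                      columns=["orf_id", "system", "family", "provenance"])
    mk = pd.DataFrame([["a", "marker", "amt", "gathering-score"]],
                      columns=["orf_id", "system", "family", "provenance"])
    combined = combine_assignments(tp, mk)
    assert len(combined) == 2  # same ORF, two systems: allowed
    caz = pd.DataFrame([["a", "CAZyme", "GH16", "x"], ["a", "CAZyme", "GH13", "x"]],
                       columns=["orf_id", "system", "family", "provenance"])
    with pytest.raises(StratiscopeError, match="multiple CAZyme"):
        combine_assignments(caz)
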