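"""Dataset curation: labeling, host/TM/PDB filters, balancing, independence."""

import pytest

from soluprot.curation import (
    CurationRecord,
    LabelRules,
    balance_dataset,
    binarize_solubility,
    curate,
    enforce_independence,
    filter_host,
    filter_transmembrane,
    label_record,
    pdb_rescue,
    read_curation_records,
    write_curation_records,
)
from soluprot.seqio import INSOLUBLE, SOLUBLE, ProteinRecord
from soluprot.synthetic import gen_curation_records

SEQ = "ACDEFGHIKLMNPQRSTVWYACDEF"


def _rec(statuses=(), stop=None, protocol="expressed in Escherichia coli BL21",
         tm=False, tid="t1", seq=SEQ):
    return CurationRecord(tid, seq, tuple(statuses), stop, protocol, tm)


@pytest.mark.parametrize(
    "statuses,stop,expected",
    [
        (("cloned", "expressed", "purified"), None, SOLUBLE),
        (("cloned", "expressed"), "work stopped: expression failed", INSOLUBLE),
        (("cloned", "expressed"), None, "unknown"),  # no explicit stop status
        (("cloned",), "budget exhausted", "unknown"),  # stop not insolubility
        # soluble state takes precedence over an insoluble-sounding stop
        (("soluble", "purified"), "purification failed", SOLUBLE),
        (("Crystallized",), None, SOLUBLE),  # case-insensitive matching
    ],
)
def test_label_record(statuses, stop, expected):
    assert label_record(_rec(statuses, stop)) == expected


def test_label_rules_validation():
    with pytest.raises(ValueError):
        LabelRules(soluble_states=())


def test_filter_host():
    coli = _rec(tid="a")
    insect = _rec(protocol="baculovirus insect cell expression", tid="b")
    empty_allowed = CurationRecord("c", SEQ, ("cloned",), None, None, False)
    rules = LabelRules(confirmed_protocols=frozenset({"c"}))
    kept = filter_host([coli, insect, empty_allowed], rules)
    assert [r.target_id for r in kept] == ["a", "c"]


def test_filter_transmembrane():
    recs = [ProteinRecord("a", SEQ, SOLUBLE), ProteinRecord("b", SEQ, SOLUBLE)]
    assert [r.id for r in filter_transmembrane(recs, [True, False])] == ["b"]
    assert filter_transmembrane(recs, [True, True]) == []
    with pytest.raises(ValueError):
        filter_transmembrane(recs, [True])


def test_pdb_rescue():
    subset = [ProteinRecord("pdb1", SEQ)]
    insol_match = ProteinRecord("a", SEQ, INSOLUBLE)
    sol_match = ProteinRecord("b", SEQ, SOLUBLE)
    insol_other = ProteinRecord("c", SEQ[::-1], INSOLUBLE)
    kept = pdb_rescue([insol_match, sol_match, insol_other], subset)
    assert [r.id for r in kept] == ["b", "c"]


@pytest.mark.parametrize("level,expected", [(0, INSOLUBLE), (1, SOLUBLE), (5, SOLUBLE)])
def test_binarize_solubility(level, expected):
    assert binarize_solubility(level) == expected


def test_binarize_out_of_range():
    with pytest.raises(ValueError):
        binarize_solubility(6)


def _records_of_length(prefix, n, length, label):
    return [ProteinRecord(f"{prefix}{i}", "A" * length, label) for i in range(n)]


def test_balance_dataset_downsamples_per_bin():
    pos = _records_of_length("p", 10, 30, SOLUBLE) + _records_of_length("P", 4, 80, SOLUBLE)
    neg = _records_of_length("n", 5, 30, INSOLUBLE) + _records_of_length("N", 4, 80, INSOLUBLE)
    bp, bn = balance_dataset(pos, neg, bin_width=25, seed=42)
    assert len(bp) == len(bn) == 9  # 5 in the 30-residue bin, 4 in the 80s
    assert sum(1 for r in bp if len(r.sequence) == 30) == 5
    # already-balanced input is unchanged
    bp2, bn2 = balance_dataset(bp, bn, bin_width=25, seed=42)
    assert {r.id for r in bp2} == {r.id for r in bp}
    # determinism under the seed
    assert [r.id for r in balance_dataset(pos, neg, 25, 7)[0]] == [
        r.id for r in balance_dataset(pos, neg, 25, 7)[0]
    ]


def test_balance_dataset_empty_class():
    with pytest.raises(ValueError):
        balance_dataset([], _records_of_length("n", 3, 30, INSOLUBLE))


def test_enforce_independence():
    train = [ProteinRecord("t", SEQ, SOLUBLE)]
    test = [
        ProteinRecord("dup", SEQ, SOLUBLE),
        ProteinRecord("far", "W" * 25, SOLUBLE),
    ]
    kept = enforce_independence(test, train, threshold=0.25)
    assert [r.id for r in kept] == ["far"]
    # threshold 1.0: only exact duplicates go
    kept = enforce_independence(test, train, threshold=1.0)
    assert [r.id for r in kept] == ["far"]
    near = [ProteinRecord("near", SEQ[:-1] + "W", SOLUBLE)]
    assert enforce_independence(near, train, threshold=1.0) == near


def test_curate_pipeline_attrition_reconciles():
    """Every record is accounted for at each step of the synthetic pipeline."""
    mix = {"soluble-path": 0.3, "insoluble-stop": 0.25, "unknown": 0.15,
           "non-coli-host": 0.1, "transmembrane": 0.1, "pdb-rescuable": 0.1}
    data = gen_curation_records(300, seed=5, scenario_mix=mix)
    counts = data.scenario_counts()
    pos, neg, report = curate(
        data.records, pdb_subset=data.pdb_subset, cluster=False, seed=0
    )
    steps = {s["step"]: s for s in report.steps}
    assert steps["host_filter"]["in"] == 300
    assert steps["host_filter"]["out"] == 300 - counts["non-coli-host"]
    assert steps["labeling"]["out"] == (
        steps["host_filter"]["out"] - counts["unknown"]
    )
    assert steps["transmembrane_filter"]["out"] == (
        steps["labeling"]["out"] - counts["transmembrane"]
    )
    assert steps["sequence_validity"]["out"] == steps["transmembrane_filter"]["out"]
    assert steps["pdb_rescue"]["out"] == (
        steps["sequence_validity"]["out"] - counts["pdb-rescuable"]
    )
    assert len(pos) == len(neg)  # balanced output
    for a, b in zip(report.steps, report.steps[1:]):
        assert b["in"] == a["out"]  # chain is gap-free


def test_curation_record_round_trip(tmp_path):
    recs = [
        _rec(("cloned", "soluble"), None, tid="x"),
        _rec(("cloned",), "expression failed", tid="y", tm=True),
    ]
    path = tmp_path / "records.jsonl"
    write_curation_records(recs, path)
    assert read_curation_records(path) == recs
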