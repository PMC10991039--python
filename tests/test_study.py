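import hashlib

import numpy as np
import pandas as pd
import pytest

from cdforest import (
    ConditionSpec,
    MethodSpec,
    StudyRecord,
    aggregate,
    agreement_analysis,
    run_study,
)
from cdforest.study import records_frame

CONDS = [
    ConditionSpec(k=1, n=250, vpf=4, primary_bin="large"),
    ConditionSpec(k=3, n=250, vpf=4, rho=0.2, primary_bin="medium"),
]


def oracle() -> MethodSpec:
    # k = vpf divides p, so the truth is recoverable from the shape alone
    return MethodSpec(name="oracle", apply=lambda d, rng: d.p // 4)


def constant(k: int, name: str | None = None) -> MethodSpec:
    return MethodSpec(name=name or f"const{k}", apply=lambda d, rng: k)


def make_records(k_true: int, k_hats, method="m") -> list[StudyRecord]:
    cond = ConditionSpec(k=k_true, n=250, vpf=4, rho=0.2 if k_true > 1 else 0.0)
    return [
        StudyRecord(condition=cond, replication=i, method=method,
                    k_true=k_true, k_hat=kh)
        for i, kh in enumerate(k_hats)
    ]


class TestRunStudy:
    def test_record_bookkeeping(self):
        records = run_study(CONDS[:1], [constant(1), constant(2)],
                            replications=3, seed=0)
        assert len(records) == 1 * 3 * 2
        assert {r.method for r in records} == {"const1", "const2"}

    def test_paired_design_same_data_per_cell(self):
        seen: dict[tuple, list[str]] = {}

        def probe(name):
            def apply(d, rng):
                h = hashlib.sha1(d.values.tobytes()).hexdigest()
                seen.setdefault((name,), []).append(h)
                return 1
            return MethodSpec(name=name, apply=apply)

        run_study(CONDS, [probe("a"), probe("b")], replications=2, seed=3)
        assert seen[("a",)] == seen[("b",)]
        # distinct cells see distinct data
        assert len(set(seen[("a",)])) == len(seen[("a",)])

    def test_seeded_reproducibility(self):
        r1 = run_study(CONDS, [oracle()], replications=2, seed=7)
        r2 = run_study(CONDS, [oracle()], replications=2, seed=7)
        assert [r.k_hat for r in r1] == [r.k_hat for r in r2]

    def test_journal_resume_skips_done_cells(self, tmp_path):
        journal = tmp_path / "records.jsonl"
        first = run_study(CONDS, [oracle()], replications=2, seed=1,
                          journal_path=journal)
        again = run_study(CONDS, [oracle()], replications=2, seed=1,
                          journal_path=journal)
        assert len(first) == len(again) == 4
        assert journal.read_text().count("\n") == 4  # nothing re-run

    def test_failing_method_is_recorded_as_missing(self):
        def boom(d, rng):
            raise RuntimeError("nope")
        records = run_study(CONDS[:1], [MethodSpec("boom", boom), oracle()],
                            replications=2, seed=2)
        assert {r.method for r in records} == {"oracle"}


class TestAggregate:
    def test_hand_checked_cell(self):
        table = aggregate(make_records(3, [3, 3, 4]))
        row = table.iloc[0]
        assert row["accuracy"] == pytest.approx(2 / 3)
        assert row["bias"] == pytest.approx(1 / 3)
        assert row["overfactor_rate"] == pytest.approx(1 / 3)
        assert row["underfactor_rate"] == 0.0
        assert row["n_cells"] == 3

    def test_rates_partition_to_one(self):
        rng = np.random.default_rng(0)
        records = make_records(3, rng.integers(1, 6, size=200))
        table = aggregate(records)
        total = table[["accuracy", "underfactor_rate", "overfactor_rate"]].sum(axis=1)
        assert np.allclose(total, 1.0)

    def test_oracle_method_is_perfect_on_every_facet(self):
        records = run_study(CONDS, [oracle()], replications=3, seed=5)
        for by in (["method"], ["method", "k"], ["method", "n", "vpf"]):
            table = aggregate(records, by=by)
            assert (table["accuracy"] == 1.0).all()
            assert (table["bias"] == 0.0).all()

    def test_idempotent_on_same_records(self):
        records = make_records(3, [2, 3, 3, 5])
        pd.testing.assert_frame_equal(aggregate(records), aggregate(records))

    def test_unknown_grouping_key(self):
        with pytest.raises(KeyError):
            aggregate(make_records(3, [3]), by=["nope"])


class TestAgreement:
    def test_identical_predictions(self):
        recs = make_records(3, [3, 3, 4, 2], method="a") + \
               make_records(3, [3, 3, 4, 2], method="b")
        out = agreement_analysis(recs, "a", "b")
        assert out["agreement_rate"] == 1.0
        assert out["accuracy_given_agreement"] == pytest.approx(0.5)
        assert len(out["by_difference"]) == 1

    def test_disjoint_predictions(self):
        recs = make_records(3, [3, 3], method="a") + \
               make_records(3, [4, 5], method="b")
        out = agreement_analysis(recs, "a", "b")
        assert out["agreement_rate"] == 0.0
        assert np.isnan(out["accuracy_given_agreement"])

    def test_difference_table_frequencies_sum_to_one(self):
        rng = np.random.default_rng(1)
        recs = make_records(3, rng.integers(1, 6, 50), method="a") + \
               make_records(3, rng.integers(1, 6, 50), method="b")
        out = agreement_analysis(recs, "a", "b")
        assert out["by_difference"]["frequency"].sum() == pytest.approx(1.0)

    def test_unpaired_inputs_rejected(self):
        recs = make_records(3, [3], method="a")
        with pytest.raises(ValueError):
            agreement_analysis(recs, "a", "b")
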