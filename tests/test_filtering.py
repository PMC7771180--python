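"""Filtering semantics: low-read rule, blank rule, replicate and primer merging."""

import warnings

import numpy as np
import pandas as pd
import pytest

from trophiq import (
    calibrate_min_read_threshold, combine_replicates_additive,
    combine_replicates_conservative, filter_blank_contamination,
    generate_study, merge_primers, primer_recovery_summary,
    remove_low_read_bins,
)
from trophiq.data_model import BLANK_TYPES
from conftest import small_config


def _reads(rows):
    return pd.DataFrame(rows, columns=["sample_id", "run_id", "bin_id", "reads"])


def _meta(samples):
    """samples: list of (sample_id, sample_type, batch, seqrun)."""
    df = pd.DataFrame(samples, columns=["sample_id", "sample_type",
                                        "extraction_batch_id", "sequencing_run_id"])
    df["bat_species"] = pd.NA
    df["site_id"] = "s1"
    df["region_id"] = "r"
    df["broad_class"] = pd.NA
    df["fine_class"] = pd.NA
    return df


class TestLowReadRule:
    def test_singletons_removed_and_boundary_retained(self):
        t = _reads([("s1", "A1", "b1", 1), ("s1", "A1", "b2", 2)])
        out, audit = remove_low_read_bins(t, min_reads=2)
        assert list(out["bin_id"]) == ["b2"]
        assert list(audit["bin_id"]) == ["b1"] and audit["rule"].iloc[0] == "singleton"

    def test_min_reads_one_is_identity(self):
        t = _reads([("s1", "A1", "b1", 1), ("s1", "A2", "b2", 7)])
        out, audit = remove_low_read_bins(t, min_reads=1)
        pd.testing.assert_frame_equal(out, t)
        assert audit.empty

    def test_idempotent_and_audit_reconstructs_input(self, study):
        out1, audit = remove_low_read_bins(study.reads)
        out2, audit2 = remove_low_read_bins(out1)
        pd.testing.assert_frame_equal(out1, out2)
        assert audit2.empty
        assert len(out1) + len(audit) == len(study.reads)


class TestBlankRule:
    meta = staticmethod(lambda: _meta([
        ("s1", "dropping", "X1", "SEQ1"),
        ("s2", "dropping", "X2", "SEQ1"),
        ("blk", "blank_extraction", "X1", "SEQ1"),
    ]))

    def test_below_10x_removed_boundary_retained(self):
        t = _reads([("blk", "A1", "b1", 5),
                    ("s1", "A1", "b1", 49),    # 49 < 50 -> removed
                    ("s1", "A2", "b1", 50),    # 50 >= 50 -> retained
                    ("s1", "A1", "b2", 3)])    # absent from blanks -> untouched
        out, audit = filter_blank_contamination(t, self.meta(), scope="global")
        kept = set(map(tuple, out[["sample_id", "run_id", "bin_id"]].values))
        assert ("s1", "A1", "b1") not in kept
        assert ("s1", "A2", "b1") in kept and ("s1", "A1", "b2") in kept
        assert set(audit["rule"]) == {"blank_extraction"}
        assert audit["blank_reads"].iloc[0] == 5

    def test_batch_scope_limits_extraction_blanks_to_their_batch(self):
        t = _reads([("blk", "A1", "b1", 5),
                    ("s1", "A1", "b1", 20),    # same batch, < 50 -> removed
                    ("s2", "A1", "b1", 20)])   # other batch -> retained
        out, _ = filter_blank_contamination(t, self.meta(), scope="batch")
        assert set(out["sample_id"]) == {"blk", "s2"}

    def test_no_blanks_is_a_warned_noop(self):
        t = _reads([("s1", "A1", "b1", 5)])
        meta = _meta([("s1", "dropping", "X1", "SEQ1")])
        with pytest.warns(UserWarning, match="no blank"):
            out, audit = filter_blank_contamination(t, meta)
        pd.testing.assert_frame_equal(out, t)
        assert audit.empty

    def test_max_over_blanks_in_scope_is_used(self):
        meta = _meta([("s1", "dropping", "X1", "SEQ1"),
                      ("blk1", "blank_extraction", "X1", "SEQ1"),
                      ("blk2", "blank_extraction", "X1", "SEQ1")])
        t = _reads([("blk1", "A1", "b1", 2), ("blk2", "A1", "b1", 6),
                    ("s1", "A1", "b1", 30)])   # 30 < 60 under the max rule
        out, _ = filter_blank_contamination(t, meta, scope="batch")
        assert "s1" not in set(out["sample_id"])

    def test_planted_contaminants_removed_and_nothing_else(self, study):
        t1, _ = remove_low_read_bins(study.reads)
        out, audit = filter_blank_contamination(t1, study.metadata, scope="global")
        cont = study.truth.contaminant_bins
        assert set(audit["bin_id"]) <= cont
        m = study.metadata.set_index("sample_id")["sample_type"]
        blanks = t1[t1["sample_id"].map(m).isin(BLANK_TYPES)]
        rb = blanks.groupby("bin_id")["reads"].max()
        samp = t1[~t1["sample_id"].map(m).isin(BLANK_TYPES)]
        removable = (samp["bin_id"].isin(cont)
                     & (samp["reads"] < 10 * samp["bin_id"].map(rb)))
        kept = set(map(tuple, out[["sample_id", "run_id", "bin_id"]].values))
        removed = [tuple(k) not in kept for k in
                   samp.loc[removable, ["sample_id", "run_id", "bin_id"]].values]
        assert np.mean(removed) >= 0.95


class TestReplicateCombination:
    def test_additive_unions_replicates_and_sums_reads(self):
        t = _reads([("s1", "A1", "b1", 3), ("s1", "A2", "b2", 4),
                    ("s1", "A1", "b3", 2), ("s1", "A2", "b3", 5)])
        out = combine_replicates_additive(t)
        got = out.set_index("bin_id")["reads"]
        assert set(out["bin_id"]) == {"b1", "b2", "b3"} and got["b3"] == 7

    def test_conservative_intersects_replicates_per_primer(self):
        rows = [("s1", r, b, 200) for r, b in
                [("A1", "b1"), ("A2", "b1"),   # both A replicates -> kept
                 ("A1", "b2"),                 # A replicate 1 only -> dropped
                 ("B1", "b3"), ("B2", "b3")]]  # both B replicates -> kept
        out, dropped, audit = combine_replicates_conservative(_reads(rows))
        assert not dropped
        assert set(out["bin_id"]) == {"b1", "b3"}
        assert set(audit["bin_id"]) == {"b2"}

    def test_sample_dropped_if_any_run_at_or_below_100(self):
        rows = [("s1", r, "b1", n) for r, n in
                [("A1", 150), ("A2", 150), ("B1", 150), ("B2", 99)]]
        _, dropped, _ = combine_replicates_conservative(_reads(rows))
        assert dropped == {"s1"}
        rows = [("s1", r, "b1", n) for r, n in
                [("A1", 150), ("A2", 150), ("B1", 150), ("B2", 100)]]
        _, dropped, _ = combine_replicates_conservative(_reads(rows))
        assert dropped == {"s1"}  # exactly 100 is not "> 100"
        rows = [("s1", r, "b1", 101) for r in ["A1", "A2", "B1", "B2"]]
        _, dropped, _ = combine_replicates_conservative(_reads(rows))
        assert not dropped

    def test_sample_with_missing_runs_dropped(self):
        rows = [("s1", r, "b1", 500) for r in ["A1", "A2", "B1"]]
        rows += [("s2", r, "b1", 500) for r in ["A1", "A2", "B1", "B2"]]
        _, dropped, _ = combine_replicates_conservative(_reads(rows))
        assert dropped == {"s1"}

    @pytest.mark.parametrize("seed", range(20))
    def test_conservative_subset_of_additive(self, seed):
        study = generate_study(small_config(seed=seed, samples_per_site=2,
                                            n_sweep_samples_per_site=1))
        add = combine_replicates_additive(study.reads)
        con, _, _ = combine_replicates_conservative(study.reads)
        a = add.groupby(["sample_id", "primer_id"])["bin_id"].agg(set)
        c = con.groupby(["sample_id", "primer_id"])["bin_id"].agg(set)
        assert all(bins <= a.get(key, set()) for key, bins in c.items())


class TestPrimerMerging:
    def test_union_and_inclusion_exclusion(self):
        pp = pd.DataFrame({
            "sample_id": ["s1"] * 4, "primer_id": ["A", "A", "B", "B"],
            "bin_id": ["b1", "b2", "b2", "b3"], "reads": [1, 2, 3, 4],
        })
        merged = merge_primers(pp)
        assert set(merged["bin_id"]) == {"b1", "b2", "b3"}
        assert merged.set_index("bin_id")["reads"]["b2"] == 5
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = set(rng.choice(20, size=rng.integers(1, 10), replace=False))
            b = set(rng.choice(20, size=rng.integers(1, 10), replace=False))
            rows = ([("s", "A", f"b{i}", 1) for i in a]
                    + [("s", "B", f"b{i}", 1) for i in b])
            pp = pd.DataFrame(rows, columns=["sample_id", "primer_id",
                                             "bin_id", "reads"])
            assert len(merge_primers(pp)) == len(a) + len(b) - len(a & b)

    def test_one_empty_primer_yields_the_other(self):
        pp = pd.DataFrame({"sample_id": ["s1"], "primer_id": ["A"],
                           "bin_id": ["b1"], "reads": [5]})
        assert set(merge_primers(pp)["bin_id"]) == {"b1"}

    def test_recovery_summary_counts_and_proportions(self, study):
        add = combine_replicates_additive(study.reads)
        summary = primer_recovery_summary(add, study.taxonomy)
        props = summary[[c for c in summary.columns if c.startswith("prop_")]]
        assert np.allclose(props.sum(axis=1), 1.0)
        # identical primer outputs -> everything "both"
        sym = pd.concat([
            add.assign(primer_id="A"), add.assign(primer_id="B")
        ]).drop_duplicates(["sample_id", "primer_id", "bin_id"])
        s2 = primer_recovery_summary(sym, study.taxonomy)
        assert (s2["prop_both"] == 1.0).all()
        # disjoint outputs -> zero "both"
        disj = pd.DataFrame({"sample_id": ["s", "s"], "primer_id": ["A", "B"],
                             "bin_id": [study.taxonomy["bin_id"].iloc[0],
                                        study.taxonomy["bin_id"].iloc[1]],
                             "reads": [1, 1]})
        s3 = primer_recovery_summary(disj, study.taxonomy)
        assert (s3["n_both"] == 0).all()


class TestThresholdCalibration:
    def test_hand_jaccard_score(self):
        """Molecular {Diptera, Araneae} vs morphological {Diptera}: 1/2."""
        sweep = _reads([("w1", "A1", "b1", 5), ("w1", "A1", "b2", 5)])
        tax = pd.DataFrame({"bin_id": ["b1", "b2"],
                            "order_name": ["Diptera", "Araneae"]})
        morph = pd.DataFrame({"sweep_sample_id": ["w1"],
                              "order_name": ["Diptera"], "individuals": [3]})
        chosen, scores = calibrate_min_read_threshold(sweep, tax, morph)
        assert scores[1] == pytest.approx(0.5)

    def test_ties_break_to_smallest_threshold(self):
        sweep = _reads([("w1", "A1", "b1", 50)])
        tax = pd.DataFrame({"bin_id": ["b1"], "order_name": ["Diptera"]})
        morph = pd.DataFrame({"sweep_sample_id": ["w1"],
                              "order_name": ["Diptera"], "individuals": [3]})
        chosen, scores = calibrate_min_read_threshold(sweep, tax, morph)
        assert chosen == 1 and all(v == 1.0 for v in scores.values())

    def test_no_common_samples_raises(self):
        sweep = _reads([("w1", "A1", "b1", 5)])
        tax = pd.DataFrame({"bin_id": ["b1"], "order_name": ["Diptera"]})
        morph = pd.DataFrame({"sweep_sample_id": ["w9"],
                              "order_name": ["Diptera"], "individuals": [1]})
        with pytest.raises(Exception, match="no samples shared"):
            calibrate_min_read_threshold(sweep, tax, morph)
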