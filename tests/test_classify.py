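"""Classification labels, RPM profiles, ambiguity audit and series report."""

from __future__ import annotations

import numpy as np
import pytest

import sirnafam as sf
from conftest import SHARED20

GROUP1, GROUP2 = "group1", "group2"


def _library(records: dict[str, int], total: int, library_id="lib", stage=""):
    return sf.ReadLibrary(library_id, stage, total, records)


@pytest.fixture()
def toy_assignment(toy_family, toy_index):
    a_seq = toy_family.get("CHS4").sequence
    b_seq = toy_family.get("CHS7").sequence
    records = {
        a_seq[:21]: 10,            # matches CHS4 and its identical repeat CHS4b
        b_seq[5:26]: 4,            # matches only CHS7
        SHARED20: 2,               # 20-mer in the shared block: cross-group
        "ACGT" * 5 + "A": 7,       # matches nothing
    }
    lib = _library(records, 1000)
    return sf.classify(lib, toy_family, toy_index), lib


class TestClassify:
    def test_partition_labels(self, toy_assignment):
        asn, _ = toy_assignment
        labels = dict(zip(asn.df["sequence"], asn.df["label"]))
        a, b, shared, junk = labels.keys()
        assert labels[a] == "group1_unique"
        assert labels[b] == "group2_unique"
        assert labels[shared] == "ambiguous"
        assert labels[junk] == "unmatched"

    def test_within_group_multimatch_stays_unique(self, toy_assignment):
        asn, _ = toy_assignment
        row = asn.df[asn.df["label"] == "group1_unique"].iloc[0]
        assert set(row["genes"]) == {"CHS4", "CHS4b"}

    def test_partition_is_exact(self, toy_assignment):
        asn, lib = toy_assignment
        assert asn.label_counts().sum() == sum(lib.records.values())

    def test_family_without_both_groups_rejected(self, toy_family):
        lonely = sf.GeneFamily(
            [sf.GeneRecord("A", "ACGT" * 10)], {"A"}, set()
        )
        idx = sf.build_index(lonely, k=8)
        with pytest.raises(ValueError):
            sf.classify(_library({"ACGT" * 5: 1}, 10), lonely, idx)


class TestProfile:
    def test_single_record_rpm(self, toy_family, toy_index):
        seq21 = toy_family.get("CHS4").sequence[:21]
        lib = _library({seq21: 10}, 1000)
        asn = sf.classify(lib, toy_family, toy_index)
        prof = sf.profile(asn, lib)
        assert prof.rpm.loc["CHS4", 21] == pytest.approx(10_000.0)
        assert prof.rpm.loc["CHS4"].drop(21).sum() == 0.0
        assert prof.gene_totals["CHS4"] == pytest.approx(10_000.0)

    def test_multimatch_double_counts_genes_once_per_group(
        self, toy_family, toy_index
    ):
        seq21 = toy_family.get("CHS4").sequence[:21]
        lib = _library({seq21: 5}, 1000)
        asn = sf.classify(lib, toy_family, toy_index)
        prof = sf.profile(asn, lib)
        assert prof.rpm.loc["CHS4", 21] == prof.rpm.loc["CHS4b", 21] == 5000.0
        assert prof.group_totals[GROUP1] == pytest.approx(5000.0)

    def test_fractional_attribution_splits_counts(self, toy_family, toy_index):
        seq21 = toy_family.get("CHS4").sequence[:21]
        lib = _library({seq21: 5}, 1000)
        asn = sf.classify(lib, toy_family, toy_index)
        prof = sf.profile(asn, lib, attribution="fractional")
        assert prof.rpm.loc["CHS4", 21] == pytest.approx(2500.0)
        assert prof.group_totals[GROUP1] == pytest.approx(5000.0)

    def test_label_rpm_conserves_library_total(self, toy_assignment):
        asn, lib = toy_assignment
        prof = sf.profile(asn, lib)
        expect = 1e6 * sum(lib.records.values()) / lib.total_trimmed_reads
        assert sum(prof.label_rpm.values()) == pytest.approx(expect)

    def test_empty_assignment_gives_zero_matrix(self, toy_family, toy_index):
        lib = _library({"ACGTACGTACGTACGTACGTA": 1}, 100)
        asn = sf.classify(lib, toy_family, toy_index)
        prof = sf.profile(asn, lib)
        assert prof.rpm.values.sum() == 0.0


class TestGeneRestrictedCounts:
    def test_exclusivity_and_lengths(self, toy_family, toy_index):
        a_seq = toy_family.get("CHS4").sequence
        b_seq = toy_family.get("CHS7").sequence
        lib = _library({a_seq[38:60]: 3, b_seq[1:22]: 2, SHARED20: 9}, 1000)
        asn = sf.classify(lib, toy_family, toy_index)
        tab = sf.gene_restricted_counts(asn, lib, "CHS4", "CHS7")
        assert tab.loc[22, "CHS4_only"] == pytest.approx(3000.0)
        assert tab.loc[21, "CHS7_only"] == pytest.approx(2000.0)
        # the shared 20-mer matches both genes, so it appears in neither
        assert tab.loc[20].sum() == 0.0

    def test_unknown_gene_rejected(self, toy_assignment):
        asn, lib = toy_assignment
        with pytest.raises(KeyError):
            sf.gene_restricted_counts(asn, lib, "CHS4", "NOPE")


class TestAmbiguityAudit:
    def test_zero_mm_audit_equals_ambiguous_rpm(self, toy_family, toy_index):
        a_seq = toy_family.get("CHS4").sequence
        lib = _library({SHARED20: 4, a_seq[:21]: 6}, 1000)
        asn = sf.classify(lib, toy_family, toy_index)
        prof = sf.profile(asn, lib)
        audit = sf.ambiguity_audit(lib, toy_family, toy_index)
        assert audit.table.loc["group1_vs_group2", 0] == pytest.approx(
            prof.label_rpm["ambiguous"]
        )

    def test_planted_two_mismatch_read_counted_only_at_two(
        self, toy_family, toy_index
    ):
        a_seq = toy_family.get("CHS4").sequence
        b_seq = toy_family.get("CHS7").sequence
        # a CHS4 21-mer two substitutions away from the CHS7 sequence
        read = a_seq[:21]
        dist_b = min(
            sum(x != y for x, y in zip(read, b_seq[i : i + 21]))
            for i in range(len(b_seq) - 20)
        )
        lib = _library({read: 5}, 1000)
        audit = sf.ambiguity_audit(lib, toy_family, toy_index, (0, 2, 3))
        assert audit.table.loc["group1_vs_group2", 0] == 0.0
        if dist_b <= 2:
            assert audit.table.loc["group1_vs_group2", 2] == pytest.approx(5000.0)

    def test_monotone_in_budget(self, synth_family, synth_index, rng):
        family, _ = synth_family
        g1 = [g for g in family if g.group_id == GROUP1]
        records = {}
        for _ in range(300):
            g = g1[int(rng.integers(len(g1)))]
            s = int(rng.integers(0, len(g) - 21))
            records[g.sequence[s : s + 21]] = records.get(g.sequence[s : s + 21], 0) + 1
        lib = _library(records, 10_000)
        audit = sf.ambiguity_audit(lib, family, synth_index, (0, 1, 2))
        row = audit.table.loc["group1_vs_group2"]
        assert row[0] <= row[1] <= row[2]
        assert row[2] > row[0] or row[2] == 0.0


class TestSeriesReport:
    def test_single_library_matches_profile(self, toy_family, toy_index):
        seq21 = toy_family.get("CHS4").sequence[:21]
        lib = _library({seq21: 10}, 1000, "only", "stage1")
        report = sf.series_report([lib], toy_family, toy_index)
        assert report.gene_rpm.loc[("stage1", "CHS4"), "rpm"] == pytest.approx(10_000)
        assert report.transition_stage is None

    def test_duplicate_library_ids_rejected(self, toy_family, toy_index):
        lib = _library({"ACGT" * 5 + "A": 1}, 100, "dup")
        with pytest.raises(ValueError):
            sf.series_report([lib, lib], toy_family, toy_index)

    def test_transition_found_when_group2_overtakes(self, toy_family, toy_index):
        a_seq = toy_family.get("CHS4").sequence[:21]
        b_seq = toy_family.get("CHS7").sequence[:21]
        libs = [
            _library({a_seq: 10}, 1000, "s0", "early"),
            _library({a_seq: 10, b_seq: 11}, 1000, "s1", "mid"),
            _library({a_seq: 1, b_seq: 50}, 1000, "s2", "late"),
        ]
        report = sf.series_report(libs, toy_family, toy_index)
        assert report.transition_stage == "mid"
        assert report.transition_index == 1

    def test_parameter_recovery_of_secondary_fraction(self):
        """With known secondary fraction f and no sequencing error, the
        estimated fraction group2/(group1+group2) lands within 3 binomial
        standard errors of f."""
        family, _ = sf.make_family(sf.SyntheticFamilySpec(), seed=5)
        index = sf.build_index(family)
        n = 20_000
        for i, f in enumerate((0.0, 0.1, 0.5, 0.9)):
            spec = sf.StageSpec(
                stage_label=f"f{f}",
                primary_rpm=(1 - f) * 1e6,
                secondary_rpm=f * 1e6,
                background_rpm=0.0,
                library_size=n,
                seed=100 + i,
            )
            lib = sf.simulate_stage(family, spec)
            asn = sf.classify(lib, family, index)
            counts = asn.label_counts()
            g1, g2 = counts["group1_unique"], counts["group2_unique"]
            est = g2 / (g1 + g2)
            se = np.sqrt(max(f * (1 - f), 1e-12) / n)
            assert abs(est - f) <= max(3 * se, 3 / n)
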