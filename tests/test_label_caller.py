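"""The four-criterion classifier, labeling proportions, and status calls."""

import numpy as np
import pytest

from sipcall import (
    LabelCall,
    LabelSet,
    PipelineConfig,
    ValidationError,
    call_fraction,
    call_phylotype,
    call_treatment,
    classify_importance,
    evaluate_criteria,
    labeling_proportions,
)
from sipcall.label_caller import CriteriaResult, TreatmentKey

from conftest import make_meta, make_table


def brute_force_labeled(ra13, ra12, ra13l):
    """Independent restatement of the four printed rules."""
    rule1 = ra13 > ra12                 # higher than the 12C fraction
    rule2 = ra13l < ra13                # light lower than the tested fraction
    rule3 = ra13 >= 0.5                 # at least 0.5% in the 13C fraction
    rule4 = (ra13 - ra12) >= 0.1        # at least 0.1 points above the control
    return rule1 and rule2 and rule3 and rule4


def member(pid, ra, fraction="H", key=None):
    key = key or TreatmentKey("16S", "substrate_sip", "methanol")
    criteria = CriteriaResult(
        c1=True, c2=True, c3=True, c4=True,
        fraction=fraction, ra_13c_frac=ra, ra_12c_frac=0.0, ra_13c_light=0.0,
    )
    return LabelCall(phylotype_id=pid, key=key, fraction=fraction, criteria=criteria)


class TestEvaluateCriteria:
    @pytest.mark.parametrize(
        "triple,passes,failing",
        [
            ((0.6, 0.4, 0.2), True, None),
            ((0.45, 0.0, 0.0), False, "c3"),   # below the 0.5% floor
            ((5.0, 4.95, 0.0), False, "c4"),   # difference 0.05 < 0.1
            ((0.5, 0.0, 0.5), False, "c2"),    # light not strictly lower
        ],
    )
    def test_printed_examples(self, triple, passes, failing, config):
        result = evaluate_criteria(*triple, "H", config)
        assert result.potentially_labeled is passes
        if failing:
            assert getattr(result, failing) is False

    def test_out_of_range_abundance_rejected(self, config):
        with pytest.raises(ValidationError):
            evaluate_criteria(101.0, 0.0, 0.0, "H", config)
        with pytest.raises(ValidationError):
            evaluate_criteria(1.0, -0.1, 0.0, "M", config)

    @pytest.mark.parametrize("fraction", ["H", "M"])
    def test_oracle_equivalence_random_triples(self, fraction, config):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            # mix smooth values with near-threshold ones
            ra13 = float(rng.choice([rng.uniform(0, 3), rng.uniform(0.4, 0.6)]))
            ra12 = float(rng.choice([rng.uniform(0, 3), ra13 - rng.uniform(0, 0.2)]))
            ra12 = min(max(ra12, 0.0), 100.0)
            ra13l = float(rng.uniform(0, 3))
            got = evaluate_criteria(ra13, ra12, ra13l, fraction, config)
            assert got.potentially_labeled == brute_force_labeled(ra13, ra12, ra13l)

    def test_monotone_in_13c_abundance(self, config):
        """Raising the 13C fraction abundance never turns a label off."""
        rng = np.random.default_rng(23)
        for _ in range(300):
            ra12 = float(rng.uniform(0, 2))
            ra13l = float(rng.uniform(0, 2))
            ra13 = float(rng.uniform(0, 3))
            bumped = min(ra13 + float(rng.uniform(0, 3)), 100.0)
            before = evaluate_criteria(ra13, ra12, ra13l, "H", config)
            after = evaluate_criteria(bumped, ra12, ra13l, "H", config)
            if before.potentially_labeled:
                assert after.potentially_labeled


class TestLabelingProportions:
    def test_arithmetic(self, config):
        key = TreatmentKey("16S", "substrate_sip", "methanol")
        ls = LabelSet(key=key, fraction="H",
                      members=[member("a", 3.0), member("b", 1.0)])
        out = labeling_proportions(ls, config)
        lps = {c.phylotype_id: c.lp for c in out.members}
        assert lps == {"a": 75.0, "b": 25.0}

    def test_single_member_is_100(self, config):
        key = TreatmentKey("16S", "substrate_sip", "methanol")
        ls = LabelSet(key=key, fraction="H", members=[member("a", 0.7)])
        out = labeling_proportions(ls, config)
        assert out.members[0].lp == 100.0

    def test_three_member_shares(self, config):
        key = TreatmentKey("16S", "substrate_sip", "methanol")
        ls = LabelSet(
            key=key, fraction="M",
            members=[member("a", 0.5, "M"), member("b", 0.5, "M"), member("c", 1.0, "M")],
        )
        lps = {c.phylotype_id: c.lp for c in labeling_proportions(ls, config).members}
        assert lps == {"a": 25.0, "b": 25.0, "c": 50.0}

    def test_empty_set_passes_through(self, config):
        key = TreatmentKey("16S", "substrate_sip", "methanol")
        ls = LabelSet(key=key, fraction="H")
        assert labeling_proportions(ls, config).n == 0

    def test_normalization_property(self, config):
        rng = np.random.default_rng(31)
        key = TreatmentKey("16S", "substrate_sip", "methanol")
        for _ in range(200):
            n = int(rng.integers(1, 12))
            ras = rng.uniform(0.5, 100.0 / n, size=n)
            ls = LabelSet(
                key=key, fraction="H",
                members=[member(f"t{i}", float(r)) for i, r in enumerate(ras)],
            )
            out = labeling_proportions(ls, config)
            assert abs(sum(c.lp for c in out.members) - 100.0) < 1e-9


class TestImportance:
    @pytest.mark.parametrize(
        "lp,expected", [(5.0, "major"), (4.99, "minor"), (100.0, "major"), (0.0, "minor")]
    )
    def test_threshold_inclusive(self, lp, expected, config):
        assert classify_importance(lp, config) == expected


def build_pooled_table(ra_by_lib, total=10_000):
    """Construct a pooled OtuTable realizing the given RA (%) per library."""
    metas, counts = [], {}
    for (isotope, pool), ras in ra_by_lib.items():
        lib = f"{isotope}_{pool}"
        metas.append(make_meta(lib, isotope=isotope, pool=pool))
        col = {pid: int(round(ra / 100.0 * total)) for pid, ra in ras.items()}
        used = sum(col.values())
        col["_filler"] = col.get("_filler", 0) + (total - used)
        counts[lib] = col
    return make_table(counts, metas)


class TestCallFraction:
    key = TreatmentKey("16S", "substrate_sip", "methanol")

    def test_single_passing_phylotype_gets_lp_100(self, config):
        table = build_pooled_table(
            {
                ("c13", "H"): {"a": 2.0, "b": 0.3},
                ("c12", "H"): {"a": 0.1, "b": 0.3},
                ("c13", "L"): {"a": 0.5, "b": 0.3},
            }
        )
        ls = labeling_proportions(call_fraction(table, self.key, "H", config), config)
        assert ls.n == 1 and ls.members[0].phylotype_id == "a"
        assert ls.members[0].lp == 100.0

    def test_no_passers_gives_empty_set(self, config):
        table = build_pooled_table(
            {
                ("c13", "H"): {"a": 0.3},
                ("c12", "H"): {"a": 0.3},
                ("c13", "L"): {"a": 0.3},
            }
        )
        ls = call_fraction(table, self.key, "H", config)
        assert ls.n == 0 and ls.members == []

    def test_absent_in_comparison_counts_as_zero(self, config):
        # phylotype absent from 12C H and 13C L: treated as RA 0, so it passes
        table = build_pooled_table(
            {
                ("c13", "H"): {"a": 1.0},
                ("c12", "H"): {},
                ("c13", "L"): {},
            }
        )
        ls = call_fraction(table, self.key, "H", config)
        assert ls.member_ids() == {"a"}

    def test_missing_library_error_names_coordinates(self, config):
        table = build_pooled_table(
            {("c13", "H"): {"a": 1.0}, ("c13", "L"): {"a": 0.1}}
        )
        with pytest.raises(ValidationError) as err:
            call_fraction(table, self.key, "H", config)
        message = str(err.value)
        assert "methanol" in message and "c12" in message and "'H'" in message

    def test_permutation_invariance(self, config):
        ras = {
            ("c13", "H"): {"a": 2.0, "b": 1.0, "c": 0.6},
            ("c12", "H"): {"a": 0.1},
            ("c13", "L"): {"b": 0.2},
        }
        table = build_pooled_table(ras)
        shuffled = table.counts.sample(frac=1.0, random_state=3)
        from sipcall import OtuTable

        table2 = OtuTable(counts=shuffled, libraries=table.libraries)
        ls1 = labeling_proportions(call_fraction(table, self.key, "H", config), config)
        ls2 = labeling_proportions(call_fraction(table2, self.key, "H", config), config)
        assert [(c.phylotype_id, c.lp) for c in ls1.members] == [
            (c.phylotype_id, c.lp) for c in ls2.members
        ]


class TestCallPhylotype:
    key = TreatmentKey("16S", "substrate_sip", "methanol")

    def make_sets(self, h_ids, m_ids):
        h = LabelSet(key=self.key, fraction="H",
                     members=[member(p, 1.0, "H") for p in h_ids])
        m = LabelSet(key=self.key, fraction="M",
                     members=[member(p, 1.0, "M") for p in m_ids])
        return h, m

    def test_h_only_is_labeled(self):
        h, m = self.make_sets(["x"], [])
        assert call_phylotype(h, m, "x").status == "labeled"

    def test_m_only_is_weakly_labeled(self):
        h, m = self.make_sets([], ["x"])
        assert call_phylotype(h, m, "x").status == "weakly_labeled"

    def test_both_is_labeled_with_two_calls_retained(self):
        h, m = self.make_sets(["x"], ["x"])
        status = call_phylotype(h, m, "x")
        assert status.status == "labeled"
        assert {c.fraction for c in status.calls} == {"H", "M"}

    def test_neither_is_unlabeled(self):
        h, m = self.make_sets(["y"], ["z"])
        assert call_phylotype(h, m, "x").status == "unlabeled"


def test_call_treatment_statuses_cover_both_fractions(config):
    table = build_pooled_table(
        {
            ("c13", "H"): {"a": 2.0},
            ("c12", "H"): {"a": 0.1},
            ("c13", "M"): {"b": 1.5, "a": 0.2},
            ("c12", "M"): {"b": 0.2},
            ("c13", "L"): {"a": 0.1, "b": 0.1},
        }
    )
    key = TreatmentKey("16S", "substrate_sip", "methanol")
    tc = call_treatment(table, key, config)
    assert tc.statuses["a"].status == "labeled"
    assert tc.statuses["b"].status == "weakly_labeled"
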