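"""Peptidome statistics against brute-force oracles and forced examples."""

import numpy as np
import pandas as pd
import pytest

from pairscan import peptidome as pep
from pairscan import synthetic
from pairscan.config import SyntheticConfig

from conftest import random_peptide_table


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------

def brute_collapse(table):
    """Group-and-sum over charge states, NaN only when all charges missing."""
    totals = {}
    samples = table.samples
    for _, row in table.data.iterrows():
        acc = totals.setdefault(row["sequence"], [None] * len(samples))
        for j, s in enumerate(samples):
            v = row[s]
            if not np.isnan(v):
                acc[j] = v if acc[j] is None else acc[j] + v
    return {seq: [np.nan if v is None else v for v in acc]
            for seq, acc in totals.items()}


def brute_ip_fraction(table, sample):
    ip = pp = 0.0
    for _, row in table.data.iterrows():
        v = row[sample]
        if np.isnan(v):
            continue
        last = row["sequence"][-1]
        if last in pep.IP_RESIDUES:
            ip += v
        elif last in pep.PP_RESIDUES:
            pp += v
    return np.nan if ip + pp == 0 else ip / (ip + pp)


def brute_length_fraction(table, sample, lo=8, hi=12):
    num = den = 0.0
    for _, row in table.data.iterrows():
        v = row[sample]
        if np.isnan(v):
            continue
        den += v
        if lo <= len(row["sequence"]) <= hi:
            num += v
    return np.nan if den == 0 else num / den


# ---------------------------------------------------------------------------

class TestIO:
    def test_round_trip_bit_identical(self, tmp_path, rng):
        table = random_peptide_table(rng)
        pep.write_peptide_table(table, tmp_path / "t.tsv", tmp_path / "d.tsv")
        back = pep.read_peptide_table(tmp_path / "t.tsv", tmp_path / "d.tsv")
        pd.testing.assert_frame_equal(table.data, back.data)

    def test_empty_data_section_is_ok(self, tmp_path, rng):
        table = random_peptide_table(rng, n_peptides=1)
        table.data = table.data.iloc[:0]
        pep.write_peptide_table(table, tmp_path / "t.tsv", tmp_path / "d.tsv")
        back = pep.read_peptide_table(tmp_path / "t.tsv", tmp_path / "d.tsv")
        assert len(back) == 0

    def test_design_sample_mismatch_raises(self, rng):
        table = random_peptide_table(rng)
        with pytest.raises(pep.SchemaError):
            pep.PeptideTable(table.data,
                             table.design.iloc[:-1]).validate()

    def test_invalid_residue_names_row(self, rng):
        table = random_peptide_table(rng, n_peptides=3)
        table.data.loc[1, "sequence"] = "AXC"
        with pytest.raises(pep.SchemaError, match="row"):
            table.validate()


class TestCollapse:
    def test_two_charges_sum(self, rng):
        table = random_peptide_table(rng, n_peptides=1, n_samples=1,
                                     missing_rate=0.0, max_charge=2)
        table.data = pd.DataFrame(
            {"sequence": ["PEPTIDEK", "PEPTIDEK"], "charge": [2, 3],
             "s0": [10.0, 5.0]})
        out = pep.collapse_charge_states(table)
        assert len(out) == 1
        assert out.data["s0"].iloc[0] == 15.0

    def test_single_charge_unchanged(self, rng):
        table = random_peptide_table(rng, max_charge=1, missing_rate=0.0)
        out = pep.collapse_charge_states(table)
        np.testing.assert_allclose(
            out.data[out.samples].to_numpy(),
            table.data[table.samples].to_numpy())

    def test_matches_brute_force_group_and_sum(self, rng):
        table = random_peptide_table(rng, n_peptides=40, missing_rate=0.3)
        out = pep.collapse_charge_states(table)
        expected = brute_collapse(table)
        assert set(out.data["sequence"]) == set(expected)
        for _, row in out.data.iterrows():
            np.testing.assert_allclose(
                [row[s] for s in out.samples], expected[row["sequence"]])

    def test_conserves_total_intensity(self, rng):
        table = random_peptide_table(rng, missing_rate=0.2)
        out = pep.collapse_charge_states(table)
        for s in table.samples:
            assert np.nansum(out.data[s]) == pytest.approx(
                np.nansum(table.data[s]))

    def test_all_missing_stays_missing(self):
        design = pd.DataFrame({"treatment": ["a"], "cell": ["x"],
                               "replicate": [1]}, index=["s0"])
        data = pd.DataFrame({"sequence": ["AAAK", "AAAK"], "charge": [2, 3],
                             "s0": [np.nan, np.nan]})
        out = pep.collapse_charge_states(pep.PeptideTable(data, design))
        assert np.isnan(out.data["s0"].iloc[0])


class TestClassifyCterm:
    def test_phf6_tau_peptide_is_immunoproteasome(self):
        # C-terminal K of the PHF6-motif-containing tau peptide
        assert pep.classify_cterm("HVPGGGSVQIVYKPVDLSK") == "immunoproteasome"

    @pytest.mark.parametrize("seq,expected", [
        ("AAAAD", "constitutive"),
        ("AAAAP", "unassigned"),
        ("AC", "unassigned"),
        ("GGF", "immunoproteasome"),
    ])
    def test_examples(self, seq, expected):
        assert pep.classify_cterm(seq) == expected

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            pep.classify_cterm("")

    def test_partition_covers_alphabet(self):
        """Every standard residue maps to exactly one class."""
        for aa in pep.AMINO_ACIDS:
            cls = pep.classify_cterm("A" + aa)
            assert cls in ("immunoproteasome", "constitutive", "unassigned")
        assert pep.IP_RESIDUES | pep.PP_RESIDUES | pep.UNASSIGNED_RESIDUES \
            == frozenset(pep.AMINO_ACIDS)
        assert not pep.IP_RESIDUES & pep.PP_RESIDUES


def _single_sample_table(rows):
    design = pd.DataFrame({"treatment": ["a"], "cell": ["x"],
                           "replicate": [1]}, index=["s0"])
    data = pd.DataFrame(rows, columns=["sequence", "s0"])
    return pep.PeptideTable(data, design, collapsed=True)


class TestIpFraction:
    def test_three_to_one(self):
        t = _single_sample_table([("AAAK", 3.0), ("AAAD", 1.0)])
        assert pep.ip_fraction(t, "s0") == 0.75

    def test_all_constitutive_is_zero(self):
        t = _single_sample_table([("AAAD", 3.0), ("AAAE", 1.0)])
        assert pep.ip_fraction(t, "s0") == 0.0

    def test_zero_denominator_flagged_nan(self):
        t = _single_sample_table([("AAAP", 3.0)])   # unassigned only
        assert np.isnan(pep.ip_fraction(t, "s0"))

    def test_odds_mode(self):
        t = _single_sample_table([("AAAK", 3.0), ("AAAD", 1.0)])
        assert pep.ip_fraction(t, "s0", mode="odds") == 3.0

    def test_matches_brute_force(self, rng):
        table = pep.collapse_charge_states(
            random_peptide_table(rng, n_peptides=500, missing_rate=0.1))
        for s in table.samples:
            got = pep.ip_fraction(table, s)
            want = brute_ip_fraction(table, s)
            assert got == pytest.approx(want, nan_ok=True)

    def test_scale_invariance_and_monotonicity(self, rng):
        table = pep.collapse_charge_states(
            random_peptide_table(rng, missing_rate=0.0))
        s = table.samples[0]
        base = pep.ip_fraction(table, s)
        scaled = table.data.copy()
        scaled[s] *= 7.5
        assert pep.ip_fraction(pep.PeptideTable(scaled, table.design,
                                                collapsed=True), s) \
            == pytest.approx(base)
        bumped = table.data.copy()
        is_ip = bumped["sequence"].str[-1].isin(list(pep.IP_RESIDUES))
        bumped.loc[is_ip, s] *= 3.0
        assert pep.ip_fraction(pep.PeptideTable(bumped, table.design,
                                                collapsed=True), s) >= base


class TestLengthFraction:
    def test_half(self):
        t = _single_sample_table([("A" * 8, 2.0), ("A" * 12, 2.0),
                                  ("A" * 15, 4.0)])
        assert pep.length_fraction(t, "s0") == 0.5

    def test_all_in_window_is_one(self):
        t = _single_sample_table([("A" * 9, 2.0), ("A" * 11, 5.0)])
        assert pep.length_fraction(t, "s0") == 1.0

    def test_window_inclusive_at_both_ends(self):
        inside = _single_sample_table([("A" * 8, 1.0), ("A" * 12, 1.0)])
        outside = _single_sample_table([("A" * 7, 1.0), ("A" * 13, 1.0)])
        assert pep.length_fraction(inside, "s0") == 1.0
        assert pep.length_fraction(outside, "s0") == 0.0

    def test_matches_brute_force(self, rng):
        table = pep.collapse_charge_states(
            random_peptide_table(rng, n_peptides=300, missing_rate=0.1))
        for s in table.samples:
            assert pep.length_fraction(table, s) == pytest.approx(
                brute_length_fraction(table, s), nan_ok=True)

    def test_no_detection_flagged_nan(self):
        t = _single_sample_table([("A" * 9, np.nan)])
        assert np.isnan(pep.length_fraction(t, "s0"))


class TestRestrictToProtein:
    def test_exact_match_and_absence(self):
        t = _single_sample_table([("MKV", 1.0), ("WWW", 1.0)])
        out = pep.restrict_to_protein(t, "MKV")
        assert list(out.data["sequence"]) == ["MKV"]

    def test_matches_brute_force_substring_search(self, rng):
        parent = synthetic.gen_parent_protein(3, length=200)
        table = pep.collapse_charge_states(
            random_peptide_table(rng, n_peptides=100))
        extra = _single_sample_table([(parent[10:20], 1.0)])
        out = pep.restrict_to_protein(table, parent)
        expected = {s for s in table.data["sequence"] if s in parent}
        assert set(out.data["sequence"]) == expected
        assert pep.restrict_to_protein(extra, parent).data.shape[0] == 1


class TestAggregationScore:
    def test_single_peptide_returns_its_score(self):
        t = _single_sample_table([("A" * 10, 5.0)])
        s = pep.default_aggregation_scorer("A" * 10)
        assert pep.aggregation_score(t, "s0") == pytest.approx(s)

    def test_equal_weights_average(self):
        scorer = pep.AggregationScorer(
            fn=lambda seq: 1.0 if seq[0] == "V" else 0.0, name="toy")
        t = _single_sample_table([("V" + "A" * 9, 2.0), ("A" * 10, 2.0)])
        assert pep.aggregation_score(t, "s0", scorer=scorer) == 0.5

    def test_length_window_6_to_15_inclusive(self):
        scorer = pep.AggregationScorer(fn=lambda seq: 1.0, name="const")
        t = _single_sample_table([("A" * 5, 100.0), ("A" * 16, 100.0),
                                  ("A" * 6, 1.0), ("A" * 15, 1.0)])
        # out-of-window peptides contribute to neither sum
        assert pep.aggregation_score(t, "s0", scorer=scorer) == 1.0
        only_out = _single_sample_table([("A" * 5, 1.0), ("A" * 16, 1.0)])
        assert np.isnan(pep.aggregation_score(only_out, "s0", scorer=scorer))

    def test_score_within_contributing_range(self, rng):
        table = pep.collapse_charge_states(
            random_peptide_table(rng, missing_rate=0.0))
        s = table.samples[0]
        val = pep.aggregation_score(table, s)
        lengths = table.data["sequence"].str.len()
        in_range = table.data.loc[lengths.between(6, 15), "sequence"]
        scores = [pep.default_aggregation_scorer(x) for x in in_range]
        assert min(scores) <= val <= max(scores)


def brute_two_way_anova(y, a, b):
    """Textbook balanced two-way ANOVA sums of squares."""
    y, a, b = np.asarray(y, float), np.asarray(a), np.asarray(b)
    grand = y.mean()
    ss = {}
    lev_a, lev_b = np.unique(a), np.unique(b)
    n_cell = len(y) / (len(lev_a) * len(lev_b))
    ss["A"] = sum((y[a == la].mean() - grand) ** 2 * (a == la).sum()
                  for la in lev_a)
    ss["B"] = sum((y[b == lb].mean() - grand) ** 2 * (b == lb).sum()
                  for lb in lev_b)
    ss_cells = sum(((y[(a == la) & (b == lb)].mean() - grand) ** 2) * n_cell
                   for la in lev_a for lb in lev_b)
    ss["AB"] = ss_cells - ss["A"] - ss["B"]
    ss["err"] = sum((y[(a == la) & (b == lb)]
                     - y[(a == la) & (b == lb)].mean()) ** 2
                    for la in lev_a for lb in lev_b).sum()
    df_a, df_b = len(lev_a) - 1, len(lev_b) - 1
    df_ab = df_a * df_b
    df_err = len(y) - len(lev_a) * len(lev_b)
    ms_err = ss["err"] / df_err
    return {"A": (ss["A"] / df_a) / ms_err,
            "B": (ss["B"] / df_b) / ms_err,
            "AB": (ss["AB"] / df_ab) / ms_err}


def _design_2x2(n_rep):
    rows = []
    for t in ("untreated", "IFNg"):
        for c in ("H4", "BAG2_KD"):
            for r in range(1, n_rep + 1):
                rows.append((f"{t}.{c}.{r}", t, c, r))
    return pd.DataFrame(
        [(r[1], r[2], r[3]) for r in rows],
        columns=["treatment", "cell", "replicate"],
        index=[r[0] for r in rows])


class TestCompareGroups:
    def test_f_matches_sums_of_squares_oracle(self, rng):
        design = _design_2x2(4)
        y = pd.Series(rng.normal(size=len(design)), index=design.index)
        res = pep.compare_groups(y, design)
        want = brute_two_way_anova(y.to_numpy(),
                                   design["treatment"].to_numpy(),
                                   design["cell"].to_numpy())
        got = res.anova["F"]
        assert got["C(treatment)"] == pytest.approx(want["A"])
        assert got["C(cell)"] == pytest.approx(want["B"])
        assert got["C(treatment):C(cell)"] == pytest.approx(want["AB"])

    def test_planted_main_effect_recovered(self):
        """A planted treatment effect is detected while cell and interaction
        stay null at alpha=0.05 (majority across seeds)."""
        hits_a, false_b = 0, 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            design = _design_2x2(4)
            y = pd.Series(r.normal(size=len(design)), index=design.index)
            y[design["treatment"] == "IFNg"] += 3.0
            res = pep.compare_groups(y, design)
            p = res.anova["PR(>F)"]
            hits_a += p["C(treatment)"] < 0.05
            false_b += p["C(cell)"] < 0.05
        assert hits_a >= 18
        assert false_b <= 4

    def test_constant_response_flagged_degenerate(self):
        design = _design_2x2(2)
        y = pd.Series(1.0, index=design.index)
        res = pep.compare_groups(y, design)
        assert res.degenerate
        assert res.anova["F"].isna().all()

    def test_underreplicated_cell_named_in_error(self):
        design = _design_2x2(2).iloc[:-1]   # last cell has 1 replicate
        y = pd.Series(np.arange(len(design), dtype=float), index=design.index)
        with pytest.raises(ValueError, match="BAG2_KD"):
            pep.compare_groups(y, design)

    def test_tukey_table_present(self, rng):
        design = _design_2x2(3)
        y = pd.Series(rng.normal(size=len(design)), index=design.index)
        res = pep.compare_groups(y, design)
        assert res.tukey is not None and len(res.tukey) == 6  # C(4,2) pairs
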