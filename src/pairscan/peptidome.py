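"""Peptide-level immunopeptidome statistics.

The unit of analysis is a peptide quantification table: peptide sequences with
charge states and per-sample precursor intensities, plus a sample design table
(treatment x cell-line factors). The statistics computed here are the ones a
proteasome-specificity analysis needs:

* charge-state collapsing (precursor quantities summed per peptide sequence);
* C-terminal cleavage classification into immunoproteasome-type
  (hydrophobic/basic C-termini) vs constitutive-proteasome-type
  (acidic/small-polar C-termini);
* the per-sample intensity-weighted immunoproteasome fraction (IP:PP);
* the MHC-I-compatible length fraction (intensity share of 8-12 aa peptides);
* an abundance-weighted mean aggregation-propensity score over 6-15-mers;
* a two-way (treatment x cell) ANOVA with Tukey post-hoc over any per-sample
  statistic.

Missing intensities mean "not detected" and contribute zero weight to the
summary statistics; no peptide-level imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS", "IP_RESIDUES", "PP_RESIDUES", "UNASSIGNED_RESIDUES",
    "PeptideTable", "AggregationScorer", "GroupComparison",
    "read_peptide_table", "write_peptide_table",
    "collapse_charge_states", "classify_cterm", "ip_fraction",
    "length_fraction", "restrict_to_protein", "aggregation_score",
    "default_aggregation_scorer", "compare_groups",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: C-terminal residues diagnostic of immunoproteasome (chymotryptic/tryptic-like)
#: cleavage.
IP_RESIDUES = frozenset("FYLIVWMRK")
#: C-terminal residues diagnostic of constitutive-proteasome (caspase-like /
#: small-polar) cleavage.
PP_RESIDUES = frozenset("DESTAGQN")
#: Residues in neither diagnostic set; peptides ending here are left unassigned
#: and excluded from both the numerator and denominator of the IP fraction.
UNASSIGNED_RESIDUES = frozenset("CHP")

assert IP_RESIDUES | PP_RESIDUES | UNASSIGNED_RESIDUES == frozenset(AMINO_ACIDS)
assert not (IP_RESIDUES & PP_RESIDUES)


class SchemaError(ValueError):
    """Table/design mismatch or malformed input."""


@dataclass
class PeptideTable:
    """Peptide x sample intensity table with its sample design.

    ``data`` columns: ``sequence``, ``charge`` (absent after charge collapsing),
    then one float column per sample (NaN = not detected). ``design`` is indexed
    by sample id with columns ``treatment``, ``cell``, ``replicate``.
    """

    data: pd.DataFrame
    design: pd.DataFrame
    collapsed: bool = False

    @property
    def samples(self) -> list:
        return list(self.design.index)

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> "PeptideTable":
        cols = [c for c in self.data.columns if c not in ("sequence", "charge")]
        if set(cols) != set(self.design.index):
            missing = set(self.design.index) - set(cols)
            extra = set(cols) - set(self.design.index)
            raise SchemaError(
                f"sample columns and design rows differ (missing={sorted(missing)}, "
                f"extra={sorted(extra)})")
        for col in ("treatment", "cell", "replicate"):
            if col not in self.design.columns:
                raise SchemaError(f"design table lacks column {col!r}")
        triples = self.design[["treatment", "cell", "replicate"]]
        if triples.duplicated().any():
            raise SchemaError("(treatment, cell, replicate) triples must be unique")
        bad = ~self.data["sequence"].map(_is_valid_sequence)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"row {row}: invalid residue in sequence "
                f"{self.data['sequence'].iloc[row]!r}")
        if self.collapsed and self.data["sequence"].duplicated().any():
            raise SchemaError("collapsed table has duplicate sequences")
        return self


def _is_valid_sequence(seq: object) -> bool:
    return (isinstance(seq, str) and len(seq) >= 1
            and all(ch in AMINO_ACIDS for ch in seq))


def read_peptide_table(path, design_path) -> PeptideTable:
    """Read a peptide TSV (sequence, charge, one column per sample) + design TSV.

    Empty intensity cells are recorded as missing (NaN), never as zero.
    """
    data = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    design = pd.read_csv(design_path, sep="\t", index_col="sample_id")
    if "sequence" not in data.columns:
        raise SchemaError("peptide table lacks a 'sequence' column")
    collapsed = "charge" not in data.columns
    if not collapsed:
        data["charge"] = data["charge"].astype(int)
    sample_cols = [c for c in data.columns if c not in ("sequence", "charge")]
    data[sample_cols] = data[sample_cols].astype(float)
    return PeptideTable(data=data, design=design, collapsed=collapsed).validate()


def write_peptide_table(table: PeptideTable, path, design_path) -> None:
    table.data.to_csv(path, sep="\t", index=False)
    table.design.to_csv(design_path, sep="\t", index_label="sample_id")


def collapse_charge_states(table: PeptideTable) -> PeptideTable:
    """Sum precursor intensities across charge states for each peptide sequence.

    A cell missing in every charge state stays missing (the sum of nothing is
    not zero); a cell observed in any charge state is the sum of the observed
    ones.
    """
    if table.collapsed or "charge" not in table.data.columns:
        return PeptideTable(table.data.copy(), table.design, collapsed=True)
    sample_cols = table.samples
    grouped = (table.data.groupby("sequence", sort=False)[sample_cols]
               .sum(min_count=1).reset_index())
    return PeptideTable(grouped, table.design, collapsed=True).validate()


def classify_cterm(sequence: str) -> str:
    """Classify a peptide by its C-terminal residue.

    Returns ``"immunoproteasome"`` (C-term in FYLIVWMRK), ``"constitutive"``
    (C-term in DESTAGQN) or ``"unassigned"`` (C, H or P, which belong to
    neither diagnostic set).
    """
    if not sequence:
        raise ValueError("cannot classify an empty sequence")
    last = sequence[-1]
    if last in IP_RESIDUES:
        return "immunoproteasome"
    if last in PP_RESIDUES:
        return "constitutive"
    if last in UNASSIGNED_RESIDUES:
        return "unassigned"
    raise ValueError(f"unknown residue {last!r}")


def _sample_intensities(table: PeptideTable, sample) -> np.ndarray:
    if sample not in table.design.index:
        raise KeyError(f"unknown sample {sample!r}")
    return table.data[sample].to_numpy(dtype=float)


def ip_fraction(table: PeptideTable, sample, mode: str = "fraction") -> float:
    """Intensity-weighted immunoproteasome share for one sample.

    ``mode="fraction"`` (default) returns IP / (IP + PP); ``mode="odds"``
    returns the odds IP / PP. Unassigned peptides are excluded from both sums;
    missing intensities contribute zero. Returns NaN when the relevant
    denominator is zero (undefined, not "no immunoproteasome activity").
    """
    if not table.collapsed:
        raise ValueError("collapse charge states before computing ip_fraction")
    if mode not in ("fraction", "odds"):
        raise ValueError("mode must be 'fraction' or 'odds'")
    inten = np.nan_to_num(_sample_intensities(table, sample), nan=0.0)
    classes = table.data["sequence"].map(classify_cterm).to_numpy()
    ip = inten[classes == "immunoproteasome"].sum()
    pp = inten[classes == "constitutive"].sum()
    denom = ip + pp if mode == "fraction" else pp
    if denom == 0:
        return float("nan")
    return float(ip / denom)


def length_fraction(table: PeptideTable, sample, lo: int = 8, hi: int = 12) -> float:
    """Intensity share of peptides whose length is in the inclusive window [lo, hi].

    The denominator is the total intensity of all detected peptides regardless
    of cleavage class. NaN when nothing is detected in the sample.
    """
    if not table.collapsed:
        raise ValueError("collapse charge states before computing length_fraction")
    inten = np.nan_to_num(_sample_intensities(table, sample), nan=0.0)
    total = inten.sum()
    if total == 0:
        return float("nan")
    lengths = table.data["sequence"].str.len().to_numpy()
    in_window = (lengths >= lo) & (lengths <= hi)
    return float(inten[in_window].sum() / total)


def restrict_to_protein(table: PeptideTable, parent_sequence: str) -> PeptideTable:
    """Keep only peptides that are exact substrings of a parent protein."""
    keep = table.data["sequence"].map(lambda s: s in parent_sequence)
    return PeptideTable(table.data.loc[keep].reset_index(drop=True),
                        table.design, collapsed=table.collapsed)


@dataclass(frozen=True)
class AggregationScorer:
    """Pluggable peptide -> aggregation-propensity score contract.

    ``fn`` must be deterministic and defined for all peptides of length 6-15.
    """

    fn: Callable[[str], float]
    name: str
    version: str = "1"

    def __call__(self, sequence: str) -> float:
        return float(self.fn(sequence))


_AGG_PRONE = frozenset("VILFYWMC")
_AGG_BREAKING = frozenset("PGDEKR")


def _composition_heuristic(sequence: str) -> float:
    n = len(sequence)
    prone = sum(ch in _AGG_PRONE for ch in sequence) / n
    breaking = sum(ch in _AGG_BREAKING for ch in sequence) / n
    return 0.5 * (prone - breaking + 1.0)   # rescale [-1, 1] -> [0, 1]


#: Composition heuristic stand-in scorer: fraction of beta/amyloid-prone
#: residues (V,I,L,F,Y,W,M,C) minus fraction of aggregation-breaking residues
#: (P,G,D,E,K,R), rescaled to [0, 1]. A placeholder for a trained
#: aggregation-propensity model, which is a pluggable input here.
default_aggregation_scorer = AggregationScorer(
    fn=_composition_heuristic, name="composition-heuristic", version="1")


def aggregation_score(table: PeptideTable, sample,
                      scorer: AggregationScorer = default_aggregation_scorer,
                      len_lo: int = 6, len_hi: int = 15) -> float:
    """Abundance-weighted mean aggregation score over peptides of length 6-15.

    Weights are raw (not log) precursor intensities; peptides outside the
    inclusive length window contribute to neither sum. NaN when no peptide
    passes the filter with nonzero intensity.
    """
    if not table.collapsed:
        raise ValueError("collapse charge states before computing aggregation_score")
    inten = np.nan_to_num(_sample_intensities(table, sample), nan=0.0)
    lengths = table.data["sequence"].str.len().to_numpy()
    mask = (lengths >= len_lo) & (lengths <= len_hi) & (inten > 0)
    if not mask.any():
        return float("nan")
    scores = np.array([scorer(s) for s in table.data["sequence"][mask]])
    w = inten[mask]
    return float(np.sum(w * scores) / np.sum(w))


@dataclass
class GroupComparison:
    """Two-way ANOVA result over a per-sample statistic.

    ``anova`` has one row per term (treatment, cell, interaction, residual)
    with sum_sq, df, F and p; ``tukey`` holds all pairwise treatment-x-cell
    cell-mean comparisons with familywise-adjusted p. ``degenerate`` is True
    when the response has zero variance (F undefined).
    """

    anova: pd.DataFrame
    tukey: Optional[pd.DataFrame]
    degenerate: bool = False


def compare_groups(per_sample_stat, design: pd.DataFrame) -> GroupComparison:
    """Two-way ANOVA (treatment x cell) with Tukey HSD post-hoc.

    ``per_sample_stat`` maps sample id -> statistic (dict or Series), one value
    per design row. Every (treatment, cell) cell must hold >= 2 replicates.
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    stat = pd.Series(per_sample_stat, dtype=float).reindex(design.index)
    if stat.isna().any():
        missing = list(stat.index[stat.isna()])
        raise ValueError(f"statistic missing for samples {missing}")
    frame = design.copy()
    frame["y"] = stat
    counts = frame.groupby(["treatment", "cell"], observed=True).size()
    small = counts[counts < 2]
    if len(small):
        cell = small.index[0]
        raise ValueError(
            f"design cell (treatment={cell[0]!r}, cell={cell[1]!r}) has "
            f"{int(small.iloc[0])} replicate(s); need >= 2")
    if np.ptp(stat.to_numpy()) == 0:
        idx = ["C(treatment)", "C(cell)", "C(treatment):C(cell)", "Residual"]
        anova = pd.DataFrame(np.nan, index=idx,
                             columns=["sum_sq", "df", "F", "PR(>F)"])
        return GroupComparison(anova=anova, tukey=None, degenerate=True)
    model = ols("y ~ C(treatment) * C(cell)", data=frame).fit()
    anova = anova_lm(model, typ=2)
    groups = (frame["treatment"].astype(str) + ":" + frame["cell"].astype(str))
    tk = pairwise_tukeyhsd(frame["y"].to_numpy(), groups.to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:],
                         columns=[str(c) for c in tk.summary().data[0]])
    return GroupComparison(anova=anova, tukey=tukey, degenerate=False)
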