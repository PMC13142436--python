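"""Structure-motif signature analysis.

A protein's structure profile (sequence, 3-state secondary structure H/E/C,
per-residue relative solvent accessibility) is decomposed into maximal
same-state runs; every window of three consecutive runs whose combined span is
25-35 residues is a candidate motif. Candidates are kept when strictly more
than 40% of their residues are solvent-exposed (rSASA strictly above 0.2).
Retained motifs are embedded, scored with the full-protein classifier, and the
top vs bottom score quartiles are contrasted feature-by-feature with two-sided
Mann-Whitney U tests and Benjamini-Hochberg adjustment, over an interpretable
panel of sequence-composition features.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from math import comb
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

__all__ = [
    "StructureProfile", "SecondaryElement", "Motif", "ContrastResult",
    "collapse_dssp", "read_structure_profiles", "write_structure_profiles",
    "segment_elements", "enumerate_composites", "exposure_filter",
    "composition_features", "FEATURE_GROUPS", "mann_whitney_u",
    "score_motifs", "quartile_contrast",
]

SS_STATES = "HEC"

# standard DSSP 8-state -> 3-state collapse
_DSSP_COLLAPSE = {"G": "H", "H": "H", "I": "H", "B": "E", "E": "E"}


def collapse_dssp(ss8: str) -> str:
    """Collapse a DSSP-style 8-state string to 3 states (GHI->H, BE->E, rest->C)."""
    return "".join(_DSSP_COLLAPSE.get(ch, "C") for ch in ss8)


@dataclass
class StructureProfile:
    """One protein: sequence, 3-state secondary structure, per-residue rSASA."""

    protein_id: str
    sequence: str
    ss: str
    rsasa: np.ndarray

    def __post_init__(self):
        self.rsasa = np.asarray(self.rsasa, dtype=float)
        n = len(self.sequence)
        if len(self.ss) != n or len(self.rsasa) != n:
            raise ValueError(
                f"{self.protein_id}: sequence, ss and rsasa lengths differ")
        bad = set(self.ss) - set(SS_STATES)
        if bad:
            raise ValueError(
                f"{self.protein_id}: invalid secondary-structure state(s) {bad}")
        if ((self.rsasa < 0) | (self.rsasa > 1)).any():
            raise ValueError(f"{self.protein_id}: rsasa must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SecondaryElement:
    """A maximal same-state run, span [start, end) in residue coordinates."""

    state: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Motif:
    """A contiguous 3-element secondary-structure composite."""

    protein_id: str
    states: Tuple[str, ...]
    start: int
    end: int
    sequence: str
    ss: str
    rsasa: np.ndarray
    exposed_mask: Optional[np.ndarray] = None
    exposed_frac: Optional[float] = None
    features: Optional[Dict[str, float]] = None
    score: Optional[float] = None

    @property
    def length(self) -> int:
        return self.end - self.start


def read_structure_profiles(path) -> List[StructureProfile]:
    """Read the long-format profile TSV (protein_id, position, residue, ss, rsasa).

    Positions must be contiguous from 0 within each protein.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str,
                                            "ss": str})
    profiles = []
    for pid, grp in df.groupby("protein_id", sort=False):
        pos = grp["position"].to_numpy()
        if not np.array_equal(pos, np.arange(len(grp))):
            raise ValueError(f"{pid}: positions are not contiguous from 0")
        profiles.append(StructureProfile(
            protein_id=str(pid),
            sequence="".join(grp["residue"]),
            ss="".join(grp["ss"]),
            rsasa=grp["rsasa"].to_numpy(dtype=float)))
    return profiles


def write_structure_profiles(profiles: Iterable[StructureProfile], path) -> None:
    rows = []
    for p in profiles:
        for i in range(len(p)):
            rows.append((p.protein_id, i, p.sequence[i], p.ss[i], p.rsasa[i]))
    pd.DataFrame(rows, columns=["protein_id", "position", "residue", "ss",
                                "rsasa"]).to_csv(path, sep="\t", index=False)


def segment_elements(profile: StructureProfile) -> List[SecondaryElement]:
    """Maximal same-state runs, in order; spans tile the protein exactly."""
    elements = []
    start = 0
    for state, run in itertools.groupby(profile.ss):
        n = sum(1 for _ in run)
        elements.append(SecondaryElement(state=state, start=start, end=start + n))
        start += n
    return elements


def enumerate_composites(profile: StructureProfile,
                         elements: Optional[Sequence[SecondaryElement]] = None,
                         n_elements: int = 3,
                         len_lo: int = 25, len_hi: int = 35) -> List[Motif]:
    """Candidate motifs: every window of ``n_elements`` consecutive elements
    whose combined residue span is within [len_lo, len_hi] (inclusive)."""
    if elements is None:
        elements = segment_elements(profile)
    out = []
    for i in range(len(elements) - n_elements + 1):
        window = elements[i:i + n_elements]
        start, end = window[0].start, window[-1].end
        if len_lo <= end - start <= len_hi:
            out.append(Motif(
                protein_id=profile.protein_id,
                states=tuple(e.state for e in window),
                start=start, end=end,
                sequence=profile.sequence[start:end],
                ss=profile.ss[start:end],
                rsasa=profile.rsasa[start:end]))
    return out


def exposure_filter(candidates: Iterable[Motif],
                    rsasa_thresh: float = 0.2,
                    min_exposed_frac: float = 0.4) -> List[Motif]:
    """Keep motifs with strictly more than ``min_exposed_frac`` exposed residues.

    A residue is exposed iff its rSASA strictly exceeds ``rsasa_thresh``; a
    value of exactly 0.2 is buried, and a motif at exactly 40% exposure is
    rejected.
    """
    kept = []
    for m in candidates:
        mask = m.rsasa > rsasa_thresh
        frac = float(mask.mean())
        if frac > min_exposed_frac:
            kept.append(replace(m, exposed_mask=mask, exposed_frac=frac))
    return kept


# ---------------------------------------------------------------------------
# composition features
# ---------------------------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

FEATURE_GROUPS: Dict[str, str] = {
    "acidic": "DE",
    "positive": "KRH",
    "charged": "DEKR",
    "charged_h": "DEKRH",
    "polar": "STNQ",
    "hydrophobic": "AVILFYWM",
    "aromatic": "FYW",
    "amide": "NQ",
}


def composition_features(motif: Motif, scope: str = "full") -> Dict[str, float]:
    """Single-residue fractions, grouped-class fractions and net-charge summaries.

    ``scope="full"`` uses every motif residue; ``scope="exposed"`` restricts to
    residues flagged exposed (requires exposure_filter to have run). With zero
    exposed residues every feature is NaN (undefined, flagged, not zero).

    Net-charge summaries: ``net_charge`` = frac(K)+frac(R) - frac(D)-frac(E);
    ``net_charge_h`` additionally counts histidine at +0.1.
    """
    if scope not in ("full", "exposed"):
        raise ValueError("scope must be 'full' or 'exposed'")
    if scope == "exposed":
        if motif.exposed_mask is None:
            raise ValueError("motif has no exposure mask; run exposure_filter")
        residues = [ch for ch, keep in zip(motif.sequence, motif.exposed_mask)
                    if keep]
    else:
        residues = list(motif.sequence)
    names = ([f"frac_{aa}" for aa in AMINO_ACIDS] + list(FEATURE_GROUPS)
             + ["net_charge", "net_charge_h"])
    if not residues:
        return {name: float("nan") for name in names}
    n = len(residues)
    counts = {aa: 0 for aa in AMINO_ACIDS}
    for ch in residues:
        counts[ch] += 1
    frac = {aa: counts[aa] / n for aa in AMINO_ACIDS}
    features = {f"frac_{aa}": frac[aa] for aa in AMINO_ACIDS}
    for group, members in FEATURE_GROUPS.items():
        features[group] = sum(frac[aa] for aa in members)
    features["net_charge"] = frac["K"] + frac["R"] - frac["D"] - frac["E"]
    features["net_charge_h"] = features["net_charge"] + 0.1 * frac["H"]
    return features


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x: #{(i,j): x_i > y_j} + 0.5 #{x_i = y_j}."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(x, y, exact_max_n: int = 8) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for x, p).

    When both groups have at most ``exact_max_n`` observations the p-value is
    computed by exact enumeration of all group assignments of the pooled
    values (handling ties exactly); otherwise the normal approximation with
    tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(x, y)
    n1, n2 = len(x), len(y)
    if n1 <= exact_max_n and n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = np.arange(n1 + n2)
        us = np.fromiter(
            (_u_statistic(pooled[list(chosen)],
                          pooled[np.setdiff1d(idx, chosen, assume_unique=True)])
             for chosen in itertools.combinations(idx, n1)),
            dtype=float, count=comb(n1 + n2, n1))
        eps = 1e-9
        lower = float((us <= u_obs + eps).mean())
        upper = float((us >= u_obs - eps).mean())
        p = min(1.0, 2.0 * min(lower, upper))
        return u_obs, p
    _, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic", use_continuity=True)
    return u_obs, float(p)


# ---------------------------------------------------------------------------
# scoring and quartile contrast
# ---------------------------------------------------------------------------

def score_motifs(motifs: Sequence[Motif], embedder, model) -> List[Motif]:
    """Score motifs with the trained full-protein classifier.

    ``embedder`` maps a motif (cropped sequence + structure context) to a
    fixed-length vector; ``model`` is a trained classifier exposing
    ``predict_score`` (probabilities in [0, 1]). The embedding dimension must
    match the model's.
    """
    if not motifs:
        return []
    X = np.vstack([np.asarray(embedder(m), dtype=float) for m in motifs])
    if X.shape[1] != model.n_features_in:
        raise ValueError(
            f"embedding dimension {X.shape[1]} does not match classifier "
            f"input dimension {model.n_features_in}")
    scores = model.predict_score(X)
    return [replace(m, score=float(s)) for m, s in zip(motifs, scores)]


@dataclass
class ContrastResult:
    """Feature-wise high-vs-low-quartile contrast.

    ``table`` columns: median_high, median_low, U, p, q (BH over all features
    tested). ``n_high``/``n_low`` are the quartile group sizes.
    """

    table: pd.DataFrame
    n_high: int
    n_low: int
    score_q25: float
    score_q75: float

    def top_features(self, n: int = 10) -> pd.DataFrame:
        return self.table.sort_values(["q", "p"]).head(n)


def quartile_contrast(motifs: Sequence[Motif],
                      features: Optional[pd.DataFrame] = None,
                      scope: str = "full") -> ContrastResult:
    """Contrast composition features between top- and bottom-quartile motifs.

    Quartiles are taken over the global score distribution (linear
    interpolation percentiles); motifs whose score ties the quartile boundary
    join neither extreme group, so one value can never straddle both. Per
    feature: group medians and a two-sided Mann-Whitney U p (exact for small
    groups), BH-adjusted across the feature panel.
    """
    scored = [m for m in motifs if m.score is not None]
    if len(scored) < 8:
        raise ValueError("need at least 8 scored motifs for quartile groups")
    scores = np.array([m.score for m in scored])
    if np.ptp(scores) == 0:
        raise ValueError("all motif scores identical; quartile split degenerate")
    q25, q75 = np.percentile(scores, [25, 75])
    low_idx = np.flatnonzero(scores < q25)
    high_idx = np.flatnonzero(scores > q75)
    if len(low_idx) == 0 or len(high_idx) == 0:
        raise ValueError("quartile groups are empty after boundary-tie exclusion")
    if features is None:
        features = pd.DataFrame([composition_features(m, scope=scope)
                                 for m in scored])
    features = features.reset_index(drop=True)
    rows = {}
    pvals, names = [], []
    for name in features.columns:
        col = features[name].to_numpy(dtype=float)
        lo, hi = col[low_idx], col[high_idx]
        lo, hi = lo[~np.isnan(lo)], hi[~np.isnan(hi)]
        if len(lo) == 0 or len(hi) == 0 or (np.ptp(np.concatenate([lo, hi])) == 0):
            rows[name] = (np.median(hi) if len(hi) else np.nan,
                          np.median(lo) if len(lo) else np.nan, np.nan, np.nan)
            continue
        u, p = mann_whitney_u(hi, lo)
        rows[name] = (float(np.median(hi)), float(np.median(lo)), u, p)
        pvals.append(p)
        names.append(name)
    table = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["median_high", "median_low", "U", "p"])
    table["q"] = np.nan
    if pvals:
        table.loc[names, "q"] = bh_adjust(np.array(pvals))
    return ContrastResult(table=table, n_high=len(high_idx), n_low=len(low_idx),
                          score_q25=float(q25), score_q75=float(q75))
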