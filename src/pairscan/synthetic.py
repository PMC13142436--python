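"""Synthetic data with planted, recoverable ground truth.

Every downstream stage of the pipeline is exercised on data generated here:
peptide quantification tables with a planted immunoproteasome C-terminal bias
and MHC-I length-window share, protein intensity matrices with planted
differential features and missingness, structure profiles with Markov-chain
secondary structure, beta-distributed solvent exposure and an acidic-residue
enrichment in the positive class, composition-driven embedding vectors, and
identifier lists with an exact planted overlap.

All generators are pure functions of (config, seed): the master seed expands
into per-generator child seeds keyed by generator name, so adding a generator
never perturbs the streams of existing ones.

Design choices the generators embody: raw precursor intensities are
log-normal (label-free intensities are classically right-skewed); peptide
residues are i.i.d. draws apart from the planted C-terminal class and the
D/E shift (no homology structure); matrix missingness is completely at
random by default, with an optional intensity-dependent left-censoring mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import EmbeddingSet
from .config import ConfigError, SyntheticConfig, child_rng, child_seed
from .differential import IntensityMatrix
from .peptidome import (AMINO_ACIDS, IP_RESIDUES, PP_RESIDUES, PeptideTable)
from .structure import Motif, StructureProfile

__all__ = [
    "gen_peptidome", "gen_intensity_matrix", "SimulatedMatrix",
    "gen_structures", "gen_embeddings", "make_motif_embedder",
    "gen_id_lists", "gen_parent_protein", "gen_substring_peptides",
    "PHF6_PEPTIDE",
]

_IP_LIST = sorted(IP_RESIDUES)
_PP_LIST = sorted(PP_RESIDUES)
_AA = list(AMINO_ACIDS)

#: The aggregation-prone PHF6-motif-containing tau peptide used as a marker
#: sequence in the synthetic tau-like parent protein.
PHF6_PEPTIDE = "HVPGGGSVQIVYKPVDLSK"


def _default_design(config: SyntheticConfig,
                    treatments=("untreated", "IFNg"),
                    cells=("H4", "BAG2_KD")) -> pd.DataFrame:
    rows = []
    for t in treatments:
        for c in cells:
            for r in range(1, config.n_samples_per_group + 1):
                rows.append((f"{t}.{c}.r{r}", t, c, r))
    df = pd.DataFrame(rows, columns=["sample_id", "treatment", "cell",
                                     "replicate"])
    return df.set_index("sample_id")


def _random_peptide(rng: np.random.Generator, length: int,
                    cterm_pool: Sequence[str]) -> str:
    body = rng.choice(_AA, size=length - 1)
    cterm = cterm_pool[rng.integers(len(cterm_pool))]
    return "".join(body) + cterm


def gen_peptidome(config: SyntheticConfig,
                  treatments=("untreated", "IFNg"),
                  cells=("H4", "BAG2_KD")) -> PeptideTable:
    """Peptide table (lengths 6-25) with planted immunoproteasome and
    length-window intensity shares.

    With a scalar ``planted_ip_fraction`` each peptide's C-terminal class is a
    Bernoulli draw at that probability, and intensities are class-independent,
    so the per-sample intensity-weighted IP share converges to the planted
    value (and a planted value of exactly 1 forces every C-terminus into the
    IP set). With a per-treatment mapping (all values strictly inside (0, 1)),
    condition-specific intensity multipliers tilt each sample's share to its
    treatment's target. ``planted_len_fraction`` is handled the same way for
    the 8-12 aa window. A random subset of peptides is emitted at two charge
    states with the intensity split between them, for charge-collapse testing.
    """
    rng = config.rng("peptidome")
    design = _default_design(config, treatments, cells)
    n = config.n_peptides

    ip_spec = config.planted_ip_fraction
    len_spec = config.planted_len_fraction
    ip_map = isinstance(ip_spec, Mapping)
    len_map = isinstance(len_spec, Mapping)
    p0 = float(np.mean(list(ip_spec.values()))) if ip_map else float(ip_spec)
    q0 = float(np.mean(list(len_spec.values()))) if len_map else float(len_spec)
    if ip_map and not all(0 < v < 1 for v in ip_spec.values()):
        raise ConfigError("per-condition planted_ip_fraction must lie in (0, 1)")
    if len_map and not all(0 < v < 1 for v in len_spec.values()):
        raise ConfigError("per-condition planted_len_fraction must lie in (0, 1)")

    is_ip = rng.random(n) < p0
    in_window = rng.random(n) < q0
    out_lengths = np.array([6, 7] + list(range(13, 26)))
    sequences, seen = [], set()
    for i in range(n):
        length = (rng.integers(8, 13) if in_window[i]
                  else out_lengths[rng.integers(len(out_lengths))])
        pool = _IP_LIST if is_ip[i] else _PP_LIST
        seq = _random_peptide(rng, int(length), pool)
        while seq in seen:    # keep sequences unique pre-collapse
            seq = _random_peptide(rng, int(length), pool)
        seen.add(seq)
        sequences.append(seq)

    base = rng.lognormal(config.intensity_logmean, config.intensity_logsd,
                         size=(n, len(design)))
    for j, sample in enumerate(design.index):
        t = design.loc[sample, "treatment"]
        if ip_map:
            p_c = config.fraction_for("planted_ip_fraction", t)
            a = (p_c / (1 - p_c)) * ((1 - p0) / p0)
            base[is_ip, j] *= a
        if len_map:
            q_c = config.fraction_for("planted_len_fraction", t)
            b = (q_c / (1 - q_c)) * ((1 - q0) / q0)
            base[in_window, j] *= b

    dup = rng.random(n) < config.charge_duplicate_rate
    rows = []
    for i, seq in enumerate(sequences):
        if dup[i]:
            u = rng.uniform(0.2, 0.8)
            rows.append((seq, 2, base[i] * u))
            rows.append((seq, 3, base[i] * (1 - u)))
        else:
            rows.append((seq, 2, base[i]))
    data = pd.DataFrame(
        [(s, z, *inten) for s, z, inten in rows],
        columns=["sequence", "charge", *design.index])
    return PeptideTable(data=data, design=design).validate()


def gen_parent_protein(seed: int, length: int = 441,
                       embed: str = PHF6_PEPTIDE) -> str:
    """A synthetic tau-like parent protein: random sequence with the
    PHF6-containing marker peptide embedded mid-sequence.

    This is a synthetic stand-in, not any real tau isoform; it exists so that
    substring restriction and protein-restricted statistics can be exercised.
    """
    rng = child_rng(seed, "parent_protein")
    seq = list(rng.choice(_AA, size=length))
    pos = length // 2
    seq[pos:pos + len(embed)] = list(embed)
    return "".join(seq)


def gen_substring_peptides(parent: str, n_peptides: int, ip_fraction: float,
                           rng: np.random.Generator,
                           len_lo: int = 6, len_hi: int = 25) -> List[str]:
    """Peptides cut from a parent protein with a planted C-terminal class bias.

    Each peptide's C-terminal residue is the parent residue at its cut site,
    so the class is planted by choosing the cut position: with probability
    ``ip_fraction`` the endpoint is drawn among immunoproteasome-type
    positions, otherwise among constitutive-type positions.
    """
    ip_ends = [i for i, ch in enumerate(parent) if ch in IP_RESIDUES]
    pp_ends = [i for i, ch in enumerate(parent) if ch in PP_RESIDUES]
    if not ip_ends or not pp_ends:
        raise ValueError("parent lacks cut sites of one class")
    peptides = []
    for _ in range(n_peptides):
        pool = ip_ends if rng.random() < ip_fraction else pp_ends
        end = pool[rng.integers(len(pool))] + 1
        length = int(rng.integers(len_lo, len_hi + 1))
        start = max(0, end - length)
        if end - start >= len_lo:
            peptides.append(parent[start:end])
    return peptides


@dataclass
class SimulatedMatrix:
    """A raw intensity matrix plus its planted differential-feature flags."""

    matrix: IntensityMatrix
    is_de: pd.Series


def gen_intensity_matrix(config: SyntheticConfig,
                         conditions=("control", "treated")) -> SimulatedMatrix:
    """Raw-scale intensity matrix with ``n_de`` features shifted by
    ``de_log2fc`` (log2 scale) in the second condition.

    Values are built on the log2 scale (Gaussian noise around a log-normal
    baseline) and exponentiated as 2**L - 1, so the log2(x+1) transform
    recovers the planted effect exactly. Per-feature noise variances follow a
    scaled inverse-chi-squared prior (scale ``noise_sd``**2, df
    ``noise_prior_df``; df=inf makes them homogeneous), the variance model an
    empirical-Bayes moderated fit assumes. Missing cells are completely at
    random at ``missing_rate`` (or intensity-dependent left-censored in
    ``missing_mode="censor"``).
    """
    if config.n_de > config.n_features:
        raise ConfigError("n_de exceeds n_features")
    rng = config.rng("intensity_matrix")
    nf, ns = config.n_features, config.n_samples_per_group
    samples = ([f"{conditions[0]}.r{i+1}" for i in range(ns)]
               + [f"{conditions[1]}.r{i+1}" for i in range(ns)])
    cond = pd.Series([conditions[0]] * ns + [conditions[1]] * ns, index=samples)
    log2e = float(np.log2(np.e))
    baseline = rng.normal(config.intensity_logmean * log2e,
                          config.intensity_logsd * log2e, size=nf)
    d0 = config.noise_prior_df
    if np.isinf(d0):
        noise_sd = np.full(nf, config.noise_sd)
    else:
        noise_sd = config.noise_sd * np.sqrt(d0 / rng.chisquare(d0, size=nf))
    L = (baseline[:, None]
         + rng.normal(0.0, 1.0, size=(nf, 2 * ns)) * noise_sd[:, None])
    is_de = np.zeros(nf, dtype=bool)
    de_idx = rng.choice(nf, size=config.n_de, replace=False)
    is_de[de_idx] = True
    sign = rng.choice([-1.0, 1.0], size=config.n_de)
    L[de_idx, ns:] += sign[:, None] * config.de_log2fc
    raw = np.power(2.0, np.maximum(L, 0.0)) - 1.0

    if config.missing_rate > 0:
        if config.missing_mode == "mcar":
            mask = rng.random(raw.shape) < config.missing_rate
        else:
            # left-censoring: missingness odds decay with log2 intensity rank
            ranks = np.argsort(np.argsort(L, axis=None)).reshape(L.shape)
            prob = config.missing_rate * 2.0 * (1.0 - ranks / ranks.size)
            mask = rng.random(raw.shape) < prob
        raw = np.where(mask, np.nan, raw)

    features = [f"prot{i:05d}" for i in range(nf)]
    values = pd.DataFrame(raw, index=features, columns=samples)
    return SimulatedMatrix(
        matrix=IntensityMatrix(values=values, conditions=cond),
        is_de=pd.Series(is_de, index=features))


# ---------------------------------------------------------------------------
# structures and embeddings
# ---------------------------------------------------------------------------

def _emission_probs(delta: float) -> np.ndarray:
    base = np.full(20, 1.0 / 20.0)
    if delta == 0:
        return base
    probs = base.copy()
    de_idx = [AMINO_ACIDS.index("D"), AMINO_ACIDS.index("E")]
    de_total = 2.0 / 20.0 + delta
    if not 0 < de_total < 1:
        raise ConfigError("acidic_enrichment_delta pushes D/E mass out of (0,1)")
    others = [i for i in range(20) if i not in de_idx]
    probs[de_idx] = de_total / 2.0
    probs[others] = (1.0 - de_total) / len(others)
    return probs


def gen_structures(config: SyntheticConfig
                   ) -> Tuple[List[StructureProfile], np.ndarray]:
    """Structure profiles plus binary class labels (first half positive).

    Secondary structure is a 3-state Markov chain (states H, E, C) started in
    H with the configured transition matrix; rSASA is i.i.d.
    Beta(exposure_alpha, exposure_beta); sequences are i.i.d. residue draws,
    with the positive class's D/E emission probability raised by
    ``acidic_enrichment_delta``.
    """
    rng = config.rng("structures")
    T = np.asarray(config.ss_transition, dtype=float)
    n_pos = config.n_proteins // 2 + config.n_proteins % 2
    labels = np.array([1] * n_pos + [0] * (config.n_proteins - n_pos))
    probs = {1: _emission_probs(config.acidic_enrichment_delta),
             0: _emission_probs(0.0)}
    profiles = []
    for i in range(config.n_proteins):
        length = int(rng.integers(config.protein_len_lo,
                                  config.protein_len_hi + 1))
        seq = "".join(rng.choice(_AA, size=length, p=probs[labels[i]]))
        states = np.empty(length, dtype=int)
        states[0] = 0
        for j in range(1, length):
            states[j] = rng.choice(3, p=T[states[j - 1]])
        ss = "".join("HEC"[s] for s in states)
        rsasa = rng.beta(config.exposure_alpha, config.exposure_beta,
                         size=length)
        profiles.append(StructureProfile(
            protein_id=f"SYN{i:04d}", sequence=seq, ss=ss, rsasa=rsasa))
    return profiles, labels


def _composition_vector(sequence: str) -> np.ndarray:
    counts = np.zeros(20)
    for ch in sequence:
        counts[AMINO_ACIDS.index(ch)] += 1
    return counts / max(len(sequence), 1)


def _embedding_map(config: SyntheticConfig) -> np.ndarray:
    rng = config.rng("embedding_map")
    return rng.normal(0.0, 1.0, size=(config.embedding_dim, 20))


def _item_key(item) -> str:
    if isinstance(item, Motif):
        return f"motif:{item.protein_id}:{item.start}:{item.end}"
    if isinstance(item, StructureProfile):
        return f"protein:{item.protein_id}"
    return f"seq:{item}"


def _embed_one(sequence: str, key: str, W: np.ndarray,
               config: SyntheticConfig) -> np.ndarray:
    noise_rng = child_rng(config.seed, "embedding_noise:" + key)
    signal = config.embedding_signal * (W @ _composition_vector(sequence))
    return signal + noise_rng.normal(0.0, config.embedding_noise_sd,
                                     size=config.embedding_dim)


def gen_embeddings(items: Sequence, config: SyntheticConfig,
                   labels: Optional[Sequence[int]] = None) -> EmbeddingSet:
    """Composition-driven embedding vectors for proteins or motifs.

    Each vector is a fixed random linear map of the item's 20-dim residue
    composition, scaled by ``embedding_signal``, plus isotropic Gaussian
    noise; with ``embedding_signal=0`` the vectors are pure noise. The noise
    stream is keyed per item, so the same item always gets the same vector
    regardless of batch composition or order.
    """
    W = _embedding_map(config)
    X = np.vstack([_embed_one(getattr(it, "sequence", str(it)), _item_key(it),
                              W, config) for it in items])
    ids = [_item_key(it) for it in items]
    if labels is None:
        labels = np.zeros(len(items), dtype=int)
    return EmbeddingSet(ids=ids, X=X, labels=np.asarray(labels, dtype=int))


def make_motif_embedder(config: SyntheticConfig):
    """A motif -> vector callable matching :func:`gen_embeddings` item-wise."""
    W = _embedding_map(config)

    def embed(motif: Motif) -> np.ndarray:
        return _embed_one(motif.sequence, _item_key(motif), W, config)

    return embed


def gen_id_lists(size_a: int, size_b: int, n_shared: int,
                 seed: int = 0) -> Tuple[List[str], List[str]]:
    """Two identifier lists with exactly ``n_shared`` common elements."""
    if n_shared > min(size_a, size_b):
        raise ValueError("n_shared exceeds a list size")
    rng = child_rng(seed, "id_lists")
    total = size_a + size_b - n_shared
    ids = [f"P{i:06d}" for i in range(total)]
    ids = list(rng.permutation(ids))
    shared = ids[:n_shared]
    only_a = ids[n_shared:n_shared + (size_a - n_shared)]
    only_b = ids[n_shared + (size_a - n_shared):]
    return shared + only_a, shared + only_b
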