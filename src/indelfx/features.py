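"""Per-variant feature engineering.

Each variant is described by properties of the wildtype protein around the
variant site:

* general features — relative position in the sequence, numbers of residues
  inserted and deleted;
* local composition — amino-acid frequencies in the ten-residue windows on
  either side of the variant, and the length of the single-amino-acid repeat
  at the variant site (1 when the variant is not in a repeat);
* evolutionary features — the maximum conservation index over the affected
  range, and cumulative homolog counts per organism at sequence-identity
  levels 50..95% in 5% steps;
* predicted functional features — per mechanism, the number of residues with
  confident property predictions within windows of 4 and 20 residues of the
  variant site and over the whole protein;
* optional gene-level function scores, passed through unchanged.

All windows clip silently at the protein termini.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .variants import AA_ALPHABET, IndelVariant, ProteinRecord, variant_kind

HOMOLOG_IDENTITY_THRESHOLDS = tuple(range(50, 100, 5))  # 10 cumulative bins


@dataclass
class PropertyTrack:
    """Per-residue scores for one structural/functional mechanism.

    ``confident_threshold`` is the score cutoff at which the upstream
    residue-level predictor operates at a 10% false-positive rate; a residue
    is "confidently predicted" to exhibit the mechanism when its score is at
    or above this cutoff.  ``alpha`` is the optional class prior of the
    mechanism used by the prior-corrected P-value.
    """

    mechanism: str
    scores: np.ndarray
    confident_threshold: float
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("track scores must be a 1-D vector")
        if not 0.0 <= self.confident_threshold <= 1.0:
            # thresholds live on the predictor's [0,1] score scale; an
            # unreachable cutoff (e.g. 1.01 in tests) is permitted via
            # direct attribute assignment only
            raise ValueError("confident_threshold must be in [0, 1]")
        if self.alpha is not None and not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")

    def confident_mask(self) -> np.ndarray:
        return self.scores >= self.confident_threshold


@dataclass
class FeatureConfig:
    """Which feature groups to build and from which named inputs."""

    mechanisms: Sequence[str] = ()
    conservation: Sequence[str] = ()
    include_composition: bool = True
    include_general: bool = True
    include_homologs: bool = True
    include_gene_scores: bool = False
    gene_score_length: int = 0
    presence_flags: bool = False


def general_features(v: IndelVariant, L: int) -> tuple:
    """(relative position, residues inserted, residues deleted)."""
    return (v.start / L, len(v.inserted_seq), len(v.deleted_seq))


def _flank_windows(v: IndelVariant, L: int, w: int) -> list:
    """Wildtype positions in the two w-residue windows flanking the variant
    span, excluding any deleted residues."""
    if v.deleted_seq:
        left_hi, right_lo = v.start - 1, v.end + 1
    else:
        left_hi, right_lo = v.start, v.start + 1
    left = range(max(1, left_hi - w + 1), left_hi + 1)
    right = range(right_lo, min(L, right_lo + w - 1) + 1)
    return [p for p in left if p >= 1] + [p for p in right if p <= L]


def window_aa_frequency(v: IndelVariant, seq: str) -> np.ndarray:
    """Amino-acid frequencies in the ten-residue windows on either side of
    the variant, normalized by the number of residues actually present."""
    positions = _flank_windows(v, len(seq), 10)
    freqs = np.zeros(len(AA_ALPHABET))
    if not positions:
        return freqs
    index = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    n = 0
    for p in positions:
        aa = seq[p - 1]
        n += 1
        if aa in index:  # X contributes to the denominator only
            freqs[index[aa]] += 1
    return freqs / n


def _run_length_at(seq: str, pos: int) -> int:
    aa = seq[pos - 1]
    lo = pos
    while lo > 1 and seq[lo - 2] == aa:
        lo -= 1
    hi = pos
    while hi < len(seq) and seq[hi] == aa:
        hi += 1
    return hi - lo + 1


def repeat_run_length(v: IndelVariant, seq: str) -> int:
    """Length of the maximal single-amino-acid run containing the variant
    site; 1 when the variant does not lie in a repeat.

    Deletions and complex indels take the longest run containing any deleted
    residue.  Insertions evaluate the two residues flanking the insertion
    point and take the larger containing run.
    """
    L = len(seq)
    if v.deleted_seq:
        positions = range(v.start, v.end + 1)
    else:
        positions = [p for p in (v.start, v.start + 1) if 1 <= p <= L]
    if not positions:
        return 1
    return max(_run_length_at(seq, p) for p in positions)


def conservation_feature(v: IndelVariant, cons: Sequence[float]) -> float:
    """Maximum conservation index over the affected range.

    Deletions/complex indels: maximum over the deleted span.  An insertion
    of ``k`` residues after residue ``p``: maximum over the window
    ``p..p+k-1`` (starting from the residue just before the insertion site,
    window size = number of inserted residues), clipped to ``[1, L]``.
    """
    cons = np.asarray(cons, dtype=float)
    L = len(cons)
    if v.deleted_seq:
        lo, hi = v.start, v.end
    else:
        k = len(v.inserted_seq)
        lo, hi = v.start, v.start + k - 1
    lo, hi = max(1, lo), min(L, hi)
    if lo > hi:  # fully clipped window (e.g. single-residue N-terminal insertion)
        lo = hi = min(L, max(1, v.start if v.start >= 1 else 1))
    return float(cons[lo - 1:hi].max())


def homolog_count_features(identities: Sequence[float]) -> np.ndarray:
    """Cumulative homolog counts at identity levels 50..95% in 5% steps.

    ``counts[i]`` is the number of homologs with percent identity at or
    above the i-th threshold, so counts are nonincreasing across the 10
    bins and a 100%-identity homolog contributes to every bin.
    """
    ids = np.asarray(list(identities), dtype=float)
    if ids.size and (ids.min() < 0 or ids.max() > 100):
        raise ValueError("identities must be percentages in [0, 100]")
    return np.array([(ids >= t).sum() for t in HOMOLOG_IDENTITY_THRESHOLDS],
                    dtype=float)


def _variant_span(v: IndelVariant, L: int) -> tuple:
    """Inclusive wildtype span of the variant site (insertion: the two
    residues around the boundary), clipped to [1, L]."""
    if v.deleted_seq:
        lo, hi = v.start, v.end
    else:
        lo, hi = v.start, v.start + 1
    return max(1, lo), min(L, hi)


def functional_residue_counts(v: IndelVariant, track: PropertyTrack) -> tuple:
    """Counts of confidently predicted residues near the variant.

    Returns ``(count_w4, count_w20, count_whole)``: the number of residues
    with score >= the track's confident threshold within 4 and 20 residues
    of the variant span, and over the entire protein.  Windows clip at the
    termini; the variant span itself is included.
    """
    mask = track.confident_mask()
    L = mask.size
    lo, hi = _variant_span(v, L)
    out = []
    for w in (4, 20):
        a, b = max(1, lo - w), min(L, hi + w)
        out.append(int(mask[a - 1:b].sum()))
    out.append(int(mask.sum()))
    return tuple(out)


class MissingInputError(KeyError):
    """A protein lacks a track/conservation vector required by the config."""


def feature_names(config: FeatureConfig) -> tuple:
    """Deterministic feature ordering for a config (groups in fixed order)."""
    names = []
    if config.include_general:
        names += ["rel_position", "n_inserted", "n_deleted"]
    if config.include_composition:
        names += [f"aa_freq_{aa}" for aa in AA_ALPHABET]
        names.append("repeat_run_length")
    names += [f"cons_{c}" for c in config.conservation]
    if config.include_homologs:
        for org in ("human", "mouse"):
            names += [f"homolog_{org}_ge{t}" for t in HOMOLOG_IDENTITY_THRESHOLDS]
        if config.presence_flags:
            names.append("homolog_present")
    for mech in config.mechanisms:
        names += [f"func_{mech}_w4", f"func_{mech}_w20", f"func_{mech}_whole"]
    if config.include_gene_scores:
        names += [f"gene_{i}" for i in range(config.gene_score_length)]
        if config.presence_flags:
            names.append("gene_present")
    return tuple(names)


def feature_groups(config: FeatureConfig) -> dict:
    """Map feature name -> group label, for ablation experiments."""
    groups = {}
    for name in feature_names(config):
        if name in ("rel_position", "n_inserted", "n_deleted"):
            g = "general"
        elif name.startswith("aa_freq_") or name == "repeat_run_length":
            g = "composition"
        elif name.startswith("cons_"):
            g = "conservation"
        elif name.startswith("homolog_"):
            g = "homolog"
        elif name.startswith("func_"):
            w = name.rsplit("_", 1)[1]
            g = {"w4": "functional_w4", "w20": "functional_w20",
                 "whole": "functional_whole"}[w]
        else:
            g = "gene"
        groups[name] = g
    return groups


def assemble_feature_vector(v: IndelVariant, protein: ProteinRecord,
                            config: FeatureConfig) -> dict:
    """Build the named feature map for one variant.

    Missing *required* inputs (mechanism tracks, conservation vectors named
    in the config) raise :class:`MissingInputError` listing every absent
    name; missing *optional* groups (homologs, gene scores) are imputed as
    zeros, with a presence flag when ``config.presence_flags`` is set.
    """
    missing = [m for m in config.mechanisms if m not in protein.tracks]
    missing += [c for c in config.conservation if c not in protein.conservation]
    if missing:
        raise MissingInputError(
            f"protein {protein.protein_id} lacks required inputs: {missing}")

    L = len(protein)
    out: dict = {}
    if config.include_general:
        rel, n_ins, n_del = general_features(v, L)
        out.update(rel_position=rel, n_inserted=float(n_ins),
                   n_deleted=float(n_del))
    if config.include_composition:
        for aa, f in zip(AA_ALPHABET, window_aa_frequency(v, protein.sequence)):
            out[f"aa_freq_{aa}"] = float(f)
        out["repeat_run_length"] = float(repeat_run_length(v, protein.sequence))
    for c in config.conservation:
        out[f"cons_{c}"] = conservation_feature(v, protein.conservation[c])
    if config.include_homologs:
        have = bool(protein.homolog_identities_human
                    or protein.homolog_identities_mouse)
        for org in ("human", "mouse"):
            ids = getattr(protein, f"homolog_identities_{org}")
            for t, c in zip(HOMOLOG_IDENTITY_THRESHOLDS,
                            homolog_count_features(ids)):
                out[f"homolog_{org}_ge{t}"] = float(c)
        if config.presence_flags:
            out["homolog_present"] = float(have)
    for mech in config.mechanisms:
        w4, w20, whole = functional_residue_counts(v, protein.tracks[mech])
        out[f"func_{mech}_w4"] = float(w4)
        out[f"func_{mech}_w20"] = float(w20)
        out[f"func_{mech}_whole"] = float(whole)
    if config.include_gene_scores:
        gs = protein.gene_scores
        if gs is None:
            vec = np.zeros(config.gene_score_length)
            have = False
        else:
            vec = np.asarray(gs, dtype=float)
            have = True
            if vec.size != config.gene_score_length:
                raise ValueError(
                    f"gene_scores length {vec.size} != configured "
                    f"{config.gene_score_length}")
        for i, g in enumerate(vec):
            out[f"gene_{i}"] = float(g)
        if config.presence_flags:
            out["gene_present"] = float(have)
    if not all(np.isfinite(list(out.values()))):
        raise ValueError("non-finite feature value")
    return out


def assemble_feature_matrix(variants: Sequence[IndelVariant],
                            proteins: dict,
                            config: FeatureConfig) -> pd.DataFrame:
    """Feature matrix for a cohort (rows follow the input variant order)."""
    cols = feature_names(config)
    rows = [assemble_feature_vector(v, proteins[v.protein_id], config)
            for v in variants]
    df = pd.DataFrame(rows, columns=list(cols))
    return df
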