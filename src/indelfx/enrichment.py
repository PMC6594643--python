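"""Cohort-level enrichment statistics.

For a mechanism, ``F_pathogenic`` and ``F_neutral`` are the fractions of
canonical-sequence variants in each cohort whose modified residues (the
deleted range for deletions and complex indels; the two residues on either
side of the insertion point for insertions) are confidently predicted to
exhibit the mechanism.  The enrichment (trend) value

    E = (F_pathogenic - F_neutral) / (F_pathogenic + F_neutral)

lies in [-1, 1]; positive values indicate an excess of functional impact
among residues hit by pathogenic variants, negative values an excess in the
neutral cohort.  Significance is assigned with a two-sided Fisher's exact
test, Bonferroni-corrected over the number of mechanisms tested.

Somatic recurrence stratification: a variant is *recurrent* when some
residue it impacts is hit at least twice in the catalogue (by missense or
indel variants; hit counts arrive precomputed), and *highly recurrent* at
25 or more hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy import stats

from .features import PropertyTrack
from .variants import IndelVariant, impacted_residues

RECURRENT_MIN_HITS = 2
HIGHLY_RECURRENT_MIN_HITS = 25


@dataclass
class EnrichmentResult:
    """Per-mechanism enrichment between two cohorts."""

    mechanism: str
    f_pathogenic: float
    f_neutral: float
    E: float                 # NaN when both fractions are 0
    counts: tuple            # ((path_hit, path_miss), (neut_hit, neut_miss))
    fisher_p: float
    bonferroni_p: float
    bonferroni_significant: bool
    n_tests: int


def variant_impacts(v: IndelVariant, track: PropertyTrack) -> bool:
    """True when at least one enrichment-mode residue of *v* is confidently
    predicted to exhibit the track's mechanism."""
    mask = track.confident_mask()
    L = mask.size
    return any(mask[r - 1] for r in impacted_residues(v, L, "enrichment"))


def fraction_impacting(variants: Sequence[IndelVariant], proteins: dict,
                       mechanism: str) -> tuple:
    """(fraction, impacted count, total) of variants impacting a mechanism."""
    variants = list(variants)
    if not variants:
        raise ValueError("empty cohort")
    hits = sum(variant_impacts(v, proteins[v.protein_id].tracks[mechanism])
               for v in variants)
    return hits / len(variants), int(hits), len(variants)


def enrichment_value(f_path: float, f_neut: float) -> float:
    """Trend value E = (f_path - f_neut) / (f_path + f_neut).

    Undefined (NaN) when both fractions are zero.
    """
    for f in (f_path, f_neut):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
    denom = f_path + f_neut
    if denom == 0.0:
        return float("nan")
    return (f_path - f_neut) / denom


def fisher_enrichment(table, n_tests: int = 1) -> tuple:
    """Two-sided Fisher's exact test with Bonferroni correction.

    *table* is a 2x2 count matrix (rows = cohorts, columns = impacted /
    not impacted).  Two-sidedness follows the point-probability criterion:
    the P-value sums the probabilities of all tables, with the observed
    margins, no more likely than the observed one.  Returns
    ``(p, p_bonferroni, significant_at_0.05)``.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 nonnegative counts")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    p = float(stats.fisher_exact(t, alternative="two-sided").pvalue)
    p_bonf = min(1.0, p * n_tests)
    return p, p_bonf, p_bonf < 0.05


def fisher_one_sided(table, alternative: str = "greater") -> float:
    """One-sided Fisher P, recorded alongside the two-sided value for
    diagnosing sidedness conventions."""
    t = np.asarray(table, dtype=int)
    return float(stats.fisher_exact(t, alternative=alternative).pvalue)


def label_recurrence(variants: Sequence[IndelVariant],
                     residue_hit_counts: Dict[tuple, int]) -> list:
    """Stratify variants by somatic recurrence of their impacted residues.

    ``residue_hit_counts`` maps (protein_id, residue) -> total observation
    count across the catalogue.  A variant's recurrence is the maximum hit
    count over its enrichment-mode impacted residues: >= 2 is ``recurrent``
    and >= 25 ``highly_recurrent``; otherwise ``non_recurrent``.
    """
    out = []
    for v in variants:
        hits = [residue_hit_counts.get((v.protein_id, r), 0)
                for r in impacted_residues(v, _infer_length(v), "enrichment")]
        m = max(hits, default=0)
        if m >= HIGHLY_RECURRENT_MIN_HITS:
            out.append("highly_recurrent")
        elif m >= RECURRENT_MIN_HITS:
            out.append("recurrent")
        else:
            out.append("non_recurrent")
    return out


def _infer_length(v: IndelVariant) -> int:
    # hit-count lookups beyond the protein terminus simply miss, so a
    # generous bound is safe when the sequence length is not at hand
    return v.end + 2


def dedupe_variants(variants: Sequence[IndelVariant],
                    proteins: dict = None,
                    canonical_only: bool = True) -> list:
    """One event per (protein, locus, alleles); optionally restrict to
    canonical proteins.  Used by the cohort functional analyses."""
    seen = set()
    out = []
    for v in variants:
        if canonical_only and proteins is not None \
                and not proteins[v.protein_id].canonical:
            continue
        k = v.key()
        if k not in seen:
            seen.add(k)
            out.append(v)
    return out


def enrichment_report(path_variants: Sequence[IndelVariant],
                      neut_variants: Sequence[IndelVariant],
                      proteins: dict,
                      mechanisms: Sequence[str]) -> list:
    """Per-mechanism enrichment of the pathogenic vs the neutral cohort.

    Bonferroni correction uses the number of mechanisms tested; results are
    sorted by \\|E\\| descending (NaN E last).
    """
    mechanisms = list(mechanisms)
    if not mechanisms:
        raise ValueError("empty mechanism list")
    if not path_variants or not neut_variants:
        raise ValueError("both cohorts must be nonempty")
    n_tests = len(mechanisms)
    results = []
    for mech in mechanisms:
        fp, kp, np_ = fraction_impacting(path_variants, proteins, mech)
        fn, kn, nn = fraction_impacting(neut_variants, proteins, mech)
        table = ((kp, np_ - kp), (kn, nn - kn))
        p, p_bonf, sig = fisher_enrichment(table, n_tests=n_tests)
        results.append(EnrichmentResult(
            mechanism=mech, f_pathogenic=fp, f_neutral=fn,
            E=enrichment_value(fp, fn), counts=table, fisher_p=p,
            bonferroni_p=p_bonf, bonferroni_significant=sig,
            n_tests=n_tests))
    results.sort(key=lambda r: (-(abs(r.E) if not math.isnan(r.E) else -1),
                                r.mechanism))
    return results
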