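"""Per-variant functional-impact statistics.

For each structural/functional mechanism, a variant's impact score is the
number of impacted residues (the deleted range plus three flanking residues
on each side) that are confidently predicted to exhibit the mechanism.  The
score is compared against a null distribution built from the impact scores
of the neutral cohort: the empirical P-value is the fraction of neutral
variants scoring at least as high.

Because mechanisms differ in how frequently they occur, raw P-values are
not comparable across mechanisms.  The prior-corrected P-value

    P' = (1 - alpha) * P

downweights common mechanisms, where ``alpha`` is the class prior (the
frequency of the mechanism).  The correction derives from the definition of
the false discovery rate with the P-value standing in for the false
positive rate and the denominator dropped, so P' <= P always and
significance is called at P' < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .features import PropertyTrack
from .variants import IndelVariant, ProteinRecord, impacted_residues

SIGNIFICANCE_LEVEL = 0.05
MAX_REPORTED_MECHANISMS = 5


@dataclass
class ImpactResult:
    """Per-mechanism impact statistics for one variant."""

    mechanism: str
    impact_score: int
    p_value: float
    alpha: float
    p_prime: float
    significant: bool


@dataclass
class NullDistribution:
    """Impact scores of the neutral cohort for one mechanism."""

    mechanism: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.size == 0:
            raise ValueError("null distribution must be nonempty")
        if not np.all(self.scores == np.round(self.scores)):
            raise ValueError("impact scores are integer counts")
        self.scores = self.scores.astype(int)


def impact_score(v: IndelVariant, track: PropertyTrack,
                 L: Optional[int] = None) -> int:
    """Number of impacted residues confidently predicted for the mechanism."""
    if L is None:
        L = len(track.scores)
    mask = track.confident_mask()
    return int(sum(mask[r - 1] for r in impacted_residues(v, L, "impact")))


def empirical_p(score: float, null: NullDistribution,
                add_one: bool = False) -> float:
    """Fraction of null scores at least as high as *score*.

    The literal fraction can be exactly 0 for scores above the null's
    maximum; ``add_one=True`` switches to (k+1)/(n+1) for users who need a
    strictly positive P-value.
    """
    k = int((null.scores >= score).sum())
    n = null.scores.size
    return (k + 1) / (n + 1) if add_one else k / n


def prior_correct(p: float, alpha: float) -> float:
    """Prior-corrected P-value P' = (1 - alpha) * P."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    return (1.0 - alpha) * p


def fdr_from_rates(alpha: float, fpr: float, tpr: float) -> float:
    """False discovery rate from the class prior and the two error rates:
    FDR = (1-alpha)*FPR / (alpha*TPR + (1-alpha)*FPR).

    Documents the approximation behind :func:`prior_correct`: with the
    P-value approximating the FPR and the denominator dropped, the FDR
    reduces to the prior-corrected P-value.
    """
    for name, r in (("alpha", alpha), ("fpr", fpr), ("tpr", tpr)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    denom = alpha * tpr + (1.0 - alpha) * fpr
    if denom <= 0.0:
        raise ZeroDivisionError("alpha*TPR + (1-alpha)*FPR must be > 0")
    return (1.0 - alpha) * fpr / denom


def build_null(variants: Sequence[IndelVariant], proteins: dict,
               mechanism: str) -> NullDistribution:
    """Null distribution of impact scores from a (neutral) cohort."""
    scores = [impact_score(v, proteins[v.protein_id].tracks[mechanism])
              for v in variants]
    return NullDistribution(mechanism=mechanism, scores=np.array(scores))


def evaluate_impact(v: IndelVariant, track: PropertyTrack,
                    null: NullDistribution,
                    alpha: Optional[float] = None,
                    add_one: bool = False) -> ImpactResult:
    """Impact score, empirical P and prior-corrected P for one mechanism.

    ``alpha`` precedence: explicit argument, then the track's stored prior,
    then 0 (no correction, P' = P — conservative toward the uncorrected
    P-value).
    """
    if alpha is None:
        alpha = track.alpha if track.alpha is not None else 0.0
    s = impact_score(v, track)
    p = empirical_p(s, null, add_one=add_one)
    pp = prior_correct(p, alpha)
    return ImpactResult(mechanism=track.mechanism, impact_score=s,
                        p_value=p, alpha=alpha, p_prime=pp,
                        significant=pp < SIGNIFICANCE_LEVEL)


def rank_mechanisms(v: IndelVariant, tracks: Dict[str, PropertyTrack],
                    nulls: Dict[str, NullDistribution],
                    alphas: Optional[Dict[str, float]] = None,
                    add_one: bool = False) -> list:
    """Top mechanisms significantly impacted by *v* (at most five).

    Mechanisms with prior-corrected P < 0.05 are sorted by P' ascending;
    ties break toward the larger impact score, then mechanism name, so the
    output is invariant to input ordering.
    """
    results = []
    for name in sorted(tracks):
        if name not in nulls:
            raise KeyError(f"mechanism {name!r} has no null distribution")
        alpha = alphas.get(name) if alphas else None
        results.append(evaluate_impact(v, tracks[name], nulls[name],
                                       alpha=alpha, add_one=add_one))
    significant = [r for r in results if r.significant]
    significant.sort(key=lambda r: (r.p_prime, -r.impact_score, r.mechanism))
    return significant[:MAX_REPORTED_MECHANISMS]


def naive_alpha_estimate(scores_unlabeled, scores_positive,
                         cap: float = 0.99) -> float:
    """Conservative class-prior estimate from classifier score samples.

    Ratio of mean scores (unlabeled over labeled-positive), capped into
    [0, *cap*].  When the unlabeled sample is distributed like the positive
    sample the estimate saturates at the cap; when it is purely negative
    with near-zero scores the estimate approaches 0.  A directly configured
    alpha always takes precedence over this estimate.
    """
    u = np.asarray(scores_unlabeled, dtype=float)
    p = np.asarray(scores_positive, dtype=float)
    if u.size == 0 or p.size == 0:
        raise ValueError("both score samples must be nonempty")
    if p.mean() <= 0:
        return 0.0
    return float(np.clip(u.mean() / p.mean(), 0.0, cap))


def is_single_residue(v: IndelVariant) -> bool:
    """Cohort-analysis filter: variants whose event size is one residue."""
    return v.size == 1


def predicted_flag(score: float, neutral_scores,
                   percentile: float = 95.0) -> bool:
    """Cohort 'predicted' rule: impact score at or above the given
    percentile of the neutral score distribution (default 95th)."""
    return bool(score >= np.percentile(
        np.asarray(neutral_scores, dtype=float), percentile))
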