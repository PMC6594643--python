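"""Seeded generator of synthetic proteins, tracks and variant cohorts.

The generator emulates the structure of a pathogenic-vs-population indel
study: proteins with occasional single-amino-acid repeat segments; per
mechanism, planted contiguous functional sites whose per-residue property
scores are drawn from a high beta component (Beta(8, 2) by default) against
a low background (Beta(2, 8)), with the confident threshold set at the
background's 90th percentile to mirror 10%-FPR track cutoffs; conservation
tracks correlated with the planted sites; and labeled variant cohorts in
which pathogenic variants preferentially hit functional residues while
neutral variants land uniformly.  Optional label noise hides
pathogenic-like variants inside the neutral set, emulating the
positive-unlabeled character of population training data.

Everything is reproducible from the mandatory seed, and the planted ground
truth is returned so downstream modules can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .features import PropertyTrack
from .variants import AA_ALPHABET, IndelVariant, ProteinRecord


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the standard conditions
    used throughout the test-suite and the reproduction script."""

    n_proteins: int = 300
    length_range: Tuple[int, int] = (60, 300)
    repeat_segment_rate: float = 0.3
    n_mechanisms: int = 4
    functional_site_density: float = 0.10
    track_background_beta: Tuple[float, float] = (2.0, 8.0)
    track_site_beta: Tuple[float, float] = (8.0, 2.0)
    n_pathogenic: int = 700
    n_neutral: int = 1300
    pathogenic_site_affinity: float = 0.9
    neutral_offsite_bias: float = 0.6
    # a minority of proteins are disease-associated and attract most
    # pathogenic variants, giving protein-level features real signal
    disease_protein_fraction: float = 0.3
    pathogenic_disease_affinity: float = 0.85
    label_noise_rate: float = 0.0
    # probability of event sizes 1, 2, 3, ... residues (short events dominate)
    indel_length_distribution: Tuple[float, ...] = (
        0.65, 0.15, 0.08, 0.05, 0.04, 0.03)
    kind_probs: Tuple[float, float, float] = (0.60, 0.25, 0.15)  # del/ins/cpx
    conservation_signal_weight: float = 0.6
    duplicate_protein_rate: float = 0.0
    duplicate_identity: float = 95.0
    gene_score_length: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("repeat_segment_rate", "functional_site_density",
                     "pathogenic_site_affinity", "neutral_offsite_bias",
                     "label_noise_rate", "duplicate_protein_rate",
                     "disease_protein_fraction", "pathogenic_disease_affinity"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.length_range[0] < 30:
            raise ValueError("protein lengths must be >= 30")
        if abs(sum(self.indel_length_distribution) - 1.0) > 1e-9:
            raise ValueError("indel_length_distribution must sum to 1")
        if abs(sum(self.kind_probs) - 1.0) > 1e-9:
            raise ValueError("kind_probs must sum to 1")

    @property
    def mechanisms(self) -> Tuple[str, ...]:
        return tuple(f"mech{i}" for i in range(self.n_mechanisms))

    @property
    def confident_threshold(self) -> float:
        """Background's 90th percentile: the 10%-FPR cutoff of the track."""
        a, b = self.track_background_beta
        return float(stats.beta.ppf(0.9, a, b))


def _random_sequence(rng: np.random.Generator, length: int,
                     repeat_rate: float) -> str:
    seq = list(rng.choice(list(AA_ALPHABET), size=length))
    if rng.random() < repeat_rate:
        run_len = int(rng.integers(4, 11))
        start = int(rng.integers(0, length - run_len + 1))
        aa = str(rng.choice(list(AA_ALPHABET)))
        seq[start:start + run_len] = [aa] * run_len
    return "".join(seq)


def _plant_sites(rng: np.random.Generator, length: int,
                 density: float) -> np.ndarray:
    """Boolean site mask covering roughly *density* of the residues with
    contiguous segments of 3-8 residues."""
    mask = np.zeros(length, dtype=bool)
    target = density * length
    guard = 0
    while mask.sum() < target and guard < 100:
        seg = int(rng.integers(3, 9))
        start = int(rng.integers(0, max(1, length - seg + 1)))
        mask[start:start + seg] = True
        guard += 1
    return mask


def _make_protein(rng: np.random.Generator, pid: str,
                  config: GeneratorConfig, sequence: Optional[str] = None,
                  site_masks: Optional[dict] = None) -> tuple:
    L = len(sequence) if sequence else int(
        rng.integers(config.length_range[0], config.length_range[1] + 1))
    if sequence is None:
        sequence = _random_sequence(rng, L, config.repeat_segment_rate)
    if site_masks is None:
        site_masks = {m: _plant_sites(rng, L, config.functional_site_density)
                      for m in config.mechanisms}
    a_bg, b_bg = config.track_background_beta
    a_site, b_site = config.track_site_beta
    thr = config.confident_threshold
    tracks = {}
    for m in config.mechanisms:
        scores = rng.beta(a_bg, b_bg, size=L)
        mask = site_masks[m]
        scores[mask] = rng.beta(a_site, b_site, size=int(mask.sum()))
        tracks[m] = PropertyTrack(mechanism=m, scores=scores,
                                  confident_threshold=thr)
    site_any = np.zeros(L, dtype=bool)
    for mask in site_masks.values():
        site_any |= mask
    w = config.conservation_signal_weight
    cons = np.clip(w * site_any + (1 - w) * rng.uniform(size=L), 0.0, 1.0)
    gene = rng.uniform(size=config.gene_score_length) \
        if config.gene_score_length else None
    protein = ProteinRecord(
        protein_id=pid, sequence=sequence, canonical=True, tracks=tracks,
        conservation={"default": cons}, gene_scores=gene,
        homolog_identities_human=list(rng.uniform(50, 100,
                                                  size=rng.poisson(3.0))),
        homolog_identities_mouse=list(rng.uniform(50, 100,
                                                  size=rng.poisson(2.0))))
    return protein, site_masks, site_any


def _place_variant(rng: np.random.Generator, protein: ProteinRecord,
                   site_any: np.ndarray, mode: str, label: str,
                   config: GeneratorConfig,
                   allele_count: Optional[int]) -> Optional[tuple]:
    """Place one variant; *mode* is 'site', 'offsite' or 'uniform'."""
    L = len(protein)
    if mode == "site":
        pool = np.flatnonzero(site_any)
    elif mode == "offsite":
        pool = np.flatnonzero(~site_any)
    else:
        pool = np.arange(L)
    if pool.size == 0:
        return None
    anchor = int(pool[rng.integers(pool.size)]) + 1  # 1-based residue
    kind = ("deletion", "insertion", "complex")[
        int(rng.choice(3, p=config.kind_probs))]
    lengths = config.indel_length_distribution
    size = int(rng.choice(np.arange(1, len(lengths) + 1), p=lengths))
    if kind == "insertion":
        # insert after the anchor so both flanking residues include it
        p = min(anchor, L)
        ins = "".join(rng.choice(list(AA_ALPHABET), size=size))
        v = IndelVariant(protein.protein_id, p, p, "", ins, label=label,
                         allele_count=allele_count)
        return v, anchor
    start = max(1, min(anchor, L - size + 1))
    end = start + size - 1
    deleted = protein.sequence[start - 1:end]
    ins = ""
    if kind == "complex":
        ins_len = int(rng.choice(np.arange(1, len(lengths) + 1), p=lengths))
        ins = "".join(rng.choice(list(AA_ALPHABET), size=ins_len))
    v = IndelVariant(protein.protein_id, start, end, deleted, ins,
                     label=label, allele_count=allele_count)
    return v, anchor


def generate_dataset(config: GeneratorConfig):
    """Generate (proteins, variants, ground_truth) from the config.

    ``proteins`` maps protein_id -> :class:`ProteinRecord` with tracks and
    conservation attached; ``variants`` is the pathogenic cohort followed
    by the neutral cohort; ``ground_truth`` records the planted site masks,
    per-variant site placement and hidden-positive flags, and the track
    threshold — enough to recompute expected impacted fractions exactly.
    """
    rng = np.random.default_rng(config.seed)
    proteins: Dict[str, ProteinRecord] = {}
    site_masks_all: Dict[str, dict] = {}
    site_any_all: Dict[str, np.ndarray] = {}
    disease: Dict[str, bool] = {}
    for i in range(config.n_proteins):
        pid = f"P{i:04d}"
        protein, masks, site_any = _make_protein(rng, pid, config)
        proteins[pid] = protein
        site_masks_all[pid] = masks
        site_any_all[pid] = site_any
        disease[pid] = bool(rng.random() < config.disease_protein_fraction)
    # optional near-identical isoforms: same sites and homologs (and the
    # same disease association), fresh track noise
    base_ids = list(proteins)
    for pid in base_ids:
        if rng.random() < config.duplicate_protein_rate:
            base = proteins[pid]
            dup_seq = _substitute(rng, base.sequence,
                                  1.0 - config.duplicate_identity / 100.0)
            dup_id = pid + "iso"
            protein, masks, site_any = _make_protein(
                rng, dup_id, config, sequence=dup_seq,
                site_masks=site_masks_all[pid])
            protein.homolog_identities_human = list(
                base.homolog_identities_human)
            protein.homolog_identities_mouse = list(
                base.homolog_identities_mouse)
            proteins[dup_id] = protein
            site_masks_all[dup_id] = masks
            site_any_all[dup_id] = site_any
            disease[dup_id] = disease[pid]

    with_sites = [p for p in proteins if site_any_all[p].any()]
    if not with_sites:
        raise ValueError("infeasible config: no protein has functional sites")
    all_ids = list(proteins)
    disease_with_sites = [p for p in with_sites if disease[p]]
    disease_ids = [p for p in all_ids if disease[p]]

    variants = []
    vt_truth = []

    def draw(label: str, mode: str, ac: Optional[int],
             prefer_disease: bool = False):
        for _ in range(50):
            if prefer_disease:
                pool = disease_with_sites if mode == "site" else disease_ids
            else:
                pool = with_sites if mode == "site" else all_ids
            if not pool:
                pool = with_sites if mode == "site" else all_ids
            pid = pool[int(rng.integers(len(pool)))]
            placed = _place_variant(rng, proteins[pid], site_any_all[pid],
                                    mode, label, config, ac)
            if placed is not None:
                return placed
        raise ValueError("infeasible config: could not place variant")

    for _ in range(config.n_pathogenic):
        mode = "site" if rng.random() < config.pathogenic_site_affinity \
            else "uniform"
        prefer = rng.random() < config.pathogenic_disease_affinity
        v, anchor = draw("pathogenic", mode, None, prefer_disease=prefer)
        variants.append(v)
        vt_truth.append({
            "on_site": bool(site_any_all[v.protein_id][anchor - 1]),
            "hidden_positive": False, "anchor": anchor})
    for _ in range(config.n_neutral):
        hidden = rng.random() < config.label_noise_rate
        prefer = False
        if hidden:
            mode = "site" if rng.random() < config.pathogenic_site_affinity \
                else "uniform"
            prefer = rng.random() < config.pathogenic_disease_affinity
        else:
            mode = "offsite" if rng.random() < config.neutral_offsite_bias \
                else "uniform"
        ac = int(rng.geometric(0.05))
        u = rng.random()
        if u < 0.05:
            ac = 0
        elif u < 0.20:
            ac = 1
        v, anchor = draw("neutral", mode, ac, prefer_disease=prefer)
        variants.append(v)
        vt_truth.append({
            "on_site": bool(site_any_all[v.protein_id][anchor - 1]),
            "hidden_positive": hidden, "anchor": anchor})

    ground_truth = {
        "config": asdict(config),
        "confident_threshold": config.confident_threshold,
        "mechanisms": list(config.mechanisms),
        "sites": {pid: {m: np.flatnonzero(mask).astype(int).tolist()
                        for m, mask in masks.items()}
                  for pid, masks in site_masks_all.items()},
        "disease_proteins": sorted(p for p, d in disease.items() if d),
        "variants": vt_truth,
    }
    return proteins, variants, ground_truth


def _substitute(rng: np.random.Generator, sequence: str,
                fraction: float) -> str:
    """Point-substitute a fraction of positions with different residues."""
    L = len(sequence)
    n_sub = int(round(fraction * L))
    seq = list(sequence)
    idx = rng.choice(L, size=n_sub, replace=False)
    for i in idx:
        choices = [aa for aa in AA_ALPHABET if aa != seq[i]]
        seq[i] = str(rng.choice(choices))
    return "".join(seq)


def generate_homolog_family(base_protein: ProteinRecord,
                            identities: Sequence[float],
                            seed: int = 0) -> list:
    """Mutated copies of *base_protein* at the requested percent identities.

    Each copy differs from the base by random point substitutions so the
    realized identity is within about 2 percentage points of the request.
    Copies carry the base's conservation/gene data but no tracks.
    """
    rng = np.random.default_rng(seed)
    out = []
    for j, ident in enumerate(identities):
        if not 0.0 < ident <= 100.0:
            raise ValueError("identities must be in (0, 100]")
        seq = _substitute(rng, base_protein.sequence, 1.0 - ident / 100.0)
        out.append(ProteinRecord(
            protein_id=f"{base_protein.protein_id}_hom{j}",
            sequence=seq, canonical=False))
    return out
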