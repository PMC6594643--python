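"""Readers and writers for all interchange formats.

Formats (all plain text; residue positions 1-based inclusive):

* FASTA — protein sequences (IDs = first whitespace-delimited header token).
* Variant TSV — ``protein_id`` plus either ``hgvs_p`` or explicit
  ``start, end, deleted_seq, inserted_seq`` columns; optional ``label``,
  ``allele_count``, ``recurrence_count``.
* Track TSV — ``protein_id, position, mechanism, score``; thresholds file —
  ``mechanism, confident_threshold, alpha``.
* Conservation TSV — ``protein_id, position, alignment, value``.
* Homolog TSV — ``protein_id, organism, percent_identity``.
* Residue hit-count TSV — ``protein_id, position, count``.
* Null-distribution TSV — ``mechanism, score, count``.
* Predictions TSV — score, class calls at three FPR levels, and up to five
  significant mechanisms with (impact score, P, P').
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import PropertyTrack
from .impact import NullDistribution
from .variants import (IndelVariant, ProteinRecord, VariantError,
                       VALID_SEQUENCE_LETTERS, parse_variant_notation)

logger = logging.getLogger("indelfx")

PREDICTION_COLUMNS = [
    "variant_id", "protein_id", "start", "end", "deleted_seq",
    "inserted_seq", "score", "call_fpr10", "call_fpr5", "call_fpr1",
]
_MECH_FIELDS = ("mechanism", "impact_score", "p", "p_prime")


def read_fasta(path) -> Dict[str, ProteinRecord]:
    """Read proteins from FASTA; sequences are uppercased and validated
    (the 20 standard letters plus X)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_SEQUENCE_LETTERS
        if bad:
            raise VariantError(f"{rec.id}: illegal letters {sorted(bad)}")
        records[rec.id] = ProteinRecord(protein_id=rec.id, sequence=seq)
    if not records:
        raise VariantError(f"no FASTA records in {path}")
    return records


def write_fasta(proteins: Dict[str, ProteinRecord], path) -> None:
    recs = [SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
            for p in proteins.values()]
    SeqIO.write(recs, str(path), "fasta")


def read_variants(path, proteins: Dict[str, ProteinRecord],
                  drop_ac_zero: bool = False,
                  drop_ac_one: bool = False) -> list:
    """Read and validate a variant TSV against its proteins.

    Rows failing protein lookup or reference checks raise with the
    offending 1-based data line number.  ``drop_ac_zero`` removes
    low-quality variants with allele count 0; ``drop_ac_one`` additionally
    removes singletons (AC exactly 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        pid = d["protein_id"]
        if pid not in proteins:
            raise VariantError(f"{path} line {line}: unknown protein {pid!r}")
        kwargs = {}
        for k in ("label", "allele_count", "recurrence_count"):
            val = d.get(k)
            if val is not None and not (isinstance(val, float) and np.isnan(val)):
                kwargs[k] = int(val) if k != "label" else str(val)
        try:
            if "hgvs_p" in d and isinstance(d["hgvs_p"], str):
                v = parse_variant_notation(d["hgvs_p"], proteins[pid], **kwargs)
            else:
                v = IndelVariant(pid, int(d["start"]), int(d["end"]),
                                 _str(d.get("deleted_seq")),
                                 _str(d.get("inserted_seq")), **kwargs)
                v.validate_against(proteins[pid].sequence)
        except VariantError as exc:
            raise VariantError(f"{path} line {line}: {exc}") from exc
        if drop_ac_zero and v.allele_count == 0:
            continue
        if drop_ac_one and v.allele_count is not None and v.allele_count <= 1:
            continue
        out.append(v)
    return out


def _str(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return str(x)


def write_variants(variants: Sequence[IndelVariant], path) -> None:
    rows = [{"protein_id": v.protein_id, "start": v.start, "end": v.end,
             "deleted_seq": v.deleted_seq, "inserted_seq": v.inserted_seq,
             "label": v.label, "allele_count": v.allele_count,
             "recurrence_count": v.recurrence_count} for v in variants]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tracks(path, thresholds_path,
                proteins: Dict[str, ProteinRecord]) -> None:
    """Attach property tracks (long-format TSV) to proteins in place."""
    thr = pd.read_csv(thresholds_path, sep="\t").set_index("mechanism")
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    for (pid, mech), grp in df.groupby(["protein_id", "mechanism"]):
        if pid not in proteins:
            raise VariantError(f"track references unknown protein {pid!r}")
        protein = proteins[pid]
        scores = np.zeros(len(protein))
        pos = grp["position"].to_numpy(dtype=int)
        if pos.min() < 1 or pos.max() > len(protein):
            raise VariantError(f"track position out of range for {pid}")
        scores[pos - 1] = grp["score"].to_numpy(dtype=float)
        alpha = None
        if "alpha" in thr.columns and not np.isnan(thr.loc[mech, "alpha"]):
            alpha = float(thr.loc[mech, "alpha"])
        protein.tracks[mech] = PropertyTrack(
            mechanism=mech, scores=scores,
            confident_threshold=float(thr.loc[mech, "confident_threshold"]),
            alpha=alpha)


def write_tracks(proteins: Dict[str, ProteinRecord], path,
                 thresholds_path) -> None:
    rows, thr = [], {}
    for p in proteins.values():
        for mech, track in p.tracks.items():
            thr[mech] = (track.confident_threshold, track.alpha)
            for i, s in enumerate(track.scores, start=1):
                rows.append((p.protein_id, i, mech, s))
    pd.DataFrame(rows, columns=["protein_id", "position", "mechanism",
                                "score"]).to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        [{"mechanism": m, "confident_threshold": t, "alpha": a}
         for m, (t, a) in sorted(thr.items())],
    ).to_csv(thresholds_path, sep="\t", index=False)


def read_conservation(path, proteins: Dict[str, ProteinRecord]) -> None:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    for (pid, name), grp in df.groupby(["protein_id", "alignment"]):
        if pid not in proteins:
            raise VariantError(f"conservation references unknown protein {pid!r}")
        protein = proteins[pid]
        vec = np.zeros(len(protein))
        pos = grp["position"].to_numpy(dtype=int)
        vec[pos - 1] = grp["value"].to_numpy(dtype=float)
        protein.conservation[name] = vec


def write_conservation(proteins: Dict[str, ProteinRecord], path) -> None:
    rows = []
    for p in proteins.values():
        for name, vec in p.conservation.items():
            for i, val in enumerate(vec, start=1):
                rows.append((p.protein_id, i, name, val))
    pd.DataFrame(rows, columns=["protein_id", "position", "alignment",
                                "value"]).to_csv(path, sep="\t", index=False)


def read_homologs(path, proteins: Dict[str, ProteinRecord]) -> None:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    for (pid, org), grp in df.groupby(["protein_id", "organism"]):
        if pid in proteins:
            setattr(proteins[pid], f"homolog_identities_{org}",
                    list(grp["percent_identity"].astype(float)))


def write_homologs(proteins: Dict[str, ProteinRecord], path) -> None:
    rows = []
    for p in proteins.values():
        for org in ("human", "mouse"):
            for ident in getattr(p, f"homolog_identities_{org}"):
                rows.append((p.protein_id, org, ident))
    pd.DataFrame(rows, columns=["protein_id", "organism",
                                "percent_identity"]).to_csv(
        path, sep="\t", index=False)


def read_hit_counts(path) -> Dict[tuple, int]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return {(r.protein_id, int(r.position)): int(r.count)
            for r in df.itertuples(index=False)}


def read_null_distributions(path) -> Dict[str, NullDistribution]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for mech, grp in df.groupby("mechanism"):
        scores = np.repeat(grp["score"].to_numpy(dtype=int),
                           grp["count"].to_numpy(dtype=int))
        out[mech] = NullDistribution(mechanism=mech, scores=scores)
    return out


def write_null_distributions(nulls: Dict[str, NullDistribution], path) -> None:
    rows = []
    for mech, null in sorted(nulls.items()):
        vals, counts = np.unique(null.scores, return_counts=True)
        rows += [(mech, int(s), int(c)) for s, c in zip(vals, counts)]
    pd.DataFrame(rows, columns=["mechanism", "score", "count"]).to_csv(
        path, sep="\t", index=False)


def write_predictions(variants: Sequence[IndelVariant], scores,
                      impact_reports: Sequence[list], path,
                      thresholds: Optional[dict] = None) -> None:
    """Write the per-variant prediction table.

    One row per variant: pathogenicity score (6 decimals), class calls at
    the 10/5/1% FPR thresholds, then up to five significant mechanisms as
    ``(mechanism, impact_score, p, p_prime)`` column groups (empty when
    fewer mechanisms are significant).  Probabilities are printed in
    scientific notation with 3 significant figures.
    """
    from .classifier import PUBLISHED_THRESHOLDS, classify_at_threshold
    thresholds = thresholds or PUBLISHED_THRESHOLDS
    scores = np.asarray(scores, dtype=float)
    if not (len(variants) == scores.size == len(impact_reports)):
        raise ValueError("variants, scores and impact reports must align")
    rows = []
    for i, (v, s, report) in enumerate(zip(variants, scores, impact_reports)):
        row = {
            "variant_id": f"{v.protein_id}:{v.start}-{v.end}:"
                          f"{v.deleted_seq or '-'}>{v.inserted_seq or '-'}",
            "protein_id": v.protein_id, "start": v.start, "end": v.end,
            "deleted_seq": v.deleted_seq, "inserted_seq": v.inserted_seq,
            "score": f"{s:.6f}",
            "call_fpr10": classify_at_threshold(s, 0.10, thresholds=thresholds),
            "call_fpr5": classify_at_threshold(s, 0.05, thresholds=thresholds),
            "call_fpr1": classify_at_threshold(s, 0.01, thresholds=thresholds),
        }
        for j in range(5):
            prefix = f"mech{j + 1}_"
            if j < len(report):
                r = report[j]
                row[prefix + "mechanism"] = r.mechanism
                row[prefix + "impact_score"] = r.impact_score
                row[prefix + "p"] = f"{r.p_value:.3g}"
                row[prefix + "p_prime"] = f"{r.p_prime:.3g}"
            else:
                for f in _MECH_FIELDS:
                    row[prefix + ("mechanism" if f == "mechanism" else f)] = ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_enrichment_report(results, path) -> None:
    rows = [{
        "mechanism": r.mechanism, "f_pathogenic": r.f_pathogenic,
        "f_neutral": r.f_neutral, "E": r.E, "fisher_p": f"{r.fisher_p:.3g}",
        "bonferroni_p": f"{r.bonferroni_p:.3g}",
        "significant": r.bonferroni_significant,
    } for r in results]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ground_truth(ground_truth: dict, path) -> None:
    Path(path).write_text(json.dumps(ground_truth, indent=1))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_config(config, path) -> None:
    """Serialize any dataclass config (resolved run config) as JSON."""
    if dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    Path(path).write_text(json.dumps(config, indent=1, default=str))
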