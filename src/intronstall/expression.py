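"""Transcript-level summary statistics: splicing efficiency, induction folds.

These operate on linear-scale abundances (RT-qPCR quantities already
back-transformed from Ct space upstream of this package).
"""

from __future__ import annotations

import pandas as pd

from .exceptions import UndefinedStatisticError
from .models import TranscriptQuant

SPECIES = ("pre_mrna", "mrna", "exon2_total")


def splicing_efficiency(q: TranscriptQuant) -> float:
    """mRNA / (mRNA + pre-mRNA); the spliced fraction of transcript copies."""
    total = q.mrna + q.pre_mrna
    if total <= 0:
        raise UndefinedStatisticError(f"{q.gene_id} ({q.condition}): mRNA + pre-mRNA is zero")
    return q.mrna / total


def efficiency_ratio(q_restrictive: TranscriptQuant, q_permissive: TranscriptQuant) -> float:
    """Splicing efficiency at the restrictive condition relative to permissive."""
    denom = splicing_efficiency(q_permissive)
    if denom == 0:
        raise UndefinedStatisticError("permissive-condition efficiency is zero")
    return splicing_efficiency(q_restrictive) / denom


def relative_to_baseline(
    series: list[TranscriptQuant], baseline_label: str
) -> dict[str, dict[str, float | None]]:
    """Fold change of each species at each timepoint over the baseline.

    Returns {condition: {species: fold or None}}; a species whose baseline
    value is zero is reported as None (undefined) while the others are still
    computed.
    """
    baseline = next((q for q in series if q.condition == baseline_label), None)
    if baseline is None:
        raise UndefinedStatisticError(f"baseline condition {baseline_label!r} absent from series")
    out: dict[str, dict[str, float | None]] = {}
    for q in series:
        folds: dict[str, float | None] = {}
        for sp in SPECIES:
            base = getattr(baseline, sp)
            folds[sp] = None if base == 0 else getattr(q, sp) / base
        out[q.condition] = folds
    return out


def read_quants_tsv(path: str) -> list[TranscriptQuant]:
    """Load a long-format TSV (gene_id, condition, species, value)."""
    df = pd.read_csv(path, sep="\t")
    quants: dict[tuple[str, str], TranscriptQuant] = {}
    for _, row in df.iterrows():
        key = (str(row["gene_id"]), str(row["condition"]))
        q = quants.setdefault(key, TranscriptQuant(gene_id=key[0], condition=key[1]))
        setattr(q, str(row["species"]), float(row["value"]))
    return list(quants.values())


def write_quants_tsv(quants: list[TranscriptQuant], path: str) -> None:
    rows = [
        {"gene_id": q.gene_id, "condition": q.condition, "species": sp, "value": getattr(q, sp)}
        for q in quants
        for sp in SPECIES
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
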