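"""Reciprocal-best-hit (RBH) ortholog pairing.

Two genes, one per genome, are called putative orthologs when each is the
other's highest-scoring match in the all-vs-all similarity search.  The
result is one-to-one by construction; genes absent from the similarity
tables, or whose best hit is not reciprocated, simply remain unpaired.

Ties on bitscore are broken by lower e-value, then by lexicographically
smaller subject identifier, so the pairing is deterministic across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, TextIO, Union

import pandas as pd

from .genome_model import GenomeAnnotation, SimilarityRecord, ValidationError

__all__ = ["OrthologMap", "best_hits", "reciprocal_best_hits",
           "read_ortholog_tsv", "write_ortholog_tsv"]


@dataclass
class OrthologMap:
    """One-to-one gene pairs between genome A and genome B."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValidationError("ortholog map is not one-to-one")
        self.pairs = sorted(self.pairs)

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    @property
    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}

    def transpose(self) -> "OrthologMap":
        return OrthologMap([(b, a) for a, b in self.pairs])

    def bind(self, annot_a: GenomeAnnotation, annot_b: GenomeAnnotation) -> None:
        """Validate that every mapped gene exists in its annotation."""
        for a, b in self.pairs:
            if a not in annot_a:
                raise ValidationError(
                    f"ortholog map gene {a!r} absent from annotation "
                    f"{annot_a.species_label!r}"
                )
            if b not in annot_b:
                raise ValidationError(
                    f"ortholog map gene {b!r} absent from annotation "
                    f"{annot_b.species_label!r}"
                )


def best_hits(
    records: Iterable[SimilarityRecord],
    *,
    min_bitscore: float | None = None,
    max_evalue: float | None = None,
    self_hits_excluded: bool = False,
) -> dict[str, str]:
    """Best-scoring subject per query.

    Maximal bitscore wins; ties break by lower e-value, then by
    lexicographically smaller subject_id.  Optional score/e-value filters
    are applied before ranking.  An empty record list yields an empty map.
    """
    best: dict[str, SimilarityRecord] = {}
    for rec in records:
        if self_hits_excluded and rec.query_id == rec.subject_id:
            continue
        if min_bitscore is not None and rec.bitscore < min_bitscore:
            continue
        if max_evalue is not None and rec.evalue > max_evalue:
            continue
        cur = best.get(rec.query_id)
        if cur is None or _beats(rec, cur):
            best[rec.query_id] = rec
    return {q: r.subject_id for q, r in best.items()}


def _beats(new: SimilarityRecord, old: SimilarityRecord) -> bool:
    key_new = (-new.bitscore, new.evalue, new.subject_id)
    key_old = (-old.bitscore, old.evalue, old.subject_id)
    return key_new < key_old


def reciprocal_best_hits(
    records_ab: Iterable[SimilarityRecord],
    records_ba: Iterable[SimilarityRecord],
    *,
    min_bitscore: float | None = None,
    max_evalue: float | None = None,
) -> OrthologMap:
    """Pairs (g, h) with best_AB(g) = h and best_BA(h) = g."""
    ab = best_hits(records_ab, min_bitscore=min_bitscore, max_evalue=max_evalue)
    ba = best_hits(records_ba, min_bitscore=min_bitscore, max_evalue=max_evalue)
    pairs = [(g, h) for g, h in ab.items() if ba.get(h) == g]
    return OrthologMap(pairs)


def write_ortholog_tsv(
    omap: OrthologMap,
    dest: Union[str, Path, TextIO],
    bitscores_ab: Mapping[tuple[str, str], float] | None = None,
    bitscores_ba: Mapping[tuple[str, str], float] | None = None,
) -> None:
    """TSV with columns gene_a, gene_b, bitscore_ab, bitscore_ba."""
    rows = []
    for a, b in omap.pairs:
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "bitscore_ab": (bitscores_ab or {}).get((a, b), float("nan")),
                "bitscore_ba": (bitscores_ba or {}).get((b, a), float("nan")),
            }
        )
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "bitscore_ab", "bitscore_ba"]).to_csv(
        dest, sep="\t", index=False
    )


def read_ortholog_tsv(source: Union[str, Path, TextIO]) -> OrthologMap:
    df = pd.read_csv(source, sep="\t", dtype={"gene_a": str, "gene_b": str})
    return OrthologMap(list(zip(df.gene_a, df.gene_b)))
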