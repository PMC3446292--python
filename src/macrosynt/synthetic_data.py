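"""Simulated genome pairs with known rearrangement history.

The generator produces the statistical structure the synteny analyses
assume: an ancestral multi-scaffold genome with ordered, stranded genes;
two descendants derived by inversions, transpositions, translocations,
fusions and fissions plus gene loss/gain; a ground-truth one-to-one
ortholog map; all-vs-all similarity tables in which true orthologs score
highest with tunable paralog confusion; and scaffold sequences with a
background GC of 0.53, planted high-GC (0.61) repeat clusters and terminal
telomere-motif arrays — the GC values observed genome-wide vs inside
retrotransposon clusters in compact green-algal genomes.

Every operation is a pure function of (inputs, seed).  Event logs carry
concrete parameters so that :func:`replay_events` reproduces the derived
gene orders exactly — the replay oracle used by the test-suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from .genome_model import (
    GenomeAnnotation,
    RepeatInterval,
    write_bed,
    write_blast_tab,
    write_fasta,
    write_gff3,
)
from .orthology import OrthologMap
from .synteny_stats import ParameterError

__all__ = [
    "EventPlan",
    "SimulatedGenomePair",
    "simulate_ancestor",
    "apply_events",
    "replay_events",
    "simulate_pair",
    "simulate_similarity",
    "simulate_landscape_sequences",
    "gene_orders",
    "write_fixture_bundle",
]

# gene order representation: per scaffold a list of (gene_id, strand)
Orders = list[tuple[str, list[tuple[str, str]]]]


@dataclass(frozen=True)
class EventPlan:
    """Counts of rearrangement events and per-gene loss/gain rates.

    Segment lengths for inversion/transposition/translocation are geometric
    in gene units with mean ``mean_segment_genes``.
    """

    n_inversions: int = 0
    n_transpositions: int = 0
    n_translocations: int = 0
    n_fusions: int = 0
    n_fissions: int = 0
    gene_loss_rate: float = 0.0
    gene_gain_rate: float = 0.0
    mean_segment_genes: float = 3.0

    def __post_init__(self) -> None:
        for name in ("n_inversions", "n_transpositions", "n_translocations",
                     "n_fusions", "n_fissions"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("gene_loss_rate", "gene_gain_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.mean_segment_genes < 1.0:
            raise ParameterError("mean_segment_genes must be >= 1")


@dataclass
class SimulatedGenomePair:
    """Two descendants of one simulated ancestor plus ground truth."""

    ancestor: GenomeAnnotation
    genome_a: GenomeAnnotation
    genome_b: GenomeAnnotation
    truth: OrthologMap
    event_log_a: list[dict[str, Any]]
    event_log_b: list[dict[str, Any]]
    seed: int


def _layout(
    species_label: str,
    orders: Orders,
    mean_gene_len: float,
    mean_intergenic: float,
    rng: np.random.Generator,
) -> GenomeAnnotation:
    """Assign base-pair coordinates to a gene-order structure.

    Gene and intergenic lengths are exponential with the requested means;
    scaffold length is the end of the last gene plus one trailing gap.  The
    statistics downstream depend only on order and membership, so exact
    positions just need to be valid and non-overlapping.
    """
    scaffolds: list[tuple[str, int]] = []
    loci: list[tuple[str, str, int, int, str]] = []
    for sid, genes in orders:
        pos = 0
        for gene_id, strand in genes:
            pos += max(1, int(rng.exponential(mean_intergenic)))
            glen = max(1, int(rng.exponential(mean_gene_len)))
            loci.append((gene_id, sid, pos, pos + glen, strand))
            pos += glen
        pos += max(1, int(rng.exponential(mean_intergenic)))
        scaffolds.append((sid, pos))
    return GenomeAnnotation.from_loci(species_label, scaffolds, loci)


def simulate_ancestor(
    n_scaffolds: int = 10,
    genes_per_scaffold: int = 40,
    mean_gene_len: float = 1500.0,
    mean_intergenic: float = 500.0,
    seed: int = 0,
    species_label: str = "ancestor",
) -> GenomeAnnotation:
    """Ancestral genome: ``n_scaffolds`` scaffolds of ``genes_per_scaffold``
    non-overlapping genes each, strands uniform, coordinates exponential."""
    if n_scaffolds <= 0 or genes_per_scaffold <= 0:
        raise ParameterError("n_scaffolds and genes_per_scaffold must be positive")
    if mean_gene_len <= 0 or mean_intergenic <= 0:
        raise ParameterError("mean lengths must be positive")
    rng = np.random.default_rng(seed)
    orders: Orders = []
    g = 0
    for s in range(n_scaffolds):
        genes = []
        for _ in range(genes_per_scaffold):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append((f"anc_g{g:05d}", strand))
            g += 1
        orders.append((f"anc_s{s:02d}", genes))
    return _layout(species_label, orders, mean_gene_len, mean_intergenic, rng)


def gene_orders(annot: GenomeAnnotation) -> Orders:
    """The (scaffold_id, [(gene_id, strand), ...]) structure of an
    annotation — the object event replay is compared against."""
    return [
        (sid, [(g.gene_id, g.strand) for g in annot.genes_on(sid)])
        for sid in annot.scaffold_ids
    ]


# -- event operators (pure, applied to Orders in place) ---------------------


def _apply_one(orders: Orders, ev: dict[str, Any]) -> None:
    kind = ev["type"]
    if kind == "inversion":
        sid, genes = orders[ev["scaffold"]]
        s, L = ev["start"], ev["length"]
        seg = [(g, "-" if st == "+" else "+") for g, st in reversed(genes[s:s + L])]
        orders[ev["scaffold"]] = (sid, genes[:s] + seg + genes[s + L:])
    elif kind == "transposition":
        sid, genes = orders[ev["scaffold"]]
        s, L, p = ev["start"], ev["length"], ev["insert_pos"]
        seg = genes[s:s + L]
        rest = genes[:s] + genes[s + L:]
        orders[ev["scaffold"]] = (sid, rest[:p] + seg + rest[p:])
    elif kind == "translocation":
        src_sid, src = orders[ev["source"]]
        s, L = ev["start"], ev["length"]
        seg = src[s:s + L]
        orders[ev["source"]] = (src_sid, src[:s] + src[s + L:])
        dst_sid, dst = orders[ev["dest"]]
        p = ev["insert_pos"]
        orders[ev["dest"]] = (dst_sid, dst[:p] + seg + dst[p:])
    elif kind == "fusion":
        i, j = ev["first"], ev["second"]
        sid_i, genes_i = orders[i]
        _sid_j, genes_j = orders[j]
        orders[i] = (sid_i, genes_i + genes_j)
        del orders[j]
    elif kind == "fission":
        sid, genes = orders[ev["scaffold"]]
        b = ev["breakpoint"]
        orders[ev["scaffold"]] = (sid, genes[:b])
        orders.append((ev["new_scaffold_id"], genes[b:]))
    elif kind == "loss":
        lost = set(ev["genes"])
        for k, (sid, genes) in enumerate(orders):
            orders[k] = (sid, [(g, st) for g, st in genes if g not in lost])
    elif kind == "gain":
        for gene_id, strand, sidx, pos in ev["insertions"]:
            sid, genes = orders[sidx]
            orders[sidx] = (sid, genes[:pos] + [(gene_id, strand)] + genes[pos:])
    else:  # pragma: no cover
        raise ParameterError(f"unknown event type {kind!r}")


def _geometric_len(rng: np.random.Generator, mean: float, cap: int) -> int:
    # geometric on {1, 2, ...} with the requested mean, truncated to cap
    return min(int(rng.geometric(1.0 / mean)), cap)


_MAX_RETRIES = 100


def _draw_event(
    orders: Orders, kind: str, plan: EventPlan, rng: np.random.Generator,
    tag: int = 0,
) -> dict[str, Any]:
    for _ in range(_MAX_RETRIES):
        if kind == "inversion" or kind == "transposition":
            k = int(rng.integers(len(orders)))
            n = len(orders[k][1])
            need = 1 if kind == "inversion" else 2
            if n < need:
                continue
            s = int(rng.integers(n))
            L = _geometric_len(rng, plan.mean_segment_genes, n - s)
            if kind == "inversion":
                return {"type": kind, "scaffold": k, "start": s, "length": L}
            if n - L < 1:
                continue
            p = int(rng.integers(n - L + 1))
            return {"type": kind, "scaffold": k, "start": s, "length": L,
                    "insert_pos": p}
        elif kind == "translocation":
            if len(orders) < 2:
                break
            src = int(rng.integers(len(orders)))
            n = len(orders[src][1])
            if n < 1:
                continue
            dst = int(rng.integers(len(orders)))
            if dst == src:
                continue
            s = int(rng.integers(n))
            L = _geometric_len(rng, plan.mean_segment_genes, n - s)
            p = int(rng.integers(len(orders[dst][1]) + 1))
            return {"type": kind, "source": src, "start": s, "length": L,
                    "dest": dst, "insert_pos": p}
        elif kind == "fusion":
            if len(orders) < 2:
                break
            i, j = rng.choice(len(orders), size=2, replace=False)
            return {"type": kind, "first": int(min(i, j)), "second": int(max(i, j))}
        elif kind == "fission":
            k = int(rng.integers(len(orders)))
            n = len(orders[k][1])
            if n < 2:
                continue
            b = int(rng.integers(1, n))
            return {"type": kind, "scaffold": k, "breakpoint": b,
                    "new_scaffold_id": f"{orders[k][0]}x{tag}"}
    raise ParameterError(f"could not draw a feasible {kind} event")


def apply_events(
    annot: GenomeAnnotation,
    plan: EventPlan,
    seed: int = 0,
    species_label: str = "derived",
    mean_gene_len: float = 1500.0,
    mean_intergenic: float = 500.0,
) -> tuple[GenomeAnnotation, list[dict[str, Any]], OrthologMap]:
    """Derive a genome from ``annot`` under the event plan.

    Returns (derived annotation, event log, truth map ancestor -> derived).
    Derived gene ids are prefixed with the species label so the two branches
    of a pair never collide.  Rearrangements conserve gene identity; only
    loss removes genes from the truth map and gains enter without orthologs.
    """
    rng = np.random.default_rng(seed)
    orders = gene_orders(annot)
    log: list[dict[str, Any]] = []

    schedule = (
        ["inversion"] * plan.n_inversions
        + ["transposition"] * plan.n_transpositions
        + ["translocation"] * plan.n_translocations
        + ["fusion"] * plan.n_fusions
        + ["fission"] * plan.n_fissions
    )
    rng.shuffle(schedule)
    for kind in schedule:
        ev = _draw_event(orders, kind, plan, rng, tag=len(log))
        _apply_one(orders, ev)
        log.append(ev)

    if plan.gene_loss_rate > 0:
        all_genes = [g for _, genes in orders for g, _ in genes]
        lost = [g for g in all_genes if rng.random() < plan.gene_loss_rate]
        if lost:
            ev = {"type": "loss", "genes": lost}
            _apply_one(orders, ev)
            log.append(ev)
    if plan.gene_gain_rate > 0:
        n_now = sum(len(genes) for _, genes in orders)
        n_gain = int(rng.binomial(n_now, plan.gene_gain_rate)) if n_now else 0
        insertions = []
        for i in range(n_gain):
            sidx = int(rng.integers(len(orders)))
            pos = int(rng.integers(len(orders[sidx][1]) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            insertions.append((f"novel_g{i:04d}", strand, sidx, pos))
        if insertions:
            ev = {"type": "gain", "insertions": insertions}
            _apply_one(orders, ev)
            log.append(ev)

    prefix = species_label
    renamed: Orders = [
        (f"{prefix}_{sid}", [(f"{prefix}_{g}", st) for g, st in genes])
        for sid, genes in orders
    ]
    derived = _layout(species_label, renamed, mean_gene_len, mean_intergenic, rng)
    ancestral = {g.gene_id for g in annot.genes}
    truth = OrthologMap(
        [(g, f"{prefix}_{g}")
         for _, genes in orders for g, _ in genes if g in ancestral]
    )
    return derived, log, truth


def replay_events(
    annot: GenomeAnnotation, log: list[dict[str, Any]], species_label: str
) -> Orders:
    """Re-apply a recorded event log to the ancestor.

    Deterministic — the log carries concrete parameters — and returns the
    derived gene-order structure (ids renamed as in :func:`apply_events`)
    for comparison with ``gene_orders(derived)``.
    """
    orders = gene_orders(annot)
    for ev in log:
        _apply_one(orders, ev)
    return [
        (f"{species_label}_{sid}", [(f"{species_label}_{g}", st) for g, st in genes])
        for sid, genes in orders
    ]


def simulate_pair(
    n_scaffolds: int = 10,
    genes_per_scaffold: int = 40,
    plan_a: EventPlan = EventPlan(),
    plan_b: EventPlan = EventPlan(),
    seed: int = 0,
    mean_gene_len: float = 1500.0,
    mean_intergenic: float = 500.0,
) -> SimulatedGenomePair:
    """Two independent descendants of one simulated ancestor.

    The pair truth map composes the two per-branch maps: exactly the
    ancestral genes lost on neither branch.
    """
    root = np.random.SeedSequence(seed)
    s_anc, s_a, s_b = (int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3))
    anc = simulate_ancestor(
        n_scaffolds, genes_per_scaffold, mean_gene_len, mean_intergenic, s_anc
    )
    genome_a, log_a, truth_a = apply_events(
        anc, plan_a, s_a, "A", mean_gene_len, mean_intergenic
    )
    genome_b, log_b, truth_b = apply_events(
        anc, plan_b, s_b, "B", mean_gene_len, mean_intergenic
    )
    anc_to_a = truth_a.a_to_b
    anc_to_b = truth_b.a_to_b
    truth = OrthologMap(
        [(anc_to_a[g], anc_to_b[g]) for g in anc_to_a if g in anc_to_b]
    )
    return SimulatedGenomePair(anc, genome_a, genome_b, truth, log_a, log_b, seed)


def simulate_similarity(
    pair: SimulatedGenomePair,
    ortholog_bitscore_mean: float = 500.0,
    background_bitscore_mean: float = 100.0,
    confusion_rate: float = 0.0,
    background_records_per_gene: float = 2.0,
    seed: int = 0,
):
    """All-vs-all similarity tables (A->B, B->A) with planted RBH signal.

    Every truth pair receives reciprocal top-scoring records.  A
    ``confusion_rate`` fraction of pairs have one direction's best hit
    redirected to a random decoy (paralog confusion); background records
    connect random non-ortholog gene pairs at a lower score.
    """
    from .genome_model import SimilarityRecord

    if ortholog_bitscore_mean <= background_bitscore_mean:
        raise ParameterError(
            "ortholog_bitscore_mean must exceed background_bitscore_mean"
        )
    rng = np.random.default_rng(seed)
    a_genes = [g.gene_id for g in pair.genome_a.genes]
    b_genes = [g.gene_id for g in pair.genome_b.genes]
    rec_ab: list[SimilarityRecord] = []
    rec_ba: list[SimilarityRecord] = []

    def _rec(q: str, s: str, bits: float) -> SimilarityRecord:
        bits = max(10.0, bits)
        return SimilarityRecord(q, s, round(bits, 1), 10.0 ** (-bits / 10.0), 90.0)

    for a, b in pair.truth.pairs:
        bits = rng.normal(ortholog_bitscore_mean, ortholog_bitscore_mean * 0.05)
        rec_ab.append(_rec(a, b, bits))
        rec_ba.append(_rec(b, a, bits + rng.normal(0, 5)))
        if rng.random() < confusion_rate:
            # a paralog decoy outscores the true ortholog in one direction
            decoy = b_genes[int(rng.integers(len(b_genes)))]
            if decoy != b:
                rec_ab.append(_rec(a, decoy, bits * 1.2))

    n_bg = int(background_records_per_gene * len(a_genes))
    for _ in range(n_bg):
        a = a_genes[int(rng.integers(len(a_genes)))]
        b = b_genes[int(rng.integers(len(b_genes)))]
        bits = rng.normal(background_bitscore_mean, background_bitscore_mean * 0.2)
        if rng.random() < 0.5:
            rec_ab.append(_rec(a, b, bits))
        else:
            rec_ba.append(_rec(b, a, bits))
    return rec_ab, rec_ba


def simulate_landscape_sequences(
    annot: GenomeAnnotation,
    background_gc: float = 0.53,
    cluster_gc: float = 0.61,
    clusters_per_scaffold: int = 1,
    cluster_span: int = 20000,
    elements_per_cluster: int = 3,
    telomere_motif: str = "TTTAGGG",
    telomere_copies: int = 20,
    seed: int = 0,
):
    """Scaffold sequences with planted repeat clusters and telomere arrays.

    Bases are i.i.d. at ``background_gc``; each planted cluster span is
    resampled at ``cluster_gc`` and annotated as ``elements_per_cluster``
    abutting repeat intervals (emulating nested retrotransposon copies).
    Telomere arrays are written as tandem motif copies at both scaffold
    ends.  Returns (sequences, repeat BED intervals, planted-truth list).
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def _draw(n: int, gc: float) -> np.ndarray:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return rng.choice(4, size=n, p=p)

    telo = telomere_motif * telomere_copies
    sequences: dict[str, str] = {}
    bed: list[RepeatInterval] = []
    truth: list[dict[str, Any]] = []
    for sid, length in annot.scaffolds:
        needed = 2 * len(telo) + clusters_per_scaffold * (cluster_span + 4000) + 4000
        if length < needed:
            raise ParameterError(
                f"scaffold {sid} (length {length}) too short for the requested "
                f"landscape (needs >= {needed} bp)"
            )
        codes = _draw(length, background_gc)
        # evenly spaced cluster anchors, jittered, kept off the telomeres
        usable0 = len(telo) + 2000
        usable1 = length - len(telo) - 2000 - cluster_span
        slot = (usable1 - usable0) // max(1, clusters_per_scaffold)
        for ci in range(clusters_per_scaffold):
            lo = usable0 + ci * slot
            start = int(lo + rng.integers(max(1, slot - cluster_span)))
            codes[start:start + cluster_span] = _draw(cluster_span, cluster_gc)
            elen = cluster_span // elements_per_cluster
            for e in range(elements_per_cluster):
                e0 = start + e * elen
                e1 = start + cluster_span if e == elements_per_cluster - 1 else e0 + elen
                bed.append(RepeatInterval(sid, e0, e1, "Zepp"))
            truth.append({"scaffold_id": sid, "start": start,
                          "end": start + cluster_span})
        seq = "".join(bases[codes])
        if telomere_copies > 0:
            seq = telo + seq[len(telo):length - len(telo)] + telo
        sequences[sid] = seq
    return sequences, bed, truth


def write_fixture_bundle(
    out_dir: str | Path,
    pair: SimulatedGenomePair,
    records_ab=None,
    records_ba=None,
    sequences=None,
    repeats=None,
) -> None:
    """Write a simulated pair (and optional similarity/landscape layers) as
    a GFF3 + FASTA + BED + BLAST-tabular fixture bundle plus truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gff3(pair.genome_a, out / "genome_a.gff3")
    write_gff3(pair.genome_b, out / "genome_b.gff3")
    if records_ab is not None:
        write_blast_tab(records_ab, out / "similarity_ab.tsv")
    if records_ba is not None:
        write_blast_tab(records_ba, out / "similarity_ba.tsv")
    if sequences is not None:
        write_fasta(sequences, out / "genome_b.fasta")
    if repeats is not None:
        write_bed(repeats, out / "repeats_b.bed")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": pair.seed,
                "truth_pairs": pair.truth.pairs,
                "event_log_a": pair.event_log_a,
                "event_log_b": pair.event_log_b,
            },
            fh,
            indent=1,
        )
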