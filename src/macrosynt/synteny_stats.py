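"""Synteny and colinearity statistics with permutation null models.

Synteny (conservation of gene *content* between scaffolds) is measured on
the scaffold-by-scaffold ortholog-sharing contingency table: per-scaffold-
pair Z-scores against a "non-syntenic" null in which ortholog pairs are
re-associated at random, and a chi-square-derived synteny correlation
coefficient

    rho = sum_ij (n_ij - e_ij)^2 / (n * min(r-1, c-1) * e_ij),
    e_ij = n_i. * n_.j / n

(the Housworth-Postlethwait association measure; 1 at perfect one-to-one
scaffold association, 0 at independence).

Colinearity (conservation of gene *order*) is measured by the number of
conserved pairs of adjacent orthologs (CPAOs): two adjacent genes in one
genome whose orthologs are adjacent in the other.  Its null reshuffles the
order of ALL genes (orthologs and non-orthologs) of one genome, keeping the
number of genes per scaffold constant.

Both nulls report Z = (observed - null_mean) / null_sd over seeded
replicates; replicates with null_sd = 0 are flagged undefined rather than
reported as 0 or infinity.  By the paper-trail convention used throughout,
Z > 3 marks significantly-higher-than-null (one-sided P < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .genome_model import GenomeAnnotation, GenomeModelError
from .orthology import OrthologMap

__all__ = [
    "ContingencyMatrix",
    "SyntenyCorrelationResult",
    "PairZMatrix",
    "CPAOResult",
    "UndefinedStatisticError",
    "ParameterError",
    "build_contingency",
    "synteny_correlation",
    "randomize_ortholog_assignment",
    "scaffold_pair_significance",
    "synteny_correlation_significance",
    "count_cpao",
    "cpao_significance",
]

AdjacencyMode = Literal["all_genes", "orthologs_only"]


class UndefinedStatisticError(GenomeModelError):
    """The requested statistic is undefined for this input."""


class ParameterError(GenomeModelError):
    pass


# ---------------------------------------------------------------------------
# Contingency matrix
# ---------------------------------------------------------------------------


@dataclass
class ContingencyMatrix:
    """r x c ortholog-sharing counts n_ij with marginals and expectations."""

    row_ids: list[str]
    col_ids: list[str]
    counts: np.ndarray  # shape (r, c), non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_ids), len(self.col_ids)):
            raise ParameterError("contingency shape does not match labels")
        if (self.counts < 0).any():
            raise ParameterError("negative count in contingency matrix")

    @property
    def r(self) -> int:
        return len(self.row_ids)

    @property
    def c(self) -> int:
        return len(self.col_ids)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def expected(self) -> np.ndarray:
        """e_ij = n_i. * n_.j / n (NaN where a marginal or n is zero)."""
        n = self.n
        if n == 0:
            return np.full_like(self.counts, np.nan, dtype=float)
        e = np.outer(self.row_totals, self.col_totals) / float(n)
        e[e == 0] = np.nan
        return e


def build_contingency(
    omap: OrthologMap,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
) -> ContingencyMatrix:
    """Tally n_ij = orthologs shared by scaffold i of A and scaffold j of B.

    Scaffolds with zero orthologs appear as all-zero rows/columns; they are
    only excluded inside the rho computation, where e_ij = 0 makes the
    formula undefined.
    """
    omap.bind(annot_a, annot_b)
    row_ids = annot_a.scaffold_ids
    col_ids = annot_b.scaffold_ids
    ri = {sid: i for i, sid in enumerate(row_ids)}
    ci = {sid: j for j, sid in enumerate(col_ids)}
    counts = np.zeros((len(row_ids), len(col_ids)), dtype=np.int64)
    for a, b in omap.pairs:
        counts[ri[annot_a.gene(a).scaffold_id], ci[annot_b.gene(b).scaffold_id]] += 1
    return ContingencyMatrix(row_ids, col_ids, counts)


def synteny_correlation(m: ContingencyMatrix) -> float:
    """Housworth-Postlethwait synteny correlation rho of a contingency table.

    Rows/columns with zero marginal totals are dropped (their expected
    counts vanish and carry no orthology information); the effective r and c
    shrink accordingly.  Undefined when n = 0 or fewer than two non-empty
    scaffolds remain on either side.
    """
    n = m.n
    if n == 0:
        raise UndefinedStatisticError("synteny correlation undefined for n = 0")
    keep_r = m.row_totals > 0
    keep_c = m.col_totals > 0
    r_eff, c_eff = int(keep_r.sum()), int(keep_c.sum())
    if r_eff < 2 or c_eff < 2:
        raise UndefinedStatisticError(
            f"synteny correlation needs >= 2 non-empty scaffolds per genome "
            f"(got {r_eff} x {c_eff})"
        )
    sub = m.counts[np.ix_(keep_r, keep_c)].astype(float)
    e = np.outer(m.row_totals[keep_r], m.col_totals[keep_c]) / float(n)
    chi2 = ((sub - e) ** 2 / e).sum()
    return float(chi2 / (n * min(r_eff - 1, c_eff - 1)))


# ---------------------------------------------------------------------------
# Re-association null (synteny statistics)
# ---------------------------------------------------------------------------


def _pair_scaffold_indices(
    omap: OrthologMap, annot_a: GenomeAnnotation, annot_b: GenomeAnnotation
) -> tuple[np.ndarray, np.ndarray]:
    ri = {sid: i for i, sid in enumerate(annot_a.scaffold_ids)}
    ci = {sid: j for j, sid in enumerate(annot_b.scaffold_ids)}
    a_idx = np.array([ri[annot_a.gene(a).scaffold_id] for a, _ in omap.pairs], dtype=np.int64)
    b_idx = np.array([ci[annot_b.gene(b).scaffold_id] for _, b in omap.pairs], dtype=np.int64)
    return a_idx, b_idx


def randomize_ortholog_assignment(
    omap: OrthologMap,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    seed: int | np.random.Generator = 0,
) -> OrthologMap:
    """One draw of the non-syntenic re-association null.

    The B-side genes of the ortholog pairs are permuted uniformly at random
    among the pairs.  Because only the pairing changes — not which genes are
    orthologous — the number of orthologs per scaffold (every row and column
    marginal of the contingency table) is conserved by construction.
    """
    if omap.n == 0:
        raise ParameterError("cannot randomize an empty ortholog map")
    omap.bind(annot_a, annot_b)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b_side = [b for _, b in omap.pairs]
    perm = rng.permutation(len(b_side))
    return OrthologMap(
        [(a, b_side[perm[i]]) for i, (a, _) in enumerate(omap.pairs)]
    )


@dataclass
class PairZMatrix:
    """Per-scaffold-pair observed counts and Z-scores vs the re-association
    null; NaN z marks pairs whose null sd is zero (undefined, not 0)."""

    row_ids: list[str]
    col_ids: list[str]
    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray
    replicates: int
    seed: int

    @property
    def undefined(self) -> np.ndarray:
        return self.null_sd == 0

    @property
    def significant(self) -> np.ndarray:
        """One-sided significance mask at the Z > 3 convention."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.z, nan=-np.inf) > 3.0


def scaffold_pair_significance(
    omap: OrthologMap,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    replicates: int = 1000,
    seed: int = 0,
) -> PairZMatrix:
    """Z-score of each scaffold pair's shared-ortholog count against the
    re-association null (ortholog pairs re-associated at random, per-scaffold
    ortholog counts held constant)."""
    if replicates < 2:
        raise ParameterError("replicates must be >= 2")
    obs = build_contingency(omap, annot_a, annot_b)
    a_idx, b_idx = _pair_scaffold_indices(omap, annot_a, annot_b)
    r, c = obs.r, obs.c
    rng = np.random.default_rng(seed)
    total = np.zeros(r * c)
    total_sq = np.zeros(r * c)
    for _ in range(replicates):
        b_perm = b_idx[rng.permutation(b_idx.size)]
        counts = np.bincount(a_idx * c + b_perm, minlength=r * c)
        total += counts
        total_sq += counts.astype(float) ** 2
    mean = (total / replicates).reshape(r, c)
    var = (total_sq / replicates).reshape(r, c) - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs.counts - mean) / sd, np.nan)
    return PairZMatrix(
        obs.row_ids, obs.col_ids, obs.counts, mean, sd, z, replicates, seed
    )


@dataclass
class SyntenyCorrelationResult:
    rho: float
    null_mean: float
    null_sd: float
    z: float  # NaN when null_sd == 0
    replicates: int
    seed: int

    @property
    def undefined(self) -> bool:
        return self.null_sd == 0


def synteny_correlation_significance(
    omap: OrthologMap,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    replicates: int = 1000,
    seed: int = 0,
) -> SyntenyCorrelationResult:
    """rho on the observed map, with Z against the re-association null.

    The null conserves all marginals, so the expected counts e_ij (and the
    set of non-empty scaffolds) are identical across replicates; only the
    cell counts change.
    """
    if replicates < 2:
        raise ParameterError("replicates must be >= 2")
    obs = build_contingency(omap, annot_a, annot_b)
    rho_obs = synteny_correlation(obs)  # raises if undefined
    a_idx, b_idx = _pair_scaffold_indices(omap, annot_a, annot_b)
    r, c = obs.r, obs.c
    keep_r = obs.row_totals > 0
    keep_c = obs.col_totals > 0
    k = min(int(keep_r.sum()) - 1, int(keep_c.sum()) - 1)
    e = np.outer(obs.row_totals[keep_r], obs.col_totals[keep_c]) / float(obs.n)
    rng = np.random.default_rng(seed)
    rhos = np.empty(replicates)
    for t in range(replicates):
        b_perm = b_idx[rng.permutation(b_idx.size)]
        counts = np.bincount(a_idx * c + b_perm, minlength=r * c).reshape(r, c)
        sub = counts[np.ix_(keep_r, keep_c)]
        rhos[t] = ((sub - e) ** 2 / e).sum() / (obs.n * k)
    mean, sd = float(rhos.mean()), float(rhos.std())  # population sd
    z = (rho_obs - mean) / sd if sd > 0 else float("nan")
    return SyntenyCorrelationResult(rho_obs, mean, sd, z, replicates, seed)


# ---------------------------------------------------------------------------
# CPAO: conserved pairs of adjacent orthologs
# ---------------------------------------------------------------------------


@dataclass
class CPAOResult:
    """CPAO count, the pair quadruples (gene_a, gene_a', gene_b, gene_b'),
    and — when a null was run — its moments and Z-score."""

    n_cpao: int
    pair_list: list[tuple[str, str, str, str]]
    null_mean: float | None = None
    null_sd: float | None = None
    z: float | None = None
    replicates: int | None = None
    seed: int | None = None

    @property
    def undefined(self) -> bool:
        return self.null_sd == 0

    def __post_init__(self) -> None:
        if self.n_cpao != len(self.pair_list):
            raise ParameterError("n_cpao must equal the number of listed pairs")


def _adjacent_mapped_pairs(
    annot: GenomeAnnotation, mapped: set[str], mode: AdjacencyMode
) -> list[tuple[str, str]]:
    """Adjacent gene pairs of one genome with both members in the map.

    all_genes: adjacency over every annotated gene — an intervening
    non-ortholog breaks adjacency.  orthologs_only: adjacency among mapped
    genes after skipping non-orthologs.
    """
    out: list[tuple[str, str]] = []
    for sid in annot.scaffold_ids:
        genes = annot.genes_on(sid)
        if mode == "orthologs_only":
            genes = [g for g in genes if g.gene_id in mapped]
            out.extend(
                (g.gene_id, h.gene_id) for g, h in zip(genes, genes[1:])
            )
        else:
            out.extend(
                (g.gene_id, h.gene_id)
                for g, h in zip(genes, genes[1:])
                if g.gene_id in mapped and h.gene_id in mapped
            )
    return out


def _b_position_arrays(
    scaf: np.ndarray, ordinal: np.ndarray, mapped_mask: np.ndarray, mode: AdjacencyMode
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (scaffold index, position) used for B-side adjacency.

    In all_genes mode the position is the genome ordinal; in orthologs_only
    mode it is the gene's rank among mapped genes of its scaffold (unmapped
    genes get sentinel positions that can never be adjacent).
    """
    if mode == "all_genes":
        return scaf, ordinal
    pos = np.full(scaf.size, -10, dtype=np.int64)
    idx = np.flatnonzero(np.asarray(mapped_mask, dtype=bool))
    if idx.size == 0:
        return scaf, pos
    order = idx[np.lexsort((ordinal[idx], scaf[idx]))]
    s = scaf[order]
    starts = np.r_[True, s[1:] != s[:-1]]
    run_start = np.maximum.accumulate(np.where(starts, np.arange(order.size), 0))
    pos[order] = np.arange(order.size) - run_start
    return scaf, pos


def count_cpao(
    omap: OrthologMap,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    adjacency_mode: AdjacencyMode = "all_genes",
) -> CPAOResult:
    """Count conserved pairs of adjacent orthologs (no null model).

    A CPAO is an unordered pair of genes consecutive by ordinal on one
    scaffold of genome A, both orthology-mapped, whose images are consecutive
    by ordinal on one scaffold of genome B.  Orientation and strand are
    ignored; adjacency never spans a scaffold boundary.
    """
    omap.bind(annot_a, annot_b)
    a_to_b = omap.a_to_b
    b_genes = [g.gene_id for g in annot_b.genes]
    b_index = {gid: i for i, gid in enumerate(b_genes)}
    scaf_ids = {sid: i for i, sid in enumerate(annot_b.scaffold_ids)}
    scaf = np.array([scaf_ids[g.scaffold_id] for g in annot_b.genes], dtype=np.int64)
    ordinal = np.array([g.ordinal for g in annot_b.genes], dtype=np.int64)
    mapped_mask = np.array([gid in omap.b_to_a for gid in b_genes])
    scafp, pos = _b_position_arrays(scaf, ordinal, mapped_mask, adjacency_mode)

    pairs: list[tuple[str, str, str, str]] = []
    for ga, gb in _adjacent_mapped_pairs(annot_a, set(a_to_b), adjacency_mode):
        ha, hb = a_to_b[ga], a_to_b[gb]
        u, v = b_index[ha], b_index[hb]
        if scafp[u] == scafp[v] and abs(int(pos[u]) - int(pos[v])) == 1:
            pairs.append((ga, gb, ha, hb))
    return CPAOResult(len(pairs), pairs)


def cpao_significance(
    omap: OrthologMap,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    replicates: int = 1000,
    seed: int = 0,
    shuffled_genome: Literal["A", "B"] = "B",
    adjacency_mode: AdjacencyMode = "all_genes",
) -> CPAOResult:
    """CPAO count with Z-score against the gene-order-reshuffling null.

    Each null replicate permutes ALL gene identities (orthologs and
    non-orthologs) of the chosen genome uniformly across gene slots
    genome-wide, keeping the number of genes per scaffold constant, and
    recounts CPAOs.
    """
    if replicates < 2:
        raise ParameterError("replicates must be >= 2")
    if shuffled_genome == "A":
        # symmetric statistic: shuffle-A equals shuffle-B on the transpose
        res = cpao_significance(
            omap.transpose(), annot_b, annot_a, replicates, seed, "B", adjacency_mode
        )
        return CPAOResult(
            res.n_cpao,
            [(a, b, c, d) for (c, d, a, b) in res.pair_list],
            res.null_mean, res.null_sd, res.z, res.replicates, res.seed,
        )

    observed = count_cpao(omap, annot_a, annot_b, adjacency_mode)
    a_to_b = omap.a_to_b
    b_to_a = omap.b_to_a
    b_genes = [g.gene_id for g in annot_b.genes]
    nb = len(b_genes)
    b_index = {gid: i for i, gid in enumerate(b_genes)}
    # fixed slot layout of genome B: slot s lives on scaffold slot_scaf[s]
    # at ordinal slot_ord[s]; a replicate assigns genes to slots
    scaf_ids = {sid: i for i, sid in enumerate(annot_b.scaffold_ids)}
    slot_scaf = np.array([scaf_ids[g.scaffold_id] for g in annot_b.genes], dtype=np.int64)
    slot_ord = np.array([g.ordinal for g in annot_b.genes], dtype=np.int64)
    mapped_mask = np.array([gid in b_to_a for gid in b_genes])
    adj = _adjacent_mapped_pairs(annot_a, set(a_to_b), adjacency_mode)
    u = np.array([b_index[a_to_b[g]] for g, _ in adj], dtype=np.int64)
    v = np.array([b_index[a_to_b[h]] for _, h in adj], dtype=np.int64)

    rng = np.random.default_rng(seed)
    counts = np.empty(replicates, dtype=np.int64)
    slot_of_gene = np.empty(nb, dtype=np.int64)
    for t in range(replicates):
        perm = rng.permutation(nb)  # perm[s] = gene placed in slot s
        slot_of_gene[perm] = np.arange(nb)
        scaf_g = slot_scaf[slot_of_gene]
        ord_g = slot_ord[slot_of_gene]
        scafp, pos = _b_position_arrays(scaf_g, ord_g, mapped_mask, adjacency_mode)
        counts[t] = np.sum((scafp[u] == scafp[v]) & (np.abs(pos[u] - pos[v]) == 1))
    mean, sd = float(counts.mean()), float(counts.std())
    z = (observed.n_cpao - mean) / sd if sd > 0 else float("nan")
    return CPAOResult(
        observed.n_cpao, observed.pair_list, mean, sd, z, replicates, seed
    )
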