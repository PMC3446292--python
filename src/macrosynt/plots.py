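"""Ortholog dot-plot rendering.

The layout follows the classic whole-genome macro-synteny figure: scaffolds
of each genome ordered by decreasing length along the axes, box widths
proportional to scaffold bp, one dot per ortholog pair at the two gene
midpoints in cumulative coordinates, colored by strand agreement, and the
scaffold-pair boxes shaded by their synteny Z-score (the z > 3 class
visually distinct).
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .genome_model import GenomeAnnotation
from .orthology import OrthologMap
from .synteny_stats import PairZMatrix, ParameterError

__all__ = ["DotPlotSpec", "build_dotplot_spec", "render_dotplot"]


@dataclass
class DotPlotSpec:
    """Serialized geometry of a dot plot, renderer-independent.

    dots: (x, y, same_strand, gene_a, gene_b) in cumulative bp coordinates.
    boxes: (scaffold_a, scaffold_b, x0, x1, y0, y1, z_class) with z_class in
    {"undefined", "ns", "significant"}.
    """

    scaffolds_a: list[tuple[str, int]]  # decreasing length, top_k only
    scaffolds_b: list[tuple[str, int]]
    offsets_a: dict[str, int]
    offsets_b: dict[str, int]
    dots: list[tuple[float, float, bool, str, str]]
    boxes: list[tuple[str, str, float, float, float, float, str]]


def build_dotplot_spec(
    omap: OrthologMap,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    zmatrix: PairZMatrix | None = None,
    top_k: int = 29,
) -> DotPlotSpec:
    """Compute the dot-plot geometry for the top_k biggest scaffolds."""
    omap.bind(annot_a, annot_b)
    if zmatrix is not None and (
        zmatrix.row_ids != annot_a.scaffold_ids
        or zmatrix.col_ids != annot_b.scaffold_ids
    ):
        raise ParameterError("Z-matrix dimensions do not match the annotations")

    def _top(annot: GenomeAnnotation) -> list[tuple[str, int]]:
        return sorted(annot.scaffolds, key=lambda t: (-t[1], t[0]))[:top_k]

    sc_a, sc_b = _top(annot_a), _top(annot_b)
    off_a, off_b = {}, {}
    pos = 0
    for sid, L in sc_a:
        off_a[sid] = pos
        pos += L
    pos = 0
    for sid, L in sc_b:
        off_b[sid] = pos
        pos += L

    dots = []
    for a, b in omap.pairs:
        ga, gb = annot_a.gene(a), annot_b.gene(b)
        if ga.scaffold_id not in off_a or gb.scaffold_id not in off_b:
            continue
        dots.append(
            (
                off_a[ga.scaffold_id] + ga.midpoint,
                off_b[gb.scaffold_id] + gb.midpoint,
                ga.strand == gb.strand,
                a,
                b,
            )
        )

    zlookup = {}
    if zmatrix is not None:
        for i, rid in enumerate(zmatrix.row_ids):
            for j, cid in enumerate(zmatrix.col_ids):
                if zmatrix.undefined[i, j]:
                    zlookup[(rid, cid)] = "undefined"
                elif zmatrix.z[i, j] > 3.0:
                    zlookup[(rid, cid)] = "significant"
                else:
                    zlookup[(rid, cid)] = "ns"
    boxes = []
    for sid_a, La in sc_a:
        for sid_b, Lb in sc_b:
            boxes.append(
                (
                    sid_a,
                    sid_b,
                    float(off_a[sid_a]),
                    float(off_a[sid_a] + La),
                    float(off_b[sid_b]),
                    float(off_b[sid_b] + Lb),
                    zlookup.get((sid_a, sid_b), "undefined"),
                )
            )
    return DotPlotSpec(sc_a, sc_b, off_a, off_b, dots, boxes)


_BOX_COLORS = {"significant": "#ffb347", "ns": "#ffffff", "undefined": "#eeeeee"}


def render_dotplot(
    omap: OrthologMap,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    zmatrix: PairZMatrix | None = None,
    top_k: int = 29,
    out_path: str = "dotplot.svg",
    fmt: str | None = None,
) -> DotPlotSpec:
    """Render the ortholog dot plot to SVG or PNG; returns the spec used."""
    spec = build_dotplot_spec(omap, annot_a, annot_b, zmatrix, top_k)
    fig, ax = plt.subplots(figsize=(8, 8))
    for _, _, x0, x1, y0, y1, zclass in spec.boxes:
        ax.add_patch(
            Rectangle(
                (x0, y0), x1 - x0, y1 - y0,
                facecolor=_BOX_COLORS[zclass], edgecolor="0.6", linewidth=0.3,
            )
        )
    same = [(x, y) for x, y, s, *_ in spec.dots if s]
    opp = [(x, y) for x, y, s, *_ in spec.dots if not s]
    if same:
        ax.plot(*zip(*same), ".", color="red", ms=2, label="same strand")
    if opp:
        ax.plot(*zip(*opp), ".", color="green", ms=2, label="opposite strand")
    xmax = sum(L for _, L in spec.scaffolds_a) or 1
    ymax = sum(L for _, L in spec.scaffolds_b) or 1
    ax.set_xlim(0, xmax)
    ax.set_ylim(0, ymax)
    ax.set_xlabel(f"{annot_a.species_label} (cumulative bp)")
    ax.set_ylabel(f"{annot_b.species_label} (cumulative bp)")
    fig.savefig(out_path, format=fmt)
    plt.close(fig)
    return spec
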