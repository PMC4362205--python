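"""SVG renderers: barcode logos, sequence logos, dependency and 2D heatmaps.

A *barcode logo* compresses a PWM column into a stack of colored bars: at
each position four bars are drawn whose widths are the base frequencies
(range 0-1), while the height and color intensity of all bars at that
position equal the frequency of the most common base (range 0.25-1, taken
literally: a uniform column gets height/intensity 0.25).  Columns of similar
composition then produce similar color stripes, which makes visual alignment
of many motifs practical where stacked-letter logos become unreadable.

All renderers are pure: identical input gives byte-identical SVG.
"""

from __future__ import annotations

import numpy as np

from .dependency import PairDependencyTable
from .pwm import PWM
from .similarity import SimilarityMatrix, tree_leaf_order

# Base colors: common logo convention.
BASE_COLORS = {
    "A": (34, 139, 34),    # green
    "C": (0, 0, 205),      # blue
    "G": (255, 165, 0),    # orange
    "T": (205, 0, 0),      # red
}
ROW_ORDER = "ACGT"


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _rgb(color: tuple[int, int, int], intensity: float = 1.0) -> str:
    """Blend a base color toward white as intensity drops below 1."""
    r, g, b = (round(255 + (c - 255) * intensity) for c in color)
    return f"rgb({r},{g},{b})"


def _svg_doc(width: float, height: float, body: list[str]) -> str:
    head = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n'
    )
    return head + "\n".join(body) + "\n</svg>\n"


def barcode_logo(pwm: PWM, column_width: float = 20.0, height: float = 60.0) -> str:
    """Barcode-logo SVG for a PWM.

    Per column: four bars (A,C,G,T order) with widths = base frequency x
    column width; bar height and color intensity both equal the maximum base
    frequency of the column (identity map on [0.25, 1]).  Bars are
    bottom-aligned.
    """
    body: list[str] = []
    for i in range(pwm.width):
        col = pwm.frequencies[:, i]
        maxf = float(col.max())
        bar_h = maxf * height
        y = height - bar_h
        x = i * column_width
        for b, freq in zip(ROW_ORDER, col):
            wseg = float(freq) * column_width
            if wseg > 0:
                body.append(
                    f'<rect class="bar" data-base="{b}" data-pos="{i + 1}" '
                    f'data-freq="{_fmt(float(freq))}" data-maxfreq="{_fmt(maxf)}" '
                    f'x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(wseg)}" '
                    f'height="{_fmt(bar_h)}" fill="{_rgb(BASE_COLORS[b], maxf)}"/>'
                )
            x += wseg
    return _svg_doc(pwm.width * column_width, height, body)


def sequence_logo(pwm: PWM, column_width: float = 20.0, height: float = 60.0) -> str:
    """Conventional information-content sequence logo (letter heights in bits).

    Letter height = frequency x column information content; a column carries
    at most 2 bits, which maps to the full drawing height.
    """
    ic = pwm.information_content()
    body: list[str] = []
    for i in range(pwm.width):
        col = pwm.frequencies[:, i]
        order = np.argsort(col)  # draw small letters first, from the bottom
        y = height
        for bi in order:
            freq = float(col[bi])
            letter_bits = freq * float(ic[i])
            h = letter_bits / 2.0 * height
            if h <= 0:
                continue
            y -= h
            b = ROW_ORDER[bi]
            # Glyph drawn in a 10x10 box, scaled to the letter cell.
            sx = column_width / 10.0
            sy = h / 10.0
            body.append(
                f'<text class="letter" data-base="{b}" data-pos="{i + 1}" '
                f'data-bits="{_fmt(letter_bits)}" '
                f'transform="translate({_fmt(i * column_width)},{_fmt(y + h)}) '
                f'scale({_fmt(sx)},{_fmt(sy)})" font-family="monospace" '
                f'font-size="13" fill="{_rgb(BASE_COLORS[b])}">{b}</text>'
            )
    return _svg_doc(pwm.width * column_width, height, body)


def _heat_color(frac: float) -> str:
    """White -> red ramp for dependency scores."""
    frac = min(max(frac, 0.0), 1.0)
    return _rgb((205, 0, 0), frac)


def dependency_heatmap(
    table: PairDependencyTable, tile: float = 36.0, max_score: float = 100.0
) -> str:
    """Upper-triangle position-pair heatmap with over/under dot grids.

    Tile (i, j) is colored by the pair's mispredict score; the 4x4 dot grid
    inside marks dinucleotides over- (yellow) or under- (blue) represented
    relative to the mononucleotide prediction.
    """
    w = table.width
    body: list[str] = []
    dot_r = tile / 12.0
    for (i, j) in table.pairs():
        x, y = j * tile, i * tile
        score = table.score_pct[(i, j)]
        body.append(
            f'<rect class="tile" data-i="{i + 1}" data-j="{j + 1}" '
            f'data-score="{_fmt(score)}" x="{_fmt(x)}" y="{_fmt(y)}" '
            f'width="{_fmt(tile)}" height="{_fmt(tile)}" '
            f'fill="{_heat_color(score / max_score)}" stroke="rgb(128,128,128)" '
            f'stroke-width="0.5"/>'
        )
        sign = table.sign[(i, j)]
        for a in range(4):
            for b in range(4):
                s = sign[a, b]
                if s == "neutral":
                    fill = "rgb(200,200,200)"
                elif s == "over":
                    fill = "rgb(255,215,0)"
                else:
                    fill = "rgb(30,60,255)"
                cx = x + (b + 0.5) * tile / 4.0
                cy = y + (a + 0.5) * tile / 4.0
                body.append(
                    f'<circle class="dot" data-pair="{ROW_ORDER[a]}{ROW_ORDER[b]}" '
                    f'data-sign="{s}" cx="{_fmt(cx)}" cy="{_fmt(cy)}" '
                    f'r="{_fmt(dot_r)}" fill="{fill}"/>'
                )
    return _svg_doc(w * tile, w * tile, body)


def _scale2d(motif_s: float, aa_s: float) -> str:
    """2D color scale: motif similarity drives red, protein similarity green;
    both high -> yellow, motif-only -> red, protein-only -> green."""
    m = min(max(motif_s, 0.0), 1.0)
    a = min(max(aa_s, 0.0), 1.0)
    r = round(40 + 215 * m)
    g = round(40 + 215 * a)
    b = 40
    return f"rgb({r},{g},{b})"


def similarity_heatmap_2d(
    motif_sim: SimilarityMatrix,
    aa_sim: SimilarityMatrix,
    ordering: str | list[str] | None = None,
    tile: float = 12.0,
    aa_max: float | None = None,
) -> str:
    """Two-dimensional motif x protein similarity heatmap.

    One cell per motif pair, colored on a 2D scale (one axis motif
    similarity, the other protein-sequence similarity; both high = yellow).
    Rows/columns follow ``ordering``: a Newick string, an explicit id list,
    or the input order.  Protein similarities are scaled to [0, 1] by
    ``aa_max`` (default: the matrix maximum).
    """
    if set(motif_sim.ids) != set(aa_sim.ids):
        raise ValueError("motif and protein similarity matrices have different ids")
    if ordering is None:
        ids = list(motif_sim.ids)
    elif isinstance(ordering, str):
        ids = tree_leaf_order(ordering)
    else:
        ids = list(ordering)
    if set(ids) != set(motif_sim.ids):
        raise ValueError("ordering ids do not match matrix ids")
    mi = {x: i for i, x in enumerate(motif_sim.ids)}
    ai = {x: i for i, x in enumerate(aa_sim.ids)}
    if aa_max is None:
        aa_max = float(aa_sim.matrix.max()) or 1.0
    body: list[str] = []
    for r, idr in enumerate(ids):
        for c, idc in enumerate(ids):
            ms = float(motif_sim.matrix[mi[idr], mi[idc]])
            asim = float(aa_sim.matrix[ai[idr], ai[idc]]) / aa_max
            body.append(
                f'<rect class="cell" data-row="{idr}" data-col="{idc}" '
                f'data-motif="{_fmt(ms)}" data-aa="{_fmt(asim)}" '
                f'x="{_fmt(c * tile)}" y="{_fmt(r * tile)}" '
                f'width="{_fmt(tile)}" height="{_fmt(tile)}" '
                f'fill="{_scale2d(ms, asim)}"/>'
            )
    n = len(ids)
    return _svg_doc(n * tile, n * tile, body)
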