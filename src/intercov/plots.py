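"""Static circos-style and matrix renderings of covariation scores.

The circos drawing has four concentric tracks: reference residue labels,
a per-position conservation ring (red = conserved, blue = variable, with
the colour ramp anchored at the 5th/95th percentiles of the conservation
values), a protein-segment ring, and Bezier chords for the selected top
links — red when the two positions belong to different proteins, the
segment colour when both belong to the same one. The matrix view plots the
upper triangle only, coloured by score rank band (dark red ranks 1-100,
orange 101-500, yellow 501-2500; deeper ranks are not drawn).

Rendering is a deterministic function of its inputs (no RNG).
"""

from __future__ import annotations

import math

import numpy as np

from .compare import INTER, ScoreTable, rank_pairs, top_class_pairs

SEGMENT_COLORS = ["#2e8b57", "#8a2be2", "#e07b00", "#4682b4",
                  "#8b4513", "#008080"]  # green, violet, orange, blue, ...
RANK_BANDS = [(100, "#8b0000"), (500, "#ff8c00"), (2500, "#ffd500")]


def _conservation_color(value: float, lo: float, hi: float) -> str:
    """Red (high) to blue (low), linear between the anchor percentiles."""
    if hi <= lo:
        t = 0.5
    else:
        t = min(max((value - lo) / (hi - lo), 0.0), 1.0)
    r = int(round(40 + 215 * t))
    b = int(round(40 + 215 * (1 - t)))
    return f"#{r:02x}30{b:02x}"


def _position_angle(k: int, L: int) -> float:
    return 2 * math.pi * k / L - math.pi / 2


def _xy(radius: float, angle: float, cx: float = 250.0, cy: float = 250.0):
    return cx + radius * math.cos(angle), cy + radius * math.sin(angle)


def render_circos(table: ScoreTable, conservation: np.ndarray,
                  selection: dict, reference: str | None = None) -> str:
    """Render the circos view to an SVG string.

    ``selection`` is {'class': 'inter'|'intra'|'both', 'n': int}: the top-n
    links of that class are drawn (an error propagates from links_needed
    when fewer exist). Each selected pair contributes exactly one
    ``class="chord"`` path.
    """
    L = table.L
    conservation = np.asarray(conservation, dtype=float)
    if conservation.shape != (L,):
        raise ValueError("conservation must have one value per column")
    ranked = rank_pairs(table)
    top = top_class_pairs(ranked, selection["class"], selection["n"])

    lo, hi = np.percentile(conservation, [5, 95])
    seg_color = {label: SEGMENT_COLORS[k % len(SEGMENT_COLORS)]
                 for k, (label, _, _) in enumerate(table.segments)}
    col_label = np.empty(L, dtype=object)
    for label, start, end in table.segments:
        col_label[start:end] = label

    parts = ['<svg xmlns="http://www.w3.org/2000/svg" width="500" '
             'height="500" viewBox="0 0 500 500">',
             '<rect width="500" height="500" fill="white"/>']

    # residue label track (thinned for long alignments)
    step = max(1, math.ceil(L / 72))
    for k in range(0, L, step):
        angle = _position_angle(k, L)
        x, y = _xy(212, angle)
        residue = reference[k] if reference else ""
        deg = math.degrees(angle)
        parts.append(
            f'<text class="residue-label" x="{x:.1f}" y="{y:.1f}" '
            f'font-size="7" text-anchor="middle" '
            f'transform="rotate({deg + 90:.1f} {x:.1f} {y:.1f})">'
            f'{residue}{k + 1}</text>')

    # conservation and segment tracks as per-position ticks
    half = math.pi / L
    for k in range(L):
        angle = _position_angle(k, L)
        for radius, width, color, cls in [
            (188, 16, _conservation_color(conservation[k], lo, hi),
             "conservation"),
            (168, 12, seg_color[col_label[k]], "segment"),
        ]:
            x0, y0 = _xy(radius - width / 2, angle - half)
            x1, y1 = _xy(radius + width / 2, angle - half)
            x2, y2 = _xy(radius + width / 2, angle + half)
            x3, y3 = _xy(radius - width / 2, angle + half)
            parts.append(
                f'<path class="{cls}" d="M {x0:.1f} {y0:.1f} L {x1:.1f} '
                f'{y1:.1f} L {x2:.1f} {y2:.1f} L {x3:.1f} {y3:.1f} Z" '
                f'fill="{color}" stroke="none"/>')

    # chords
    for row in top.itertuples(index=False):
        ai = _position_angle(int(row.i), L)
        aj = _position_angle(int(row.j), L)
        x1, y1 = _xy(158, ai)
        x2, y2 = _xy(158, aj)
        if row.cls == INTER:
            color = "#d62728"  # red: positions belong to different proteins
        else:
            color = seg_color[row.cls.split(":", 1)[1]]
        parts.append(
            f'<path class="chord" d="M {x1:.1f} {y1:.1f} Q 250 250 '
            f'{x2:.1f} {y2:.1f}" fill="none" stroke="{color}" '
            f'stroke-width="1.2" opacity="0.75"/>')

    parts.append("</svg>")
    return "\n".join(parts)


def render_matrix(table: ScoreTable, ax=None):
    """Upper-triangular rank-band scatter of the score matrix.

    Returns the matplotlib Axes. Pairs ranked deeper than 2500 are not
    plotted; segment boundaries are drawn as grid lines.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ranked = rank_pairs(table)
    prev = 0
    for upper, color in RANK_BANDS:
        band = ranked.iloc[prev:upper]
        if len(band):
            # x = larger index, so points fall in the upper triangle
            ax.scatter(band["j"] + 1, band["i"] + 1, s=6, c=color,
                       label=f"ranks {prev + 1}-{upper}")
        prev = upper
    for _, start, end in table.segments[:-1]:
        ax.axvline(end + 0.5, color="grey", lw=0.6)
        ax.axhline(end + 0.5, color="grey", lw=0.6)
    L = table.L
    ax.set_xlim(0.5, L + 0.5)
    ax.set_ylim(L + 0.5, 0.5)
    ax.set_xlabel("position j")
    ax.set_ylabel("position i")
    ax.set_title(f"{table.method}: score rank bands (upper triangle)")
    ax.legend(loc="lower left", fontsize=7)
    return ax


def save_figure(ax, path) -> None:
    """Save to SVG/PNG/PDF according to the file suffix, without metadata
    that would break byte-level reproducibility."""
    fig = ax.figure
    fig.savefig(path, dpi=150, metadata=_empty_metadata(str(path)))


def _empty_metadata(path: str):
    if path.endswith(".png"):
        return {"Software": None}
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".pdf"):
        return {"CreationDate": None}
    return None
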