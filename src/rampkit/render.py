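"""Deterministic RAMP profile rendering (plain text and SVG).

Profiles over the same panel always render with the same bar order and the
same per-ratio colors, which is what makes side-by-side comparison of
knockdown signatures work.  The SVG writer is hand-rolled and fully
deterministic: rendering the same profile twice yields byte-identical
files.  Missing entries (below-detection ratios) are drawn as hatched
placeholders, never as zero-height bars.
"""

from __future__ import annotations

from .ramp import RAMPProfile

__all__ = ["render_text", "render_svg", "PALETTE"]

#: fixed color palette; ratio i of a panel always gets PALETTE[i % len].
PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
    "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
)

_BAR_HALF = 24  # character cells per log2 unit span in text mode


def render_text(profile: RAMPProfile, max_abs: float = 4.0) -> str:
    """Signed bar strings, one line per ratio, grouped by tile."""
    lines = []
    title = profile.metadata.get("factor", "")
    if title:
        lines.append(f"RAMP profile: {title}")
    current_tile = None
    width = max(len(e.definition.label) for e in profile.entries)
    for e in profile.entries:
        if e.definition.tile != current_tile:
            current_tile = e.definition.tile
            name = "vs PTP" if current_tile == 1 else "substrate-product & exclusive"
            lines.append(f"-- tile {current_tile} ({name}) --")
        label = e.definition.label.rjust(width)
        if e.value is None:
            lines.append(f"{label} {'.' * _BAR_HALF}|{'.' * _BAR_HALF}  missing")
            continue
        v = max(-max_abs, min(max_abs, e.value))
        cells = round(abs(v) / max_abs * _BAR_HALF)
        left = ("#" * cells).rjust(_BAR_HALF) if v < 0 else " " * _BAR_HALF
        right = ("#" * cells).ljust(_BAR_HALF) if v > 0 else " " * _BAR_HALF
        sd = f" +/- {e.sd:.2f}" if e.sd is not None else ""
        lines.append(f"{label} {left}|{right} {e.value:+.2f}{sd} (n={e.n})")
    return "\n".join(lines) + "\n"


def render_svg(
    profile: RAMPProfile,
    path,
    max_abs: float = 4.0,
    header_comment: str | None = None,
) -> None:
    """Two-tile bar chart with SD error bars; byte-identical per input."""
    bar_w, gap, h_half = 26, 8, 110
    pad_l, pad_t, tile_gap, label_h = 50, 30, 46, 80
    tiles = sorted({e.definition.tile for e in profile.entries})
    per_tile = {t: [e for e in profile.entries if e.definition.tile == t] for t in tiles}
    width = pad_l + max(len(v) for v in per_tile.values()) * (bar_w + gap) + 40
    height = pad_t + len(tiles) * (2 * h_half + label_h + tile_gap)

    def y_of(val: float, y0: float) -> float:
        v = max(-max_abs, min(max_abs, val))
        return y0 - v / max_abs * h_half

    out = ['<?xml version="1.0" encoding="UTF-8"?>']
    if header_comment:
        out.append(f"<!-- {header_comment} -->")
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'font-family="monospace" font-size="11">'
    )
    out.append(
        '<defs><pattern id="hatch" width="6" height="6" patternUnits="userSpaceOnUse">'
        '<path d="M0,6 L6,0" stroke="#999999" stroke-width="1"/></pattern></defs>'
    )
    title = profile.metadata.get("factor", "")
    if title:
        out.append(f'<text x="{pad_l}" y="18">{title}</text>')
    color_idx = {e.definition.label: i for i, e in enumerate(profile.entries)}
    for t_i, tile in enumerate(tiles):
        y0 = pad_t + h_half + t_i * (2 * h_half + label_h + tile_gap)
        entries = per_tile[tile]
        x_end = pad_l + len(entries) * (bar_w + gap)
        out.append(
            f'<line x1="{pad_l - 6}" y1="{y0:.1f}" x2="{x_end}" y2="{y0:.1f}" '
            'stroke="#000000" stroke-width="1"/>'
        )
        for grid in (-2, 2):
            yg = y_of(grid, y0)
            out.append(
                f'<line x1="{pad_l - 6}" y1="{yg:.1f}" x2="{x_end}" y2="{yg:.1f}" '
                'stroke="#dddddd" stroke-width="1"/>'
            )
            out.append(f'<text x="{pad_l - 46}" y="{yg + 4:.1f}">{grid:+d}</text>')
        for i, e in enumerate(entries):
            x = pad_l + i * (bar_w + gap)
            color = PALETTE[color_idx[e.definition.label] % len(PALETTE)]
            if e.value is None:
                out.append(
                    f'<rect x="{x}" y="{y0 - 30:.1f}" width="{bar_w}" height="60" '
                    'fill="url(#hatch)" stroke="#999999"/>'
                )
            else:
                y1 = y_of(e.value, y0)
                top, hgt = (min(y0, y1), abs(y1 - y0))
                out.append(
                    f'<rect x="{x}" y="{top:.2f}" width="{bar_w}" height="{hgt:.2f}" '
                    f'fill="{color}"/>'
                )
                if e.sd is not None:
                    y_lo = y_of(e.value - e.sd, y0)
                    y_hi = y_of(e.value + e.sd, y0)
                    cx = x + bar_w / 2
                    out.append(
                        f'<line x1="{cx:.1f}" y1="{y_hi:.2f}" x2="{cx:.1f}" y2="{y_lo:.2f}" '
                        'stroke="#000000" stroke-width="1"/>'
                    )
                    for yy in (y_hi, y_lo):
                        out.append(
                            f'<line x1="{cx - 5:.1f}" y1="{yy:.2f}" x2="{cx + 5:.1f}" '
                            f'y2="{yy:.2f}" stroke="#000000" stroke-width="1"/>'
                        )
            out.append(
                f'<text x="{x + bar_w / 2:.1f}" y="{y0 + h_half + 12:.1f}" '
                f'text-anchor="end" transform="rotate(-60 {x + bar_w / 2:.1f} '
                f'{y0 + h_half + 12:.1f})">{e.definition.label}</text>'
            )
    out.append("</svg>")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out) + "\n")
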