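"""Deterministic SVG rendering of the comparison figure.

Layout: term labels on the left, indentation showing ancestry; one
equal-width glyph panel per analysis on the right, sharing row baselines.
Within a panel a triangle marks the odds ratio (up = over-represented,
down = under-represented; green = significant, pink = not) and a vertical
bar marks the fold change (red = significant, grey = not).  Both glyphs sit
on the panel's shared horizontal axis; the axis mode chooses whether the
printed scale is the fold-change range (auto-fit) or the odds-ratio range
(0–25 by default).

Output is a pure function of its inputs: fixed float formatting, no
timestamps, no generated ids — identical calls produce identical bytes,
which is what makes golden-file testing of figures possible.
"""

from __future__ import annotations

import importlib.util
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

from .display import DisplayRow
from .errors import EmptyFigureError, RasterizerUnavailableError

AxisMode = Literal["fold_change", "odds_ratio"]

DEFAULT_ODDS_RATIO_MAX = 25.0


@dataclass(frozen=True)
class AxisConfig:
    """Shared horizontal scale of the glyph panels."""

    mode: AxisMode = "fold_change"
    minimum: float = 0.0
    maximum: float | None = None  # None: 25 for odds_ratio, auto-fit for fold
    clamp: bool = True

    def resolved(self, rows: Sequence[DisplayRow]) -> "AxisConfig":
        """Fill in the default maximum (auto-fit for fold change)."""
        if self.maximum is not None:
            if self.minimum >= self.maximum:
                raise ValueError("axis minimum must be < maximum")
            return self
        if self.mode == "odds_ratio":
            return replace(self, maximum=DEFAULT_ODDS_RATIO_MAX)
        peak = 0.0
        for row in rows:
            for rec, _sig, fold in row.per_analysis:
                if fold is not None and math.isfinite(fold):
                    peak = max(peak, fold)
        return replace(self, maximum=float(max(1, math.ceil(peak))))

    def place(self, value: float) -> tuple[float, bool]:
        """Clamp a value into [minimum, maximum]; flag whether clamping bit."""
        assert self.maximum is not None
        lo, hi = self.minimum, self.maximum
        if value < lo:
            return (lo, True) if self.clamp else (value, False)
        if value > hi:
            return (hi, True) if self.clamp else (value, False)
        return value, False


@dataclass(frozen=True)
class GlyphSpec:
    """Resolved drawing instructions for one record in one panel."""

    triangle_x: float
    triangle_orientation: Literal["up", "down"]
    triangle_colour: str
    bar_x: float | None
    bar_colour: str
    triangle_clamped: bool = False
    bar_clamped: bool = False


@dataclass(frozen=True)
class StyleOptions:
    """Fixed geometry/colour defaults keeping golden files stable."""

    row_height: float = 22.0
    label_width: float = 280.0
    panel_width: float = 150.0
    panel_gap: float = 18.0
    margin: float = 14.0
    header_height: float = 26.0
    axis_height: float = 22.0
    indent_px: float = 14.0
    font_family: str = "Helvetica, Arial, sans-serif"
    font_size: float = 11.0
    triangle_half_width: float = 5.0
    triangle_height: float = 9.0
    bar_width: float = 3.0
    bar_height: float = 14.0
    colour_significant_triangle: str = "#2ca02c"  # green
    colour_nonsignificant_triangle: str = "#f7b6d2"  # pink
    colour_significant_bar: str = "#d62728"  # red
    colour_nonsignificant_bar: str = "#9e9e9e"  # grey
    colours: dict = field(default_factory=dict)  # name → hex overrides

    def colour(self, key: str) -> str:
        return self.colours.get(key, getattr(self, f"colour_{key}"))


def build_glyph(
    record,
    significant: bool,
    fold: float | None,
    axis: AxisConfig,
) -> GlyphSpec:
    """Map one record's statistics onto glyph geometry on a resolved axis."""
    if axis.maximum is None:
        raise ValueError("axis must be resolved (maximum set) before build_glyph")
    tri_x, tri_clamped = axis.place(record.odds_ratio)
    if fold is None:
        bar_x, bar_clamped = None, False
    else:
        bar_x, bar_clamped = axis.place(fold)
    style = StyleOptions()
    return GlyphSpec(
        triangle_x=tri_x,
        triangle_orientation="up" if record.direction == "over" else "down",
        triangle_colour=(
            style.colour("significant_triangle")
            if significant
            else style.colour("nonsignificant_triangle")
        ),
        bar_x=bar_x,
        bar_colour=(
            style.colour("significant_bar")
            if significant
            else style.colour("nonsignificant_bar")
        ),
        triangle_clamped=tri_clamped,
        bar_clamped=bar_clamped,
    )


def _fmt(v: float) -> str:
    """Fixed two-decimal coordinate formatting (byte-stable output)."""
    return f"{v:.2f}"


def _axis_label(axis: AxisConfig) -> str:
    return "fold change" if axis.mode == "fold_change" else "odds ratio"


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def render_figure(
    rows: Sequence[DisplayRow],
    labels: Sequence[str],
    axis: AxisConfig | None = None,
    style: StyleOptions | None = None,
    caption: str | None = None,
) -> str:
    """Render display rows into a standalone SVG 1.1 document (text).

    One label column plus one panel per analysis in label order; every panel
    draws its own axis line and min/mid/max tick labels.  Raises
    :class:`EmptyFigureError` on zero rows or zero analyses.
    """
    if not rows:
        raise EmptyFigureError("no rows to render")
    if not labels:
        raise EmptyFigureError("no analyses to render")
    style = style or StyleOptions()
    axis = (axis or AxisConfig()).resolved(rows)
    assert axis.maximum is not None

    n_rows = len(rows)
    n_panels = len(labels)
    caption_h = style.header_height if caption else 0.0
    width = (
        style.margin * 2
        + style.label_width
        + n_panels * style.panel_width
        + (n_panels - 1) * style.panel_gap
    )
    height = (
        style.margin * 2
        + caption_h
        + style.header_height
        + n_rows * style.row_height
        + style.axis_height
    )

    def panel_x0(j: int) -> float:
        return (
            style.margin
            + style.label_width
            + j * (style.panel_width + style.panel_gap)
        )

    def to_px(j: int, value: float) -> float:
        frac = (value - axis.minimum) / (axis.maximum - axis.minimum)
        return panel_x0(j) + frac * style.panel_width

    top = style.margin + caption_h + style.header_height
    axis_y = top + n_rows * style.row_height + 6.0

    parts: list[str] = []
    parts.append(
        '<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">'
    )
    parts.append(
        f'<rect x="0" y="0" width="{_fmt(width)}" height="{_fmt(height)}" '
        'fill="#ffffff"/>'
    )
    font = f'font-family="{style.font_family}" font-size="{_fmt(style.font_size)}"'

    if caption:
        parts.append(
            f'<text x="{_fmt(style.margin)}" y="{_fmt(style.margin + 12.0)}" '
            f'{font} font-weight="bold">{_esc(caption)}</text>'
        )

    # column headers
    for j, label in enumerate(labels):
        cx = panel_x0(j) + style.panel_width / 2.0
        parts.append(
            f'<text x="{_fmt(cx)}" y="{_fmt(style.margin + caption_h + 14.0)}" '
            f'{font} text-anchor="middle">{_esc(label)}</text>'
        )

    # rows
    for i, row in enumerate(rows):
        y_mid = top + i * style.row_height + style.row_height / 2.0
        lx = style.margin + row.indent * style.indent_px
        parts.append(
            f'<text x="{_fmt(lx)}" y="{_fmt(y_mid + style.font_size / 2.0 - 1.0)}" '
            f'{font} class="term-label">{_esc(row.label)}</text>'
        )
        # faint row guide across the panels
        gx0 = panel_x0(0)
        gx1 = panel_x0(n_panels - 1) + style.panel_width
        parts.append(
            f'<line x1="{_fmt(gx0)}" y1="{_fmt(y_mid)}" x2="{_fmt(gx1)}" '
            f'y2="{_fmt(y_mid)}" stroke="#eeeeee" stroke-width="1"/>'
        )
        for j, entry in enumerate(row.per_analysis):
            rec, sig, fold = entry
            if rec is None:
                continue
            glyph = build_glyph(rec, sig, fold, axis)
            parts.extend(_draw_glyph(glyph, j, y_mid, to_px, style))

    # per-panel axes
    for j in range(n_panels):
        x0, x1 = panel_x0(j), panel_x0(j) + style.panel_width
        parts.append(
            f'<line x1="{_fmt(x0)}" y1="{_fmt(axis_y)}" x2="{_fmt(x1)}" '
            f'y2="{_fmt(axis_y)}" stroke="#333333" stroke-width="1"/>'
        )
        mid_val = (axis.minimum + axis.maximum) / 2.0
        for value in (axis.minimum, mid_val, axis.maximum):
            tx = to_px(j, value)
            parts.append(
                f'<line x1="{_fmt(tx)}" y1="{_fmt(axis_y)}" x2="{_fmt(tx)}" '
                f'y2="{_fmt(axis_y + 4.0)}" stroke="#333333" stroke-width="1"/>'
            )
            label = f"{value:g}"
            parts.append(
                f'<text x="{_fmt(tx)}" y="{_fmt(axis_y + 15.0)}" {font} '
                f'text-anchor="middle">{label}</text>'
            )
    # one axis-mode label under the first panel
    parts.append(
        f'<text x="{_fmt(panel_x0(0))}" y="{_fmt(axis_y + 15.0 + 12.0)}" {font} '
        f'font-style="italic">{_axis_label(axis)}</text>'
    )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _draw_glyph(glyph: GlyphSpec, j: int, y_mid: float, to_px, style) -> list[str]:
    parts: list[str] = []
    if glyph.bar_x is not None:
        bx = to_px(j, glyph.bar_x)
        parts.append(
            f'<rect x="{_fmt(bx - style.bar_width / 2.0)}" '
            f'y="{_fmt(y_mid - style.bar_height / 2.0)}" '
            f'width="{_fmt(style.bar_width)}" height="{_fmt(style.bar_height)}" '
            f'fill="{glyph.bar_colour}" class="fold-bar"/>'
        )
        if glyph.bar_clamped:
            parts.append(_overflow_marker(bx, y_mid - style.bar_height / 2.0 - 3.0))
    tx = to_px(j, glyph.triangle_x)
    h = style.triangle_height
    w = style.triangle_half_width
    if glyph.triangle_orientation == "up":
        pts = (
            f"{_fmt(tx)},{_fmt(y_mid - h / 2.0)} "
            f"{_fmt(tx - w)},{_fmt(y_mid + h / 2.0)} "
            f"{_fmt(tx + w)},{_fmt(y_mid + h / 2.0)}"
        )
    else:
        pts = (
            f"{_fmt(tx)},{_fmt(y_mid + h / 2.0)} "
            f"{_fmt(tx - w)},{_fmt(y_mid - h / 2.0)} "
            f"{_fmt(tx + w)},{_fmt(y_mid - h / 2.0)}"
        )
    parts.append(
        f'<polygon points="{pts}" fill="{glyph.triangle_colour}" '
        'class="odds-ratio-triangle"/>'
    )
    if glyph.triangle_clamped:
        parts.append(_overflow_marker(tx, y_mid - h / 2.0 - 3.0))
    return parts


def _overflow_marker(x: float, y: float) -> str:
    """Small chevron flagging a value clamped to the axis end."""
    return (
        f'<path d="M {_fmt(x - 2.5)} {_fmt(y)} L {_fmt(x)} {_fmt(y - 3.0)} '
        f'L {_fmt(x + 2.5)} {_fmt(y)}" stroke="#333333" stroke-width="1" '
        'fill="none" class="overflow-marker"/>'
    )


def export_png(svg_text: str, dpi: float = 96.0) -> bytes:
    """Rasterize an SVG document to PNG bytes at the requested dpi.

    Requires an importable SVG rasterizer (``cairosvg``); raises
    :class:`RasterizerUnavailableError` advising SVG output when none is
    present.  Output dimensions scale linearly with dpi (96 = 1:1).
    """
    if dpi <= 0:
        raise ValueError(f"dpi must be positive, got {dpi}")
    if importlib.util.find_spec("cairosvg") is None:
        raise RasterizerUnavailableError(
            "no SVG rasterizer available (cairosvg not importable); "
            "use the SVG output directly"
        )
    import cairosvg  # pragma: no cover - depends on optional rasterizer

    return cairosvg.svg2png(bytestring=svg_text.encode(), scale=dpi / 96.0)
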