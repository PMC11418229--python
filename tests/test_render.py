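import math
import random
import re
from pathlib import Path

import pytest

from goenrichview import (
    AnalysisSet,
    AxisConfig,
    Selection,
    StyleOptions,
    assemble_rows,
    attach,
    build_glyph,
    export_png,
    render_figure,
)
from goenrichview.errors import EmptyFigureError, RasterizerUnavailableError

from conftest import B, D, E, R, make_record
from golden_cases import GOLDEN_CASES

GOLDEN_DIR = Path(__file__).parent / "golden"

STYLE = StyleOptions()


def resolved_axis(mode="fold_change", maximum=10.0):
    return AxisConfig(mode=mode, maximum=maximum)


class TestBuildGlyph:
    def test_significant_over_record(self):
        rec = make_record(odds_ratio=3.2)
        glyph = build_glyph(rec, True, 4.0, resolved_axis())
        assert glyph.triangle_orientation == "up"
        assert glyph.triangle_colour == STYLE.colour_significant_triangle
        assert glyph.triangle_x == 3.2
        assert glyph.bar_x == 4.0
        assert glyph.bar_colour == STYLE.colour_significant_bar

    def test_nonsignificant_under_record(self):
        rec = make_record(
            direction="under", odds_ratio=0.9, observed_count=1,
            expected_count=4.0, p_value=0.8,
        )
        glyph = build_glyph(rec, False, 0.25, resolved_axis())
        assert glyph.triangle_orientation == "down"
        assert glyph.triangle_colour == STYLE.colour_nonsignificant_triangle
        assert glyph.bar_colour == STYLE.colour_nonsignificant_bar

    def test_infinite_odds_ratio_clamps_to_axis_max(self):
        rec = make_record(odds_ratio=math.inf)
        glyph = build_glyph(rec, True, None, resolved_axis("odds_ratio", 25.0))
        assert glyph.triangle_x == 25.0
        assert glyph.triangle_clamped
        assert glyph.bar_x is None

    @pytest.mark.parametrize("direction", ["over", "under"])
    @pytest.mark.parametrize("significant", [True, False])
    @pytest.mark.parametrize("mode", ["fold_change", "odds_ratio"])
    def test_semantics_cube(self, direction, significant, mode):
        """All 8 (direction x significance x axis mode) combinations map to
        the documented glyph semantics: up=over/down=under, green/pink
        triangle and red/grey bar by significance, in either axis mode."""
        rec = make_record(direction=direction, odds_ratio=2.0)
        glyph = build_glyph(rec, significant, 1.5, resolved_axis(mode, 25.0))
        assert glyph.triangle_orientation == ("up" if direction == "over" else "down")
        expect_tri = (
            STYLE.colour_significant_triangle
            if significant
            else STYLE.colour_nonsignificant_triangle
        )
        expect_bar = (
            STYLE.colour_significant_bar
            if significant
            else STYLE.colour_nonsignificant_bar
        )
        assert glyph.triangle_colour == expect_tri
        assert glyph.bar_colour == expect_bar


class TestRenderFigure:
    @pytest.mark.parametrize("name", sorted(GOLDEN_CASES))
    def test_matches_golden_file(self, name):
        rows, labels, axis, caption = GOLDEN_CASES[name]()
        svg = render_figure(rows, labels, axis, caption=caption)
        assert svg == (GOLDEN_DIR / f"{name}.svg").read_text()

    @pytest.mark.parametrize("name", sorted(GOLDEN_CASES))
    def test_repeated_render_is_byte_identical(self, name):
        rows, labels, axis, caption = GOLDEN_CASES[name]()
        a = render_figure(rows, labels, axis, caption=caption)
        b = render_figure(rows, labels, axis, caption=caption)
        assert a == b

    def test_four_rows_four_analyses_structure(self):
        rows, labels, axis, _ = GOLDEN_CASES["single_path_four_analyses"]()
        svg = render_figure(rows, labels, axis)
        assert svg.count('class="term-label"') == 4
        assert svg.count("<polygon") <= 16

    def test_empty_panel_has_no_polygons(self):
        rows, labels, axis, _ = GOLDEN_CASES["single_row_empty_panel"]()
        svg = render_figure(rows, labels, axis)
        assert "<polygon" not in svg
        assert svg.count('class="term-label"') == 1

    def test_zero_rows_is_error(self):
        with pytest.raises(EmptyFigureError):
            render_figure([], ["a"])

    def test_zero_analyses_is_error(self, diamond):
        index = attach(diamond, AnalysisSet(analyses=[("a", {})]))
        rows = assemble_rows(Selection(paths=[(R,)]), diamond, index)
        with pytest.raises(EmptyFigureError):
            render_figure(rows, [])

    def test_triangle_position_is_affine_in_odds_ratio(self, diamond):
        """Parse triangle apexes back out of the SVG and compare with the
        affine value->pixel map, for 10 random odds ratios (tol 0.01 px)."""
        rng = random.Random(42)
        values = [round(rng.uniform(0.0, 25.0), 3) for _ in range(10)]
        axis = AxisConfig(mode="odds_ratio", maximum=25.0)
        style = StyleOptions()
        aset = AnalysisSet(
            analyses=[
                (
                    f"a{i}",
                    {E: make_record(go_id=E, odds_ratio=v, expected_count=0.0,
                                    observed_count=0)},
                )
                for i, v in enumerate(values)
            ]
        )
        index = attach(diamond, aset)
        rows = assemble_rows(Selection(paths=[(R, B, D, E)]), diamond, index)
        svg = render_figure(rows, aset.labels, axis, style)
        apexes = [
            float(m.group(1).split(",")[0])
            for m in re.finditer(r'<polygon points="([^ ]+) ', svg)
        ]
        assert len(apexes) == 10
        for j, (v, px) in enumerate(zip(values, apexes)):
            x0 = style.margin + style.label_width + j * (
                style.panel_width + style.panel_gap
            )
            expected = x0 + v / 25.0 * style.panel_width
            assert abs(px - expected) <= 0.01

    def test_fold_axis_default_autofits_to_ceiling(self, diamond):
        aset = AnalysisSet(
            analyses=[("a", {E: make_record(go_id=E, observed_count=13,
                                            expected_count=2.0)})]
        )
        index = attach(diamond, aset)
        rows = assemble_rows(Selection(paths=[(R, B, D, E)]), diamond, index)
        axis = AxisConfig(mode="fold_change").resolved(rows)
        assert axis.maximum == 7.0  # ceil(13 / 2.0)


class TestExportPng:
    def test_nonpositive_dpi_rejected(self):
        with pytest.raises(ValueError):
            export_png("<svg/>", dpi=0)

    def test_rasterizer_contract(self):
        """Without an importable rasterizer the capability error advises SVG;
        with one, dimensions must scale linearly with dpi."""
        rows, labels, axis, _ = GOLDEN_CASES["single_row_empty_panel"]()
        svg = render_figure(rows, labels, axis)
        try:
            png = export_png(svg, dpi=192.0)
        except RasterizerUnavailableError as exc:
            assert "SVG" in str(exc)
            return
        assert png[:8] == b"\x89PNG\r\n\x1a\n"
        width = int.from_bytes(png[16:20], "big")
        m = re.search(r'width="([0-9.]+)"', svg)
        assert width == round(float(m.group(1)) * 2)
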