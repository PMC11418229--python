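"""Regenerate the committed golden SVG figures under tests/golden/.

Run from the repository root after any deliberate change to figure layout,
then inspect the diffs before committing.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "tests"))

from goenrichview import render_figure  # noqa: E402
from golden_cases import GOLDEN_CASES  # noqa: E402


def main() -> None:
    outdir = ROOT / "tests" / "golden"
    outdir.mkdir(parents=True, exist_ok=True)
    for name, build in GOLDEN_CASES.items():
        rows, labels, axis, caption = build()
        svg = render_figure(rows, labels, axis, caption=caption)
        path = outdir / f"{name}.svg"
        path.write_text(svg)
        print(f"wrote {path} ({len(svg)} bytes)")


if __name__ == "__main__":
    main()
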