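"""Saving and re-importing a path selection, including the stale-edge case.

A selection file pins down which root-to-term paths a figure shows, so the
same display can be recreated later or applied to a new dataset.  When the
ontology has moved on and an edge no longer exists, loading reports every
broken edge but still hands back the valid subset.
"""

import io

from goenrichview import Selection, load_selection, parse_obo, save_selection
from goenrichview.errors import StaleSelectionError

DIAMOND = """format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: branch B
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000004
name: join D
namespace: biological_process
is_a: GO:0000002
"""

ont = parse_obo(io.StringIO(DIAMOND))

sel = Selection(paths=[("GO:0000001", "GO:0000002", "GO:0000004")])
buf = io.StringIO()
save_selection(sel, buf)
print("saved selection file:")
print(buf.getvalue())

buf.seek(0)
back = load_selection(buf, ont)
print("round-trip identical:", back.paths == sel.paths)

# A file written against an older ontology that still had a C branch:
stale = io.StringIO(
    "#gotermpaths v1\n"
    "GO:0000001>GO:0000002>GO:0000004\n"
    "GO:0000001>GO:0000003>GO:0000004\n"
)
try:
    load_selection(stale, ont)
except StaleSelectionError as exc:
    print("stale edges reported:", exc.failures)
    print("valid paths kept:", exc.selection.paths)
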