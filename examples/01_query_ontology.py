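"""Load a toy ontology and ask the questions a tree browser would answer.

Builds a 5-term diamond DAG (two routes from the root to the same join
term), then enumerates root-to-term paths, counts them with the memoized
recurrence, and finds the nearest common ancestor of the two branches.
"""

import io

from goenrichview import (
    count_paths_to,
    enumerate_paths,
    nearest_common_ancestor,
    parse_obo,
    search_terms,
)

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
id: GO:0000003
name: branch C
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000004
name: join D
namespace: biological_process
is_a: GO:0000002
is_a: GO:0000003

[Term]
id: GO:0000005
name: leaf E
namespace: biological_process
is_a: GO:0000004
"""

ont = parse_obo(io.StringIO(DIAMOND))
print(f"terms loaded: {len(ont)}")

# Every root-to-term path, in the ">"-joined selection-file syntax.
# Two paths exist because the join term has two parents.
for path in enumerate_paths(ont, "GO:0000005"):
    print("path:", ">".join(path))
print("path count via recurrence:", count_paths_to(ont, "GO:0000005"))

# The deepest term ancestral to both branches is the root.
print("NCA of B and C:", nearest_common_ancestor(ont, ["GO:0000002", "GO:0000003"]))

# Name search: case-insensitive substring, shortest name first.
print("search 'branch':", search_terms(ont, "branch"))
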