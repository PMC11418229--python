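import io

import pytest

from goenrichview import parse_obo
from goenrichview.enrichment import EnrichmentRecord

DIAMOND_OBO = """format-version: 1.2

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
alt_id: GO:0009004
is_a: GO:0000002
is_a: GO:0000003

[Term]
id: GO:0000005
name: leaf E
namespace: biological_process
is_a: GO:0000004
"""

R, B, C, D, E = (f"GO:000000{i}" for i in range(1, 6))
D_ALT = "GO:0009004"


@pytest.fixture
def diamond_text():
    return DIAMOND_OBO


@pytest.fixture
def diamond():
    """R; B,C is_a R; D is_a B,C; E is_a D — 5 terms, 5 edges, root R."""
    return parse_obo(io.StringIO(DIAMOND_OBO))


def make_record(
    go_id=D,
    p_value=0.001,
    odds_ratio=3.2,
    expected_count=2.5,
    observed_count=10,
    gene_set_size=40,
    term_name="join D",
    direction="over",
):
    return EnrichmentRecord(
        go_id=go_id,
        p_value=p_value,
        odds_ratio=odds_ratio,
        expected_count=expected_count,
        observed_count=observed_count,
        gene_set_size=gene_set_size,
        term_name=term_name,
        direction=direction,
    )
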