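"""Shared test helpers: hand-built assignments and single-group tables."""

import pandas as pd

import sweetspots as sw
from sweetspots.spots import BreakMethod, SpotCategory


def assignment_from_codes(codes, ids=None, combination="walkability_no2"):
    """Build a SpotAssignment directly from spot codes (for regression tests)."""
    rules = {r.name: r for r in sw.builtin_rulesets()}[combination]
    ids = ids or [f"D{i}" for i in range(len(codes))]
    frame = pd.DataFrame(
        {
            "class_first": codes,
            "class_second": codes,
            "code": codes,
            "category": [SpotCategory(c).name for c in codes],
        },
        index=pd.Index(ids, name="da_id"),
    )
    return sw.SpotAssignment(
        combination=combination, frame=frame, rules=rules, method=BreakMethod.QUARTILE
    )


def table_with_group(values, registry, ids=None, group="grp"):
    ids = ids or [f"D{i}" for i in range(len(values))]
    df = pd.DataFrame({group: values}, index=pd.Index(ids, name="da_id"))
    return sw.DATable(df, 2006, registry, demo_groups=[group])
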