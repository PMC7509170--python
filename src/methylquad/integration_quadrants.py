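"""Expression-methylation integration: four-quadrant DEMG classification.

Genes that are simultaneously differentially expressed (DEG, up/down) and
differentially methylated (DMG, hyper/hypo) are DEMGs and fall into one of
four quadrants: up-hyper, up-hypo, down-hyper, down-hypo. Conflicted DMGs
(mixed-direction regions) are excluded before intersection.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .region_methylation import DmgCall

QUADRANTS = ("up-hyper", "up-hypo", "down-hyper", "down-hypo")


def classify_quadrants(
    deg_records: pd.DataFrame, dmg_calls: Iterable[DmgCall]
) -> pd.DataFrame:
    """Intersect DEG and DMG calls into quadrants.

    ``deg_records`` must contain only significant rows (direction up or
    down); a row with direction ``none`` is a contract violation. Returns
    one row per DEMG: gene, deg_direction, dmg_direction, quadrant.
    """
    if (deg_records["direction"] == "none").any():
        raise ValueError("deg_records contains direction 'none'; filter upstream")
    deg_dir = deg_records["direction"].to_dict()
    rows = []
    for call in dmg_calls:
        if call.conflicted or call.gene not in deg_dir:
            continue
        quadrant = f"{deg_dir[call.gene]}-{call.direction}"
        rows.append(
            {
                "gene": call.gene,
                "deg_direction": deg_dir[call.gene],
                "dmg_direction": call.direction,
                "quadrant": quadrant,
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "deg_direction", "dmg_direction", "quadrant"])
    if out["gene"].duplicated().any():
        raise ValueError("a gene appears in more than one DMG call")
    return out.sort_values("gene").reset_index(drop=True)


def quadrant_counts(demg_calls: pd.DataFrame) -> dict[str, int]:
    """Per-quadrant counts plus their total (= |DEMG set|)."""
    counts = demg_calls["quadrant"].value_counts().to_dict()
    out = {q: int(counts.get(q, 0)) for q in QUADRANTS}
    out["total"] = int(sum(out[q] for q in QUADRANTS))
    return out


def quadrant_genes(demg_calls: pd.DataFrame) -> dict[str, list[str]]:
    return {
        q: sorted(demg_calls.loc[demg_calls["quadrant"] == q, "gene"])
        for q in QUADRANTS
    }


def overlap_summary(list_a: Sequence[str], list_b: Sequence[str]) -> dict:
    """Two-set Venn counts with percentages under three denominators.

    The headline percentage uses the union size; percentages relative to
    |a| and |b| are also reported because the appropriate denominator is
    a study-design choice.
    """
    a, b = set(list_a), set(list_b)
    both = a & b
    union = a | b
    def pct(n: int, d: int) -> float:
        return 100.0 * n / d if d else 0.0
    return {
        "a_only": len(a - b),
        "b_only": len(b - a),
        "both": len(both),
        "union": len(union),
        "percent_both_of_union": pct(len(both), len(union)),
        "percent_both_of_a": pct(len(both), len(a)),
        "percent_both_of_b": pct(len(both), len(b)),
    }
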