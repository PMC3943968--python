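"""Accession-keyed combination of all experiments into one overview table.

Per-experiment result tables are outer-joined on the leading protein
accession; accession groups (from platforms that report protein groups) are
aligned to their leading accession first.  Every populated cell remains
traceable to its source experiment through a provenance map.  The overview is
annotated with plasma/CSF ratio bands and summarised by cross-experiment
contingency tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import Category

__all__ = [
    "CombinedOverview",
    "ConsistencyReport",
    "align_accessions",
    "annotate_ratio_band",
    "add_ratio_bands",
    "cross_reference",
    "consistency_report",
]


@dataclass
class CombinedOverview:
    """Wide accession-keyed join of per-experiment tables.

    Columns are prefixed ``<experiment>:``; ``provenance`` maps each column
    to its source experiment label; ``group_members`` lists, per leading
    accession, the other members of its protein group, and
    ``shared_peptides`` flags entries whose peptides also match other
    accessions.
    """

    table: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def experiments(self) -> list[str]:
        return sorted(set(self.provenance.values()))


def align_accessions(
    tables: Mapping[str, pd.DataFrame],
    groups: Mapping[str, Sequence[str]] | None = None,
) -> CombinedOverview:
    """Outer-join per-experiment tables on the leading accession.

    ``groups`` maps a leading accession to the other members of its protein
    group; member accessions found in any table are re-keyed to their leader.
    An accession that is a leader of one group and a member of another is a
    conflict and fails loudly.  No source row is duplicated or lost.
    """
    groups = {k: tuple(v) for k, v in (groups or {}).items()}
    member_to_leader: dict[str, str] = {}
    for leader, members in groups.items():
        for m in members:
            if m == leader:
                continue
            if m in groups:
                raise ValueError(
                    f"accession {m!r} is leading one group and a member of the "
                    f"group led by {leader!r}"
                )
            if m in member_to_leader and member_to_leader[m] != leader:
                raise ValueError(f"accession {m!r} is a member of two groups")
            member_to_leader[m] = leader

    blocks: list[pd.DataFrame] = []
    provenance: dict[str, str] = {}
    for label, df in tables.items():
        if not df.index.is_unique:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"table {label!r}: duplicate accessions {dups}")
        mapped = df.rename(index=member_to_leader)
        if not mapped.index.is_unique:
            dups = mapped.index[mapped.index.duplicated()].unique().tolist()
            raise ValueError(
                f"table {label!r}: accessions {dups} collapse onto one leading "
                "accession; resolve the group before combining"
            )
        mapped = mapped.add_prefix(f"{label}:")
        for col in mapped.columns:
            provenance[col] = label
        blocks.append(mapped)
    combined = pd.concat(blocks, axis=1, join="outer")
    combined.index.name = "accession"

    combined["group_members"] = [
        ";".join(groups.get(acc, ())) for acc in combined.index
    ]
    combined["shared_peptides"] = [bool(groups.get(acc)) for acc in combined.index]
    return CombinedOverview(table=combined, provenance=provenance, groups=groups)


def annotate_ratio_band(
    mean_ratio: float | None, band_low: float = 0.2, band_high: float = 0.4
) -> str:
    """Band of an equal-protein plasma/CSF ratio: high (> 0.4), low (< 0.2),
    mid (the closed interval in between) or none for a missing ratio."""
    if mean_ratio is None or (isinstance(mean_ratio, float) and math.isnan(mean_ratio)):
        return "none"
    if mean_ratio < 0:
        raise ValueError("plasma/CSF ratio must be >= 0")
    if mean_ratio > band_high:
        return "high"
    if mean_ratio < band_low:
        return "low"
    return "mid"


def add_ratio_bands(
    overview: CombinedOverview,
    ratio_col: str = "plasma_csf:mean_ratio",
    band_low: float = 0.2,
    band_high: float = 0.4,
) -> CombinedOverview:
    """Annotate the overview with a ``ratio_band`` column from ``ratio_col``."""
    if ratio_col not in overview.table.columns:
        raise KeyError(f"column {ratio_col!r} not in overview")
    overview.table["ratio_band"] = [
        annotate_ratio_band(v, band_low, band_high) for v in overview.table[ratio_col]
    ]
    overview.provenance["ratio_band"] = overview.provenance[ratio_col]
    return overview


def cross_reference(
    candidates: Sequence[str],
    overview: CombinedOverview,
    category_col: str = "contamination:category",
) -> dict[str, int]:
    """Overlap of an external candidate list with the overview's categories.

    Candidates are matched on the leading accession or any group member.
    Returns counts per category plus the number of unmatched candidates.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list is empty")
    if category_col not in overview.table.columns:
        raise KeyError(f"column {category_col!r} not in overview")
    member_to_leader = {
        m: leader for leader, members in overview.groups.items() for m in members
    }
    counts = {c.value: 0 for c in Category}
    unmatched = 0
    for acc in candidates:
        leader = acc if acc in overview.table.index else member_to_leader.get(acc)
        if leader is None:
            unmatched += 1
            continue
        cat = overview.table.at[leader, category_col]
        if isinstance(cat, float) and math.isnan(cat):
            cat = Category.NOT_EVALUABLE.value
        counts[Category(cat).value] += 1
    counts["matched"] = len(candidates) - unmatched
    counts["unmatched"] = unmatched
    return counts


@dataclass
class ConsistencyReport:
    """Cross-experiment agreement summary.

    ``contamination_vs_band`` and ``contamination_vs_rcg`` are contingency
    tables; the fractions quantify the expected concordances: high plasma/CSF
    ratio band → affected by blood contamination, low band → unaffected, and
    category agreement between the contamination and gradient experiments.
    """

    contamination_vs_band: pd.DataFrame
    contamination_vs_rcg: pd.DataFrame | None
    high_band_affected_fraction: float
    low_band_unaffected_fraction: float
    contamination_rcg_agreement: float | None


def consistency_report(
    overview: CombinedOverview,
    contamination_col: str = "contamination:category",
    rcg_col: str = "rcg:category",
    band_col: str = "ratio_band",
) -> ConsistencyReport:
    """Contingency tables and agreement fractions across experiments."""
    t = overview.table
    if len(t) == 0:
        raise ValueError("overview is empty")
    if len(overview.experiments) < 2:
        raise ValueError("at least 2 experiments must be populated")
    if contamination_col not in t.columns or band_col not in t.columns:
        raise ValueError("overview lacks contamination categories or ratio bands")

    contam = t[contamination_col].fillna(Category.NOT_EVALUABLE.value)
    band = t[band_col].fillna("none")
    vs_band = pd.crosstab(contam, band)

    def _fraction(band_name: str, category: Category) -> float:
        in_band = (band == band_name) & (contam != Category.NOT_EVALUABLE.value)
        if int(in_band.sum()) == 0:
            return math.nan
        return float((contam[in_band] == category.value).mean())

    high_aff = _fraction("high", Category.AFFECTED)
    low_unaff = _fraction("low", Category.UNAFFECTED)

    vs_rcg = None
    agreement = None
    if rcg_col in t.columns:
        rcg = t[rcg_col].fillna(Category.NOT_EVALUABLE.value)
        vs_rcg = pd.crosstab(contam, rcg)
        both = (contam != Category.NOT_EVALUABLE.value) & (rcg != Category.NOT_EVALUABLE.value)
        agreement = float((contam[both] == rcg[both]).mean()) if int(both.sum()) else math.nan
    return ConsistencyReport(
        contamination_vs_band=vs_band,
        contamination_vs_rcg=vs_rcg,
        high_band_affected_fraction=high_aff,
        low_band_unaffected_fraction=low_unaff,
        contamination_rcg_agreement=agreement,
    )
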