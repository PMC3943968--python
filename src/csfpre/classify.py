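"""Three-way categorization of pre-analytical effects and the cross-platform merge.

Each experiment assigns every evaluable protein exactly one of three
categories — affected, uncertain, unaffected — from its fold changes and, for
the gradient experiment, the linearity (R²) of its ratio profile.  Boundary
conventions (the printed inequalities leave exact ties open) are fixed here
and documented per function:

* contamination / centrifugation: FC exactly at the affected threshold (1.5)
  → affected; exactly at the unaffected threshold (1.2) → uncertain;
* gradient: R² exactly 0.7 or 0.3 falls in the middle band; FC exactly 1.2
  with mid R² → unaffected; FC exactly 1.5 with high R² → affected.

Contamination classification is directional (abundance increases only);
suppression — a ≥ 2-fold decrease at the high spike level — is a separate
flag, never a category.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Category",
    "ClassificationResult",
    "classify_contamination",
    "classify_rcg",
    "classify_centrifugation",
    "merge_categories",
    "count_categories",
    "classify_contamination_table",
    "classify_rcg_table",
    "classify_centrifugation_table",
    "merge_category_series",
    "exclude_depleted",
]


class Category(str, enum.Enum):
    AFFECTED = "affected"
    UNCERTAIN = "uncertain"
    UNAFFECTED = "unaffected"
    NOT_EVALUABLE = "not_evaluable"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass(frozen=True)
class ClassificationResult:
    """One protein's category in one experiment, with the evidence behind it."""

    category: Category
    evidence: dict = field(default_factory=dict)
    suppressed: bool = False
    strong: bool = False
    accession: str | None = None
    experiment: str = ""


def _is_missing(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def classify_contamination(
    fc_low: float | None,
    fc_high: float | None,
    fc_affected: float = 1.5,
    fc_unaffected: float = 1.2,
    suppression_fc: float = 2.0,
    accession: str | None = None,
) -> ClassificationResult:
    """Categorize a protein from its directional spike/reference fold changes.

    ``fc_low`` and ``fc_high`` are the spiked-over-reference ratios at the low
    (0.5%) and high (2%) spike levels; either may be missing (single-level
    designs are allowed).  Affected: any available increase ≥ ``fc_affected``.
    Unaffected: all available increases < ``fc_unaffected``.  Otherwise
    uncertain.  The suppression flag is set when the high-level ratio shows at
    least a ``suppression_fc``-fold decrease.
    """
    available = [fc for fc in (fc_low, fc_high) if not _is_missing(fc)]
    evidence = {"fc_low": fc_low, "fc_high": fc_high}
    suppressed = not _is_missing(fc_high) and fc_high <= 1.0 / suppression_fc
    if not available:
        return ClassificationResult(Category.NOT_EVALUABLE, evidence, accession=accession,
                                    experiment="contamination")
    if any(fc >= fc_affected for fc in available):
        cat = Category.AFFECTED
    elif all(fc < fc_unaffected for fc in available):
        cat = Category.UNAFFECTED
    else:
        cat = Category.UNCERTAIN
    return ClassificationResult(cat, evidence, suppressed=suppressed, accession=accession,
                                experiment="contamination")


def classify_rcg(
    fc_1_7: float | None,
    r_squared: float | None,
    fc_affected: float = 1.5,
    fc_unaffected: float = 1.2,
    r2_low: float = 0.3,
    r2_high: float = 0.7,
    accession: str | None = None,
) -> ClassificationResult:
    """Categorize a protein's gradient behaviour from symmetric FC and R².

    High linearity (R² > 0.7): FC ≥ 1.5 → affected, else uncertain.  Middle
    band (0.3 ≤ R² ≤ 0.7): FC > 1.2 → uncertain, else unaffected.  Poor
    linearity (R² < 0.3): unaffected regardless of FC.
    """
    evidence = {"fc_1_7": fc_1_7, "r_squared": r_squared}
    if _is_missing(fc_1_7) or _is_missing(r_squared):
        return ClassificationResult(Category.NOT_EVALUABLE, evidence, accession=accession,
                                    experiment="rcg")
    if r_squared > r2_high:
        cat = Category.AFFECTED if fc_1_7 >= fc_affected else Category.UNCERTAIN
    elif r_squared >= r2_low:
        cat = Category.UNCERTAIN if fc_1_7 > fc_unaffected else Category.UNAFFECTED
    else:
        cat = Category.UNAFFECTED
    return ClassificationResult(cat, evidence, accession=accession, experiment="rcg")


def classify_centrifugation(
    fc: float | None,
    fc_affected: float = 1.5,
    fc_unaffected: float = 1.2,
    strong_fc: float = 10.0,
    accession: str | None = None,
) -> ClassificationResult:
    """Categorize from the not-centrifuged / centrifuged fold change.

    Above ``fc_affected`` the protein is affected by (omission of)
    centrifugation; the ``strong`` flag additionally marks > 10-fold
    increases, the hemoglobin/carbonic-anhydrase class of cell-associated
    markers.
    """
    evidence = {"fc": fc}
    if _is_missing(fc):
        return ClassificationResult(Category.NOT_EVALUABLE, evidence, accession=accession,
                                    experiment="centrifugation")
    if fc > fc_affected:
        return ClassificationResult(Category.AFFECTED, evidence, strong=fc > strong_fc,
                                    accession=accession, experiment="centrifugation")
    if fc < fc_unaffected:
        cat = Category.UNAFFECTED
    else:
        cat = Category.UNCERTAIN
    return ClassificationResult(cat, evidence, accession=accession, experiment="centrifugation")


def merge_categories(a: Category | str, b: Category | str) -> Category:
    """Merge two platforms' categories for the same protein.

    Identical inputs return themselves; not_evaluable is the identity
    element; conflicting pairs follow the merge rules
    affected + unaffected = uncertain, affected + uncertain = affected,
    unaffected + uncertain = unaffected.  Commutative and idempotent.
    """
    a, b = Category(a), Category(b)
    if a == b:
        return a
    if a is Category.NOT_EVALUABLE:
        return b
    if b is Category.NOT_EVALUABLE:
        return a
    pair = {a, b}
    if pair == {Category.AFFECTED, Category.UNAFFECTED}:
        return Category.UNCERTAIN
    if pair == {Category.AFFECTED, Category.UNCERTAIN}:
        return Category.AFFECTED
    return Category.UNAFFECTED  # {unaffected, uncertain}


def count_categories(results: Iterable[ClassificationResult | Category | str]) -> dict[str, int]:
    """Counts per category; the evaluable counts partition the evaluable set."""
    counts = {c.value: 0 for c in Category}
    total = 0
    for r in results:
        cat = r.category if isinstance(r, ClassificationResult) else Category(r)
        counts[cat.value] += 1
        total += 1
    counts["total"] = total
    counts["total_evaluable"] = total - counts[Category.NOT_EVALUABLE.value]
    return counts


def _result_row(r: ClassificationResult) -> dict:
    row = {"category": r.category.value, "suppressed": r.suppressed, "strong": r.strong}
    row.update(r.evidence)
    return row


def classify_contamination_table(
    ratios: pd.DataFrame,
    low_col: str,
    high_col: str,
    fc_affected: float = 1.5,
    fc_unaffected: float = 1.2,
    suppression_fc: float = 2.0,
) -> pd.DataFrame:
    """Apply :func:`classify_contamination` to a ratio table.

    ``ratios`` is indexed by accession with directional spike/reference
    columns ``low_col`` and ``high_col`` (either may be absent for
    single-level designs, passed as ``low_col=None``-like empty string).
    """
    rows = {}
    for acc in ratios.index:
        lo = float(ratios.at[acc, low_col]) if low_col in ratios.columns else math.nan
        hi = float(ratios.at[acc, high_col]) if high_col in ratios.columns else math.nan
        rows[acc] = _result_row(
            classify_contamination(lo, hi, fc_affected, fc_unaffected, suppression_fc, accession=acc)
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "accession"
    return out


def classify_rcg_table(
    fits: pd.DataFrame,
    fc_affected: float = 1.5,
    fc_unaffected: float = 1.2,
    r2_low: float = 0.3,
    r2_high: float = 0.7,
) -> pd.DataFrame:
    """Apply :func:`classify_rcg` to a gradient-fit table (``fc_1_7``, ``r_squared``)."""
    rows = {}
    for acc, row in fits.iterrows():
        fc = row["fc_1_7"]
        r2 = row["r_squared"]
        if "evaluable" in fits.columns and not row["evaluable"]:
            fc, r2 = math.nan, math.nan
        rows[acc] = _result_row(
            classify_rcg(fc, r2, fc_affected, fc_unaffected, r2_low, r2_high, accession=acc)
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "accession"
    return out


def classify_centrifugation_table(
    fc: pd.Series,
    fc_affected: float = 1.5,
    fc_unaffected: float = 1.2,
    strong_fc: float = 10.0,
) -> pd.DataFrame:
    """Apply :func:`classify_centrifugation` to a not-centrifuged/centrifuged FC series."""
    rows = {
        acc: _result_row(
            classify_centrifugation(v, fc_affected, fc_unaffected, strong_fc, accession=acc)
        )
        for acc, v in fc.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "accession"
    return out


def merge_category_series(a: pd.Series, b: pd.Series) -> pd.Series:
    """Element-wise :func:`merge_categories` over the union of accessions."""
    idx = a.index.union(b.index)
    out = pd.Series(index=idx, dtype=object, name="category")
    for acc in idx:
        ca = Category(a[acc]) if acc in a.index else Category.NOT_EVALUABLE
        cb = Category(b[acc]) if acc in b.index else Category.NOT_EVALUABLE
        out[acc] = merge_categories(ca, cb).value
    return out


def exclude_depleted(table: pd.DataFrame, depletion_list: Sequence[str]) -> pd.DataFrame:
    """Drop immunoaffinity-depleted proteins before classification.

    Mirrors the depleted-workflow convention of omitting the quantitative data
    of the depletion-column targets (albumin, transthyretin, ...) from the
    results.
    """
    return table.loc[~table.index.isin(set(depletion_list))]
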