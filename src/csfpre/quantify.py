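"""Reference ratios, fold changes, gradient fits, %CV and MRM quantification.

Ratios are always computed on the linear scale against a designated reference
sample (the pooled reference channel of the labelling designs).  Duplicate
channels of a condition are arithmetically averaged before ratio computation.
Missing operands propagate to missing ratios; nothing is imputed.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RatioTable",
    "GradientFit",
    "Transition",
    "MrmMeasurement",
    "ratio_to_reference",
    "fold_change",
    "fit_gradient",
    "fit_gradient_table",
    "percent_cv",
    "select_quantifier_transition",
    "rollup_peptides",
    "filter_quantifiable",
]


@dataclass
class RatioTable:
    """Per-protein ratios versus the reference, one column per condition."""

    ratios: pd.DataFrame
    reference: str
    provenance: str = ""

    @property
    def accessions(self) -> list[str]:
        return self.ratios.index.tolist()


def ratio_to_reference(
    matrix: AbundanceMatrix, reference_id: str | None = None, provenance: str = ""
) -> RatioTable:
    """Divide each condition's abundances by the reference abundances.

    Duplicate channels (samples sharing a condition label, e.g. the twice-
    included RCG end points) are averaged on the linear scale first, including
    duplicates of the reference itself.  A ratio is missing wherever either
    operand is missing or the reference abundance is zero.
    """
    if reference_id is not None and reference_id not in matrix.sample_ids:
        raise KeyError(f"reference sample {reference_id!r} not in matrix")
    by_condition: dict[str, list[str]] = {}
    for sid, meta in matrix.sample_meta.items():
        by_condition.setdefault(meta.condition, []).append(sid)

    if reference_id is not None:
        ref_condition = matrix.meta(reference_id).condition
    else:
        candidates = [c for c, sids in by_condition.items() if c == "reference"]
        if not candidates:
            raise KeyError("no sample with role 'reference' found; pass reference_id")
        ref_condition = candidates[0]

    averaged = pd.DataFrame(
        {
            cond: matrix.values[sids].mean(axis=1, skipna=False)
            for cond, sids in by_condition.items()
        }
    )
    ref = averaged[ref_condition]
    if ref.isna().all():
        raise ValueError(f"reference condition {ref_condition!r} is entirely missing")
    ref = ref.where(ref != 0)  # zero reference -> missing ratio
    others = [c for c in averaged.columns if c != ref_condition]
    ratios = averaged[others].div(ref, axis=0)
    return RatioTable(ratios=ratios, reference=ref_condition, provenance=provenance)


def fold_change(a, b, symmetric: bool = True):
    """Fold change between two positive ratios or abundances.

    With ``symmetric=True`` returns ``max(a/b, b/a)`` — the magnitude of the
    change, direction carried separately — otherwise the directional ``a/b``.
    Non-positive or missing inputs yield a missing result (with a warning for
    non-positive ones).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    invalid = ~(a > 0) | ~(b > 0)
    nonpositive = ((a <= 0) | (b <= 0)) & ~np.isnan(a) & ~np.isnan(b)
    if np.any(nonpositive):
        logger.warning("fold_change: %d non-positive inputs set to missing", int(np.sum(nonpositive)))
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = a / b
        if symmetric:
            fc = np.maximum(fc, b / a)
    fc = np.where(invalid, np.nan, fc)
    return float(fc) if fc.ndim == 0 else fc


@dataclass(frozen=True)
class GradientFit:
    """Least-squares line of ratio against RCG point index, plus end-point FCs.

    ``fc_1_7`` / ``fc_2_7`` are symmetric fold changes computed from the
    observed (not fitted) ratios at the first/second and last points.
    ``increasing_toward_lumbar`` is True when the point-1 ratio exceeds the
    last point's ratio (plasma-like behaviour).
    """

    slope: float
    intercept: float
    r_squared: float
    fc_1_7: float
    fc_2_7: float
    increasing_toward_lumbar: bool | None
    n_points: int
    evaluable: bool = True


_NOT_EVALUABLE = GradientFit(
    slope=math.nan,
    intercept=math.nan,
    r_squared=math.nan,
    fc_1_7=math.nan,
    fc_2_7=math.nan,
    increasing_toward_lumbar=None,
    n_points=0,
    evaluable=False,
)


def fit_gradient(
    ratios: Sequence[float],
    points: Sequence[int] | None = None,
    fitted_endpoints: bool = False,
) -> GradientFit:
    """Ordinary least squares of ratio vs integer point index.

    ``r_squared = 1 - SS_res / SS_tot``; the degenerate case ``SS_tot = 0``
    (constant ratios — the protein cannot exhibit a gradient) is defined as
    ``r_squared = 0``.  Fewer than 3 non-missing points marks the fit
    not-evaluable.  With ``fitted_endpoints=True`` the end-point fold changes
    use the fitted line instead of the observed ratios.
    """
    y = np.asarray(ratios, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float) if points is None else np.asarray(points, dtype=float)
    if len(x) != len(y):
        raise ValueError("points and ratios must have equal length")
    ok = np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return replace(_NOT_EVALUABLE, n_points=n)
    xs, ys = x[ok], y[ok]
    xm, ym = xs.mean(), ys.mean()
    sxx = float(np.sum((xs - xm) ** 2))
    sxy = float(np.sum((xs - xm) * (ys - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = float(np.sum((ys - (slope * xs + intercept)) ** 2))
    ss_tot = float(np.sum((ys - ym) ** 2))
    if ss_tot <= 0.0:
        r2 = 0.0
    else:
        r2 = min(max(1.0 - ss_res / ss_tot, 0.0), 1.0)

    first, second, last = x.min(), None, x.max()
    if len(x) >= 2:
        second = np.sort(np.unique(x))[1]

    def _at(p: float | None) -> float:
        if p is None:
            return math.nan
        if fitted_endpoints:
            return slope * p + intercept
        vals = y[(x == p) & ok]
        return float(vals[0]) if len(vals) else math.nan

    y1, y2, yK = _at(first), _at(second), _at(last)
    fc17 = fold_change(y1, yK, symmetric=True)
    fc27 = fold_change(y2, yK, symmetric=True)
    direction = None
    if np.isfinite(y1) and np.isfinite(yK):
        direction = bool(y1 > yK)
    return GradientFit(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        fc_1_7=fc17,
        fc_2_7=fc27,
        increasing_toward_lumbar=direction,
        n_points=n,
        evaluable=True,
    )


_RCG_COL = re.compile(r"^rcg_(\d+)$")


def fit_gradient_table(table: RatioTable, fitted_endpoints: bool = False) -> pd.DataFrame:
    """Fit every protein of an RCG ratio table; returns one row per accession.

    Columns named ``rcg_<k>`` supply the point index; other columns are
    ignored.  Proteins with fewer than 3 non-missing points are marked
    ``evaluable = False`` and counted in the log.
    """
    cols = {int(m.group(1)): c for c in table.ratios.columns if (m := _RCG_COL.match(c))}
    if len(cols) < 3:
        raise ValueError("ratio table has fewer than 3 rcg_<k> columns")
    points = sorted(cols)
    sub = table.ratios[[cols[k] for k in points]]
    rows = []
    for acc, row in sub.iterrows():
        fit = fit_gradient(row.to_numpy(), points=points, fitted_endpoints=fitted_endpoints)
        rows.append(
            {
                "accession": acc,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "fc_1_7": fit.fc_1_7,
                "fc_2_7": fit.fc_2_7,
                "increasing_toward_lumbar": fit.increasing_toward_lumbar,
                "n_points": fit.n_points,
                "evaluable": fit.evaluable,
            }
        )
    out = pd.DataFrame(rows).set_index("accession")
    n_excluded = int((~out["evaluable"]).sum())
    if n_excluded:
        logger.info("fit_gradient_table: %d proteins with < 3 points excluded", n_excluded)
    return out


def percent_cv(values: Sequence[float]) -> float:
    """100 × sample standard deviation / mean; missing if fewer than 2 values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2 or np.mean(v) == 0:  # CV undefined at zero mean
        return math.nan
    return 100.0 * float(np.std(v, ddof=1)) / float(np.mean(v))


@dataclass(frozen=True)
class Transition:
    label: str
    endogenous_area: float
    sis_area: float


@dataclass(frozen=True)
class MrmMeasurement:
    """One peptide's MRM transitions plus the chosen quantifier, if selected."""

    peptide: str
    transitions: tuple[Transition, ...]
    chosen_transition: str | None = None
    ratio: float | None = None

    def __post_init__(self) -> None:
        if len(self.transitions) < 3:
            raise ValueError(
                f"peptide {self.peptide!r}: at least 3 transitions must be monitored"
            )


def select_quantifier_transition(
    m: MrmMeasurement, interference_flags: Mapping[str, bool] | None = None
) -> MrmMeasurement | None:
    """Choose the most intense interference-free transition as quantifier.

    The quantifier is the unflagged transition with the largest SIS (heavy
    standard) peak area; the peptide ratio is endogenous/SIS of that
    transition.  Returns ``None`` (and logs) when every transition is flagged.
    """
    flags = interference_flags or {}
    candidates = [t for t in m.transitions if not flags.get(t.label, False)]
    if not candidates:
        logger.warning("peptide %s: all transitions flagged, excluded", m.peptide)
        return None
    chosen = max(candidates, key=lambda t: t.sis_area)
    if chosen.sis_area <= 0:
        logger.warning("peptide %s: chosen transition has non-positive SIS area", m.peptide)
        return None
    return replace(m, chosen_transition=chosen.label, ratio=chosen.endogenous_area / chosen.sis_area)


def rollup_peptides(peptide_ratios: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Roll peptide ratios up to proteins as the median, recording counts."""
    rows = []
    for accession, ratios in peptide_ratios.items():
        v = np.asarray(list(ratios), dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            raise ValueError(f"protein {accession!r}: at least one peptide ratio required")
        rows.append({"accession": accession, "ratio": float(np.median(v)), "n_peptides": len(v)})
    return pd.DataFrame(rows).set_index("accession")


def filter_quantifiable(
    matrix: AbundanceMatrix, min_unique_peptides: int = 2, min_contexts: int = 2
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Keep proteins quantified with enough unique peptides in enough contexts.

    With per-sample peptide counts, a context is a sample; the protein is
    retained when at least ``min_contexts`` samples reach
    ``min_unique_peptides``.  With one experiment-wide count per protein the
    context criterion reduces to the single count.  Returns the filtered
    matrix and an exclusion report (accession, reason).
    """
    if matrix.peptide_counts is None:
        raise ValueError("peptide counts are required for quantifiability filtering")
    pc = matrix.peptide_counts
    if isinstance(pc, pd.Series):
        n_contexts = (pc >= min_unique_peptides).astype(int)
        max_contexts = 1
    else:
        n_contexts = (pc >= min_unique_peptides).sum(axis=1)
        max_contexts = pc.shape[1]
    keep = n_contexts >= min(min_contexts, max_contexts) if min_contexts > 0 else n_contexts >= 0
    removed = matrix.values.index[~keep]
    report = pd.DataFrame(
        {
            "accession": removed,
            "reason": [
                f"fewer than {min_unique_peptides} unique peptides in "
                f"{min(min_contexts, max_contexts)} or more contexts"
                for _ in removed
            ],
        }
    ).set_index("accession")
    filtered = AbundanceMatrix(
        matrix.values.loc[keep],
        dict(matrix.sample_meta),
        pc.loc[keep],
    )
    return filtered, report
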