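"""Mechanistic contamination and gradient models, QC rules and ratio statistics.

The contamination forward model treats a contaminated CSF sample as a volume
mixture of CSF and whole blood.  Whole blood contributes a plasma phase —
whose effect on a protein scales with its equal-volume plasma/CSF
concentration ratio ``r_volume`` — and a cellular payload (erythrocytes and
platelets) of which centrifugation before freezing removes a configurable
fraction.  For a blood volume fraction ``f``::

    fc(f) = (1 - f) + f * [ (1 - caf) * r_volume
                            + caf * payload_ratio * (1 - removal * centrifuged) ]

so an albumin-like protein (``r_volume`` = 177, no cellular phase) shows a
fold change of 0.98 + 0.02 * 177 = 4.52 at a 2% spike — the typical four-fold
increase of liver-secreted proteins.  The inverse model recovers ``f`` from
observed fold changes of high-ratio proteins.

The gradient model treats the plasma-protein concentration as linear in
collection position along the lumbar-to-ventricular axis, from
``end_to_end_fc`` (relative units) at 0 mL down to 1 at the full collected
volume, and predicts how the collected volume shifts the measured
concentration of plasma-derived proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import percent_cv

__all__ = [
    "ContaminationEstimate",
    "PlasmaCsfRatio",
    "GradientModel",
    "QcResult",
    "predict_spike_fc",
    "estimate_blood_fraction",
    "qc_sample",
    "predict_volume_effect",
    "total_protein_fc",
    "plasma_csf_ratio",
    "plasma_csf_ratio_table",
    "to_equal_volume",
]

#: Default minimum equal-volume plasma/CSF ratio for a protein to enter the
#: contamination-fraction estimate; excludes mixed-origin proteins whose CSF
#: level owes much to intrathecal synthesis.
DEFAULT_R_FLOOR = 50.0

#: Maximum erythrocyte count per µL for an acceptable CSF sample.
ERYTHROCYTE_LIMIT = 500.0


def predict_spike_fc(
    r_volume: float,
    f: float,
    cell_assoc_frac: float = 0.0,
    centrifuged: bool = True,
    removal: float = 0.95,
    payload_ratio: float = 0.0,
):
    """Predicted fold change of a protein at blood volume fraction ``f``.

    Vectorized over ``r_volume`` / ``cell_assoc_frac`` / ``payload_ratio``.
    Strictly increasing in ``f`` and ``r_volume``; equals 1 at ``f = 0``.
    """
    f = float(f)
    if not 0.0 <= f <= 1.0:
        raise ValueError("blood fraction must be in [0, 1]")
    r = np.asarray(r_volume, dtype=float)
    caf = np.asarray(cell_assoc_frac, dtype=float)
    payload = np.asarray(payload_ratio, dtype=float)
    kept = 1.0 - removal * (1.0 if centrifuged else 0.0)
    fc = (1.0 - f) + f * ((1.0 - caf) * r + caf * payload * kept)
    return float(fc) if fc.ndim == 0 else fc


@dataclass(frozen=True)
class ContaminationEstimate:
    """Median-based estimate of the blood volume fraction in a sample."""

    f_hat: float
    n_proteins: int
    dispersion: float  # interquartile range of the per-protein estimates
    per_protein: pd.Series


def estimate_blood_fraction(
    observed_fc: pd.Series | Mapping[str, float],
    r_volume: pd.Series | Mapping[str, float],
    r_floor: float = DEFAULT_R_FLOOR,
    exclude: Sequence[str] = (),
) -> ContaminationEstimate:
    """Estimate the blood contamination fraction from observed fold changes.

    Inverts the forward model per protein, ``f_i = (fc_i - 1) / (r_i - 1)``,
    over proteins with ``r_volume >= r_floor`` and a directional fold change
    above 1, and takes the median for robustness against interference and
    intrathecal synthesis.  Hemoglobin-family (cell-associated) accessions
    should be passed via ``exclude``: their behaviour is centrifugation-
    dependent and not plasma-phase driven.
    """
    fc = pd.Series(observed_fc, dtype=float)
    r = pd.Series(r_volume, dtype=float)
    common = fc.index.intersection(r.index).difference(pd.Index(exclude))
    fc, r = fc[common], r[common]
    eligible = (r >= r_floor) & (fc > 1.0) & np.isfinite(fc) & np.isfinite(r)
    if int(eligible.sum()) < 3:
        raise ValueError(
            f"only {int(eligible.sum())} proteins with r_volume >= {r_floor} and fc > 1; "
            "at least 3 required — consider extending the MRM panel with "
            "high plasma/CSF ratio proteins"
        )
    f_i = (fc[eligible] - 1.0) / (r[eligible] - 1.0)
    q25, q75 = np.percentile(f_i, [25, 75])
    return ContaminationEstimate(
        f_hat=float(np.median(f_i)),
        n_proteins=int(eligible.sum()),
        dispersion=float(q75 - q25),
        per_protein=f_i,
    )


@dataclass(frozen=True)
class QcResult:
    passed: bool
    reasons: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()


def qc_sample(erythrocytes_per_ul: float, hemoglobin_detected: bool = False) -> QcResult:
    """Sample-quality rule: fail above 500 erythrocytes/µL, warn on hemoglobin."""
    if erythrocytes_per_ul < 0:
        raise ValueError("erythrocyte count must be >= 0")
    reasons: list[str] = []
    warnings: list[str] = []
    if erythrocytes_per_ul > ERYTHROCYTE_LIMIT:
        reasons.append(
            f"erythrocyte count {erythrocytes_per_ul:g}/uL exceeds {ERYTHROCYTE_LIMIT:g}/uL"
        )
    if hemoglobin_detected:
        warnings.append("hemoglobin detected: possible blood contamination")
    return QcResult(passed=not reasons, reasons=tuple(reasons), warnings=tuple(warnings))


@dataclass(frozen=True)
class GradientModel:
    """Linear rostro-caudal gradient of plasma-derived protein concentration."""

    end_to_end_fc: float = 1.6
    total_volume: float = 45.0  # mL

    def __post_init__(self) -> None:
        if self.end_to_end_fc < 1.0:
            raise ValueError("end_to_end_fc must be >= 1")
        if self.total_volume <= 0.0:
            raise ValueError("total_volume must be > 0")

    def concentration(self, position_ml: float) -> float:
        """Relative concentration at a collection position (0 = lumbar end)."""
        x = position_ml / self.total_volume
        return self.end_to_end_fc + (1.0 - self.end_to_end_fc) * x


def predict_volume_effect(
    model: GradientModel, collected_volume: float, relative_to: str = "ventricular"
) -> float:
    """Percent concentration difference of collecting only the first millilitres.

    The concentration of plasma-derived proteins falls linearly from
    ``end_to_end_fc`` at the lumbar end (0 mL) to 1 at the ventricular end
    (``total_volume`` mL).  Returns the difference between the mean over the
    first ``collected_volume`` mL and the mean over the full volume, × 100,
    in units of the ventricular-end concentration (default) or of the pooled
    full-volume mean (``relative_to="pooled"``).  Monotonically decreasing in
    the collected volume; 0 at full volume.
    """
    if not 0.0 < collected_volume <= model.total_volume:
        raise ValueError("collected_volume must be in (0, total_volume]")
    if relative_to not in {"ventricular", "pooled"}:
        raise ValueError("relative_to must be 'ventricular' or 'pooled'")
    fc, V = model.end_to_end_fc, model.total_volume
    # mean of the linear profile over [0, v]: fc + (1 - fc) * v / (2 V)
    mean_collected = fc + (1.0 - fc) * collected_volume / (2.0 * V)
    mean_pooled = (fc + 1.0) / 2.0
    diff = mean_collected - mean_pooled
    if relative_to == "pooled":
        diff /= mean_pooled
    return 100.0 * diff


def total_protein_fc(conc_lumbar: float, conc_ventricular: float) -> float:
    """Symmetric fold change between the lumbar and ventricular total protein."""
    if conc_lumbar <= 0 or conc_ventricular <= 0:
        raise ValueError("concentrations must be > 0")
    return max(conc_lumbar / conc_ventricular, conc_ventricular / conc_lumbar)


@dataclass(frozen=True)
class PlasmaCsfRatio:
    """Per-protein plasma/CSF ratio statistics across patients."""

    ratios: pd.Series  # indexed by patient id
    mean: float
    sd: float
    percent_cv: float
    n: int
    basis: str  # equal_protein or equal_volume
    accession: str | None = None
    evaluable: bool = True


def plasma_csf_ratio(
    plasma: pd.Series | Mapping[str, float],
    csf: pd.Series | Mapping[str, float],
    basis: str = "equal_protein",
    accession: str | None = None,
) -> PlasmaCsfRatio:
    """Per-patient plasma/CSF ratios with mean, sd and %CV.

    Patients missing either value are excluded; fewer than 2 complete pairs
    marks the protein not-evaluable (mirroring the two-or-more-patients
    inclusion rule).
    """
    if basis not in {"equal_protein", "equal_volume"}:
        raise ValueError("basis must be 'equal_protein' or 'equal_volume'")
    p = pd.Series(plasma, dtype=float)
    c = pd.Series(csf, dtype=float)
    common = p.index.intersection(c.index)
    p, c = p[common], c[common]
    ok = np.isfinite(p) & np.isfinite(c) & (c != 0)
    ratios = (p[ok] / c[ok]).rename("plasma_csf_ratio")
    if len(ratios) < 2:
        return PlasmaCsfRatio(
            ratios=ratios, mean=math.nan, sd=math.nan, percent_cv=math.nan,
            n=len(ratios), basis=basis, accession=accession, evaluable=False,
        )
    return PlasmaCsfRatio(
        ratios=ratios,
        mean=float(ratios.mean()),
        sd=float(ratios.std(ddof=1)),
        percent_cv=percent_cv(ratios),
        n=len(ratios),
        basis=basis,
        accession=accession,
        evaluable=True,
    )


def plasma_csf_ratio_table(matrix, basis: str = "equal_protein") -> pd.DataFrame:
    """Per-protein ratio statistics from a paired plasma/CSF abundance matrix.

    ``matrix`` is an :class:`~csfpre.io.AbundanceMatrix` whose samples carry
    ``patient_fluid`` roles; one plasma and one CSF column per patient.
    """
    plasma_cols: dict[str, str] = {}
    csf_cols: dict[str, str] = {}
    for sid, meta in matrix.sample_meta.items():
        if meta.role != "patient_fluid":
            continue
        (plasma_cols if meta.fluid == "plasma" else csf_cols)[meta.patient_id] = sid
    patients = sorted(set(plasma_cols) & set(csf_cols))
    if len(patients) < 2:
        raise ValueError("at least 2 patients with paired plasma/CSF samples required")
    rows = {}
    for acc in matrix.values.index:
        p = pd.Series({pid: matrix.values.at[acc, plasma_cols[pid]] for pid in patients})
        c = pd.Series({pid: matrix.values.at[acc, csf_cols[pid]] for pid in patients})
        r = plasma_csf_ratio(p, c, basis=basis, accession=acc)
        rows[acc] = {
            "mean_ratio": r.mean,
            "sd": r.sd,
            "percent_cv": r.percent_cv,
            "n_patients": r.n,
            "basis": r.basis,
            "evaluable": r.evaluable,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "accession"
    return out


def to_equal_volume(
    ratio_equal_protein: float, total_conc_plasma: float, total_conc_csf: float
):
    """Rescale an equal-protein-basis ratio to the equal-volume basis.

    Equal-protein loading divides each fluid by its total protein
    concentration, so multiplying back by the concentration ratio recovers
    the equal-volume (per-µL) ratio: an albumin-like ratio of ~1 on 70 vs 0.4
    µg/µL totals becomes ~175.
    """
    if total_conc_plasma <= 0 or total_conc_csf <= 0:
        raise ValueError("total protein concentrations must be > 0")
    r = np.asarray(ratio_equal_protein, dtype=float) * (total_conc_plasma / total_conc_csf)
    return float(r) if r.ndim == 0 else r
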