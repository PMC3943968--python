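"""Ground-truthed synthetic CSF proteomes and the four experiment designs.

The generator emulates the study conditions end to end so that every pipeline
stage is testable without any external data:

* a pooled-CSF proteome spiked with whole blood at 0.5% and 2% by volume,
  with and without centrifugation before freezing;
* a seven-point rostro-caudal gradient (RCG) series with a pooled reference
  channel and duplicate channels for the end points;
* five paired plasma/CSF patients with per-protein plasma/CSF concentration
  ratios spanning several orders of magnitude.

Whole blood is modelled as a plasma phase plus a cellular payload
(erythrocytes/platelets); centrifugation removes a configurable fraction of
the cellular payload only.  Technical noise is multiplicative log-normal with
a given coefficient of variation, applied independently per (protein, sample),
mean 1 so that expected abundances equal the closed-form forward model.
Everything is bit-reproducible given the same seed and spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, SampleMeta

__all__ = [
    "ORIGINS",
    "ALBUMIN_SENTINEL",
    "SimulationSpec",
    "ProteinCatalog",
    "PlasmaCsfExperiment",
    "generate_catalog",
    "simulate_blood_spike",
    "simulate_spike_experiment",
    "simulate_centrifugation_pair",
    "simulate_rcg_series",
    "simulate_plasma_csf_pairs",
    "multiplicative_noise",
    "write_ground_truth",
]

ORIGINS = ("cns", "leptomeningeal", "plasma_liver", "blood_cellular", "mixed")

#: Accession of the albumin-like sentinel protein, always present in a
#: catalog.  Its equal-volume plasma/CSF ratio is fixed at 177, the canonical
#: albumin value, and its gradient amplitude at 1.58.
ALBUMIN_SENTINEL = "SIM-ALB"

_DEFAULT_COUNTS: dict[str, int] = {
    "cns": 80,
    "leptomeningeal": 10,
    "plasma_liver": 70,
    "blood_cellular": 20,
    "mixed": 20,
}

# Per-origin log-uniform sampling ranges for the equal-volume plasma/CSF
# concentration ratio r_volume (dimensionless).  CNS and leptomeningeal
# proteins barely cross the blood-CNS barriers; liver-made plasma proteins
# span albumin-like (~177) up to IgM/fibrinogen-like (~1.5e4); the plasma
# phase of cell-associated proteins is low but their cellular payload is huge.
_R_VOLUME_RANGES = {
    "cns": (0.05, 5.0),
    "leptomeningeal": (0.05, 5.0),
    "plasma_liver": (50.0, 15000.0),
    "blood_cellular": (0.05, 1.0),
    "mixed": (5.0, 50.0),
}

# CSF concentration (arbitrary units/µL).  For liver-derived plasma proteins
# the CSF level is derived from a plasma level divided by r_volume, which
# reproduces the real anti-correlation between barrier passage and CSF level.
_C_CSF_RANGES = {
    "cns": (0.5, 100.0),
    "leptomeningeal": (1.0, 50.0),
    "blood_cellular": (0.01, 1.0),
    "mixed": (0.5, 50.0),
}
_C_PLASMA_RANGE_LIVER = (50.0, 5000.0)

#: Cellular enrichment factor ranges (payload abundance relative to c_csf per
#: unit blood fraction) for cell-associated proteins.
_PAYLOAD_RANGE = (1.0e3, 5.0e4)


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the synthetic experiments.

    Defaults mirror the study design: 0.5% and 2% blood spikes, 95% cellular
    payload removal by centrifugation, seven RCG points with a 1.6-fold
    end-to-end plasma-protein gradient, five plasma/CSF patients and 20%
    technical CV.  ``seed`` is mandatory; there is no hidden global
    randomness.
    """

    seed: int
    n_per_class: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_COUNTS))
    noise_cv: float = 0.20
    gradient_amp_plasma: float = 1.6
    spike_fractions: tuple[float, ...] = (0.005, 0.02)
    centrifugation_removal: float = 0.95
    n_rcg_points: int = 7
    n_patients: int = 5
    patient_sigma: float = 0.35
    hemoglobin_point1_spike: bool = False
    hb_point1_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        unknown = sorted(set(self.n_per_class) - set(ORIGINS))
        if unknown:
            raise ValueError(f"unknown origin classes: {unknown}")
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0.0 <= self.centrifugation_removal <= 1.0:
            raise ValueError("centrifugation_removal must be in [0, 1]")
        if any(not 0.0 <= f <= 1.0 for f in self.spike_fractions):
            raise ValueError("spike fractions must be in [0, 1]")
        if self.n_rcg_points < 3:
            raise ValueError("n_rcg_points must be >= 3")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")


@dataclass
class ProteinCatalog:
    """Per-protein ground truth driving the simulators.

    ``table`` is indexed by accession with columns ``origin``, ``c_csf``
    (true CSF concentration), ``r_volume`` (equal-volume plasma/CSF ratio),
    ``cell_assoc_frac`` (fraction of the whole-blood amount carried by cells
    or platelets), ``payload_ratio`` (cellular enrichment relative to
    ``c_csf``), ``gradient_amp`` (end-to-end RCG fold change) and
    ``depleted``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.table) == 0:
            raise ValueError("catalog must contain at least one protein")
        if not self.table.index.is_unique:
            raise ValueError("catalog accessions must be unique")
        t = self.table
        if (t["r_volume"] < 0).any() or (t["c_csf"] <= 0).any():
            raise ValueError("r_volume must be >= 0 and c_csf > 0")
        if ((t["cell_assoc_frac"] < 0) | (t["cell_assoc_frac"] > 1)).any():
            raise ValueError("cell_assoc_frac must be in [0, 1]")
        if (t["gradient_amp"] < 1).any():
            raise ValueError("gradient_amp must be >= 1")
        cns = t["origin"] == "cns"
        if (t.loc[cns, "cell_assoc_frac"] != 0).any() or (t.loc[cns, "gradient_amp"] != 1).any():
            raise ValueError("cns proteins must have cell_assoc_frac = 0 and gradient_amp = 1")
        cellular = t["origin"] == "blood_cellular"
        if (t.loc[cellular, "cell_assoc_frac"] < 0.9).any():
            raise ValueError("blood_cellular proteins must have cell_assoc_frac >= 0.9")

    @property
    def accessions(self) -> list[str]:
        return self.table.index.tolist()

    def __len__(self) -> int:
        return len(self.table)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))


def multiplicative_noise(
    rng: np.random.Generator, shape: tuple[int, ...], cv: float
) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise factors with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=shape)


def generate_catalog(spec: SimulationSpec) -> ProteinCatalog:
    """Draw a ground-truth protein catalog, deterministic given the seed.

    The albumin-like sentinel is always present, with ``r_volume`` 177 and a
    CSF concentration set to 1.2× the summed concentration of all other
    proteins, making it the dominant protein by mass as albumin is in CSF.
    """
    if sum(spec.n_per_class.values()) == 0:
        raise ValueError("catalog would contain zero proteins")
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    idx = 0
    for origin in ORIGINS:
        n = int(spec.n_per_class.get(origin, 0))
        if n == 0:
            continue
        r = _log_uniform(rng, *_R_VOLUME_RANGES[origin], n)
        if origin == "plasma_liver":
            c_plasma = _log_uniform(rng, *_C_PLASMA_RANGE_LIVER, n)
            c_csf = c_plasma / r
        else:
            c_csf = _log_uniform(rng, *_C_CSF_RANGES[origin], n)
        if origin == "blood_cellular":
            caf = rng.uniform(0.9, 1.0, size=n)
            payload = _log_uniform(rng, *_PAYLOAD_RANGE, n)
        else:
            caf = np.zeros(n)
            payload = np.zeros(n)
        if origin == "cns":
            amp = np.ones(n)
        elif origin == "leptomeningeal":
            amp = rng.uniform(1.15, 1.35, size=n)
        elif origin == "mixed":
            amp = rng.uniform(1.05, 1.30, size=n)
        else:  # plasma_liver, blood_cellular: plasma-like gradient
            amp = np.full(n, spec.gradient_amp_plasma)
        for i in range(n):
            idx += 1
            rows.append(
                {
                    "accession": f"SIM{idx:04d}",
                    "origin": origin,
                    "c_csf": float(c_csf[i]),
                    "r_volume": float(r[i]),
                    "cell_assoc_frac": float(caf[i]),
                    "payload_ratio": float(payload[i]),
                    "gradient_amp": float(amp[i]),
                    "depleted": False,
                }
            )
    table = pd.DataFrame(rows).set_index("accession")
    sentinel = pd.DataFrame(
        [
            {
                "origin": "plasma_liver",
                "c_csf": 1.2 * float(table["c_csf"].sum()),
                "r_volume": 177.0,
                "cell_assoc_frac": 0.0,
                "payload_ratio": 0.0,
                "gradient_amp": 1.58,
                "depleted": True,  # albumin is on the 14-protein depletion list
            }
        ],
        index=pd.Index([ALBUMIN_SENTINEL], name="accession"),
    )
    return ProteinCatalog(pd.concat([sentinel, table]))


def _expected_spike(
    catalog: ProteinCatalog, fraction: float, centrifuged: bool, removal: float
) -> np.ndarray:
    t = catalog.table
    c = t["c_csf"].to_numpy()
    r = t["r_volume"].to_numpy()
    caf = t["cell_assoc_frac"].to_numpy()
    payload = t["payload_ratio"].to_numpy() * c
    if centrifuged:
        payload = payload * (1.0 - removal)
    return (1.0 - fraction) * c + fraction * ((1.0 - caf) * r * c + caf * payload)


def simulate_blood_spike(
    catalog: ProteinCatalog,
    fraction: float,
    centrifuged: bool = True,
    noise_cv: float = 0.20,
    seed: int | None = None,
    centrifugation_removal: float = 0.95,
) -> AbundanceMatrix:
    """Simulate one blood spike-in plus the unspiked reference aliquot."""
    if not 0.0 <= fraction <= 0.1:
        raise ValueError("blood fraction must be in [0, 0.1]")
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    ref = catalog.table["c_csf"].to_numpy()
    spiked = _expected_spike(catalog, fraction, centrifuged, centrifugation_removal)
    values = np.column_stack([ref, spiked]) * multiplicative_noise(
        rng, (len(catalog), 2), noise_cv
    )
    sid = f"spike_{fraction:g}" + ("" if centrifuged else "_nc")
    meta = {
        "reference": SampleMeta("reference", "reference"),
        sid: SampleMeta(sid, "spiked", spike_fraction=fraction, centrifuged=centrifuged),
    }
    df = pd.DataFrame(values, index=catalog.table.index, columns=list(meta))
    return AbundanceMatrix(df, meta)


def simulate_spike_experiment(catalog: ProteinCatalog, spec: SimulationSpec) -> AbundanceMatrix:
    """Reference plus all spike levels (centrifuged), sharing one reference.

    Mirrors the discovery design where both spike levels were compared to a
    single unspiked aliquot of the same CSF pool.
    """
    rng = np.random.default_rng(spec.seed)
    cols = {"reference": catalog.table["c_csf"].to_numpy()}
    meta = {"reference": SampleMeta("reference", "reference")}
    for f in spec.spike_fractions:
        sid = f"spike_{f:g}"
        cols[sid] = _expected_spike(catalog, f, True, spec.centrifugation_removal)
        meta[sid] = SampleMeta(sid, "spiked", spike_fraction=f, centrifuged=True)
    values = np.column_stack(list(cols.values())) * multiplicative_noise(
        rng, (len(catalog), len(cols)), spec.noise_cv
    )
    df = pd.DataFrame(values, index=catalog.table.index, columns=list(cols))
    return AbundanceMatrix(df, meta)


def simulate_centrifugation_pair(
    catalog: ProteinCatalog, spec: SimulationSpec, fraction: float = 0.005
) -> AbundanceMatrix:
    """Two equal spikes of which only one is centrifuged, plus the reference."""
    rng = np.random.default_rng(spec.seed)
    cols = {
        "reference": catalog.table["c_csf"].to_numpy(),
        f"spike_{fraction:g}": _expected_spike(catalog, fraction, True, spec.centrifugation_removal),
        f"spike_{fraction:g}_nc": _expected_spike(catalog, fraction, False, spec.centrifugation_removal),
    }
    meta = {
        "reference": SampleMeta("reference", "reference"),
        f"spike_{fraction:g}": SampleMeta(
            f"spike_{fraction:g}", "spiked", spike_fraction=fraction, centrifuged=True
        ),
        f"spike_{fraction:g}_nc": SampleMeta(
            f"spike_{fraction:g}_nc", "spiked", spike_fraction=fraction, centrifuged=False
        ),
    }
    values = np.column_stack(list(cols.values())) * multiplicative_noise(
        rng, (len(catalog), 3), spec.noise_cv
    )
    df = pd.DataFrame(values, index=catalog.table.index, columns=list(cols))
    return AbundanceMatrix(df, meta)


def simulate_rcg_series(catalog: ProteinCatalog, spec: SimulationSpec) -> AbundanceMatrix:
    """Simulate the RCG series with pooled reference and duplicate end points.

    The noise-free abundance at point ``k`` (1 = lumbar-most, ``K`` =
    ventricular-most) falls linearly from ``gradient_amp * c_csf`` at point 1
    to ``c_csf`` at point ``K``.  The reference channel is the mean of the
    ``K`` noise-free point values; points 1 and ``K`` appear twice, mirroring
    the duplicated channels of the labelling design.
    """
    if (catalog.table["gradient_amp"] < 1).any():
        raise ValueError("gradient_amp must be >= 1 for every protein")
    K = spec.n_rcg_points
    rng = np.random.default_rng(spec.seed)
    c = catalog.table["c_csf"].to_numpy()
    amp = catalog.table["gradient_amp"].to_numpy()
    points = np.arange(1, K + 1)
    # expected[:, k-1]: amp*c at k=1 linearly down to c at k=K
    frac = (points - 1) / (K - 1)
    expected = c[:, None] * (amp[:, None] + (1.0 - amp[:, None]) * frac[None, :])
    if spec.hemoglobin_point1_spike:
        cellular = (catalog.table["origin"] == "blood_cellular").to_numpy()
        expected[cellular, 0] *= spec.hb_point1_factor
    reference = expected.mean(axis=1)

    cols: dict[str, np.ndarray] = {"reference": reference}
    meta: dict[str, SampleMeta] = {"reference": SampleMeta("reference", "reference")}
    for k in points:
        reps = ("rep1", "rep2") if k in (1, K) else ("",)
        for rep in reps:
            sid = f"rcg{k}" + (f"_{rep}" if rep else "")
            cols[sid] = expected[:, k - 1]
            meta[sid] = SampleMeta(sid, "rcg_point", rcg_point=int(k))
    values = np.column_stack(list(cols.values())) * multiplicative_noise(
        rng, (len(catalog), len(cols)), spec.noise_cv
    )
    df = pd.DataFrame(values, index=catalog.table.index, columns=list(cols))
    return AbundanceMatrix(df, meta)


@dataclass
class PlasmaCsfExperiment:
    """Paired plasma/CSF abundances on both normalization bases.

    ``equal_volume`` holds per-µL abundances; ``equal_protein`` holds the
    same columns rescaled so each sample contributes an equal total protein
    amount (the 10 µg loading), i.e. each column divided by its total and
    multiplied by the mean total.  ``total_protein`` is the per-sample total
    of the equal-volume columns.
    """

    equal_volume: AbundanceMatrix
    equal_protein: AbundanceMatrix
    total_protein: pd.Series


def simulate_plasma_csf_pairs(
    catalog: ProteinCatalog, spec: SimulationSpec
) -> PlasmaCsfExperiment:
    """Simulate paired plasma/CSF samples for ``n_patients`` individuals.

    Per patient, the noise-free plasma abundance is ``r_volume * c_csf``
    modulated by a patient-level log-normal factor with ln-scale sd
    ``patient_sigma`` (between-patient barrier variability, applied to plasma
    only); technical noise applies to every sample.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(catalog)
    c = catalog.table["c_csf"].to_numpy()
    r = catalog.table["r_volume"].to_numpy()
    cols: dict[str, np.ndarray] = {}
    meta: dict[str, SampleMeta] = {}
    for p in range(1, spec.n_patients + 1):
        pid = f"P{p}"
        patient = (
            np.ones(n)
            if spec.patient_sigma == 0
            else rng.lognormal(-spec.patient_sigma**2 / 2, spec.patient_sigma, size=n)
        )
        cols[f"{pid}_CSF"] = c
        cols[f"{pid}_plasma"] = r * c * patient
        meta[f"{pid}_CSF"] = SampleMeta(f"{pid}_CSF", "patient_fluid", patient_id=pid, fluid="CSF")
        meta[f"{pid}_plasma"] = SampleMeta(
            f"{pid}_plasma", "patient_fluid", patient_id=pid, fluid="plasma"
        )
    values = np.column_stack(list(cols.values())) * multiplicative_noise(
        rng, (n, len(cols)), spec.noise_cv
    )
    ev = pd.DataFrame(values, index=catalog.table.index, columns=list(cols))
    totals = ev.sum(axis=0)
    scale = float(totals.mean())
    ep = ev.div(totals, axis=1) * scale
    return PlasmaCsfExperiment(
        equal_volume=AbundanceMatrix(ev, dict(meta)),
        equal_protein=AbundanceMatrix(ep, dict(meta)),
        total_protein=totals,
    )


def write_ground_truth(catalog: ProteinCatalog, path: str | Path) -> Path:
    """Write the catalog ground truth as a TSV."""
    path = Path(path)
    catalog.table.to_csv(path, sep="\t")
    return path
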