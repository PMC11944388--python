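"""Exposure metrics, prediction error, bioequivalence ratios and safe-space sweeps.

Mean-profile bioequivalence: the test/reference (T/R) ratios of Cmax and
AUC(0-t) from simulated mean profiles, gated on the regulatory 80-125%
interval, with a stricter +/-10% flag reflecting point-estimate practice.
Tmax ratios are reported but never gated.  The particle-size safe space is
the largest D90 whose simulated tablet remains bioequivalent to a chosen
reference (oral solution or the clinical 83 um tablet).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .disposition import ConcentrationProfile
from .dissolution import classify_dissolution, simulate_dissolution
from .gi import simulate_oral
from .params import (
    DissolutionCondition,
    DispositionParams,
    DrugProperties,
    FormulationSpec,
    GIPhysiology,
)

__all__ = [
    "PKMetrics",
    "BEResult",
    "compute_metrics",
    "prediction_error",
    "tr_ratio",
    "safe_space_sweep",
    "dissolution_space_sweep",
]


@dataclass(frozen=True)
class PKMetrics:
    """Non-compartmental exposure metrics of a single profile."""

    cmax: float  #: ng/mL
    tmax: float  #: h (earliest maximizer on the output grid)
    auc_0t: float  #: ng*h/mL, linear trapezoid to t_last
    t_last: float  #: h

    def __post_init__(self) -> None:
        if self.cmax < 0 or self.auc_0t < 0:
            raise ValueError("Cmax and AUC must be non-negative")
        if not 0.0 <= self.tmax <= self.t_last:
            raise ValueError("Tmax must lie in [0, t_last]")


@dataclass(frozen=True)
class BEResult:
    """Test/reference exposure ratios and BE flags (Cmax & AUC gated only)."""

    ratio_cmax: float
    ratio_tmax: float
    ratio_auc: float
    be_80_125: bool
    be_pm10: bool

    def __post_init__(self) -> None:
        if min(self.ratio_cmax, self.ratio_auc) <= 0:
            raise ValueError("ratios must be positive")
        if self.be_pm10 and not self.be_80_125:
            raise ValueError("be_pm10 implies be_80_125")


def compute_metrics(profile: ConcentrationProfile) -> PKMetrics:
    """Cmax, earliest Tmax and trapezoidal AUC(0-t) of a profile."""
    t = profile.times_h
    c = profile.conc_ng_ml
    if len(t) < 3:
        raise ValueError("need at least 3 time points for exposure metrics")
    if np.all(c == 0):
        warnings.warn("all-zero concentration profile; metrics are zero", RuntimeWarning)
        return PKMetrics(cmax=0.0, tmax=0.0, auc_0t=0.0, t_last=float(t[-1]))
    i = int(np.argmax(c))
    return PKMetrics(
        cmax=float(c[i]),
        tmax=float(t[i]),
        auc_0t=float(np.trapezoid(c, t)),
        t_last=float(t[-1]),
    )


def prediction_error(observed: float, predicted: float) -> float:
    """%PE = (observed - predicted) / observed * 100, signed and unrounded."""
    if observed == 0:
        raise ValueError("prediction error undefined for observed = 0")
    return (observed - predicted) / observed * 100.0


def tr_ratio(test: PKMetrics, ref: PKMetrics) -> BEResult:
    """T/R exposure ratios with 80-125% and +/-10% BE flags on Cmax and AUC."""
    if ref.cmax <= 0 or ref.auc_0t <= 0 or ref.tmax <= 0:
        raise ValueError("reference metrics must be positive")
    r_cmax = test.cmax / ref.cmax
    r_auc = test.auc_0t / ref.auc_0t
    r_tmax = test.tmax / ref.tmax
    gated = (r_cmax, r_auc)
    be_wide = all(0.80 <= r <= 1.25 for r in gated)
    be_narrow = all(0.90 <= r <= 1.10 for r in gated)
    return BEResult(
        ratio_cmax=r_cmax,
        ratio_tmax=r_tmax,
        ratio_auc=r_auc,
        be_80_125=be_wide,
        be_pm10=be_narrow and be_wide,
    )


def safe_space_sweep(
    sizes_um: np.ndarray,
    drug: DrugProperties,
    physiology: GIPhysiology,
    disposition: DispositionParams,
    dose_mg: float = 5.0,
    granulation: str = "dry",
    z: float = 31.0,
    reference_size_um: float = 83.0,
    times_h: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a particle-size grid and tabulate T/R ratios vs two references.

    References are the oral solution (R1) and the ``reference_size_um``
    tablet (R2).  Returns the ratio table (one row per metric and reference,
    one column per formulation, solution first) and, per reference, the
    largest swept size whose Cmax AND AUC ratios lie within 80-125%.
    """
    sizes = np.asarray(sizes_um, dtype=float)
    if sizes.size == 0:
        raise ValueError("empty particle-size vector")
    if np.any(sizes <= 0) or np.any(np.diff(sizes) <= 0):
        raise ValueError("sizes must be positive and strictly increasing")

    sol = simulate_oral(
        drug,
        FormulationSpec(dose_mg=dose_mg, form="solution"),
        physiology,
        disposition,
        times_h=times_h,
    )
    metrics = {"solution": compute_metrics(sol.profile)}
    results = {"solution": sol}
    for s in sizes:
        r = simulate_oral(
            drug,
            FormulationSpec(dose_mg=dose_mg, form="ir_tablet", granulation=granulation, d90_um=s),
            physiology,
            disposition,
            times_h=times_h,
            z=z,
        )
        results[s] = r
        metrics[s] = compute_metrics(r.profile)
    ref2 = metrics.get(reference_size_um)
    if ref2 is None:
        ref_run = simulate_oral(
            drug,
            FormulationSpec(
                dose_mg=dose_mg, form="ir_tablet", granulation=granulation,
                d90_um=reference_size_um,
            ),
            physiology,
            disposition,
            times_h=times_h,
            z=z,
        )
        ref2 = compute_metrics(ref_run.profile)

    labels = ["solution"] + [f"{s:g} um" for s in sizes]
    rows = []
    largest_be = {}
    for ref_name, ref in (("solution", metrics["solution"]), ("tablet_ref", ref2)):
        ratios = {"solution": tr_ratio(metrics["solution"], ref)}
        for s in sizes:
            ratios[s] = tr_ratio(metrics[s], ref)
        for metric in ("cmax", "tmax", "auc"):
            rows.append(
                [ref_name, metric]
                + [getattr(ratios[k], f"ratio_{metric}") for k in ["solution", *sizes]]
            )
        passing = [s for s in sizes if ratios[s].be_80_125]
        largest_be[ref_name] = max(passing) if passing else None
    table = pd.DataFrame(rows, columns=["reference", "metric", *labels])
    return table, largest_be


def dissolution_space_sweep(
    sizes_um: np.ndarray,
    drug: DrugProperties,
    condition: DissolutionCondition,
    z: float,
    dose_mg: float = 5.0,
    granulation: str = "dry",
    times_min: np.ndarray | None = None,
) -> pd.DataFrame:
    """In vitro dissolution over a particle-size grid with BCS-rate labels.

    One row per size with % dissolved at 15/30/45/60 min and the
    very_fast/fast/not_fast classification.
    """
    sizes = np.asarray(sizes_um, dtype=float)
    if sizes.size == 0:
        raise ValueError("empty particle-size vector")
    if times_min is None:
        times_min = np.arange(5.0, 61.0, 5.0)
    rows = []
    for s in sizes:
        form = FormulationSpec(
            dose_mg=dose_mg, form="ir_tablet", granulation=granulation, d90_um=s
        )
        prof = simulate_dissolution(drug, form, condition, z=z, times_min=times_min)
        row = {"d90_um": s, "classification": classify_dissolution(prof)}
        for tq in (15.0, 30.0, 45.0, 60.0):
            row[f"pct_{int(tq)}min"] = float(
                np.interp(tq, prof.times_min, prof.pct_dissolved)
            )
        rows.append(row)
    return pd.DataFrame(rows)
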