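"""Synthetic datasets with the statistical structure the fitters assume.

Two generators emulate the study designs behind the model:

* a 16-profile mean dissolution dataset (58 observations: full profiles for
  the 20 mg wet/dry tablets and the 5 mg wet tablets in both media, plus
  eight single 30-min points for 5 mg dry tablets across a particle-size
  ladder), with additive Gaussian error on % dissolved, and
* IV/oral concentration-time profiles from the disposition model with
  additive or proportional noise, scaled by 1/sqrt(n) when the profile is a
  mean over ``n_subjects``.

Small literature-reported summary tables (observed and model-predicted PK
metrics, the fitted disposition constants and the particle-size ratio grid)
ship as checksum-pinned CSV fixtures under ``pbbm/data``.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import numpy as np
import pandas as pd

from .disposition import simulate_iv
from .dissolution import PROFILE_COLUMNS, simulate_dissolution
from .params import (
    DissolutionCondition,
    DispositionParams,
    DrugProperties,
    FormulationSpec,
    ZModelParams,
    apixaban,
)

__all__ = [
    "default_dissolution_design",
    "gen_dissolution_dataset",
    "gen_pk_dataset",
    "load_fixture",
    "FIXTURES",
]

_FULL_TIMES = (10.0, 15.0, 20.0, 30.0, 45.0, 60.0)
_FULL_TIMES_FAST = (5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0)
_SINGLE_POINT_SIZES = (11.0, 20.0, 35.0, 50.0, 65.0, 83.0, 100.0, 129.0)


def default_dissolution_design() -> list[dict]:
    """The 16-profile / 58-point mean-dissolution design.

    Full profiles: 20 mg wet and dry granulation tablets (D90 83.9 um) in
    both media; 5 mg wet granulation tablets (D90 50 and 89 um) in both
    media, with an extra early point in the faster HCl medium.  Single-point
    profiles: eight 5 mg dry tablets (D90 11-129 um) at 30 min in the
    pH 6.8 + SDS medium.
    """
    design: list[dict] = []
    for gran in ("wet", "dry"):
        for medium in ("ph68_sds", "hcl_01n"):
            design.append(
                dict(dose_mg=20.0, granulation=gran, medium=medium,
                     d90_um=83.9, times_min=_FULL_TIMES)
            )
    for d90 in (50.0, 89.0):
        design.append(
            dict(dose_mg=5.0, granulation="wet", medium="ph68_sds",
                 d90_um=d90, times_min=_FULL_TIMES)
        )
        design.append(
            dict(dose_mg=5.0, granulation="wet", medium="hcl_01n",
                 d90_um=d90, times_min=_FULL_TIMES_FAST)
        )
    for d90 in _SINGLE_POINT_SIZES:
        design.append(
            dict(dose_mg=5.0, granulation="dry", medium="ph68_sds",
                 d90_um=d90, times_min=(30.0,))
        )
    return design


def gen_dissolution_dataset(
    truth: ZModelParams,
    design: list[dict] | None = None,
    noise_sd: float = 2.0,
    seed: int = 0,
    drug: DrugProperties | None = None,
    volume_ml: float = 900.0,
) -> pd.DataFrame:
    """Simulate a dissolution dataset under the Z covariate model plus noise.

    Additive Gaussian noise (SD ``noise_sd`` % dissolved) is clipped to
    [0, 105]; output is deterministic per seed and uses the tidy profile
    schema shared with the readers and the fitter.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    drug = drug or apixaban()
    design = design if design is not None else default_dissolution_design()
    rng = np.random.default_rng(seed)
    rows = []
    for i, spec in enumerate(design):
        form = FormulationSpec(
            dose_mg=spec["dose_mg"],
            form="ir_tablet",
            granulation=spec["granulation"],
            d90_um=spec["d90_um"],
        )
        cond = DissolutionCondition(medium=spec["medium"], volume_ml=volume_ml)
        z = truth.z_for(spec["granulation"], spec["medium"])
        prof = simulate_dissolution(
            drug, form, cond, z=z, times_min=np.asarray(spec["times_min"])
        )
        pct = prof.pct_dissolved.copy()
        if noise_sd > 0:
            pct = np.clip(pct + rng.normal(0.0, noise_sd, pct.shape), 0.0, 105.0)
        for t, p in zip(prof.times_min, pct):
            rows.append(
                {
                    "profile_id": f"profile_{i:02d}",
                    "time_min": t,
                    "pct_dissolved": p,
                    "dose_mg": spec["dose_mg"],
                    "granulation": spec["granulation"],
                    "medium": spec["medium"],
                    "d90_um": spec["d90_um"],
                    "volume_mL": volume_ml,
                }
            )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def gen_pk_dataset(
    params: DispositionParams,
    dose_mg: float,
    times_h: np.ndarray,
    noise_model: str = "proportional",
    noise_scale: float = 0.05,
    n_subjects: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a (mean) IV concentration-time dataset with noise.

    ``noise_scale`` is the per-subject SD (ng/mL for 'additive', fractional
    for 'proportional'); mean profiles over ``n_subjects`` scale the SD by
    1/sqrt(n).  Concentrations are floored at zero.
    """
    if noise_model not in ("additive", "proportional"):
        raise ValueError(f"unknown noise_model {noise_model!r}")
    if noise_scale < 0 or n_subjects < 1:
        raise ValueError("noise_scale must be >= 0 and n_subjects >= 1")
    times_h = np.asarray(times_h, dtype=float)
    clean = simulate_iv(params, dose_mg, times_h).conc_ng_ml
    rng = np.random.default_rng(seed)
    scale = noise_scale / np.sqrt(n_subjects)
    if noise_model == "additive":
        noisy = clean + rng.normal(0.0, scale, clean.shape)
    else:
        noisy = clean * (1.0 + rng.normal(0.0, scale, clean.shape))
    return pd.DataFrame({"time_h": times_h, "conc_ng_mL": np.maximum(noisy, 0.0)})


# ---------------------------------------------------------------------------
# fixtures

FIXTURES = {
    "table1_disposition": "table1_disposition.csv",
    "table2_solution_pk": "table2_solution_pk.csv",
    "table3_tablet_pk": "table3_tablet_pk.csv",
    "table4_be_study": "table4_be_study.csv",
    "table5_ratios": "table5_ratios.csv",
}


def _data_root():
    return resources.files("pbbm") / "data"


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged summary-table fixture, verifying its sha256 checksum."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    root = _data_root()
    manifest = json.loads((root / "manifest.json").read_text())
    fname = FIXTURES[name]
    raw = (root / fname).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = manifest[fname]["sha256"]
    if digest != expected:
        raise RuntimeError(f"fixture {fname} checksum mismatch: {digest} != {expected}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), comment="#")
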