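"""Synthetic cohorts realising the causal chain under study.

The generator draws three groups (healthy controls, individuals with
psychosis, first-degree relatives) whose BMI distributions match the source
cohort's demographics (means 25.5 / 31.4 / 29.1 kg/m^2, SDs 5.5 / 7.4 /
6.6), links BMI monotonically to scalp thickness, and maps each subject's
scalp-to-cortex thickness to ROI field strength either by a full per-subject
FEM solve or by a monotone surrogate calibrated from FEM runs across a
scalp-thickness ladder.  With the default effect parameters the generated
data reproduce, in expectation, the qualitative pattern the analysis is
built to detect: psychosis BMI > control, psychosis scalp thickness >
control, psychosis ROI field < control.  Setting the BMI-to-thickness slope
to zero yields the mediation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import truncnorm

from .fem import ROISpec, roi_mean_magnitude, scale_to_current, solve_potential
from .phantom import (
    DLPFC_DIRECTIONS,
    STANDARD_MONTAGES,
    BmiThicknessLink,
    LayerSpec,
    attach_electrodes,
    build_layered_sphere,
    scalp_thickness_from_bmi,
)

GROUPS = ("control", "psychosis", "relative")
MONTAGE_KEYS = ("fp1fp2", "f3fp2")
HEMISPHERES = ("left", "right")

FIELD_COLUMNS = [f"efield_{m}_{h}" for m in MONTAGE_KEYS for h in HEMISPHERES]
THICKNESS_COLUMNS = ["scalp_mm", "skull_mm", "csf_mm", "cortex_mm", "scalp_to_cortex_mm"]


class ParameterError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GroupParams:
    """Marginal covariate distributions for one group."""

    bmi_mean: float
    bmi_sd: float
    age_mean: float
    age_sd: float
    male_fraction: float

    def __post_init__(self):
        if self.bmi_sd <= 0 or self.age_sd <= 0:
            raise ParameterError("SDs must be positive")
        if not 0 <= self.male_fraction <= 1:
            raise ParameterError("male fraction must be in [0, 1]")


@dataclass(frozen=True)
class CohortParams:
    """Full generative configuration; defaults are the study conditions."""

    groups: dict = None
    thickness_link: BmiThicknessLink = BmiThicknessLink(noise_sd_mm=0.5)
    # group-independent anatomy (only scalp tracks BMI by default, matching
    # the finding that only scalp and the aggregate differed robustly)
    skull_mean: float = 6.0
    skull_sd: float = 0.6
    csf_mean: float = 2.0
    csf_sd: float = 0.3
    cortex_mean: float = 3.0
    cortex_sd: float = 0.3
    field_noise_log_sd: float = 0.15   # multiplicative log-normal field noise
    medication_link: bool = False      # draw psychosis BMI from med/no-med mixture
    medication_fraction: float = 0.67
    bmi_mean_medicated: float = 31.6
    bmi_sd_medicated: float = 6.3
    bmi_mean_unmedicated: float = 28.0
    bmi_sd_unmedicated: float = 7.0
    bmi_bounds: tuple = (14.0, 60.0)
    age_bounds: tuple = (18.0, 90.0)

    def __post_init__(self):
        groups = {
            "control": GroupParams(25.5, 5.5, 38.2, 13.1, 0.48),
            "psychosis": GroupParams(31.4, 7.4, 38.8, 12.3, 0.566),
            "relative": GroupParams(29.1, 6.6, 44.6, 13.8, 0.315),
        }
        if self.groups:
            groups.update(self.groups)
        object.__setattr__(self, "groups", groups)
        for name in ("skull_sd", "csf_sd", "cortex_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.field_noise_log_sd < 0:
            raise ParameterError("field noise SD must be non-negative")

    def null(self) -> "CohortParams":
        """All groups share the control distribution and the BMI->thickness
        slope is zero: no group effect anywhere downstream."""
        ctrl = self.groups["control"]
        return replace(
            self,
            groups={g: ctrl for g in GROUPS},
            thickness_link=replace(self.thickness_link, slope_mm_per_bmi=0.0),
            medication_link=False,
        )


def _trunc_normal(rng, mean, sd, bounds, size):
    """Truncated-normal draws whose *truncated* mean equals `mean`.

    Truncation biases the mean of a clipped N(mean, sd); the location is
    shifted (solved by bisection) so the generated sample targets the stated
    group mean exactly."""
    from scipy.optimize import brentq

    def tmean(loc):
        a, b = (bounds[0] - loc) / sd, (bounds[1] - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    try:
        loc = brentq(tmean, mean - 3 * sd, mean + 3 * sd, xtol=1e-10)
    except ValueError:
        loc = mean
    lo, hi = (bounds[0] - loc) / sd, (bounds[1] - loc) / sd
    return truncnorm.rvs(lo, hi, loc=loc, scale=sd, size=size, random_state=rng)


def simulate_cohort(
    n_control: int,
    n_psychosis: int,
    n_relative: int,
    params: CohortParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw covariates (group, age, sex, BMI, medication flag) per subject.

    Reproducible: the same sizes, parameters and seed give the identical
    table.  Medication applies to the psychosis group only; when
    ``params.medication_link`` is set, psychosis BMI is drawn from the
    medicated/unmedicated mixture instead of the group marginal.
    """
    params = params or CohortParams()
    if min(n_control, n_psychosis, n_relative) < 0:
        raise ParameterError("group sizes must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    sizes = {"control": n_control, "psychosis": n_psychosis, "relative": n_relative}
    sid = 0
    for group in GROUPS:
        n = sizes[group]
        if n == 0:
            continue
        gp = params.groups[group]
        age = _trunc_normal(rng, gp.age_mean, gp.age_sd, params.age_bounds, n)
        male = rng.random(n) < gp.male_fraction
        medicated = np.zeros(n, dtype=bool)
        if group == "psychosis":
            medicated = rng.random(n) < params.medication_fraction
        if group == "psychosis" and params.medication_link:
            bmi = np.where(
                medicated,
                _trunc_normal(rng, params.bmi_mean_medicated,
                              params.bmi_sd_medicated, params.bmi_bounds, n),
                _trunc_normal(rng, params.bmi_mean_unmedicated,
                              params.bmi_sd_unmedicated, params.bmi_bounds, n),
            )
        else:
            bmi = _trunc_normal(rng, gp.bmi_mean, gp.bmi_sd, params.bmi_bounds, n)
        for i in range(n):
            rows.append(
                dict(
                    subject_id=f"S{sid:04d}",
                    group=group,
                    age=float(age[i]),
                    sex="male" if male[i] else "female",
                    bmi=float(bmi[i]),
                    medicated=bool(medicated[i]),
                )
            )
            sid += 1
    table = pd.DataFrame(rows)
    table.attrs["seed"] = int(seed)
    table.attrs["sizes"] = sizes
    return table


# -- thickness -> field surrogate ----------------------------------------


@dataclass
class FieldSurrogate:
    """Monotone map from scalp-to-cortex thickness (mm) to ROI |E| (V/m),
    one curve per montage x hemisphere, calibrated from FEM ladder runs.

    A shape-preserving (PCHIP) interpolant through the calibration points
    keeps the FEM's monotone attenuation without asserting a parametric law;
    outside the calibrated range the end slopes continue linearly.
    """

    thickness_grid: np.ndarray                 # scalp_to_cortex values, mm
    roi_means: dict                            # (montage, hemi) -> (k,) V/m
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.thickness_grid) < 5:
            raise CalibrationError("surrogate needs at least 5 calibration points")
        self._interp = {
            key: PchipInterpolator(self.thickness_grid, vals, extrapolate=False)
            for key, vals in self.roi_means.items()
        }

    def __call__(self, montage: str, hemisphere: str, scalp_to_cortex_mm):
        f = self._interp[(montage, hemisphere)]
        x = np.asarray(scalp_to_cortex_mm, dtype=float)
        lo, hi = self.thickness_grid[0], self.thickness_grid[-1]
        xc = np.clip(x, lo, hi)
        y = f(xc)
        dlo, dhi = f(lo, 1), f(hi, 1)
        y = np.where(x < lo, f(lo) + (x - lo) * dlo, y)
        y = np.where(x > hi, f(hi) + (x - hi) * dhi, y)
        return np.maximum(y, 1e-6)

    def to_dict(self) -> dict:
        return {
            "thickness_grid": self.thickness_grid.tolist(),
            "roi_means": {f"{m}:{h}": v.tolist() for (m, h), v in self.roi_means.items()},
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FieldSurrogate":
        roi = {
            tuple(k.split(":")): np.asarray(v, dtype=float)
            for k, v in d["roi_means"].items()
        }
        return cls(np.asarray(d["thickness_grid"], dtype=float), roi, d.get("meta", {}))


def _subject_rois(layers: LayerSpec):
    gm_mid = 0.5 * (layers.radii[3] + layers.radii[4])
    return {
        h: ROISpec(tuple(np.asarray(DLPFC_DIRECTIONS[h]) * gm_mid))
        for h in HEMISPHERES
    }


def _fem_roi_means(layers: LayerSpec, seed: int, current_ma: float = 2.0) -> dict:
    """One phantom build + solve per montage; ROI |E| per hemisphere."""
    mesh = build_layered_sphere(layers, seed=seed)
    rois = _subject_rois(layers)
    out = {}
    for mkey in MONTAGE_KEYS:
        wired = attach_electrodes(mesh, STANDARD_MONTAGES[mkey])
        sol = scale_to_current(solve_potential(wired, montage=mkey), current_ma)
        for h in HEMISPHERES:
            out[(mkey, h)] = roi_mean_magnitude(wired, sol, rois[h])
    return out


def calibrate_surrogate(
    scalp_thicknesses=(3.0, 5.0, 7.0, 9.0, 11.0, 13.0),
    base_layers: LayerSpec | None = None,
    seed: int = 0,
) -> FieldSurrogate:
    """Run the FEM across a scalp-thickness ladder and tabulate ROI |E|.

    The phantom's other layers stay at their defaults, so the ladder maps
    scalp-to-cortex thickness (scalp + fixed skull + fixed CSF) to field.
    """
    base = base_layers or LayerSpec(interior_coarsen_below=55.0)
    if len(scalp_thicknesses) < 5:
        raise CalibrationError("ladder needs at least 5 thickness points")
    inner = base.radii[1] - base.radii[3]  # skull + CSF
    grid, per_key = [], {}
    for t in sorted(scalp_thicknesses):
        layers = base.with_scalp_thickness(t)
        means = _fem_roi_means(layers, seed=seed)
        grid.append(t + inner)
        for key, val in means.items():
            per_key.setdefault(key, []).append(val)
    return FieldSurrogate(
        np.asarray(grid),
        {k: np.asarray(v) for k, v in per_key.items()},
        meta={
            "scalp_thicknesses_mm": list(scalp_thicknesses),
            "base_radii_mm": list(base.radii),
            "edge_length_mm": base.edge_length,
            "seed": int(seed),
        },
    )


def cohort_to_outcomes(
    table: pd.DataFrame,
    mode: str = "surrogate",
    surrogate: FieldSurrogate | None = None,
    params: CohortParams | None = None,
    base_layers: LayerSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach per-subject tissue thicknesses and ROI field strengths.

    mode="surrogate" (default) evaluates the calibrated monotone surrogate
    g(scalp_to_cortex) with multiplicative log-normal noise; mode="fem"
    builds and solves a per-subject phantom (practical for small cohorts
    only) and applies the same noise model.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    out = table.copy()
    n = len(out)
    link = params.thickness_link
    out["scalp_mm"] = scalp_thickness_from_bmi(out["bmi"].to_numpy(), link, rng)
    out["skull_mm"] = np.maximum(rng.normal(params.skull_mean, params.skull_sd, n), 1.0)
    out["csf_mm"] = np.maximum(rng.normal(params.csf_mean, params.csf_sd, n), 0.5)
    out["cortex_mm"] = np.maximum(rng.normal(params.cortex_mean, params.cortex_sd, n), 0.5)
    out["scalp_to_cortex_mm"] = out["scalp_mm"] + out["skull_mm"] + out["csf_mm"]

    noise = {
        col: np.exp(rng.normal(0.0, params.field_noise_log_sd, n))
        if params.field_noise_log_sd > 0
        else np.ones(n)
        for col in FIELD_COLUMNS
    }
    if mode == "surrogate":
        if surrogate is None:
            raise CalibrationError(
                "surrogate mode requires a calibrated FieldSurrogate "
                "(see calibrate_surrogate)"
            )
        s2c = out["scalp_to_cortex_mm"].to_numpy()
        for mkey in MONTAGE_KEYS:
            for h in HEMISPHERES:
                col = f"efield_{mkey}_{h}"
                out[col] = surrogate(mkey, h, s2c) * noise[col]
    elif mode == "fem":
        base = base_layers or LayerSpec(interior_coarsen_below=55.0)
        for col in FIELD_COLUMNS:
            out[col] = np.nan
        for i in range(n):
            layers = base.with_scalp_thickness(float(out["scalp_mm"].iloc[i]))
            means = _fem_roi_means(layers, seed=int(table.attrs.get("seed", 0)))
            for (mkey, h), val in means.items():
                col = f"efield_{mkey}_{h}"
                out.loc[out.index[i], col] = val * noise[col][i]
    else:
        raise ParameterError(f"unknown outcome mode {mode!r}")
    out.attrs.update(table.attrs)
    out.attrs["outcome_mode"] = mode
    out.attrs["outcome_seed"] = int(seed)
    return out
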