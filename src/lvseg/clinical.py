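"""Clinical indices and auto-vs-manual agreement statistics.

Volumes come from slab summation over the mask stack (slice area x
slice thickness, no inter-slice gap by default).  Left-ventricular mass
is LVM = (V_epi^ED - V_end^ED) * 1.05 g/ml; ejection fraction is
EF = 100 * (V_end^ED - V_end^ES) / V_end^ED.  Agreement between
automatic and manual values is summarized by Bland–Altman bias and
±1.96 SD limits, a one-sample t-test of the bias, and ordinary
least-squares regression with R².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class ClinicalIndices:
    v_epi_ed_ml: float
    v_end_ed_ml: float
    v_end_es_ml: float
    lvm_g: float
    ef_percent: float


@dataclass
class AgreementStats:
    n: int
    bias: float
    sd_diff: float
    loa_lower: float  # bias - 1.96 SD
    loa_upper: float  # bias + 1.96 SD
    ci_lower: float   # 95% CI of the mean difference
    ci_upper: float
    p_value: float    # one-sample t-test of mean difference vs 0
    slope: float
    intercept: float
    r_squared: float
    n_outside_limits: int


def volume_ml(mask_stack, pixel_spacing_mm, slice_thickness_mm: float,
              gap_mm: float = 0.0) -> float:
    """Slab-summation volume of a stack of binary masks, in ml.

    ``pixel_spacing_mm`` may be a scalar or (row, col) pair.  Each slice
    contributes area * (thickness + gap); 1 ml = 1000 mm^3.
    """
    if np.isscalar(pixel_spacing_mm):
        sr = sc = float(pixel_spacing_mm)
    else:
        sr, sc = (float(v) for v in pixel_spacing_mm)
    if sr <= 0 or sc <= 0 or slice_thickness_mm <= 0:
        raise ValueError("pixel spacing and slice thickness must be positive")
    if gap_mm < 0:
        raise ValueError("inter-slice gap cannot be negative")
    total_px = sum(int(np.asarray(m).astype(bool).sum()) for m in mask_stack)
    return total_px * sr * sc * (slice_thickness_mm + gap_mm) / 1000.0


def lvm_g(v_epi_ed_ml: float, v_end_ed_ml: float) -> float:
    """Left-ventricular mass in grams: (V_epi^ED - V_end^ED) * 1.05."""
    if v_epi_ed_ml < v_end_ed_ml:
        raise ValueError(
            f"epicardial volume ({v_epi_ed_ml} ml) must enclose endocardial "
            f"volume ({v_end_ed_ml} ml)"
        )
    return (v_epi_ed_ml - v_end_ed_ml) * MYOCARDIAL_DENSITY_G_PER_ML


def ef_percent(v_end_ed_ml: float, v_end_es_ml: float) -> float:
    """Ejection fraction in percent: 100 * (V_end^ED - V_end^ES) / V_end^ED."""
    if v_end_ed_ml <= 0:
        raise ValueError("end-diastolic volume must be positive")
    return 100.0 * (v_end_ed_ml - v_end_es_ml) / v_end_ed_ml


def clinical_indices(endo_ed_masks, endo_es_masks, epi_ed_masks,
                     pixel_spacing_mm, slice_thickness_mm: float,
                     gap_mm: float = 0.0) -> ClinicalIndices:
    """All indices of one case from its ED/ES mask stacks."""
    v_epi_ed = volume_ml(epi_ed_masks, pixel_spacing_mm, slice_thickness_mm, gap_mm)
    v_end_ed = volume_ml(endo_ed_masks, pixel_spacing_mm, slice_thickness_mm, gap_mm)
    v_end_es = volume_ml(endo_es_masks, pixel_spacing_mm, slice_thickness_mm, gap_mm)
    return ClinicalIndices(
        v_epi_ed_ml=v_epi_ed,
        v_end_ed_ml=v_end_ed,
        v_end_es_ml=v_end_es,
        lvm_g=lvm_g(v_epi_ed, v_end_ed),
        ef_percent=ef_percent(v_end_ed, v_end_es),
    )


def agreement(auto_values, manual_values) -> AgreementStats:
    """Bland–Altman + regression agreement between paired measurements."""
    auto = np.asarray(auto_values, dtype=float)
    manual = np.asarray(manual_values, dtype=float)
    if auto.shape != manual.shape or auto.ndim != 1:
        raise ValueError("auto and manual must be equal-length 1-D sequences")
    n = auto.size
    if n < 3:
        raise ValueError(f"agreement needs at least 3 pairs, got {n}")
    d = auto - manual
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    if sd == 0.0:
        p = 1.0 if bias == 0.0 else 0.0
        ci = (bias, bias)
    else:
        t_crit = stats.t.ppf(0.975, n - 1)
        half = t_crit * sd / np.sqrt(n)
        ci = (bias - half, bias + half)
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    if np.allclose(manual, manual[0]):
        slope, intercept, r2 = float("nan"), float("nan"), float("nan")
    else:
        res = stats.linregress(manual, auto)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    outside = int(np.sum((d < loa[0]) | (d > loa[1])))
    return AgreementStats(
        n=n, bias=bias, sd_diff=sd,
        loa_lower=float(loa[0]), loa_upper=float(loa[1]),
        ci_lower=float(ci[0]), ci_upper=float(ci[1]),
        p_value=p, slope=slope, intercept=intercept, r_squared=r2,
        n_outside_limits=outside,
    )
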