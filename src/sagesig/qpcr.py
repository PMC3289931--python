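"""Standard-curve efficiency estimation and efficiency-corrected
relative quantification (Pfaffl method).

Sign convention, fixed throughout: delta-Ct = Ct(calibrator) - Ct(sample).
A positive delta-Ct for the target therefore means the sample expresses
more target than the calibrator, and the ratio

    ratio = E_target**dCt_target / E_ref**dCt_ref

is > 1 for genes upregulated in the sample. With both efficiencies equal
to 2 this reduces to the classic 2**(-ddCt) method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class StandardCurve:
    """OLS fit of Ct against log10(dilution) for one gene."""

    gene_id: str
    points: list[tuple[float, float]]  # (log10_dilution, Ct)
    slope: float
    intercept: float
    r_squared: float
    efficiency: float  # fold amplification per cycle


@dataclass
class PfafflResult:
    gene_id: str
    sample_id: str
    calibrator_id: str
    delta_ct_target: float
    delta_ct_ref: float
    ratio: float


@dataclass
class ReplicateSummary:
    mean_ct: float
    sd_ct: float
    n: int
    outliers: list[int]
    warning: str | None = None


def fit_standard_curve(
    points: Sequence[tuple[float, float]], gene_id: str = ""
) -> StandardCurve:
    """Fit Ct = intercept + slope * log10(dilution); E = 10**(-1/slope).

    Requires >= 3 points at >= 3 distinct dilutions and a negative slope
    (Ct rises as template is diluted).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 dilution points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct dilutions")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"non-negative slope {fit.slope:.4g}: Ct must increase with dilution"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope)
    return StandardCurve(
        gene_id=gene_id,
        points=[(float(a), float(b)) for a, b in points],
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=float(efficiency),
    )


def pfaffl_ratio(
    e_target: float,
    ct_target_cal: float,
    ct_target_sample: float,
    e_ref: float,
    ct_ref_cal: float,
    ct_ref_sample: float,
    gene_id: str = "",
    sample_id: str = "",
    calibrator_id: str = "calibrator",
) -> PfafflResult:
    """Efficiency-corrected expression ratio of sample vs calibrator."""
    for e in (e_target, e_ref):
        if not 1.0 < e <= 2.2:
            raise ValueError(f"efficiency {e} outside (1, 2.2]")
    cts = (ct_target_cal, ct_target_sample, ct_ref_cal, ct_ref_sample)
    if not all(math.isfinite(ct) and ct > 0 for ct in cts):
        raise ValueError("Ct values must be finite and positive")
    d_target = ct_target_cal - ct_target_sample
    d_ref = ct_ref_cal - ct_ref_sample
    ratio = e_target ** d_target / e_ref ** d_ref
    return PfafflResult(
        gene_id=gene_id,
        sample_id=sample_id,
        calibrator_id=calibrator_id,
        delta_ct_target=d_target,
        delta_ct_ref=d_ref,
        ratio=ratio,
    )


def summarize_replicates(
    cts: Sequence[float], outlier_threshold: float = 0.5
) -> ReplicateSummary:
    """Mean and SD of replicate Ct values; replicates deviating from the
    mean by more than ``outlier_threshold`` cycles are flagged."""
    cts = [float(c) for c in cts]
    if not cts:
        raise ValueError("no replicates")
    if len(cts) == 1:
        return ReplicateSummary(
            mean_ct=cts[0], sd_ct=0.0, n=1, outliers=[],
            warning="single replicate",
        )
    mean = float(np.mean(cts))
    sd = float(np.std(cts, ddof=1))
    outliers = [i for i, c in enumerate(cts) if abs(c - mean) > outlier_threshold]
    return ReplicateSummary(mean_ct=mean, sd_ct=sd, n=len(cts), outliers=outliers)
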