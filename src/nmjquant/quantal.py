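"""Quantal-analysis estimators.

Four complementary procedures estimate how many vesicles a stimulus
releases and how many are release-ready:

* **Direct quantal content** — QC = mean EJC / mean mEJC.
* **Failure analysis** — under Poisson release at low calcium,
  QC = ln(m_total / n_fail), where n_fail counts stimuli whose response is
  indistinguishable from baseline noise and distinct from the mini
  amplitude distribution.
* **Variance-mean (multiple-probability fluctuation) analysis** — across
  calcium concentrations the EJC variance is a downward parabola in the
  mean, Var(I) = A*I - B*I^2, with N = 1/B release-ready vesicles,
  quantal size q = A/(1+CV^2) and release probability
  Pvr = I*(B/A)*(1+CV^2).
* **Cumulative-train RRP** — a 60 Hz train depletes the pool; a line fit
  to the last ten cumulative EJC amplitudes, back-extrapolated to time
  zero and divided by the mean mini amplitude, counts the pool.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .detect import NoiseModel
from .errors import (
    InsufficientDataError,
    UndefinedEstimateError,
    ValidationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "NMJSummary",
    "FailureClassification",
    "FailureResult",
    "VarianceMeanSeries",
    "VMFit",
    "TrainResult",
    "qc_ratio",
    "classify_failures",
    "failure_qc",
    "vm_points",
    "fit_parabola",
    "vm_params",
    "cumulative_rrp",
]


@dataclass(frozen=True)
class NMJSummary:
    """Per-NMJ quantal-content summary: QC = mean EJC / mean mEJC."""

    nmj_id: str
    genotype: str
    ca_mm: float
    mean_mejc_na: float
    mean_ejc_na: float
    qc: float
    n_ejc: int
    n_mejc: int


def qc_ratio(
    ejc_amplitudes,
    mejc_amplitudes,
    nmj_id: str = "",
    genotype: str = "",
    ca_mm: float = float("nan"),
) -> NMJSummary:
    """Direct quantal content: arithmetic mean EJC over arithmetic mean mEJC."""
    ejc = np.asarray(ejc_amplitudes, dtype=float)
    mejc = np.asarray(mejc_amplitudes, dtype=float)
    if ejc.size == 0 or mejc.size == 0:
        raise InsufficientDataError("qc_ratio needs at least one EJC and one mEJC amplitude")
    mean_mejc = float(mejc.mean())
    if mean_mejc <= 0:
        raise ValidationError("mean mEJC amplitude must be positive")
    mean_ejc = float(ejc.mean())
    return NMJSummary(
        nmj_id=nmj_id,
        genotype=genotype,
        ca_mm=ca_mm,
        mean_mejc_na=mean_mejc,
        mean_ejc_na=mean_ejc,
        qc=mean_ejc / mean_mejc,
        n_ejc=int(ejc.size),
        n_mejc=int(mejc.size),
    )


@dataclass(frozen=True)
class FailureClassification:
    """Per-stimulus failure flags plus the criteria that produced them.

    A stimulus is a failure iff its amplitude lies within the baseline-noise
    distribution (<= noise mean + k_noise * noise s.d.) AND below the
    ``mini_pct`` percentile of the mEJC amplitude distribution (distinct
    from minis).
    """

    is_failure: np.ndarray
    m_total: int
    n_fail: int
    noise_ceiling_na: float
    mini_floor_na: float
    k_noise: float
    mini_pct: float
    n_above_noise: int
    n_mini_like: int


def classify_failures(
    evoked_amplitudes,
    noise: NoiseModel,
    mejc_amplitudes,
    k_noise: float = 2.0,
    mini_pct: float = 5.0,
) -> FailureClassification:
    """Classify each evoked response as failure or release."""
    if not isinstance(noise, NoiseModel):
        raise ValidationError("classify_failures requires a NoiseModel")
    amps = np.asarray(evoked_amplitudes, dtype=float)
    mejc = np.asarray(mejc_amplitudes, dtype=float)
    if mejc.size < 20:
        raise InsufficientDataError(
            f"need >= 20 mEJC amplitudes for the mini-distribution reference, got {mejc.size}"
        )
    noise_ceiling = noise.mean_na + k_noise * noise.sd_na
    mini_floor = float(np.percentile(mejc, mini_pct))
    within_noise = amps <= noise_ceiling
    below_minis = amps < mini_floor
    is_failure = within_noise & below_minis
    result = FailureClassification(
        is_failure=is_failure,
        m_total=int(amps.size),
        n_fail=int(is_failure.sum()),
        noise_ceiling_na=noise_ceiling,
        mini_floor_na=mini_floor,
        k_noise=k_noise,
        mini_pct=mini_pct,
        n_above_noise=int((~within_noise).sum()),
        n_mini_like=int((within_noise & ~below_minis).sum()),
    )
    log.info(
        "failure classification: %d/%d failures (noise ceiling %.3g nA, mini floor %.3g nA; "
        "%d above noise, %d noise-level but mini-like)",
        result.n_fail,
        result.m_total,
        noise_ceiling,
        mini_floor,
        result.n_above_noise,
        result.n_mini_like,
    )
    return result


@dataclass(frozen=True)
class FailureResult:
    """Failure-analysis quantal content QC = ln(m_total / n_fail)."""

    m_total: int
    n_fail: int
    qc_fail: float


def failure_qc(m_total: int, n_fail: int) -> FailureResult:
    """Poisson estimate of quantal content from the failure count.

    With Poisson release the probability of a failure is exp(-QC), so
    QC = ln(m_total / n_fail); it decreases monotonically as failures
    become more common. Undefined with zero failures (raise advising lower
    calcium).
    """
    m_total = int(m_total)
    n_fail = int(n_fail)
    if m_total < 1 or n_fail < 0:
        raise ValidationError("m_total must be >= 1 and n_fail >= 0")
    if n_fail > m_total:
        raise ValidationError("n_fail cannot exceed m_total")
    if n_fail == 0:
        raise UndefinedEstimateError(
            "no failures observed: ln(m/n0) is undefined; lower external calcium "
            "so the Poisson failure estimator applies"
        )
    if m_total < 300:
        warnings.warn(
            f"failure protocol used {m_total} stimuli; the standard protocol uses >= 300",
            stacklevel=2,
        )
    return FailureResult(m_total=m_total, n_fail=n_fail, qc_fail=float(np.log(m_total / n_fail)))


@dataclass(frozen=True)
class VarianceMeanSeries:
    """Per-calcium (mean, variance) points for fluctuation analysis."""

    ca_mm: np.ndarray
    mean_I_na: np.ndarray
    var_I_na2: np.ndarray
    n_events: np.ndarray
    cv2: np.ndarray

    def __len__(self) -> int:
        return self.ca_mm.size


def vm_points(amplitudes_by_ca: dict) -> VarianceMeanSeries:
    """Per-calcium mean, unbiased (n-1) variance and CV^2 of EJC amplitudes.

    Levels are returned ordered by calcium. Fewer than 2 amplitudes at any
    level is an error; fewer than 20 triggers a protocol warning.
    """
    if len(amplitudes_by_ca) < 2:
        raise InsufficientDataError("variance-mean analysis needs >= 2 calcium levels")
    cas = sorted(amplitudes_by_ca)
    means, variances, counts, cv2s = [], [], [], []
    for ca in cas:
        amps = np.asarray(amplitudes_by_ca[ca], dtype=float)
        if amps.size < 2:
            raise InsufficientDataError(
                f"calcium level {ca} mM has {amps.size} amplitudes; need >= 2"
            )
        if amps.size < 20:
            warnings.warn(
                f"calcium level {ca} mM has only {amps.size} EJCs (< 20)", stacklevel=2
            )
        m = float(amps.mean())
        v = float(amps.var(ddof=1))
        means.append(m)
        variances.append(v)
        counts.append(int(amps.size))
        cv2s.append(v / (m * m) if m != 0 else float("nan"))
    return VarianceMeanSeries(
        ca_mm=np.array(cas, dtype=float),
        mean_I_na=np.array(means),
        var_I_na2=np.array(variances),
        n_events=np.array(counts),
        cv2=np.array(cv2s),
    )


@dataclass(frozen=True)
class VMFit:
    """Parabolic variance-mean fit Var(I) = A*I - B*I^2 for one NMJ.

    ``A`` is the initial slope (quantal-size scale, nA), ``B`` the curvature
    whose reciprocal is the RRP size estimate ``n_vm``. When the fit finds
    no curvature at all (B at the non-negativity boundary) ``n_vm`` is not
    reported; when B is positive but its 95% CI includes zero the estimate
    is reported with ``n_constrained=False`` as an imprecision flag.
    """

    A: float
    B: float
    n_vm: float
    rss: float
    se_A: float
    se_B: float
    n_constrained: bool
    note: str = ""


def fit_parabola(series: VarianceMeanSeries, weights: str = "invvar") -> VMFit:
    """Least-squares fit of the downward variance-mean parabola through the
    origin, constrained to A > 0, B >= 0.

    The default ``weights='invvar'`` weights each calcium level by the
    reciprocal of its squared variance: the sampling variance of a sample
    variance scales with its square, so this is the generalized
    least-squares choice and greatly stabilizes the curvature (hence the
    RRP estimate 1/B). ``'none'`` is the plain unweighted fit;
    ``'n_events'`` weights by event count.
    """
    if len(series) < 3:
        raise InsufficientDataError("parabola fit needs >= 3 calcium levels")
    I = series.mean_I_na
    V = series.var_I_na2
    if np.allclose(I, I[0]):
        raise ValidationError("degenerate design: all mean amplitudes equal")
    if weights == "n_events":
        w = np.sqrt(series.n_events.astype(float))
    elif weights == "invvar":
        w = 1.0 / np.maximum(V, 1e-12)
    elif weights == "none":
        w = np.ones_like(I)
    else:
        raise ValidationError(f"unknown weighting scheme {weights!r}")
    X = np.column_stack([I, -(I**2)])
    coef, _ = optimize.nnls(X * w[:, None], V * w)
    A, B = float(coef[0]), float(coef[1])
    resid = V - X @ coef
    rss = float(np.sum((w * resid) ** 2))

    # standard errors from the unconstrained weighted LS problem
    dof = len(series) - 2
    se_A = se_B = float("nan")
    b_ci_excludes_zero = False
    if dof > 0:
        Xw = X * w[:, None]
        xtx_inv = np.linalg.inv(Xw.T @ Xw)
        s2 = rss / dof
        se_A = float(np.sqrt(s2 * xtx_inv[0, 0]))
        se_B = float(np.sqrt(s2 * xtx_inv[1, 1]))
        tcrit = stats.t.ppf(0.975, dof)
        b_ci_excludes_zero = B - tcrit * se_B > 0
    # curvature numerically indistinguishable from zero: compare the
    # quadratic term's relative contribution at the largest mean amplitude
    if A > 0 and B * I.max() / A <= 1e-9:
        B = 0.0
    note = ""
    constrained = B > 0 and (dof <= 0 or b_ci_excludes_zero)
    if B <= 0:
        # at the non-negativity boundary: the data show no curvature at all
        note = "release probability too low to constrain N (no resolvable curvature)"
        n_vm = float("nan")
    else:
        n_vm = 1.0 / B
        if not constrained:
            note = "curvature not resolved at 95% confidence; n_vm imprecise"
    if A <= 0:
        raise ValidationError("variance-mean fit produced non-positive initial slope A")
    return VMFit(A=A, B=B, n_vm=n_vm, rss=rss, se_A=se_A, se_B=se_B, n_constrained=constrained, note=note)


def vm_params(fit: VMFit, series: VarianceMeanSeries) -> pd.DataFrame:
    """Per-calcium release probability and quantal size from the fit:
    Pvr = I*(B/A)*(1+CV^2) and q = A/(1+CV^2), each level using its own
    amplitude CV^2. The internal consistency check N*Pvr*q is reported
    alongside the observed mean amplitude.
    """
    if fit.A <= 0:
        raise ValidationError("vm_params requires a fit with A > 0")
    one_plus_cv2 = 1.0 + series.cv2
    p_vr = series.mean_I_na * (fit.B / fit.A) * one_plus_cv2
    q = fit.A / one_plus_cv2
    predicted = fit.n_vm * p_vr * q if np.isfinite(fit.n_vm) else np.full_like(p_vr, np.nan)
    return pd.DataFrame(
        {
            "ca_mm": series.ca_mm,
            "mean_I_na": series.mean_I_na,
            "cv2": series.cv2,
            "p_vr": p_vr,
            "q_na": q,
            "predicted_I_na": predicted,
        }
    )


@dataclass(frozen=True)
class TrainResult:
    """Cumulative-train RRP estimate for one NMJ."""

    cumulative_na: np.ndarray
    slope_na_per_stim: float
    intercept_na: float
    n_rrp_train: float
    floored: bool


def cumulative_rrp(train_amplitudes, mean_mejc_na: float, tail: int = 10) -> TrainResult:
    """RRP size from the cumulative EJC amplitude of a 60 Hz train.

    The running sum of the train's EJC amplitudes approaches a line whose
    slope reflects steady-state replenishment; back-extrapolating an OLS
    line through the last ``tail`` cumulative points to time zero (stimulus
    index 0) yields the cumulative amplitude contributed by the initial
    pool, which divided by the mean mini amplitude counts the release-ready
    vesicles. A negative intercept is floored at zero and flagged.
    """
    amps = np.asarray(train_amplitudes, dtype=float)
    if mean_mejc_na <= 0:
        raise ValidationError("mean_mejc_na must be positive")
    if amps.size < tail:
        raise InsufficientDataError(
            f"train has {amps.size} stimuli; need >= {tail} for the tail fit"
        )
    if amps.size != 30:
        warnings.warn(
            f"train has {amps.size} stimuli (standard protocol: 30); last-{tail} rule kept",
            stacklevel=2,
        )
    cumulative = np.cumsum(amps)
    idx = np.arange(1, amps.size + 1, dtype=float)
    slope, intercept = np.polyfit(idx[-tail:], cumulative[-tail:], 1)
    floored = intercept < 0
    eff_intercept = max(0.0, float(intercept))
    if floored:
        log.info("negative back-extrapolated intercept %.3g nA floored at 0", intercept)
    return TrainResult(
        cumulative_na=cumulative,
        slope_na_per_stim=float(slope),
        intercept_na=float(intercept),
        n_rrp_train=eff_intercept / mean_mejc_na,
        floored=floored,
    )
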