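"""Agreement between the two EELV methods.

Four related quantities are produced from a :class:`~eelvkit.study_data.PairedSeries`:

* **calibration regression** — ordinary least squares of the test method
  (washin-washout) on the reference (CT), the line a clinician would use
  to convert a bedside reading into a CT-equivalent volume;
* **Bland-Altman** — mean bias and constant 95% limits of agreement
  (mean +/- 1.96 SD of the differences);
* **non-constant bias with repeated measures** — when the bias depends on
  the measured volume and each animal contributes many linked pairs, the
  bias line ``d = b0 + b1 * m`` is estimated by *alternating regression*:
  generalized-least-squares fits of the line given animal-level variance
  components alternate with closed-form (EM) updates of those components
  until the coefficients stabilize.  Limits of agreement are then the
  line +/- 1.96 x the marginal residual SD (between-animal plus residual);
* **percentage error** — 1.96 x SD(bias) as a percentage of the grand
  mean volume, the scale-free precision index used to compare method-
  comparison studies with different volume ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from eelvkit.errors import ConvergenceError, DegenerateDataError, DomainError
from eelvkit.study_data import PairedSeries

#: Multiplier defining "limits of agreement" coverage (95% under normality).
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementResult:
    """Agreement statistics for one paired series.

    ``bias_intercept``/``bias_slope`` describe the fitted bias line
    ``d = b0 + b1 * m``; ``loa_halfwidth`` is the half-width of the 95%
    prediction band around that line.  ``mean_bias``/``constant_loa`` are
    the classical Bland-Altman quantities around a flat line, reported
    alongside for comparison.
    """

    calib_slope: float
    calib_intercept: float          # mL
    r_squared: float
    calib_p_slope: float
    calib_p_intercept: float
    calib_resid_sd: float           # mL
    bias_intercept: float           # b0, mL
    bias_slope: float               # b1, dimensionless
    bias_intercept_se: float
    bias_slope_se: float
    bias_intercept_ci: tuple[float, float]
    bias_slope_ci: tuple[float, float]
    loa_halfwidth: float            # mL, around the bias line
    mean_bias: float                # mL
    constant_loa: float             # mL, around the mean bias
    percentage_error: float         # %
    sigma2: float                   # within-animal residual variance, mL^2
    tau2: float                     # between-animal intercept variance, mL^2
    n_iter: int
    n_pairs: int
    n_animals: int
    iteration_trace: list = field(default_factory=list, repr=False)

    def bias_at(self, m) -> np.ndarray:
        """Fitted bias (mL) at pairwise mean ``m``."""
        return self.bias_intercept + self.bias_slope * np.asarray(m, dtype=float)

    def loa_at(self, m) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper 95% limits of agreement at pairwise mean ``m``."""
        center = self.bias_at(m)
        return center - self.loa_halfwidth, center + self.loa_halfwidth

    def to_dict(self) -> dict:
        return {
            "calib_slope": self.calib_slope,
            "calib_intercept_mL": self.calib_intercept,
            "r_squared": self.r_squared,
            "bias_intercept_mL": self.bias_intercept,
            "bias_slope": self.bias_slope,
            "loa_halfwidth_mL": self.loa_halfwidth,
            "mean_bias_mL": self.mean_bias,
            "constant_loa_mL": self.constant_loa,
            "percentage_error_pct": self.percentage_error,
            "n_pairs": self.n_pairs,
            "n_animals": self.n_animals,
        }


# ---------------------------------------------------------------------------
# operations


def linear_calibration(series: PairedSeries):
    """OLS of the test method on the reference: ``wiwo = a + b * ct``.

    Returns ``(slope, intercept, r_squared, p_slope, p_intercept,
    resid_sd)``; p-values are two-sided Wald.
    """
    if series.n_pairs < 3:
        raise DegenerateDataError(
            f"calibration needs >= 3 pairs, got {series.n_pairs}"
        )
    x = series.frame["eelv_ct_mL"].to_numpy(dtype=float)
    y = series.frame["eelv_wiwo_mL"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDataError("reference values are constant; fit is singular")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    resid_sd = float(np.sqrt(model.scale))
    return (
        float(slope),
        float(intercept),
        float(model.rsquared),
        float(model.pvalues[1]),
        float(model.pvalues[0]),
        resid_sd,
    )


def bland_altman(series: PairedSeries) -> tuple[float, float]:
    """Classical Bland-Altman: ``(mean_bias, constant_loa_halfwidth)``.

    The half-width is ``1.96 x SD(d)`` (sample SD, ddof=1).
    """
    if series.n_pairs < 3:
        raise DegenerateDataError(f"need >= 3 pairs, got {series.n_pairs}")
    d = series.d
    return float(np.mean(d)), float(LOA_MULTIPLIER * np.std(d, ddof=1))


def percentage_error(series: PairedSeries, multiplier: float = LOA_MULTIPLIER) -> float:
    """Precision as a percentage: ``100 x multiplier x SD(d) / mean(m)``."""
    if series.is_empty:
        raise DegenerateDataError("empty series")
    mean_m = float(np.mean(series.m))
    if mean_m <= 0:
        raise DomainError(f"grand mean volume must be > 0 mL, got {mean_m}")
    return float(100.0 * multiplier * np.std(series.d, ddof=1) / mean_m)


def nonconstant_bias_loa(
    series: PairedSeries,
    include_slope: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> AgreementResult:
    """Bias line and limits of agreement under repeated measurements.

    Alternating regression for the model::

        d_ij = b0 + b1 * m_ij + u_i + e_ij,
        u_i ~ N(0, tau^2) per animal,  e_ij ~ N(0, sigma^2)

    Each iteration (i) re-estimates ``(b0, b1)`` by GLS given the current
    variance components (block-compound-symmetric covariance, solved per
    animal via the Sherman-Morrison identity) and (ii) updates
    ``(sigma^2, tau^2)`` by a closed-form EM step.  Iteration stops when
    successive ``(b0, b1)`` change by less than ``tol`` (mL) or after
    ``max_iter`` passes, whichever is first.

    With a single animal the random intercept is aliased with ``b0``; the
    fit then degrades gracefully to OLS (``tau^2 = 0``) so that with
    ``include_slope=False`` the result coincides with classical
    Bland-Altman.

    Limits of agreement are ``bias_line(m) +/- 1.96 * sqrt(sigma^2 + tau^2)``:
    the marginal SD of a new pair from a new animal around the line.
    """
    if series.n_pairs < 4:
        raise DegenerateDataError(
            f"repeated-measures LOA needs >= 4 pairs, got {series.n_pairs}"
        )
    m = series.m
    d = series.d
    animals = series.animal_ids
    groups = [np.flatnonzero(animals == a) for a in np.unique(animals)]
    n_animals = len(groups)
    n = len(d)

    X = np.column_stack([np.ones(n), m]) if include_slope else np.ones((n, 1))
    if include_slope and np.ptp(m) == 0:
        raise DegenerateDataError("pairwise means are constant; slope is singular")

    # initialisation: pooled OLS with no between-animal variance
    beta, *_ = np.linalg.lstsq(X, d, rcond=None)
    resid = d - X @ beta
    sigma2 = max(float(resid @ resid / max(1, n - X.shape[1])), 1e-12)
    tau2 = 0.0
    single_animal = n_animals < 2

    group_sizes = np.array([len(idx) for idx in groups])

    def variance_step(resid):
        """ML variance components for the current residuals.

        Profiles sigma2 out in closed form and minimizes the remaining
        1-D negative profile loglike over the variance ratio
        lam = tau2/sigma2 (lam = 0 is the no-clustering boundary).
        """
        rss = float(resid @ resid)
        group_sums = np.array([resid[idx].sum() for idx in groups])

        def sigma2_of(lam):
            quad = rss - np.sum(lam / (1.0 + group_sizes * lam) * group_sums**2)
            return max(quad / n, 1e-12)

        def nll(lam):
            return n * math.log(sigma2_of(lam)) + float(
                np.sum(np.log1p(group_sizes * lam))
            )

        from scipy.optimize import minimize_scalar

        best = minimize_scalar(nll, bounds=(0.0, 1e3), method="bounded",
                               options={"xatol": 1e-12})
        lam = float(best.x) if best.fun <= nll(0.0) else 0.0
        if lam < 1e-10:
            lam = 0.0
        s2 = sigma2_of(lam)
        return s2, lam * s2

    trace = []
    cov_beta = None
    for it in range(1, max_iter + 1):
        # (i) GLS for the line given (sigma2, tau2)
        XtVX = np.zeros((X.shape[1], X.shape[1]))
        XtVy = np.zeros(X.shape[1])
        for idx in groups:
            Xi, yi = X[idx], d[idx]
            ni = len(idx)
            shrink = tau2 / (sigma2 + ni * tau2) if tau2 > 0 else 0.0
            # V_i^{-1} = (I - shrink * J) / sigma2
            XtVX += (Xi.T @ Xi - shrink * np.outer(Xi.sum(0), Xi.sum(0))) / sigma2
            XtVy += (Xi.T @ yi - shrink * Xi.sum(0) * yi.sum()) / sigma2
        new_beta = np.linalg.solve(XtVX, XtVy)
        cov_beta = np.linalg.inv(XtVX)

        # (ii) variance components given the current line
        resid = d - X @ new_beta
        if single_animal:
            sigma2_new = max(float(resid @ resid / max(1, n - X.shape[1])), 1e-12)
            tau2_new = 0.0
        else:
            sigma2_new, tau2_new = variance_step(resid)

        # coefficients carry the 1e-6 mL criterion; the variance
        # components (compared on their SD scale, mL) get a looser
        # stabilization check — they are re-estimated by a bounded 1-D
        # optimizer whose granularity would otherwise mask convergence,
        # but must still move off their cold start before the loop may
        # stop (the first GLS pass at tau2 = 0 would look converged)
        beta_delta = float(np.max(np.abs(new_beta - beta)))
        var_delta = float(
            max(
                abs(math.sqrt(sigma2_new) - math.sqrt(sigma2)),
                abs(math.sqrt(tau2_new) - math.sqrt(tau2)),
            )
        )
        delta = beta_delta
        converged = beta_delta < tol and var_delta < 1e-3
        trace.append(
            {
                "iter": it,
                "b0": float(new_beta[0]),
                "b1": float(new_beta[1]) if include_slope else 0.0,
                "sigma2": sigma2_new,
                "tau2": tau2_new,
                "delta": delta,
            }
        )
        beta, sigma2, tau2 = new_beta, sigma2_new, tau2_new
        if converged:
            break
    else:
        raise ConvergenceError(
            f"alternating regression did not converge in {max_iter} iterations "
            f"(last coefficient change {trace[-1]['delta']:.3g} mL)",
            trace=trace,
        )

    b0 = float(beta[0])
    b1 = float(beta[1]) if include_slope else 0.0
    se = np.sqrt(np.diag(cov_beta))
    b0_se = float(se[0])
    b1_se = float(se[1]) if include_slope else 0.0
    z = 1.959963984540054

    # marginal residual SD around the line; for the degenerate flat/OLS case
    # use the sample SD so the result matches classical Bland-Altman exactly
    resid = d - X @ beta
    if single_animal and not include_slope:
        marginal_sd = float(np.std(series.d, ddof=1))
    else:
        marginal_sd = float(np.sqrt(sigma2 + tau2))

    calib = linear_calibration(series)
    mean_bias, constant_loa = bland_altman(series)
    return AgreementResult(
        calib_slope=calib[0],
        calib_intercept=calib[1],
        r_squared=calib[2],
        calib_p_slope=calib[3],
        calib_p_intercept=calib[4],
        calib_resid_sd=calib[5],
        bias_intercept=b0,
        bias_slope=b1,
        bias_intercept_se=b0_se,
        bias_slope_se=b1_se,
        bias_intercept_ci=(b0 - z * b0_se, b0 + z * b0_se),
        bias_slope_ci=(b1 - z * b1_se, b1 + z * b1_se),
        loa_halfwidth=float(LOA_MULTIPLIER * marginal_sd),
        mean_bias=mean_bias,
        constant_loa=constant_loa,
        percentage_error=percentage_error(series),
        sigma2=float(sigma2),
        tau2=float(tau2),
        n_iter=trace[-1]["iter"],
        n_pairs=series.n_pairs,
        n_animals=series.n_animals,
        iteration_trace=trace,
    )


def convert_wiwo_to_ct(value: float, result: AgreementResult) -> tuple[float, float]:
    """Invert the calibration regression: CT-equivalent volume for a
    washin-washout reading, with an approximate propagated SE.

    Returns ``(estimate_mL, se_mL)`` where the SE propagates the
    calibration's residual SD through the inverse slope.
    """
    if abs(result.calib_slope) < 1e-9:
        raise DegenerateDataError("calibration slope ~ 0; regression not invertible")
    estimate = (value - result.calib_intercept) / result.calib_slope
    se = result.calib_resid_sd / abs(result.calib_slope)
    return float(estimate), float(se)


def plot_bland_altman(series: PairedSeries, result: AgreementResult, path) -> None:
    """Bland-Altman scatter with the fitted bias line and 95% limits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(series.m, series.d, s=18, alpha=0.7, edgecolor="none")
    grid = np.linspace(series.m.min(), series.m.max(), 50)
    lo, hi = result.loa_at(grid)
    ax.plot(grid, result.bias_at(grid), "k-", lw=1.5, label="bias line")
    ax.plot(grid, lo, "k--", lw=1, label="95% limits")
    ax.plot(grid, hi, "k--", lw=1)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("mean EELV of both methods (mL)")
    ax.set_ylabel("bias: WI-WO $-$ CT (mL)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
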