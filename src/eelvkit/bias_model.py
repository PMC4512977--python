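"""Modelling the inter-method bias as a function of ventilator settings.

The bias ``d = EELV_WI-WO - EELV_CT`` is regressed on PEEP, tidal volume
(V_T) and the per-animal baseline EELV (``EELV_Base``, the CT volume at
ARDS onset) with a random intercept per animal — each animal contributes
many linked conditions.  Models are fitted by maximum likelihood so AIC is
comparable across fixed-effect structures; backward stepwise selection
respects marginality (a main effect is never dropped while one of its
interactions remains).

Also here: Dunnett-style many-to-one contrasts of the bias at each PEEP
level against PEEP 0, and one-sample location tests of the bias against
zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from eelvkit.errors import ConvergenceError, DegenerateDataError, DomainError
from eelvkit.study_data import StudyTable

logger = logging.getLogger(__name__)

#: Full factorial fixed-effect structure: three mains, three two-way
#: interactions and the three-way interaction.
FULL_TERMS = (
    "peep",
    "vt",
    "eelv_base",
    "peep:vt",
    "peep:eelv_base",
    "vt:eelv_base",
    "peep:vt:eelv_base",
)


@dataclass(frozen=True)
class BiasModelFit:
    """One fitted random-intercept model of the bias."""

    terms: tuple[str, ...]
    params: dict[str, float]
    pvalues: dict[str, float]
    aic: float
    loglike: float
    random_intercept_var: float   # mL^2
    n_obs: int
    n_animals: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "aic": self.aic,
            "params": self.params,
            "pvalues": self.pvalues,
            "random_intercept_var": self.random_intercept_var,
        }


@dataclass(frozen=True)
class PeepContrast:
    """Mean bias difference at one PEEP level versus PEEP 0."""

    peep: float
    estimate: float               # mL
    ci_low: float
    ci_high: float
    p_adjusted: float
    n: int

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise DomainError(
                f"contrast CI [{self.ci_low}, {self.ci_high}] does not "
                f"bracket estimate {self.estimate}"
            )


@dataclass(frozen=True)
class StepwisePath:
    """Backward-selection result: the final fit plus the accepted steps."""

    final: BiasModelFit
    steps: list[dict] = field(default_factory=list)

    @property
    def aics(self) -> list[float]:
        return [s["aic"] for s in self.steps]


# ---------------------------------------------------------------------------
# model data preparation


def bias_frame(table: StudyTable) -> pd.DataFrame:
    """Model frame: one paired row with bias and covariates.

    Columns: ``animal``, ``peep`` (cm H2O), ``vt`` (mL), ``eelv_base``
    (mL), ``bias`` (mL).
    """
    frame = table.with_bias()
    out = pd.DataFrame(
        {
            "animal": frame["animal_id"],
            "peep": frame["peep_cmH2O"],
            "vt": frame["vt_mL"],
            "eelv_base": frame["eelv_base_mL"],
            "bias": frame["d_mL"],
        }
    )
    if out["eelv_base"].isna().any():
        bad = out.loc[out["eelv_base"].isna(), "animal"].unique().tolist()
        raise DegenerateDataError(
            f"baseline EELV (CT at ARDS onset) missing for animals {bad}"
        )
    return out


# ---------------------------------------------------------------------------
# operations


def fit_bias_mixed_model(
    table: StudyTable | pd.DataFrame,
    terms=FULL_TERMS,
    reml: bool = False,
) -> BiasModelFit:
    """Random-intercept linear mixed model of the bias on the given terms.

    Fitted by maximum likelihood by default so AIC comparisons across
    fixed-effect structures are valid; pass ``reml=True`` for a final
    refit with restricted ML.  Wald p-values per coefficient.
    """
    data = bias_frame(table) if isinstance(table, StudyTable) else table
    if data["animal"].nunique() < 2:
        raise DegenerateDataError("mixed model needs >= 2 animals")
    # standardize covariates before building interaction products: raw
    # scales (PEEP ~10, V_T ~10^2, EELV_Base ~10^2 mL) make the three-way
    # column ~10^6 and the Hessian numerically singular.  Likelihood, AIC
    # and Wald p-values are invariant to this linear reparametrization;
    # coefficients are reported per SD of each covariate.
    work = data.copy()
    for var in ("peep", "vt", "eelv_base"):
        sd = float(work[var].std(ddof=0))
        work[var] = (work[var] - float(work[var].mean())) / (sd if sd > 0 else 1.0)
    rhs = " + ".join(terms) if terms else "1"
    formula = f"bias ~ {rhs}"
    model = smf.mixedlm(formula, work, groups=work["animal"])
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise DegenerateDataError(
            f"rank-deficient fixed-effect design for terms {terms}; "
            "some terms are aliased"
        )
    # The profiled objective has a single free parameter (the random-
    # intercept variance ratio); derivative-free Powell locates its
    # optimum reliably, whereas gradient-based lbfgs can stop early or
    # park the variance on the zero boundary (where the reported loglike
    # degenerates to +inf), corrupting AIC comparisons between models.
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for opt_method in ("powell", "bfgs", "nm"):
            try:
                candidate = model.fit(reml=reml, method=opt_method)
            except np.linalg.LinAlgError:
                continue
            if np.isfinite(candidate.llf):
                result = candidate
                break
    if result is None:
        raise ConvergenceError(
            f"mixed-model fit failed for terms {terms}: no optimizer "
            "produced a finite likelihood"
        )
    k = model.exog.shape[1] + 1  # fixed effects + random-intercept variance
    aic = float(-2.0 * result.llf + 2.0 * k)
    fixed_names = list(model.exog_names)
    return BiasModelFit(
        terms=tuple(terms),
        params={name: float(result.params[name]) for name in fixed_names},
        pvalues={name: float(result.pvalues[name]) for name in fixed_names},
        aic=aic,
        loglike=float(result.llf),
        random_intercept_var=float(result.cov_re.iloc[0, 0]),
        n_obs=len(data),
        n_animals=data["animal"].nunique(),
        converged=bool(result.converged),
    )


def _component_factors(term: str) -> frozenset:
    return frozenset(term.split(":"))


def _droppable(terms: tuple[str, ...]) -> list[str]:
    """Terms whose factors are not strictly contained in a remaining term."""
    sets = {t: _component_factors(t) for t in terms}
    out = []
    for t, fs in sets.items():
        if not any(fs < other for o, other in sets.items() if o != t):
            out.append(t)
    return out


def stepwise_aic(
    table: StudyTable | pd.DataFrame,
    full_terms=FULL_TERMS,
) -> StepwisePath:
    """Backward stepwise selection by AIC, respecting marginality.

    From the full model, repeatedly try deleting each currently droppable
    term (one not nested in a remaining interaction); accept the single
    deletion that lowers AIC the most; stop when no deletion lowers it.
    Accepted-path AICs are non-increasing by construction.
    """
    data = bias_frame(table) if isinstance(table, StudyTable) else table
    current_terms = tuple(full_terms)
    current = fit_bias_mixed_model(data, current_terms)
    steps = [{"action": "full", "terms": current_terms, "aic": current.aic}]
    while current_terms:
        candidates = []
        for term in _droppable(current_terms):
            reduced = tuple(t for t in current_terms if t != term)
            try:
                fit = fit_bias_mixed_model(data, reduced)
            except Exception as exc:  # propagate with step context
                raise type(exc)(
                    f"{exc} (while dropping {term!r} from {current_terms})"
                ) from exc
            candidates.append((fit.aic, term, reduced, fit))
        if not candidates:
            break
        best_aic, term, reduced, fit = min(candidates, key=lambda c: c[0])
        if best_aic >= current.aic:
            break
        logger.debug("dropping %s: AIC %.2f -> %.2f", term, current.aic, best_aic)
        steps.append({"action": f"drop {term}", "terms": reduced, "aic": best_aic})
        current_terms, current = reduced, fit
    return StepwisePath(final=current, steps=steps)


def median_split_interaction(
    table: StudyTable | pd.DataFrame,
    cutoffs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """2x2x2 cell summary of the bias by high/low V_T, PEEP, EELV_Base.

    Each covariate is classified high (> cutoff) or low (<= cutoff);
    cutoffs default to the cohort medians.  Returns one row per populated
    cell with mean bias, SD and count; empty cells are simply absent.
    """
    data = bias_frame(table) if isinstance(table, StudyTable) else table
    cutoffs = dict(cutoffs or {})
    for var in ("vt", "peep", "eelv_base"):
        cutoffs.setdefault(var, float(data[var].median()))
    work = data.copy()
    for var in ("vt", "peep", "eelv_base"):
        work[f"{var}_class"] = np.where(data[var] > cutoffs[var], "high", "low")
    grouped = work.groupby(
        ["peep_class", "vt_class", "eelv_base_class"], sort=True
    )["bias"]
    summary = grouped.agg(
        mean_bias_mL="mean", sd_mL=lambda s: s.std(ddof=1), n="count"
    ).reset_index()
    summary.attrs["cutoffs"] = cutoffs
    return summary


def compare_bias_vs_peep0(
    table: StudyTable | pd.DataFrame, with_ci: bool = True
) -> list[PeepContrast]:
    """Dunnett many-to-one contrasts of mean bias at each PEEP level vs PEEP 0.

    Simultaneous 95% confidence intervals and adjusted p-values come from
    the multivariate-t distribution of the many-to-one statistics
    (equicorrelation structure); measurements are treated as exchangeable
    within a PEEP level.  ``with_ci=False`` skips the (comparatively
    expensive) simultaneous-CI root finding and reports unbounded
    intervals — useful in large simulation studies that only need the
    adjusted p-values.
    """
    data = bias_frame(table) if isinstance(table, StudyTable) else table
    control = data.loc[data["peep"] == 0, "bias"].to_numpy(dtype=float)
    if len(control) == 0:
        raise DegenerateDataError("no PEEP 0 reference rows present")
    levels = sorted(p for p in data["peep"].unique() if p != 0)
    if not levels:
        raise DegenerateDataError("no non-reference PEEP levels present")
    samples = [
        data.loc[data["peep"] == p, "bias"].to_numpy(dtype=float) for p in levels
    ]
    # the many-to-one null distribution is evaluated by quasi-Monte-Carlo;
    # a fixed generator keeps repeated analyses byte-identical
    res = stats.dunnett(
        *samples, control=control, random_state=np.random.default_rng(0)
    )
    if with_ci:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ci = res.confidence_interval(confidence_level=0.95)
        ci_low, ci_high = ci.low, ci.high
    else:
        k = len(levels)
        ci_low, ci_high = np.full(k, -np.inf), np.full(k, np.inf)
    out = []
    for i, p in enumerate(levels):
        out.append(
            PeepContrast(
                peep=float(p),
                estimate=float(np.mean(samples[i]) - np.mean(control)),
                ci_low=float(ci_low[i]),
                ci_high=float(ci_high[i]),
                p_adjusted=float(res.pvalue[i]),
                n=len(samples[i]),
            )
        )
    return out


def test_bias_zero(biases, method: str = "signed_rank") -> float:
    """Two-sided p-value for the bias location differing from zero.

    ``signed_rank`` (default) is the coherent one-sample analogue of the
    rank test (exact for n <= 25 when there are no zeros or ties);
    ``mann_whitney`` compares the sample against a zero vector of equal
    length, matching the two-sample phrasing sometimes used for this
    comparison.
    """
    x = np.asarray(biases, dtype=float)
    if len(x) < 5:
        raise DegenerateDataError(f"need n >= 5 biases, got {len(x)}")
    if np.all(x == 0):
        return 1.0
    if method == "signed_rank":
        nonzero = x[x != 0]
        has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
        mode = "exact" if (len(x) <= 25 and np.all(x != 0) and not has_ties) else "approx"
        return float(stats.wilcoxon(x, alternative="two-sided", method=mode).pvalue)
    if method == "mann_whitney":
        return float(
            stats.mannwhitneyu(x, np.zeros_like(x), alternative="two-sided").pvalue
        )
    raise DomainError(f"unknown method {method!r}")
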