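"""Before/after condition contrasts from linear mixed-effects models.

Each per-unit outcome is modelled with phase (before/after), condition and
their interaction as fixed effects, optional unit-level covariates
(centred at the grand mean), a random intercept per participant and a
variance component for the unit nested in the participant.  The contrast
of interest is the after - before estimated marginal mean difference per
condition, with Wald 90/95% confidence intervals and a standardised
effect size d = difference / sigma, where sigma pools all variance
components of the fitted model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

from .datamodel import CONDITIONS

log = logging.getLogger(__name__)

RESPONSES = (
    "delta_f",
    "brace_height",
    "attenuation_slope",
    "peak_discharge_rate",
    "recruitment_threshold",
    "derecruitment_threshold",
)

#: Default covariates per response: the deltaF model adjusts for both the
#: unit's peak discharge rate and its recruitment threshold; the other
#: rate/geometry outcomes adjust for recruitment threshold; the threshold
#: outcomes take no covariate.
DEFAULT_COVARIATES = {
    "delta_f": ("peak_discharge_rate", "recruitment_threshold"),
    "brace_height": ("recruitment_threshold",),
    "attenuation_slope": ("recruitment_threshold",),
    "peak_discharge_rate": ("recruitment_threshold",),
    "recruitment_threshold": (),
    "derecruitment_threshold": (),
}


@dataclass
class ModelSpec:
    """Mixed-model specification for one response."""

    response: str
    covariates: tuple = ()
    random_slope_time: bool = False
    unit_intercept: bool = True

    @classmethod
    def for_response(cls, response: str, **kw) -> "ModelSpec":
        if response not in RESPONSES:
            raise ValueError(f"unknown response {response!r}")
        return cls(
            response=response,
            covariates=DEFAULT_COVARIATES[response],
            **kw,
        )


@dataclass
class ContrastResult:
    """After - before marginal mean difference for one condition."""

    condition: str
    after_minus_before: float
    ci_95: tuple[float, float]
    ci_90: tuple[float, float]
    beta_interaction: tuple[float, float, float]  # (estimate, se, t)
    cohens_d: float
    sigma: float
    aic: float
    bic: float

    def row(self) -> dict:
        return {
            "condition": self.condition,
            "after_minus_before": self.after_minus_before,
            "ci95_lo": self.ci_95[0],
            "ci95_hi": self.ci_95[1],
            "ci90_lo": self.ci_90[0],
            "ci90_hi": self.ci_90[1],
            "cohens_d": self.cohens_d,
            "sigma": self.sigma,
        }


def _prepare(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = table.copy()
    needed = [spec.response, *spec.covariates]
    df = df.dropna(subset=needed)
    if df.empty:
        raise ValueError(f"no complete rows for response {spec.response!r}")
    if df["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants to fit a mixed model")
    df["phase01"] = (df["phase"] == "after").astype(float)
    df["unit_label"] = df["condition"].astype(str) + ":" + df["unit_id"].astype(str)
    for cov in spec.covariates:
        df[f"c_{cov}"] = df[cov] - df[cov].mean()
    return df


def _design(df: pd.DataFrame, spec: ModelSpec):
    conditions = [c.value for c in CONDITIONS if c.value in set(df["condition"])]
    if not conditions:
        raise ValueError("no recognised conditions in table")
    ref = conditions[0]
    cols = {"Intercept": np.ones(len(df)), "phase01": df["phase01"].to_numpy()}
    for c in conditions[1:]:
        ind = (df["condition"] == c).to_numpy(float)
        cols[f"cond[{c}]"] = ind
        cols[f"phase01:cond[{c}]"] = ind * df["phase01"].to_numpy()
    for cov in spec.covariates:
        cols[f"c_{cov}"] = df[f"c_{cov}"].to_numpy()
    exog = pd.DataFrame(cols, index=df.index)
    return exog, conditions, ref


def _fit(df, spec, reml=True):
    exog, conditions, ref = _design(df, spec)
    re_cols = ["Intercept"] + (["phase01"] if spec.random_slope_time else [])

    data = df.assign(**{c: exog[c] for c in exog.columns})
    fixed = f"{spec.response} ~ 0 + " + " + ".join(
        f"Q('{c}')" for c in exog.columns
    )
    random = "0 + " + " + ".join(f"Q('{c}')" for c in re_cols)

    def build(with_unit: bool) -> MixedLM:
        vc = {"unit": "0 + C(unit_label)"} if with_unit else None
        return MixedLM.from_formula(
            fixed,
            data=data,
            groups="participant_id",
            re_formula=random,
            vc_formula=vc,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = build(spec.unit_intercept)
        try:
            res = model.fit(reml=reml, method=["lbfgs", "powell"])
            singular = (not res.converged) or np.any(~np.isfinite(res.bse_fe))
        except (np.linalg.LinAlgError, ValueError):
            res, singular = None, True
        if singular and spec.unit_intercept:
            log.warning(
                "singular fit with unit-level variance component; refitting "
                "without it"
            )
            model = build(False)
            res = model.fit(reml=reml, method=["lbfgs", "powell"])
        if res is None or not np.all(np.isfinite(res.params)):
            raise RuntimeError(
                f"mixed model for {spec.response!r} did not converge"
            )
    return res, exog, conditions, ref


def _sigma(res) -> float:
    """Model-implied population SD: all variance components + residual."""
    var = float(res.scale)
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    if cov_re.size:
        var += float(np.trace(cov_re))
    if res.vcomp is not None and len(res.vcomp):
        var += float(np.sum(res.vcomp))
    return float(np.sqrt(var))


def fit_contrasts(
    table: pd.DataFrame, spec: ModelSpec, reml: bool = True
) -> dict[str, ContrastResult]:
    """Fit the mixed model and return after - before contrasts per condition.

    With covariates centred at their grand means and no phase x covariate
    interaction, the after - before estimated marginal mean difference for
    condition c is the phase effect (reference condition) plus the
    phase x condition interaction coefficient; Wald CIs use the normal
    approximation.
    """
    df = _prepare(table, spec)
    res, exog, conditions, ref = _fit(df, spec, reml=reml)
    names = list(res.model.exog_names)

    def idx(name: str) -> int:
        for i, n in enumerate(names):
            if name in n:
                return i
        raise KeyError(name)

    k = len(names)
    params = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:k, :k]
    sigma = _sigma(res)
    z95, z90 = sps.norm.ppf(0.975), sps.norm.ppf(0.95)

    out: dict[str, ContrastResult] = {}
    for c in conditions:
        L = np.zeros(k)
        L[idx("phase01")] = 1.0
        if c != ref:
            L[idx(f"phase01:cond[{c}]")] = 1.0
        est = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        if c != ref:
            j = idx(f"phase01:cond[{c}]")
        else:
            j = idx("phase01")
        beta = (float(params[j]), float(np.sqrt(cov[j, j])),
                float(params[j] / np.sqrt(cov[j, j])))
        out[c] = ContrastResult(
            condition=c,
            after_minus_before=est,
            ci_95=(est - z95 * se, est + z95 * se),
            ci_90=(est - z90 * se, est + z90 * se),
            beta_interaction=beta,
            cohens_d=est / sigma,
            sigma=sigma,
            aic=float(res.aic) if np.isfinite(res.aic) else np.nan,
            bic=float(res.bic) if np.isfinite(res.bic) else np.nan,
        )
    return out


def contrast_table(contrasts: dict[str, ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([c.row() for c in contrasts.values()])


def compare_covariate_models(
    table: pd.DataFrame, response: str = "delta_f", specs=None
) -> pd.DataFrame:
    """AIC/BIC comparison of the candidate covariate models (ML fits).

    The four default candidates for deltaF: no covariate; peak discharge
    rate; recruitment threshold; both.  Non-convergent candidates are
    excluded with a warning.
    """
    if specs is None:
        specs = {
            "model1": ModelSpec(response=response, covariates=()),
            "model2": ModelSpec(response=response,
                                covariates=("peak_discharge_rate",)),
            "model3": ModelSpec(response=response,
                                covariates=("recruitment_threshold",)),
            "model4": ModelSpec(
                response=response,
                covariates=("peak_discharge_rate", "recruitment_threshold"),
            ),
        }
    rows = []
    for name, spec in specs.items():
        try:
            df = _prepare(table, spec)
            res, *_ = _fit(df, spec, reml=False)
            rows.append({"model": name, "aic": float(res.aic),
                         "bic": float(res.bic)})
        except (RuntimeError, ValueError) as e:
            log.warning("model %s excluded: %s", name, e)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["best_aic"] = out["aic"] == out["aic"].min()
        out["best_bic"] = out["bic"] == out["bic"].min()
    return out


def complete_case_subset(table: pd.DataFrame) -> pd.DataFrame:
    """Participants observed in every condition and both phases.

    Sensitivity-analysis subset: a participant missing any
    condition x phase cell is removed entirely.
    """
    need = {(c.value, p) for c in CONDITIONS for p in ("before", "after")}
    keep = []
    for pid, grp in table.groupby("participant_id"):
        cells = set(zip(grp["condition"], grp["phase"]))
        if need <= cells:
            keep.append(pid)
    out = table[table["participant_id"].isin(keep)].reset_index(drop=True)
    if out.empty:
        raise ValueError("no participant completed all conditions")
    return out


def read_unit_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Import an externally produced per-unit outcome table.

    ``column_map`` maps external column names onto the canonical ones
    (participant_id, condition, phase, unit_id, the six responses); values
    of condition/phase may additionally be remapped through the optional
    "condition_values"/"phase_values" sub-dicts.  This is the entry point
    for re-analysing a deposited per-unit results table with the
    contrasts stage.
    """
    df = pd.read_csv(path)
    column_map = column_map or {}
    values = {
        k: column_map.pop(k, None) for k in ("condition_values", "phase_values")
    }
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    if values["condition_values"]:
        df["condition"] = df["condition"].map(values["condition_values"])
    if values["phase_values"]:
        df["phase"] = df["phase"].map(values["phase_values"])
    required = {"participant_id", "condition", "phase", "unit_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"unit table missing columns: {sorted(missing)}")
    return df
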