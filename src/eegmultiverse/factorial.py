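"""Factorial models of decoding performance over the multiverse.

Every preprocessing step is a categorical factor, treatment-coded against its
smallest-intervention level (the first grid level); all two-way interactions
can be included.  Group-level metrics (total T-sum per path) are modelled
with ordinary least squares; per-participant metrics with a linear mixed
model (participant random intercept, optionally diagonal random slopes —
random-effect correlations are never estimated).

Estimated marginal means (EMMs) are model predictions averaged over the
balanced grid of all other factors; omnibus F-tests and Tukey-adjusted
pairwise contrasts operate on EMM differences.  A main-effects logistic
regression links preprocessing choices to baseline-artifact occurrence, with
per-step likelihood-ratio tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .engine import MultiverseTable, StepGrid

__all__ = [
    "FactorialModelSpec", "FactorialModel", "MarginalMeansTable",
    "ArtifactModelResult", "paths_to_frame", "fit_factorial_lm",
    "fit_factorial_lmm", "estimated_marginal_means", "omnibus_and_pairwise",
    "baseline_artifact_logit",
]


@dataclass
class FactorialModelSpec:
    """What to model and how."""

    response: str = "t_sum"
    interactions: bool = True       # all two-way interactions
    random_slopes: bool = False     # LMM: diagonal random slopes per factor


@dataclass
class FactorialModel:
    """A fitted factorial model plus the design metadata EMMs need."""

    results: object                 # statsmodels results instance
    kind: str                       # "lm" | "lmm"
    factors: dict[str, list[str]]   # varied steps -> ordered levels
    formula: str
    response: str
    converged: bool = True

    @property
    def rsquared(self) -> float:
        return float(self.results.rsquared)

    @property
    def aic(self) -> float:
        return float(self.results.aic)

    @property
    def params(self) -> pd.Series:
        if self.kind == "lmm":
            return self.results.fe_params
        return self.results.params

    def _fe_cov(self) -> np.ndarray:
        cov = np.asarray(self.results.cov_params())
        k = len(self.params)
        return cov[:k, :k]

    def _design(self, df: pd.DataFrame) -> np.ndarray:
        info = self.results.model.data.design_info
        return np.asarray(patsy.dmatrix(info, df, return_type="matrix"))

    def residual_df(self) -> float:
        if self.kind == "lm":
            return float(self.results.df_resid)
        return float(self.results.model.exog.shape[0] - len(self.params))


def paths_to_frame(path_ids, grid: StepGrid | dict) -> pd.DataFrame:
    """Parse path ids into a DataFrame of categorical step levels.

    Level order follows the grid, so the first (smallest-intervention) level
    becomes the treatment-coding reference everywhere.
    """
    if isinstance(grid, dict):
        grid = StepGrid(steps={k: list(v) for k, v in grid.items()})
    rows = []
    for pid in path_ids:
        rows.append(dict(tok.split("=", 1) for tok in pid.split("|")))
    df = pd.DataFrame(rows, index=pd.Index(path_ids, name="path_id"))
    for step, levels in grid.steps.items():
        if step in df.columns:
            df[step] = pd.Categorical(df[step], categories=levels)
    return df


def _varied_factors(df: pd.DataFrame, grid: StepGrid) -> dict[str, list[str]]:
    out = {}
    for step, levels in grid.steps.items():
        if step in df.columns:
            present = [l for l in levels if l in set(df[step].astype(str))]
            if len(present) >= 2:
                out[step] = present
    return out


def _build_formula(response: str, factors: dict[str, list[str]],
                   interactions: bool) -> str:
    terms = [f"C({s}, Treatment('{lv[0]}'))" for s, lv in factors.items()]
    rhs = " + ".join(terms)
    if interactions and len(terms) > 1:
        rhs = f"({rhs}) ** 2"
    return f"{response} ~ {rhs}"


def _model_frame(values: pd.Series | pd.DataFrame, grid: StepGrid,
                 response: str) -> pd.DataFrame:
    if isinstance(values, pd.Series):
        df = values.rename(response).rename_axis("path_id").reset_index()
    else:
        df = values.copy()
        if "value" in df.columns and response not in df.columns:
            df = df.rename(columns={"value": response})
    levels = paths_to_frame(df["path_id"], grid).reset_index(drop=True)
    return pd.concat([df.reset_index(drop=True), levels], axis=1)


def fit_factorial_lm(metrics: pd.Series | MultiverseTable,
                     grid: StepGrid | dict,
                     spec: FactorialModelSpec | None = None) -> FactorialModel:
    """OLS of one group-level response per path on the factorial design.

    ``metrics`` is a Series of responses indexed by path id (or a
    :class:`MultiverseTable`, from which ``spec.response`` is extracted).
    Raises a rank-deficiency error naming missing cells if the factorial is
    incomplete enough to break estimability.
    """
    if spec is None:
        spec = FactorialModelSpec()
    if isinstance(grid, dict):
        grid = StepGrid(steps={k: list(v) for k, v in grid.items()})
    if isinstance(metrics, MultiverseTable):
        metrics = metrics.group_metric(spec.response)
    df = _model_frame(metrics, grid, spec.response)
    df = df.dropna(subset=[spec.response])
    factors = _varied_factors(df, grid)
    if not factors:
        raise ValueError("no preprocessing step varies across the paths")
    formula = _build_formula(spec.response, factors, spec.interactions)
    model = smf.ols(formula, data=df)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        empty = _empty_cells(df, factors)
        raise ValueError(f"rank-deficient design; empty cells: {empty}")
    results = model.fit()
    return FactorialModel(results=results, kind="lm", factors=factors,
                          formula=formula, response=spec.response)


def _empty_cells(df: pd.DataFrame, factors: dict[str, list[str]]):
    empty = []
    for (s1, l1), (s2, l2) in itertools.combinations(
            [(s, l) for s, lv in factors.items() for l in lv], 2):
        if s1 == s2:
            continue
        if not ((df[s1].astype(str) == l1)
                & (df[s2].astype(str) == l2)).any():
            empty.append(((s1, l1), (s2, l2)))
    return empty


def fit_factorial_lmm(per_participant: pd.DataFrame | MultiverseTable,
                      grid: StepGrid | dict,
                      spec: FactorialModelSpec | None = None) -> FactorialModel:
    """REML mixed model of per-participant metrics over the factorial.

    ``per_participant`` needs columns path_id, participant, value.  Always
    includes a participant random intercept; with ``spec.random_slopes``
    diagonal variance components (no correlations) are added for each main
    effect.  Non-convergence is flagged on the returned model, never silent.
    """
    if spec is None:
        spec = FactorialModelSpec(response="avg_accuracy")
    if isinstance(grid, dict):
        grid = StepGrid(steps={k: list(v) for k, v in grid.items()})
    if isinstance(per_participant, MultiverseTable):
        per_participant = per_participant.participant_metric(spec.response)
    if per_participant["participant"].nunique() < 2:
        raise ValueError("mixed model needs at least two participants")
    df = _model_frame(per_participant, grid, spec.response)
    df = df.dropna(subset=[spec.response])
    factors = _varied_factors(df, grid)
    formula = _build_formula(spec.response, factors, spec.interactions)
    vc = None
    if spec.random_slopes:
        vc = {s: f"0 + C({s}, Treatment('{lv[0]}'))"
              for s, lv in factors.items()}
    import warnings

    model = smf.mixedlm(formula, data=df, groups=df["participant"],
                        vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = model.fit(reml=True)
    return FactorialModel(results=results, kind="lmm", factors=factors,
                          formula=formula, response=spec.response,
                          converged=bool(results.converged))


# ---------------------------------------------------------------------------
# Estimated marginal means and contrasts
# ---------------------------------------------------------------------------

@dataclass
class MarginalMeansTable:
    step: str
    table: pd.DataFrame             # level, emm, se, pct_deviation
    grand_mean: float


def _balanced_grid(factors: dict[str, list[str]]) -> pd.DataFrame:
    names = list(factors)
    combos = list(itertools.product(*(factors[n] for n in names)))
    return pd.DataFrame(combos, columns=names)


def _level_l_vectors(model: FactorialModel, step: str) -> dict[str, np.ndarray]:
    """Per level of ``step``: the design-row average over the balanced grid
    of all other factors (the linear functional whose value is the EMM)."""
    if step not in model.factors:
        raise KeyError(f"step {step!r} is not a varied factor of the model")
    grid_df = _balanced_grid(model.factors)
    X = model._design(grid_df)
    out = {}
    for level in model.factors[step]:
        rows = (grid_df[step] == level).to_numpy()
        out[level] = X[rows].mean(axis=0)
    return out


def estimated_marginal_means(model: FactorialModel,
                             step: str) -> MarginalMeansTable:
    """EMMs of one step: average model prediction over the balanced grid of
    all other factors, with delta-method SEs and the percent deviation from
    the grand mean over the full balanced grid."""
    lvecs = _level_l_vectors(model, step)
    beta = np.asarray(model.params)
    cov = model._fe_cov()
    grid_df = _balanced_grid(model.factors)
    grand = float(model._design(grid_df).mean(axis=0) @ beta)
    rows = []
    for level, L in lvecs.items():
        emm = float(L @ beta)
        with np.errstate(all="ignore"):   # saturated fit: no residual df
            se = float(np.sqrt(L @ cov @ L))
        pct = 100.0 * (emm - grand) / grand if grand != 0 else np.nan
        rows.append(dict(level=level, emm=emm, se=se, pct_deviation=pct))
    return MarginalMeansTable(step=step, table=pd.DataFrame(rows),
                              grand_mean=grand)


def omnibus_and_pairwise(model: FactorialModel, step: str):
    """Joint F-test over a step's EMM differences plus Tukey-adjusted
    pairwise contrasts.

    Returns ``(omnibus, contrasts)``: a dict with F, df_num, df_den, p and a
    DataFrame of all level pairs with estimate, SE, t, unadjusted p and
    Tukey-adjusted p (adjusted >= unadjusted always).
    """
    lvecs = _level_l_vectors(model, step)
    levels = list(lvecs)
    if len(levels) < 2:
        raise ValueError(f"step {step!r} has fewer than two levels")
    beta = np.asarray(model.params)
    cov = model._fe_cov()
    df_den = model.residual_df()
    k = len(levels)

    Lmat = np.vstack([lvecs[l] - lvecs[levels[0]] for l in levels[1:]])
    est = Lmat @ beta
    V = Lmat @ cov @ Lmat.T
    F = float(est @ np.linalg.solve(V, est) / Lmat.shape[0])
    p_f = float(stats.f.sf(F, Lmat.shape[0], df_den))
    omnibus = dict(F=F, df_num=Lmat.shape[0], df_den=df_den, p=p_f)

    rows = []
    for la, lb in itertools.combinations(levels, 2):
        d = lvecs[la] - lvecs[lb]
        e = float(d @ beta)
        se = float(np.sqrt(d @ cov @ d))
        t = e / se if se > 0 else 0.0
        p_un = float(2 * stats.t.sf(abs(t), df_den))
        p_tk = float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k,
                                                df_den))
        rows.append(dict(level_a=la, level_b=lb, estimate=e, se=se, t=t,
                         p_unadjusted=p_un, p_tukey=max(p_tk, p_un)))
    return omnibus, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Baseline-artifact logistic regression
# ---------------------------------------------------------------------------

@dataclass
class ArtifactModelResult:
    params: pd.Series | None
    lrt: pd.DataFrame | None        # step, chi2, df, p
    converged: bool
    degenerate: bool
    message: str = ""
    steps: dict[str, list[str]] = field(default_factory=dict)


def baseline_artifact_logit(flags: pd.Series, grid: StepGrid | dict,
                            alpha: float = 0.01) -> ArtifactModelResult:
    """Main-effects logistic regression of baseline-artifact occurrence.

    ``flags`` is a binary Series indexed by path id.  Maximum-likelihood
    Newton fit with convergence threshold 1e-8 and at most 25 iterations;
    per-step likelihood-ratio chi-square tests by refitting without the step.
    All-equal outcomes or complete separation yield a flagged degenerate
    result without LRTs.
    """
    if isinstance(grid, dict):
        grid = StepGrid(steps={k: list(v) for k, v in grid.items()})
    y = flags.astype(float)
    if y.nunique() < 2:
        return ArtifactModelResult(params=None, lrt=None, converged=False,
                                   degenerate=True,
                                   message="all outcomes identical")
    df = _model_frame(y.rename("flag"), grid, "flag")
    factors = _varied_factors(df, grid)
    formula = _build_formula("flag", factors, interactions=False)

    def _fit(fml):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.glm(fml, data=df, family=sm.families.Binomial())
            return model.fit(maxiter=25, tol=1e-8)

    try:
        full = _fit(formula)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as err:
        return ArtifactModelResult(params=None, lrt=None, converged=False,
                                   degenerate=True, message=str(err))
    if not np.all(np.isfinite(full.params)) or np.abs(full.params).max() > 50:
        return ArtifactModelResult(params=full.params, lrt=None,
                                   converged=False, degenerate=True,
                                   message="quasi-separation (huge odds ratios)")
    rows = []
    for step in factors:
        rest = {s: lv for s, lv in factors.items() if s != step}
        if rest:
            reduced = _fit(_build_formula("flag", rest, interactions=False))
        else:
            reduced = _fit("flag ~ 1")
        chi2 = float(max(2 * (full.llf - reduced.llf), 0.0))
        dfree = len(factors[step]) - 1
        rows.append(dict(step=step, chi2=chi2, df=dfree,
                         p=float(stats.chi2.sf(chi2, dfree)),
                         significant=stats.chi2.sf(chi2, dfree) < alpha))
    return ArtifactModelResult(params=full.params, lrt=pd.DataFrame(rows),
                               converged=bool(full.converged),
                               degenerate=False, steps=factors)
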