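"""Logistic habitat-suitability modelling and model comparison.

The response is fish presence/pseudo-absence at sampled channel locations;
predictors are the hydraulic and substrate covariates (depth DEP, velocity
VEL, Froude number FRD, substrate class SUB3, temperature TMP), optionally
with higher-order (squared, cubed, log) terms to capture curvilinear
selection.  Models are fitted by maximum likelihood (IRLS with
step-halving) and compared with AIC, Akaike weights, Nagelkerke pseudo-R2,
the Hosmer-Lemeshow calibration statistic, a binary classification table,
and the rank-based ROC AUC.

Coefficient interpretation helpers expose odds ratios (exp(B) with Wald
95% intervals) and the interior optimum of a quadratic response
(-B_linear / (2 B_squared)), e.g. the preferred water depth of a fish whose
occurrence probability peaks at intermediate depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, rankdata

__all__ = [
    "ModelTerm",
    "FittedHabitatModel",
    "ModelComparison",
    "SeparationError",
    "CollinearityError",
    "parse_terms",
    "expand_terms",
    "design_from_arrays",
    "fit_logistic",
    "aic",
    "akaike_weights",
    "nagelkerke_r2",
    "hosmer_lemeshow",
    "classification_accuracy",
    "roc_auc",
    "backward_eliminate",
    "odds_ratios",
    "quadratic_optimum",
]

CONSTANT = "Constant"

#: Substrate classes coded against the cobble/boulder reference (class 3),
#: so positive dummy coefficients mean "more likely than on cobble/boulder".
SUB3_REFERENCE = 3
SUB3_CLASSES = (1, 2)


class SeparationError(ValueError):
    """Complete separation: coefficients diverge, no finite MLE."""


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelTerm:
    """One model term: a covariate with an optional transform.

    ``transform`` is one of ``identity``, ``square``, ``cube``, ``log`` for
    continuous variables.  A categorical term carries a dummy set coded
    against ``reference_class`` (one column per non-reference class).
    """

    variable: str
    transform: str = "identity"
    categorical: bool = False
    reference_class: int = SUB3_REFERENCE
    classes: tuple[int, ...] = SUB3_CLASSES

    def column_names(self) -> list[str]:
        if self.categorical:
            return [f"{self.variable}_{c}" for c in self.classes]
        suffix = {"identity": "", "square": "_2", "cube": "_3", "log": "_log"}[self.transform]
        return [f"{self.variable}{suffix}"]

    @property
    def label(self) -> str:
        return self.column_names()[0] if not self.categorical else self.variable


def parse_terms(spec: list[str]) -> tuple[ModelTerm, ...]:
    """Parse a compact term spec such as ``["DEP", "DEP^2", "SUB3", "log(VEL)"]``."""
    terms = []
    for item in spec:
        item = item.strip()
        if item.startswith("log(") and item.endswith(")"):
            terms.append(ModelTerm(item[4:-1], "log"))
        elif item.endswith("^2"):
            terms.append(ModelTerm(item[:-2], "square"))
        elif item.endswith("^3"):
            terms.append(ModelTerm(item[:-2], "cube"))
        elif item in ("SUB3", "SUB7"):
            n = 3 if item == "SUB3" else 7
            terms.append(
                ModelTerm(item, categorical=True, reference_class=n,
                          classes=tuple(range(1, n)))
            )
        else:
            terms.append(ModelTerm(item))
    return tuple(terms)


def _transform(values: np.ndarray, term: ModelTerm) -> np.ndarray:
    if term.transform == "identity":
        return values
    if term.transform == "square":
        return values**2
    if term.transform == "cube":
        return values**3
    if term.transform == "log":
        if np.any(values[np.isfinite(values)] <= 0):
            raise ValueError(f"log transform of non-positive {term.variable} values")
        return np.log(values)
    raise ValueError(f"unknown transform {term.transform!r}")


def design_from_arrays(terms, arrays: dict[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    """Build design columns from per-variable arrays (flat or raster-shaped).

    Shared by the sample-table and raster-prediction paths so a model is
    applied identically to training points and to map cells.
    """
    cols, names = [], []
    for term in terms:
        if term.variable not in arrays:
            raise KeyError(f"missing covariate {term.variable!r} required by the model")
        values = np.asarray(arrays[term.variable], dtype=float)
        if term.categorical:
            for c in term.classes:
                cols.append((values == c).astype(float))
                names.append(f"{term.variable}_{c}")
        else:
            cols.append(_transform(values, term))
            names.append(term.column_names()[0])
    return np.stack(cols, axis=-1) if cols else np.empty(arrays_shape(arrays) + (0,)), names


def arrays_shape(arrays: dict[str, np.ndarray]) -> tuple[int, ...]:
    return np.asarray(next(iter(arrays.values()))).shape if arrays else (0,)


def expand_terms(covariates: pd.DataFrame, terms) -> pd.DataFrame:
    """Expand a covariate table into a design table (one column per term column)."""
    if not terms:
        return pd.DataFrame(index=covariates.index)
    arrays = {t.variable: covariates[t.variable].to_numpy() for t in terms}
    X, names = design_from_arrays(terms, arrays)
    return pd.DataFrame(X.reshape(len(covariates), -1), columns=names, index=covariates.index)


@dataclass
class FittedHabitatModel:
    """A fitted (or externally specified) logistic habitat model.

    ``coef`` is indexed by design-column names plus ``Constant`` (the
    intercept, listed last).  ``minus_two_log_likelihood`` is the deviance
    -2L; ``n_params`` counts every estimated coefficient including the
    intercept and each dummy.
    """

    terms: tuple[ModelTerm, ...]
    coef: pd.Series
    se: pd.Series
    minus_two_log_likelihood: float
    n_obs: int
    cutpoint: float = 0.3
    converged: bool = True
    wald: pd.Series = field(default=None, repr=False)
    p_values: pd.Series = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coef.to_numpy())):
            raise ValueError("coefficients must be finite")
        if self.wald is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                self.wald = (self.coef / self.se) ** 2
        if self.p_values is None:
            self.p_values = pd.Series(chi2.sf(self.wald, 1), index=self.coef.index)

    @property
    def n_params(self) -> int:
        return len(self.coef)

    @property
    def aic(self) -> float:
        return aic(self.minus_two_log_likelihood, self.n_params)

    @property
    def column_names(self) -> list[str]:
        return [name for t in self.terms for name in t.column_names()]

    def linear_predictor(self, design: pd.DataFrame | np.ndarray) -> np.ndarray:
        names = self.column_names
        if isinstance(design, pd.DataFrame):
            design = design[names].to_numpy()
        beta = self.coef[names].to_numpy()
        return design @ beta + self.coef[CONSTANT]

    def predict(self, design) -> np.ndarray:
        return expit(self.linear_predictor(design))

    def predict_covariates(self, covariates: pd.DataFrame) -> np.ndarray:
        return self.predict(expand_terms(covariates, self.terms))

    def predict_arrays(self, arrays: dict[str, np.ndarray]) -> np.ndarray:
        X, names = design_from_arrays(self.terms, arrays)
        beta = self.coef[names].to_numpy()
        return expit(X @ beta + self.coef[CONSTANT])

    def table(self) -> pd.DataFrame:
        """Coefficient table: B, S.E., Wald, df, Sig."""
        return pd.DataFrame(
            {"B": self.coef, "S.E.": self.se, "Wald": self.wald,
             "df": 1, "Sig.": self.p_values}
        )

    @classmethod
    def from_coefficients(cls, terms, coef: dict[str, float],
                          se: dict[str, float] | None = None,
                          n_obs: int = 0, cutpoint: float = 0.3) -> "FittedHabitatModel":
        """Build a model from externally supplied coefficients (no refit)."""
        index = [n for t in terms for n in
                 ([f"{t.variable}_{c}" for c in t.classes] if t.categorical
                  else t.column_names())] + [CONSTANT]
        c = pd.Series({k: float(coef[k]) for k in index}, index=index)
        s = pd.Series({k: float((se or {}).get(k, np.nan)) for k in index}, index=index)
        return cls(tuple(terms), c, s, minus_two_log_likelihood=np.nan,
                   n_obs=n_obs, cutpoint=cutpoint)


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # ll = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_collinearity(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved via the smallest singular directions
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        bad = vt[rank:]
        involved = sorted({names[j] for row in bad for j in np.nonzero(np.abs(row) > 1e-6)[0]})
        raise CollinearityError(f"rank-deficient design; linearly dependent columns: {involved}")


def _flag_high_correlation(design: pd.DataFrame, terms, threshold: float = 0.95) -> None:
    """Warn about near-collinear column pairs from *different* variables.

    Within-variable pairs (e.g. DEP vs DEP_2) are expected to be correlated
    and are not flagged; cross-variable ones (velocity vs Froude, say) are.
    """
    var_of = {name: t.variable for t in terms for name in t.column_names()}
    cols = list(design.columns)
    if len(cols) < 2:
        return
    corr = design.corr().to_numpy()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if var_of.get(cols[i]) != var_of.get(cols[j]) and abs(corr[i, j]) > threshold:
                warnings.warn(
                    f"high collinearity |r|={abs(corr[i, j]):.3f} between "
                    f"{cols[i]} and {cols[j]}", stacklevel=3)


def fit_logistic(design: pd.DataFrame, labels, terms=None, cutpoint: float = 0.3,
                 max_iter: int = 100, score_tol: float = 1e-8,
                 ll_rel_tol: float = 1e-10) -> FittedHabitatModel:
    """Maximum-likelihood logistic fit by IRLS with step-halving.

    ``labels`` are 0/1 (absence/presence).  Converges when the largest
    score component is below ``score_tol`` or the relative log-likelihood
    change is below ``ll_rel_tol``.  Standard errors come from the inverse
    observed information at the optimum.
    """
    y = np.asarray(labels, dtype=float)
    if design is None:
        design = pd.DataFrame(index=range(len(y)))
    n = len(y)
    if n != len(design):
        raise ValueError("labels and design have different lengths")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if y.sum() == 0 or y.sum() == n:
        raise ValueError("need at least one presence and one absence")

    if terms is None:
        terms = tuple(ModelTerm(c) for c in design.columns)  # one identity term per column
    names = list(design.columns) + [CONSTANT]
    X = np.column_stack([design.to_numpy(dtype=float), np.ones(n)])
    _check_collinearity(X, names)
    if len(design.columns) >= 2:
        _flag_high_correlation(design, terms)

    beta = np.zeros(X.shape[1])
    eta = X @ beta
    ll = _log_likelihood(eta, y)
    converged = False
    for _ in range(max_iter):
        p = expit(eta)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        w = np.clip(p * (1.0 - p), 1e-12, None)
        info = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix during IRLS") from exc
        step = 1.0
        for _halving in range(40):
            cand = beta + step * delta
            cand_ll = _log_likelihood(X @ cand, y)
            if cand_ll >= ll:
                break
            step *= 0.5
        if abs(cand_ll - ll) < ll_rel_tol * (abs(ll) + 1.0):
            beta, eta, ll = cand, X @ cand, cand_ll
            converged = True
            break
        beta, eta, ll = cand, X @ cand, cand_ll
    if np.max(np.abs(beta)) > 1e3:
        raise SeparationError(
            "coefficients diverging (complete or quasi-complete separation)")
    if -2.0 * ll < 1e-5:
        # a zero deviance means the data are predicted perfectly: the MLE
        # is at infinity and the reported coefficients are arbitrary
        raise SeparationError("complete separation: no finite MLE")
    if not converged:
        warnings.warn("IRLS did not converge within max_iter", stacklevel=2)

    p = expit(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return FittedHabitatModel(
        terms=tuple(terms),
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        minus_two_log_likelihood=-2.0 * ll,
        n_obs=n,
        cutpoint=cutpoint,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Model-comparison statistics


def aic(minus_two_log_likelihood: float, n_params: int) -> float:
    """AIC = -2L + 2 * NPar."""
    return minus_two_log_likelihood + 2.0 * n_params


def akaike_weights(aic_values) -> np.ndarray:
    """Akaike weights w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2)."""
    a = np.asarray(aic_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one AIC value")
    delta = a - a.min()
    rel = np.exp(-delta / 2.0)
    return rel / rel.sum()


def nagelkerke_r2(minus_two_ll_model: float, minus_two_ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R2 from the model and null deviances."""
    if minus_two_ll_null <= 0:
        raise ValueError("null deviance must be positive")
    cox_snell = 1.0 - np.exp((minus_two_ll_model - minus_two_ll_null) / n)
    max_r2 = 1.0 - np.exp(-minus_two_ll_null / n)
    return float(cox_snell / max_r2)


@dataclass
class HosmerLemeshowResult:
    statistic: float
    p_value: float
    n_groups: int
    table: pd.DataFrame  # per group: n, observed/expected presences and absences


def hosmer_lemeshow(probabilities, labels, n_groups: int = 10) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow calibration statistic over fitted-probability deciles.

    Observations are ranked by fitted probability and split into
    ``n_groups`` near-equal-count groups with tied probabilities kept in
    the lower group; C-hat sums (O-E)^2/E over groups and both outcomes;
    the p-value uses chi-square with ``n_groups - 2`` df.  Groups with a
    zero expected count are merged into their neighbour with a warning.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    n = len(p)
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} observations, got {n}")
    order = np.argsort(p, kind="stable")
    p, y = p[order], y[order]

    boundaries = []
    start = 0
    for g in range(n_groups):
        end = int(round(n * (g + 1) / n_groups))
        # keep ties together: extend to cover equal probabilities
        while 0 < end < n and p[end - 1] == p[end]:
            end += 1
        if end > start:
            boundaries.append((start, end))
            start = end
        if start >= n:
            break

    rows = []
    for start, end in boundaries:
        ng = end - start
        o1 = float(y[start:end].sum())
        e1 = float(p[start:end].sum())
        rows.append([ng, o1, e1, ng - o1, ng - e1])
    table = pd.DataFrame(rows, columns=["n", "obs_presence", "exp_presence",
                                        "obs_absence", "exp_absence"])

    # merge groups whose expected count is zero for either outcome
    merged = []
    for row in table.itertuples(index=False):
        if merged and (row.exp_presence == 0 or row.exp_absence == 0):
            warnings.warn("merging Hosmer-Lemeshow group with zero expected count",
                          stacklevel=2)
            prev = merged[-1]
            merged[-1] = [a + b for a, b in zip(prev, row)]
        else:
            merged.append(list(row))
    table = pd.DataFrame(merged, columns=table.columns)

    with np.errstate(divide="ignore", invalid="ignore"):
        chat = float(
            ((table.obs_presence - table.exp_presence) ** 2 / table.exp_presence).sum()
            + ((table.obs_absence - table.exp_absence) ** 2 / table.exp_absence).sum()
        )
    dof = max(len(table) - 2, 1)
    return HosmerLemeshowResult(chat, float(chi2.sf(chat, dof)), len(table), table)


def classification_accuracy(probabilities, labels, cutpoint: float = 0.3):
    """Binary classification table at a probability cutpoint.

    Presence is predicted when p > cutpoint (strict).  Returns
    (overall accuracy %, 2x2 table as a DataFrame).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    pred = (p > cutpoint).astype(float)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    oa = 100.0 * (tp + tn) / len(y)
    table = pd.DataFrame(
        {"predicted_absence": [tn, fn], "predicted_presence": [fp, tp]},
        index=["observed_absence", "observed_presence"],
    )
    return oa, table


def roc_auc(probabilities, labels) -> float:
    """ROC area under the curve by the rank (Mann-Whitney) formulation.

    Ties contribute 1/2 through midranks.  Equals the proportion of
    (presence, absence) pairs in which the presence scores higher.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both presences and absences")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# Backward elimination


@dataclass
class ModelComparison:
    """Candidate-model comparison table plus the fitted models themselves."""

    table: pd.DataFrame
    models: dict[int, FittedHabitatModel]
    best_id: int

    @property
    def best(self) -> FittedHabitatModel:
        return self.models[self.best_id]


def _stat_row(model: FittedHabitatModel, design, y, null_m2ll, cutpoint):
    p = model.predict(design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chat = hosmer_lemeshow(p, y).statistic
    except ValueError:
        chat = np.nan
    oa, _ = classification_accuracy(p, y, cutpoint)
    return {
        "minus2L": model.minus_two_log_likelihood,
        "n_par": model.n_params,
        "AIC": model.aic,
        "C_hat": chat,
        "R2": nagelkerke_r2(model.minus_two_log_likelihood, null_m2ll, model.n_obs),
        "OA": oa,
        "AUC": roc_auc(p, y),
        "variables": ", ".join(t.label for t in model.terms) or "(intercept only)",
    }


def backward_eliminate(covariates: pd.DataFrame, labels, full_terms,
                       cutpoint: float = 0.3) -> ModelComparison:
    """AIC-driven backward elimination from a full term list.

    At each step every single-term deletion is fitted and recorded; the
    deletion with the lowest AIC is accepted if it improves on the current
    model, otherwise elimination stops.  A likelihood-ratio test against
    the parent model is logged for every candidate (AIC decides, the LRT
    is reported).  The returned table carries each candidate's full
    statistic row, delta-AIC, and Akaike weights normalised over all
    recorded models.
    """
    y = np.asarray(labels, dtype=float)
    null = fit_logistic(pd.DataFrame(index=covariates.index), y)
    null_m2ll = null.minus_two_log_likelihood

    def fit(terms):
        design = expand_terms(covariates, terms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return fit_logistic(design, y, terms=terms, cutpoint=cutpoint), design

    rows, models, seen = [], {}, {}

    def record(terms, lrt=np.nan, lrt_df=0):
        key = frozenset(n for t in terms for n in t.column_names())
        if key in seen:
            return seen[key]
        model, design = fit(terms)
        mid = len(models) + 1
        row = _stat_row(model, design, y, null_m2ll, cutpoint)
        row["model"] = mid
        row["LRT"] = lrt
        row["LRT_p"] = float(chi2.sf(lrt, lrt_df)) if lrt_df > 0 and np.isfinite(lrt) else np.nan
        rows.append(row)
        models[mid] = model
        seen[key] = mid
        return mid

    current_terms = tuple(full_terms)
    current_id = record(current_terms)
    while len(current_terms) > 1:
        current = models[current_id]
        candidates = []
        for i in range(len(current_terms)):
            reduced = current_terms[:i] + current_terms[i + 1:]
            cid = record(reduced)
            cand = models[cid]
            lrt = cand.minus_two_log_likelihood - current.minus_two_log_likelihood
            lrt_df = current.n_params - cand.n_params
            idx = next(j for j, r in enumerate(rows) if r["model"] == cid)
            if not np.isfinite(rows[idx]["LRT"]):
                rows[idx]["LRT"] = lrt
                rows[idx]["LRT_p"] = float(chi2.sf(lrt, lrt_df))
            candidates.append((cand.aic, cid))
        best_aic, best_cid = min(candidates)
        if best_aic < current.aic:
            current_id = best_cid
            current_terms = models[best_cid].terms
        else:
            break

    table = pd.DataFrame(rows).set_index("model")
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    table["w"] = akaike_weights(table["AIC"].to_numpy())
    table = table.sort_values("AIC")
    best_id = int(table.index[0])
    cols = ["minus2L", "n_par", "AIC", "dAIC", "w", "C_hat", "R2", "OA", "AUC",
            "LRT", "LRT_p", "variables"]
    return ModelComparison(table[cols], models, best_id)


# ---------------------------------------------------------------------------
# Coefficient interpretation


def odds_ratios(model: FittedHabitatModel, z: float = 1.96) -> pd.DataFrame:
    """exp(B) per coefficient with Wald 95% confidence intervals."""
    exp_b = np.exp(model.coef)
    lo = np.exp(model.coef - z * model.se)
    hi = np.exp(model.coef + z * model.se)
    return pd.DataFrame({"odds_ratio": exp_b, "ci_low": lo, "ci_high": hi})


def quadratic_optimum(model: FittedHabitatModel, variable: str) -> float:
    """Interior optimum of a quadratic response: -B_linear / (2 B_squared).

    Requires the model to contain both the linear and squared term of
    ``variable`` with a negative squared coefficient (a concave response);
    otherwise the occurrence probability has no interior maximum.
    """
    sq = f"{variable}_2"
    if variable not in model.coef.index or sq not in model.coef.index:
        raise ValueError(f"model lacks linear and squared terms for {variable}")
    b1, b2 = float(model.coef[variable]), float(model.coef[sq])
    if b2 >= 0:
        raise ValueError(f"squared coefficient for {variable} is non-negative; "
                         "no interior maximum")
    return -b1 / (2.0 * b2)
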