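"""Design-based logistic regression of cluster membership.

One dichotomous model per cluster: membership indicator regressed on
categorical covariates by weighted maximum pseudo-likelihood (IRLS),
with variance by Taylor linearization for a stratified clustered design
- per-observation score contributions are aggregated to PSU totals and
their between-PSU covariance is estimated within strata with the
``m_h / (m_h - 1)`` stratum correction and an overall
``(n - 1) / (n - p)`` correction. Wald p-values use a t reference
distribution with the design degrees of freedom (#PSUs - #strata), the
convention of the major survey packages.

Point estimates depend on the weights only through their relative
magnitudes; with one PSU per observation in a single stratum the
linearized covariance reduces to the familiar heteroskedasticity-robust
sandwich scaled by n/(n - p).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MAX_ITERATIONS = 100
DEVIANCE_RTOL = 1e-8

#: Reference levels used when building a default spec from known
#: covariate names (mirroring the published model codings).
DEFAULT_REFERENCES = {
    "age_group": "30-34",
    "residence": "urban",
    "education": "none",
    "wealth": "poorest",
    "knowledge": "low",
    "ideal_children": "1-2",
    "sex_preference": "balanced",
    "wife_beating": "no_scenario",
    "self_efficacy": "none",
    "fertility_desire": "soon",
    "intention": "does_not_intend",
    "phone_internet": "no",
    "fp_messages": "no",
    "health_visit": "no_visit",
    "insurance": "no",
    "access_problems": "none",
}


class ConvergenceError(RuntimeError):
    pass


class SeparationError(RuntimeError):
    pass


@dataclass
class SurveyDesign:
    """Per-woman weight, PSU id and stratum id.

    Strata containing a single PSU cannot contribute a variance term;
    they are collapsed into the stratum with the nearest id, with a
    logged warning (the usual certainty-unit fix).
    """

    weight: np.ndarray
    psu: np.ndarray
    stratum: np.ndarray

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=np.float64)
        self.psu = np.asarray(self.psu)
        self.stratum = np.asarray(self.stratum)
        if not (len(self.weight) == len(self.psu) == len(self.stratum)):
            raise ValueError("design fields must have equal length")
        if np.any(self.weight <= 0):
            raise ValueError("weights must be positive")
        self._collapse_singletons()

    def _collapse_singletons(self) -> None:
        strata = sorted(pd.unique(self.stratum))
        if len(strata) < 2:
            return
        counts = {
            h: pd.unique(self.psu[self.stratum == h]).size for h in strata
        }
        for pos, h in enumerate(strata):
            if counts.get(h, 0) != 1:
                continue
            # nearest surviving stratum in sorted order (previous preferred)
            candidates = [s for s in strata if s != h and s in counts]
            target = candidates[max(0, min(pos, len(candidates)) - 1)]
            logger.warning("collapsing singleton-PSU stratum %r into %r", h, target)
            self.stratum = np.where(self.stratum == h, target, self.stratum)
            counts[target] += counts.pop(h)

    @property
    def n_psus(self) -> int:
        df = pd.DataFrame({"s": self.stratum, "p": self.psu})
        return int(df.drop_duplicates().shape[0])

    @property
    def n_strata(self) -> int:
        return pd.unique(self.stratum).size

    @property
    def df(self) -> int:
        df = pd.DataFrame({"s": self.stratum, "p": self.psu})
        return int(df.drop_duplicates().shape[0] - df["s"].nunique())


@dataclass(frozen=True)
class ModelSpec:
    """Covariate terms with explicit reference levels.

    ``terms`` maps covariate name -> (levels tuple, reference level);
    each term contributes one dummy column per non-reference level.
    """

    outcome_cluster: object
    terms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (levels, ref) in self.terms.items():
            if ref not in levels:
                raise ValueError(f"term {name!r}: reference {ref!r} not a level")
            if len(set(levels)) != len(levels):
                raise ValueError(f"term {name!r}: duplicate levels")


def spec_from_data(outcome_cluster, data: pd.DataFrame, covariates=None) -> ModelSpec:
    """Build a ModelSpec from observed covariate columns, using the
    documented default reference for known names and the most frequent
    level otherwise."""
    if covariates is None:
        covariates = [c for c in data.columns if c != "case_id"]
    terms = {}
    for name in covariates:
        levels = list(pd.unique(data[name]))
        default_ref = DEFAULT_REFERENCES.get(name)
        if default_ref in levels:
            ref = default_ref
        else:
            ref = data[name].mode().iloc[0]
        levels = [ref] + [l for l in levels if l != ref]
        terms[name] = (tuple(levels), ref)
    return ModelSpec(outcome_cluster=outcome_cluster, terms=terms)


def encode_design(data: pd.DataFrame, spec: ModelSpec):
    """Dummy-encode covariates; returns (X with intercept, column names).

    Raises on empty cells: a level listed in the spec with no
    observations would make its coefficient undefined.
    """
    n = len(data)
    cols, names = [np.ones(n)], ["intercept"]
    for term, (levels, ref) in spec.terms.items():
        observed = data[term].to_numpy()
        for level in levels:
            count = int(np.sum(observed == level))
            if count == 0:
                raise ValueError(
                    f"empty covariate cell: term {term!r} level {level!r}"
                )
            if level != ref:
                cols.append((observed == level).astype(np.float64))
                names.append(f"{term}={level}")
    return np.column_stack(cols), names


@dataclass
class MembershipModel:
    """A fitted design-based logistic membership model."""

    cluster: object
    term_names: list
    coefficients: np.ndarray
    covariance: np.ndarray
    df: int
    n: int
    deviance: float
    iterations: int

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def std_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def p_values(self) -> np.ndarray:
        t = self.coefficients / self.std_errors
        return 2.0 * stats.t.sf(np.abs(t), df=self.df)

    def summary(self) -> pd.DataFrame:
        lo = self.coefficients - stats.t.ppf(0.975, self.df) * self.std_errors
        hi = self.coefficients + stats.t.ppf(0.975, self.df) * self.std_errors
        return pd.DataFrame(
            {
                "term": self.term_names,
                "coef": self.coefficients,
                "se": self.std_errors,
                "odds_ratio": self.odds_ratios,
                "or_low": np.exp(lo),
                "or_high": np.exp(hi),
                "p_value": self.p_values,
            }
        )


def _deviance(X, y, w, beta) -> float:
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    mu = np.clip(mu, 1e-300, 1 - 1e-16)
    return -2.0 * float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))


def _irls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted maximum pseudo-likelihood via iteratively reweighted
    least squares; returns (beta, X'WX at the solution, deviance, iters)."""
    beta = np.zeros(X.shape[1])
    deviances = [_deviance(X, y, w, beta)]
    for it in range(1, MAX_ITERATIONS + 1):
        eta = X @ beta
        if np.any(np.abs(eta) > 30):
            raise SeparationError(
                "perfect separation suspected (unbounded linear predictor); "
                "inspect covariate cells against the outcome"
            )
        mu = 1.0 / (1.0 + np.exp(-eta))
        v = np.clip(mu * (1.0 - mu), 1e-10, None)
        wls = w * v
        z = eta + (y - mu) / v
        xtwx = X.T @ (X * wls[:, None])
        beta = np.linalg.solve(xtwx, X.T @ (wls * z))
        deviances.append(_deviance(X, y, w, beta))
        if np.any(np.abs(beta) > 15):
            raise SeparationError(
                "perfect separation suspected (diverging coefficients); "
                "inspect covariate cells against the outcome"
            )
        if abs(deviances[-1] - deviances[-2]) <= DEVIANCE_RTOL * (
            abs(deviances[-2]) + 1e-12
        ):
            # expected information at the solution, for the sandwich bread
            mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
            v = np.clip(mu * (1.0 - mu), 1e-10, None)
            xtwx = X.T @ (X * (w * v)[:, None])
            return beta, xtwx, deviances[-1], it
    raise ConvergenceError(
        f"IRLS did not converge in {MAX_ITERATIONS} iterations; "
        f"deviance trace tail: {[round(d, 6) for d in deviances[-5:]]}"
    )


def _linearized_covariance(X, y, w, beta, xtwx, design: SurveyDesign):
    n, p = X.shape
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    scores = (w * (y - mu))[:, None] * X  # per-observation score contributions
    key = pd.DataFrame({"stratum": design.stratum, "psu": design.psu})
    mid = np.zeros((p, p))
    for h, idx in key.groupby("stratum").groups.items():
        idx = np.asarray(idx)
        psu_ids = key["psu"].to_numpy()[idx]
        totals = (
            pd.DataFrame(scores[idx]).groupby(psu_ids).sum().to_numpy()
        )
        m_h = totals.shape[0]
        if m_h < 2:
            warnings.warn(f"stratum {h!r} has a single PSU; no variance contribution")
            continue
        centered = totals - totals.mean(axis=0)
        mid += (m_h / (m_h - 1.0)) * centered.T @ centered
    mid *= (n - 1.0) / (n - p)
    binv = np.linalg.inv(xtwx)
    cov = binv @ mid @ binv
    return 0.5 * (cov + cov.T)


def fit_membership(
    y,
    spec: ModelSpec,
    data: pd.DataFrame,
    design: SurveyDesign,
) -> MembershipModel:
    """Fit one cluster-membership logistic model with linearized variance."""
    y = np.asarray(y, dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X, names = encode_design(data, spec)
    if len(y) != X.shape[0] or len(design.weight) != X.shape[0]:
        raise ValueError("outcome, data and design must have equal length")
    beta, xtwx, deviance, iterations = _irls(X, y, design.weight)
    cov = _linearized_covariance(X, y, design.weight, beta, xtwx, design)
    return MembershipModel(
        cluster=spec.outcome_cluster,
        term_names=names,
        coefficients=beta,
        covariance=cov,
        df=design.df,
        n=X.shape[0],
        deviance=deviance,
        iterations=iterations,
    )


def fit_all_clusters(
    assignment,
    spec_template: ModelSpec,
    data: pd.DataFrame,
    design: SurveyDesign,
) -> tuple[dict, pd.DataFrame]:
    """One membership model per cluster plus a combined OR table
    (one row per non-reference level, one OR/p pair per cluster).

    A failure in one cluster's model (e.g. separation) is recorded and
    the remaining clusters are still fitted.
    """
    assignment = np.asarray(assignment)
    clusters = sorted(pd.unique(assignment))
    models: dict = {}
    for c in clusters:
        spec = ModelSpec(outcome_cluster=c, terms=spec_template.terms)
        try:
            models[c] = fit_membership((assignment == c).astype(float),
                                       spec, data, design)
        except (ConvergenceError, SeparationError, ValueError) as exc:
            logger.error("cluster %r model failed: %s", c, exc)
            models[c] = exc
    rows = []
    ref_lookup = {name: ref for name, (_, ref) in spec_template.terms.items()}
    term_names = None
    for c, m in models.items():
        if not isinstance(m, MembershipModel):
            continue
        term_names = m.term_names
        break
    if term_names is None:
        raise RuntimeError("all cluster models failed")
    for tn in term_names:
        if tn == "intercept":
            continue
        term = tn.split("=", 1)[0]
        row = {"term": tn, "reference": ref_lookup[term]}
        for c, m in models.items():
            if isinstance(m, MembershipModel):
                i = m.term_names.index(tn)
                row[f"OR_{c}"] = m.odds_ratios[i]
                row[f"p_{c}"] = m.p_values[i]
            else:
                row[f"OR_{c}"] = np.nan
                row[f"p_{c}"] = np.nan
        rows.append(row)
    return models, pd.DataFrame(rows)


def collinearity_check(
    data: pd.DataFrame,
    spec: ModelSpec,
    vif_threshold: float = 10.0,
    condition_threshold: float = 30.0,
) -> pd.DataFrame:
    """Variance inflation factors and the design-matrix condition number.

    VIF_j = 1/(1 - R^2_j) from regressing column j on the other columns
    (with intercept); a duplicated column yields an infinite VIF and is
    flagged as singular.
    """
    X, names = encode_design(data, spec)
    cols = X[:, 1:]
    colnames = names[1:]
    n, p = cols.shape
    rows = []
    for j in range(p):
        xj = cols[:, j]
        others = np.column_stack([np.ones(n), np.delete(cols, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        tss = float(np.sum((xj - xj.mean()) ** 2))
        rss = float(np.sum(resid**2))
        if tss == 0:
            vif = np.inf
        else:
            r2 = 1.0 - rss / tss
            vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"term": colnames[j], "vif": vif,
                     "flag": bool(not np.isfinite(vif) or vif > vif_threshold)})
    scaled = X / np.linalg.norm(X, axis=0)
    cond = float(np.linalg.cond(scaled))
    out = pd.DataFrame(rows)
    out.attrs["condition_number"] = cond
    out.attrs["condition_flag"] = cond > condition_threshold
    if out["flag"].any() or out.attrs["condition_flag"]:
        warnings.warn(
            f"collinearity warning: max VIF "
            f"{out['vif'].replace(np.inf, np.nan).max():.2f}, "
            f"condition number {cond:.1f}"
        )
    return out
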