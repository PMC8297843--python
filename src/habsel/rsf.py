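"""Used-available logistic RSFs and the sequential model-selection algorithm.

Fitting is plain maximum-likelihood logistic regression (IRLS) of the
used/available response on centred-and-scaled covariates; the exponential
of the fitted linear predictor (intercept omitted) is the relative
selection surface.

Model selection follows the importance-ranked sequential-removal scheme
used in applied RSF work:

1. a Pearson correlation screen (|r| > 0.5 pairs resolved by
   single-variable AIC);
2. backward removal in ascending order of importance |beta/SE|, a removal
   being accepted iff it does not increase AIC (a main effect is removed
   together with any interaction or quadratic built on it); ranking is
   recomputed after every accepted removal, and the loop ends when a full
   pass accepts nothing;
3. a VIF screen (drop the worst column while any VIF > 5, refitting);
4. a 95% CI screen dropping terms whose CI spans zero — except a main
   effect whose interaction CI excludes zero, which is retained together
   with the interaction.

Every step is recorded in a replayable :class:`SelectionLedger`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import Grid, LandscapeStack
from .preprocess import UsedAvailableTable
from .synthetic import _term_values  # raw-scale term evaluation

__all__ = [
    "RSFModel",
    "SelectionLedger",
    "fit_logistic",
    "pearson_screen",
    "vif",
    "backward_select",
    "predict_rsf",
]


class SeparationError(RuntimeError):
    pass


class RankDeficiencyError(RuntimeError):
    def __init__(self, aliased: list[str]):
        super().__init__(f"design matrix rank deficient; aliased terms: {aliased}")
        self.aliased = aliased


@dataclass
class RSFModel:
    """A fitted fixed-effects RSF with its scaling metadata."""

    terms: list[str]
    beta: np.ndarray          # includes leading intercept
    se: np.ndarray
    cov: np.ndarray
    llf: float
    aic: float
    n_used: int
    n_available: int
    scaling: dict[str, tuple[float, float]]
    reference_level: str = "conifer"
    study_area: str = ""
    variant: str = "custom"   # moderate-ruggedness | high-ruggedness | custom

    @property
    def names(self) -> list[str]:
        return ["intercept"] + list(self.terms)

    def coef(self, term: str) -> float:
        return float(self.beta[self.names.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.names.index(term)])

    def conf_int(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        return {name: (b - z * s, b + z * s)
                for name, b, s in zip(self.names, self.beta, self.se)}

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "beta": self.beta, "se": self.se,
            "ci_lo": [ci[n][0] for n in self.names],
            "ci_hi": [ci[n][1] for n in self.names],
        }, index=self.names)

    def to_json(self, path) -> None:
        payload = {
            "terms": self.terms,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "cov": self.cov.tolist(),
            "llf": self.llf,
            "aic": self.aic,
            "n_used": self.n_used,
            "n_available": self.n_available,
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "reference_level": self.reference_level,
            "study_area": self.study_area,
            "variant": self.variant,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RSFModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(terms=d["terms"], beta=np.array(d["beta"]),
                   se=np.array(d["se"]), cov=np.array(d["cov"]),
                   llf=d["llf"], aic=d["aic"], n_used=d["n_used"],
                   n_available=d["n_available"],
                   scaling={k: tuple(v) for k, v in d["scaling"].items()},
                   reference_level=d["reference_level"],
                   study_area=d["study_area"], variant=d["variant"])


@dataclass
class SelectionLedger:
    """Ordered record of every model-selection decision."""

    steps: list[dict] = field(default_factory=list)

    def add(self, action: str, term: str, statistic, rationale: str) -> None:
        self.steps.append({"action": action, "term": term,
                           "statistic": statistic, "rationale": rationale})

    def dropped_terms(self) -> list[str]:
        return [s["term"] for s in self.steps
                if s["action"].endswith("-drop")]

    def replay(self, global_terms: list[str]) -> list[str]:
        """Final term set implied by the ledger's drop actions."""
        out = list(global_terms)
        for t in self.dropped_terms():
            if t in out:
                out.remove(t)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# design matrix construction

def term_column(table: UsedAvailableTable | pd.DataFrame, term: str) -> np.ndarray:
    """Design column for one term, built from the (scaled) table columns.

    Interactions are products of scaled columns; quadratics are squares
    of the scaled column (centre-then-square).
    """
    df = table.df if isinstance(table, UsedAvailableTable) else table
    if ":" in term:
        a, b = term.split(":")
        return term_column(df, a) * term_column(df, b)
    if term.endswith("^2"):
        return term_column(df, term[:-2]) ** 2
    if term not in df:
        raise KeyError(f"term {term!r} not found in table")
    return df[term].to_numpy(dtype=float)


def design_matrix(table, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(table.df if isinstance(table, UsedAvailableTable)
                        else table))]
    cols += [term_column(table, t) for t in terms]
    return np.column_stack(cols)


def _aliased_terms(X: np.ndarray, terms: list[str]) -> list[str]:
    """Terms whose columns are linearly dependent on earlier ones (QR)."""
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() or 1.0)
    bad = np.nonzero(diag < tol)[0]
    return [(["intercept"] + terms)[i] for i in bad]


def fit_logistic(table: UsedAvailableTable, terms: list[str],
                 study_area: str = "", variant: str = "custom") -> RSFModel:
    """Maximum-likelihood logistic fit of used vs available on ``terms``.

    IRLS via a binomial GLM (tolerance 1e-8, max 100 iterations); SEs
    from the observed information.  Raises on rank deficiency or perfect
    separation.
    """
    y = table.df["response"].to_numpy(dtype=float)
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ValueError("need at least one used and one available row")
    X = design_matrix(table, terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(_aliased_terms(X, terms))
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        # depending on the statsmodels version, perfect separation surfaces
        # either as an exception or as a PerfectSeparationWarning
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "error", message=".*[Pp]erfect separation.*")
            res = model.fit(maxiter=100, tol=1e-8)
    except Exception as exc:
        if "separation" in str(exc).lower() or "Separation" in type(exc).__name__:
            raise SeparationError(f"perfect separation fitting terms {terms}")
        raise
    beta = np.asarray(res.params)
    se = np.asarray(res.bse)
    if not np.all(np.isfinite(se)) or np.any(np.abs(beta) > 50):
        raise SeparationError(
            f"diverging coefficients (possible separation) for terms {terms}")
    aic = -2.0 * res.llf + 2.0 * X.shape[1]
    return RSFModel(terms=list(terms), beta=beta, se=se,
                    cov=np.asarray(res.cov_params()), llf=float(res.llf),
                    aic=float(aic),
                    n_used=int(y.sum()), n_available=int((1 - y).sum()),
                    scaling=dict(table.scaling),
                    reference_level=table.reference_level,
                    study_area=study_area, variant=variant)


# ---------------------------------------------------------------------------
# screens

def pearson_screen(table: UsedAvailableTable, candidates: list[str],
                   r_threshold: float = 0.5,
                   ledger: SelectionLedger | None = None
                   ) -> tuple[list[str], SelectionLedger]:
    """Resolve collinear candidate pairs (|r| > threshold) by
    single-variable AIC, worst pairs first."""
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate covariates")
    ledger = ledger or SelectionLedger()
    cols = {t: term_column(table, t) for t in candidates}
    pairs = []
    for i, a in enumerate(candidates):
        for b in candidates[i + 1:]:
            r = float(np.corrcoef(cols[a], cols[b])[0, 1])
            if abs(r) > r_threshold:
                pairs.append((abs(r), r, a, b))
    pairs.sort(reverse=True)  # resolve in descending |r|
    retained = list(candidates)
    aic_cache: dict[str, float] = {}

    def single_aic(t: str) -> float:
        if t not in aic_cache:
            aic_cache[t] = fit_logistic(table, [t]).aic
        return aic_cache[t]

    for _, r, a, b in pairs:
        if a not in retained or b not in retained:
            continue
        drop = a if single_aic(a) > single_aic(b) else b
        keep = b if drop == a else a
        retained.remove(drop)
        ledger.add("corr-screen-drop", drop,
                   {"r": r, "aic_dropped": single_aic(drop),
                    "aic_kept": single_aic(keep)},
                   f"|r|={abs(r):.3f}>{r_threshold} with {keep}; "
                   f"higher single-variable AIC")
    return retained, ledger


def vif(columns: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Variance inflation factor per column: 1/(1-R^2) regressing each
    column on the others plus an intercept; inf for exact collinearity."""
    X = np.asarray(columns, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("columns must be non-constant")
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# backward selection

def dependents_of(term: str, terms: list[str]) -> list[str]:
    """Interactions/quadratics in ``terms`` built on main effect ``term``."""
    deps = []
    for t in terms:
        if t == term:
            continue
        if ":" in t and term in t.split(":"):
            deps.append(t)
        elif t == f"{term}^2":
            deps.append(t)
    return deps


def backward_select(table: UsedAvailableTable, global_terms: list[str],
                    vif_threshold: float = 5.0, ci_level: float = 0.95,
                    study_area: str = "", variant: str = "custom",
                    ledger: SelectionLedger | None = None
                    ) -> tuple[RSFModel, SelectionLedger]:
    """Importance-ranked sequential AIC removal, then VIF and CI screens."""
    ledger = ledger or SelectionLedger()
    terms = list(global_terms)
    model = fit_logistic(table, terms, study_area, variant)

    # --- stage 1: sequential AIC removal, ascending importance ------------
    while True:
        importance = {t: abs(model.coef(t)) / model.se_of(t) for t in terms}
        order = sorted(terms, key=importance.get)
        accepted = False
        for t in order:
            trial_drop = [t] + dependents_of(t, terms)
            trial_terms = [u for u in terms if u not in trial_drop]
            if not trial_terms:
                continue
            trial = fit_logistic(table, trial_terms, study_area, variant)
            if trial.aic <= model.aic + 1e-9:  # ties resolved to parsimony
                for u in trial_drop:
                    ledger.add("importance-drop", u,
                               {"importance": importance[t],
                                "aic_before": model.aic,
                                "aic_after": trial.aic},
                               f"removal of {t} (with dependents) did not "
                               f"increase AIC")
                terms, model = trial_terms, trial
                accepted = True
                break
            ledger.add("importance-retain", t,
                       {"importance": importance[t],
                        "aic_before": model.aic, "aic_after": trial.aic},
                       "removal increased AIC")
        if not accepted:
            break

    # --- stage 2: VIF screen ---------------------------------------------
    while len(terms) >= 2:
        cols = np.column_stack([term_column(table, t) for t in terms])
        v = vif(cols)
        worst = int(np.argmax(v))
        if v[worst] <= vif_threshold:
            break
        t = terms[worst]
        drop = [t] + dependents_of(t, terms)
        for u in drop:
            ledger.add("vif-drop", u, {"vif": float(v[worst])},
                       f"VIF {v[worst]:.2f} > {vif_threshold}")
        terms = [u for u in terms if u not in drop]
        model = fit_logistic(table, terms, study_area, variant)

    # --- stage 3: CI screen with the interaction exception ----------------
    while True:
        ci = model.conf_int(ci_level)
        offending = []
        for t in terms:
            lo, hi = ci[t]
            if lo <= 0.0 <= hi:
                deps = dependents_of(t, terms)
                exempt = any(not (ci[d][0] <= 0.0 <= ci[d][1]) for d in deps)
                if exempt:
                    ledger.add("ci-retain-interaction", t,
                               {"ci": (lo, hi)},
                               "main-effect CI spans zero but a dependent "
                               "interaction CI excludes zero")
                else:
                    offending.append((abs(model.coef(t)) / model.se_of(t), t,
                                      (lo, hi)))
        if not offending:
            break
        _, t, bounds = min(offending)  # least informative first
        drop = [t] + dependents_of(t, terms)
        for u in drop:
            ledger.add("ci-drop", u, {"ci": bounds},
                       f"{ci_level:.0%} CI of {t} overlaps zero")
        terms = [u for u in terms if u not in drop]
        if not terms:
            break
        model = fit_logistic(table, terms, study_area, variant)

    return model, ledger


# ---------------------------------------------------------------------------
# prediction

def predict_rsf(model: RSFModel, landscape: LandscapeStack) -> Grid:
    """Relative selection surface ``w = exp(beta . x_scaled)`` per cell.

    The intercept (a sampling-ratio artefact) is omitted; frozen scaling
    metadata from the fitting table is applied to the raw layers, so the
    surface is comparable across landscapes.  Missing covariates
    propagate missing cells.
    """
    if not model.scaling:
        raise ValueError("model carries no scaling metadata")
    g = landscape.grid
    rows, cols = np.meshgrid(np.arange(g.n_rows), np.arange(g.n_cols),
                             indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    eta = np.zeros(len(rows))
    for term, beta in zip(model.terms, model.beta[1:]):
        eta += beta * _scaled_term_values(model, landscape, term, rows, cols)
    w = np.exp(eta).reshape(g.n_rows, g.n_cols)
    return g.copy_with(w)


def _scaled_term_values(model: RSFModel, landscape: LandscapeStack,
                        term: str, rows, cols) -> np.ndarray:
    if ":" in term:
        a, b = term.split(":")
        return (_scaled_term_values(model, landscape, a, rows, cols)
                * _scaled_term_values(model, landscape, b, rows, cols))
    if term.endswith("^2"):
        return _scaled_term_values(model, landscape, term[:-2], rows, cols) ** 2
    raw = _term_values(landscape, term, rows, cols)
    if term in model.scaling:
        mean, sd = model.scaling[term]
        return (raw - mean) / sd
    return raw  # cover indicators are already 0/1
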