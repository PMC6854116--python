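"""Logistic-regression engine and information-theoretic model ranking.

All submodels are binomial GLMs with a logit link, fitted by maximum
likelihood (IRLS via statsmodels). This module owns everything around
the fit: design-matrix construction from declarative term lists
(reference-cell coding for categoricals, log10 and squared-log10
transforms for divergence times), the small-sample AICc, Akaike
weights and the dAICc <= 2 confidence set, Nagelkerke's R-squared, the
G-squared likelihood-ratio test, and prediction utilities.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .exceptions import FitError

__all__ = [
    "Term",
    "DesignSpec",
    "FittedModel",
    "ModelRanking",
    "LrtResult",
    "logit",
    "inv_logit",
    "fit_logistic",
    "aicc",
    "akaike_weights",
    "rank_models",
    "nagelkerke_r2",
    "lr_test",
    "predict_prob",
]

_TERM_KINDS = ("continuous", "categorical", "log10", "sq_log10")


def logit(p):
    """log(p / (1 - p)); vectorized."""
    p = np.asarray(p, dtype=float)
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def inv_logit(x):
    """1 / (1 + exp(-x)); vectorized and overflow-safe."""
    x = np.asarray(x, dtype=float)
    out = scipy.stats.logistic.cdf(x)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Term:
    """One model term: a predictor column and how it enters the design."""

    name: str
    kind: str = "continuous"
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _TERM_KINDS:
            raise FitError(f"unknown term kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise FitError(
                f"categorical term {self.name!r} must declare a reference level")


_TERM_RE = re.compile(r"^(?P<name>\w+)(\((?P<args>[^)]*)\))?$")


def parse_term(text: str) -> Term:
    """Parse a config-style term such as ``"shade_tolerance(cat,ref=low)"``.

    Bare names are continuous; ``log10`` and ``sq_log10`` request the
    corresponding transform of a positive continuous predictor.
    """
    m = _TERM_RE.match(text.strip())
    if m is None:
        raise FitError(f"cannot parse term {text!r}")
    name = m.group("name")
    kind, ref = "continuous", None
    if m.group("args"):
        for arg in m.group("args").split(","):
            arg = arg.strip()
            if arg in ("cat", "categorical"):
                kind = "categorical"
            elif arg in ("log10", "sq_log10", "continuous"):
                kind = arg
            elif arg.startswith("ref="):
                ref = arg[4:]
            else:
                raise FitError(f"unknown term argument {arg!r} in {text!r}")
    return Term(name, kind, ref)


@dataclass(frozen=True)
class DesignSpec:
    """Declarative model formula: response plus a list of terms."""

    response: str
    terms: tuple[Term, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise FitError(f"duplicate terms in design {self.name!r}: {names}")

    @classmethod
    def from_strings(cls, response: str, terms: Sequence[str], name: str = "") -> "DesignSpec":
        return cls(response, tuple(parse_term(t) for t in terms), name or " + ".join(terms))

    def label(self) -> str:
        return self.name or (" + ".join(t.name for t in self.terms) or "null")

    def term_names(self) -> set[str]:
        return {t.name for t in self.terms}

    def build_matrix(
        self,
        data: pd.DataFrame,
        levels: Mapping[str, Sequence[str]] | None = None,
    ) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
        """Design matrix with intercept; returns (X, columns, levels_used).

        Categorical levels default to the sorted levels observed in the
        data with the declared reference first; pass ``levels`` (e.g.
        from a previous fit) to pin the coding for prediction.
        """
        n = len(data)
        cols: list[np.ndarray] = [np.ones(n)]
        names: list[str] = ["intercept"]
        levels_used: dict[str, list[str]] = {}
        for term in self.terms:
            if term.name not in data.columns:
                raise FitError(f"design needs column {term.name!r}")
            col = data[term.name]
            if term.kind == "categorical":
                values = col.astype(str).to_numpy()
                if levels and term.name in levels:
                    lv = list(levels[term.name])
                else:
                    observed = sorted(set(values))
                    if term.reference not in observed:
                        observed.append(term.reference)
                    lv = [term.reference] + [l for l in sorted(observed)
                                             if l != term.reference]
                unknown = sorted(set(values) - set(lv))
                if unknown:
                    raise FitError(
                        f"unknown level(s) {unknown} for {term.name!r}; "
                        f"known levels {lv}")
                levels_used[term.name] = lv
                for level in lv[1:]:
                    cols.append((values == level).astype(float))
                    names.append(f"{term.name}.{level}")
            else:
                x = col.to_numpy(dtype=float)
                if term.kind in ("log10", "sq_log10"):
                    if np.any(x <= 0):
                        raise FitError(
                            f"{term.name!r}: log10 transform needs positive values")
                    x = np.log10(x)
                    if term.kind == "sq_log10":
                        x = x**2
                cols.append(x)
                names.append(term.name if term.kind == "continuous"
                             else f"{term.kind}({term.name})")
        return np.column_stack(cols), names, levels_used


@dataclass(frozen=True)
class FittedModel:
    """A fitted binomial-logit GLM with its diagnostics."""

    design: DesignSpec
    columns: tuple[str, ...]
    coefficients: tuple[float, ...]
    standard_errors: tuple[float, ...]
    loglik: float
    n: int
    converged: bool
    separation_flag: bool
    term_levels: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def k_params(self) -> int:
        return len(self.coefficients)

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.columns, self.coefficients))

    def wald_table(self) -> pd.DataFrame:
        """Coefficients with SEs, z-values and normal-theory p-values."""
        beta = np.asarray(self.coefficients)
        se = np.asarray(self.standard_errors)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        return pd.DataFrame({
            "parameter": list(self.columns),
            "estimate": beta,
            "se": se,
            "z": z,
            "p": 2 * scipy.stats.norm.sf(np.abs(z)),
        })

    def aicc(self) -> float:
        return aicc(self.loglik, self.k_params, self.n)

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        X, names, _ = self.design.build_matrix(
            data, levels={k: list(v) for k, v in self.term_levels.items()})
        if list(names) != list(self.columns):
            raise FitError(
                f"prediction design {names} does not match fit {list(self.columns)}")
        return X @ np.asarray(self.coefficients)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return inv_logit(self.linear_predictor(data))

    def to_json(self) -> str:
        return json.dumps({
            "model": self.design.label(),
            "response": self.design.response,
            "coefficients": self.params,
            "standard_errors": dict(zip(self.columns, self.standard_errors)),
            "loglik": self.loglik,
            "n": self.n,
            "K": self.k_params,
            "converged": self.converged,
            "separation_flag": self.separation_flag,
            "term_levels": {k: list(v) for k, v in self.term_levels.items()},
        }, indent=2)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via the QR decomposition
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [names[j] for j in range(X.shape[1]) if diag[j] <= tol]
        raise FitError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"aliased terms: {aliased or 'undetermined'}")


def _ridge_irls(X: np.ndarray, y: np.ndarray, ridge: float,
                max_iter: int = 200, tol: float = 1e-10):
    """Newton/IRLS with an L2 penalty on all coefficients but the intercept."""
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, ridge)
    pen[0] = 0.0
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = inv_logit(eta)
        W = mu * (1 - mu)
        score = X.T @ (y - mu) - pen * beta
        H = (X.T * W) @ X + np.diag(pen)
        beta = beta + np.linalg.solve(H, score)
        mu = inv_logit(X @ beta)
        ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) +
                          (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
        if np.max(np.abs(score)) < 1e-8 or abs(ll - ll_old) < tol * max(1, abs(ll)):
            break
        ll_old = ll
    cov = np.linalg.inv((X.T * (mu * (1 - mu))) @ X + np.diag(pen))
    return beta, np.sqrt(np.diag(cov)), ll, True


def fit_logistic(
    design: DesignSpec,
    data: pd.DataFrame,
    ridge: float = 0.0,
) -> FittedModel:
    """Maximum-likelihood logistic regression.

    Raises :class:`FitError` for a non-binary or single-class response,
    a rank-deficient design (naming the aliased terms), or failure to
    converge. Quasi-complete separation (fitted probabilities within
    1e-8 of 0 or 1) is flagged, not fatal; set ``ridge`` > 0 to add a
    small L2 stabilizer when separation is a problem.
    """
    if design.response not in data.columns:
        raise FitError(f"response column {design.response!r} missing")
    y = data[design.response].to_numpy(dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise FitError(f"response must be binary 0/1, saw values {classes[:5]}")
    if len(classes) < 2:
        raise FitError(
            "degenerate response: all observations are "
            f"{int(classes[0])}; the model cannot be estimated")
    X, names, levels_used = design.build_matrix(data)
    if len(y) < X.shape[1]:
        raise FitError(
            f"n={len(y)} observations for {X.shape[1]} parameters")
    _check_rank(X, names)

    if ridge > 0:
        beta, se, ll, converged = _ridge_irls(X, y, ridge)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                    maxiter=200, tol=1e-10)
            except Exception as exc:
                raise FitError(f"IRLS failed for {design.label()!r}: {exc}") from exc
            converged = bool(getattr(res, "converged", True))
            if not converged:
                raise FitError(
                    f"IRLS did not converge for {design.label()!r} "
                    f"after {res.fit_history['iteration']} iterations")
            beta, se, ll = np.asarray(res.params), np.asarray(res.bse), float(res.llf)

    mu = inv_logit(X @ np.asarray(beta))
    separation = bool(np.any(mu < 1e-8) or np.any(mu > 1 - 1e-8))
    return FittedModel(
        design=design,
        columns=tuple(names),
        coefficients=tuple(float(b) for b in beta),
        standard_errors=tuple(float(s) for s in se),
        loglik=float(ll),
        n=len(y),
        converged=converged,
        separation_flag=separation,
        term_levels={k: tuple(v) for k, v in levels_used.items()},
    )


def aicc(loglik: float, k_params: int, n: int) -> float:
    """Small-sample-corrected AIC: -2 logL + 2K + 2K(K+1)/(n-K-1)."""
    if n <= k_params + 1:
        raise FitError(f"AICc undefined for n={n}, K={k_params}")
    return -2.0 * loglik + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n - k_params - 1)


def akaike_weights(aicc_scores: Sequence[float]) -> np.ndarray:
    """Normalized evidence weights exp(-d/2) / sum exp(-d/2)."""
    scores = np.asarray(aicc_scores, dtype=float)
    if scores.size == 0 or not np.all(np.isfinite(scores)):
        raise FitError("AICc scores must be a non-empty finite sequence")
    rel = np.exp(-(scores - scores.min()) / 2.0)
    return rel / rel.sum()


@dataclass(frozen=True)
class RankEntry:
    design: DesignSpec
    model: FittedModel | None
    aicc: float
    delta: float
    weight: float


@dataclass(frozen=True)
class ModelRanking:
    entries: tuple[RankEntry, ...]
    #: entries within 2 AICc units of the best model
    confidence_threshold: float = 2.0

    @property
    def confidence_set(self) -> tuple[RankEntry, ...]:
        return tuple(e for e in self.entries if e.delta <= self.confidence_threshold)

    @property
    def best(self) -> RankEntry:
        return self.entries[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": [e.design.label() for e in self.entries],
            "K": [e.model.k_params if e.model else np.nan for e in self.entries],
            "AICc": [e.aicc for e in self.entries],
            "dAICc": [e.delta for e in self.entries],
            "w": [e.weight for e in self.entries],
        })


def rank_models(designs: Sequence[DesignSpec], data: pd.DataFrame) -> ModelRanking:
    """Fit every candidate on the same data and rank by AICc.

    Candidates that fail to fit are dropped with a warning so one bad
    design does not abort the whole ranking.
    """
    fitted: list[tuple[DesignSpec, FittedModel, float]] = []
    for design in designs:
        try:
            model = fit_logistic(design, data)
            fitted.append((design, model, model.aicc()))
        except FitError as exc:
            warnings.warn(
                f"dropping candidate {design.label()!r} from ranking: {exc}",
                stacklevel=2)
    if not fitted:
        raise FitError("no candidate model could be fitted")
    scores = [s for _, _, s in fitted]
    weights = akaike_weights(scores)
    best = min(scores)
    entries = sorted(
        (RankEntry(d, m, s, s - best, float(w))
         for (d, m, s), w in zip(fitted, weights)),
        key=lambda e: e.aicc)
    return ModelRanking(tuple(entries))


def rank_from_scores(labels: Sequence[str], aicc_scores: Sequence[float]) -> pd.DataFrame:
    """Ranking table (dAICc, w) recomputed from published AICc scores."""
    scores = np.asarray(aicc_scores, dtype=float)
    w = akaike_weights(scores)
    df = pd.DataFrame({"model": list(labels), "AICc": scores,
                       "dAICc": scores - scores.min(), "w": w})
    return df.sort_values("AICc", ignore_index=True)


def nagelkerke_r2(model: FittedModel, null_model: FittedModel) -> float:
    """Nagelkerke's rescaled likelihood-ratio pseudo R-squared."""
    if model.n != null_model.n:
        raise FitError(
            f"model (n={model.n}) and null (n={null_model.n}) must share data")
    n = model.n
    cox_snell = 1.0 - np.exp(2.0 * (null_model.loglik - model.loglik) / n)
    max_r2 = 1.0 - np.exp(2.0 * null_model.loglik / n)
    return float(cox_snell / max_r2)


@dataclass(frozen=True)
class LrtResult:
    G2: float
    df: int
    p_value: float


def lr_test(nested: FittedModel, full: FittedModel) -> LrtResult:
    """G-squared likelihood-ratio test of a nested model against a full one."""
    if nested.n != full.n:
        raise FitError("nested and full models must be fitted to the same data")
    if not nested.design.term_names() <= full.design.term_names():
        raise FitError(
            f"{nested.design.label()!r} is not nested in {full.design.label()!r}")
    df = full.k_params - nested.k_params
    if df < 0:
        raise FitError("nested model has more parameters than the full model")
    g2 = max(0.0, 2.0 * (full.loglik - nested.loglik))
    p = 1.0 if df == 0 else float(scipy.stats.chi2.sf(g2, df))
    if df == 0 and g2 > 1e-8:
        raise FitError("models have equal K but different likelihoods: not nested")
    return LrtResult(G2=g2, df=df, p_value=p)


def predict_prob(model: FittedModel, covariates: Mapping[str, object] | pd.DataFrame):
    """Predicted probability for one covariate mapping or a data frame."""
    if isinstance(covariates, pd.DataFrame):
        return model.predict(covariates)
    row = pd.DataFrame({k: [v] for k, v in covariates.items()})
    return float(model.predict(row)[0])
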