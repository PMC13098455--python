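"""Maxdiff conditional logit estimation for best-worst scaling data.

Each task with attribute set S (|S| = k) is expanded into the k(k-1)
ordered (best, worst) pairs; the pair actually picked is the chosen
alternative.  Pair (b, w) has systematic utility u_b - u_w, with the
reference attribute's utility fixed at 0 for identification, giving the
conditional-logit probability

    P(b, w | S) = exp(u_b - u_w) / sum_{i != j in S} exp(u_i - u_j).

At beta = 0 every pair is equally likely, so the null log-likelihood is
-T * log(k(k-1)) for T tasks — with k = 3 that is -T * log 6.

Coefficients are estimated by maximum likelihood (quasi-Newton from
beta = 0 with the analytic gradient).  Classical standard errors come from
the inverse observed information; robust standard errors from the sandwich
estimator with scores summed within cluster — by default the respondent,
the natural dependence unit when each person answers several tasks.
McFadden's pseudo-R^2, AIC and BIC complete the fit summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import SurveyDataset, BWResponse, ordered_pairs

__all__ = [
    "CLMFit",
    "SubgroupSpec",
    "FitStats",
    "expand_task",
    "collapse_expansion",
    "loglik",
    "fit",
    "fit_stats",
    "subgroup_fit",
    "subgroup_table",
    "significance_stars",
    "DivergenceWarning",
]

#: |beta| beyond which a coefficient is reported as diverging (separation:
#: an attribute always or never picked when shown drives its MLE to +-inf).
_DIVERGENCE_BOUND = 10.0


class DivergenceWarning(UserWarning):
    """A coefficient appears unbounded (quasi-complete separation)."""


class FitStats(NamedTuple):
    ll_null: float
    pseudo_r2: float
    aic: float
    bic: float


@dataclass(frozen=True)
class ExpandedTask:
    """One task rendered as its k(k-1) pair alternatives."""

    task_id: int
    pairs: tuple[tuple[str, str], ...]
    chosen: int  # index into pairs

    @property
    def chosen_pair(self) -> tuple[str, str]:
        return self.pairs[self.chosen]


@dataclass(frozen=True)
class SubgroupSpec:
    """A two-category partition of the roster by one demographic variable."""

    variable: str
    categories: tuple[str, str]


@dataclass
class CLMFit:
    """Fitted maxdiff conditional logit model."""

    reference: str
    codes: tuple[str, ...]  # non-reference attributes, estimation order
    beta: np.ndarray
    robust_se: np.ndarray
    classical_se: np.ndarray
    ll_null: float
    ll_model: float
    pseudo_r2: float
    aic: float
    bic: float
    n_obs: int
    n_respondents: int
    K: int
    converged: bool
    cluster: str = "respondent"
    diverging: tuple[str, ...] = ()
    message: str = ""
    vcov_robust: np.ndarray | None = None
    vcov_classical: np.ndarray | None = None

    @property
    def z_values(self) -> np.ndarray:
        return self.beta / self.robust_se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z_values))

    @property
    def p_stars(self) -> list[str]:
        return [significance_stars(p) for p in self.p_values]

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """(K, 2) robust Wald confidence intervals."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack(
            [self.beta - z * self.robust_se, self.beta + z * self.robust_se]
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy coefficient table (one row per non-reference attribute)."""
        return pd.DataFrame(
            {
                "coefficient": self.beta,
                "robust_se": self.robust_se,
                "classical_se": self.classical_se,
                "z": self.z_values,
                "p": self.p_values,
                "stars": self.p_stars,
            },
            index=pd.Index(self.codes, name="attribute"),
        )

    def summary_rows(self) -> dict[str, float | int | str]:
        return {
            "reference": self.reference,
            "n_obs": self.n_obs,
            "n_respondents": self.n_respondents,
            "ll_null": self.ll_null,
            "ll_model": self.ll_model,
            "pseudo_r2": self.pseudo_r2,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
        }


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def expand_task(task: Sequence[str], response: BWResponse) -> ExpandedTask:
    """Expand a task into ordered-pair alternatives, marking the chosen one."""
    attrs = tuple(task)
    if response.best not in attrs or response.worst not in attrs:
        raise ValueError(
            f"response picks ({response.best}, {response.worst}) "
            f"not both in task {attrs}"
        )
    pairs = tuple(ordered_pairs(attrs))
    chosen = pairs.index((response.best, response.worst))
    return ExpandedTask(task_id=response.task_id, pairs=pairs, chosen=chosen)


def collapse_expansion(expanded: ExpandedTask) -> tuple[str, str]:
    """Recover the (best, worst) pick from an expanded task."""
    return expanded.chosen_pair


@dataclass
class _DesignArrays:
    """Responses encoded against the stack of unique task design matrices.

    ``X`` is (U, A, K): one pair-difference matrix per distinct task
    composition, A = k(k-1) alternatives, columns the non-reference
    attributes (+1 on best, -1 on worst).  ``uidx[n]`` maps response n to
    its task's row in ``X``; ``chosen[n]`` is the picked alternative;
    ``clusters[n]`` the respondent index.
    """

    codes: tuple[str, ...]
    X: np.ndarray
    uidx: np.ndarray
    chosen: np.ndarray
    clusters: np.ndarray

    @property
    def n_tasks(self) -> int:
        return len(self.uidx)

    def counts(self) -> np.ndarray:
        """(U, A) matrix of how often each alternative was chosen."""
        c = np.zeros(self.X.shape[:2])
        np.add.at(c, (self.uidx, self.chosen), 1.0)
        return c


def _design_arrays(dataset: SurveyDataset, reference: str) -> _DesignArrays:
    all_codes = dataset.attribute_codes
    if reference not in all_codes:
        raise ValueError(f"reference {reference!r} not among attributes {all_codes}")
    codes = tuple(c for c in all_codes if c != reference)
    col = {c: j for j, c in enumerate(codes)}
    K = len(codes)

    # one design matrix per distinct task composition; all tasks in a BIBD
    # have the same size k, hence the same alternative count k(k-1)
    task_u: dict[int, int] = {}
    task_pairs: dict[int, list[tuple[str, str]]] = {}
    X_rows: list[np.ndarray] = []
    for t in dataset.design:
        pairs = ordered_pairs(t.attributes)
        X = np.zeros((len(pairs), K))
        for a, (b, w) in enumerate(pairs):
            if b != reference:
                X[a, col[b]] += 1.0
            if w != reference:
                X[a, col[w]] -= 1.0
        task_u[t.task_id] = len(X_rows)
        task_pairs[t.task_id] = pairs
        X_rows.append(X)
    n_alts = {x.shape[0] for x in X_rows}
    if len(n_alts) != 1:
        raise ValueError(f"tasks have mixed sizes (alternative counts {sorted(n_alts)})")

    resp_index = {r.id: i for i, r in enumerate(dataset.roster)}
    N = len(dataset.responses)
    uidx = np.empty(N, dtype=int)
    chosen = np.empty(N, dtype=int)
    clusters = np.empty(N, dtype=int)
    for n, resp in enumerate(dataset.responses):
        uidx[n] = task_u[resp.task_id]
        chosen[n] = task_pairs[resp.task_id].index((resp.best, resp.worst))
        clusters[n] = resp_index[resp.respondent_id]
    return _DesignArrays(
        codes=codes, X=np.stack(X_rows), uidx=uidx, chosen=chosen, clusters=clusters
    )


def loglik(
    beta: Sequence[float],
    dataset: SurveyDataset,
    reference: str,
    return_grad: bool = False,
):
    """Log-likelihood (and analytic gradient) of the maxdiff pair model.

    ``beta`` holds one coefficient per non-reference attribute, in the order
    of ``dataset.attribute_codes`` with the reference removed.
    """
    arrays = _design_arrays(dataset, reference)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(arrays.codes),):
        raise ValueError(
            f"beta must have length {len(arrays.codes)} (got {beta.shape})"
        )
    ll, grad = _loglik_core(beta, arrays)
    if return_grad:
        return ll, grad
    return ll


def _loglik_core(beta: np.ndarray, arrays: _DesignArrays) -> tuple[float, np.ndarray]:
    """Vectorised log-likelihood and gradient over unique task matrices."""
    eta = arrays.X @ beta  # (U, A)
    lse = special.logsumexp(eta, axis=1)  # (U,)
    ll = float(np.sum(eta[arrays.uidx, arrays.chosen] - lse[arrays.uidx]))
    p = np.exp(eta - lse[:, None])  # (U, A)
    counts = arrays.counts()  # (U, A)
    n_u = counts.sum(axis=1)  # tasks per unique composition
    mean_x = np.einsum("ua,uak->uk", p, arrays.X)  # (U, K)
    grad = (
        np.einsum("ua,uak->k", counts, arrays.X) - n_u @ mean_x
    )
    return ll, grad


def _scores_and_information(
    beta: np.ndarray, arrays: _DesignArrays
) -> tuple[np.ndarray, np.ndarray]:
    """Per-task score vectors and the observed information at ``beta``."""
    eta = arrays.X @ beta
    p = np.exp(eta - special.logsumexp(eta, axis=1)[:, None])
    mean_x = np.einsum("ua,uak->uk", p, arrays.X)  # (U, K)
    scores = (
        arrays.X[arrays.uidx, arrays.chosen] - mean_x[arrays.uidx]
    )  # (N, K)
    n_u = np.bincount(arrays.uidx, minlength=arrays.X.shape[0]).astype(float)
    per_task_info = np.einsum("uak,ua,ual->ukl", arrays.X, p, arrays.X) - np.einsum(
        "uk,ul->ukl", mean_x, mean_x
    )
    info = np.einsum("u,ukl->kl", n_u, per_task_info)
    return scores, info


def fit_stats(ll_model: float, n_tasks: int, k: int, K: int) -> FitStats:
    """Null log-likelihood, McFadden pseudo-R^2, AIC and BIC.

    The null model (all utilities equal) puts probability 1/(k(k-1)) on
    every ordered pair, so ``ll_null = -n_tasks * log(k*(k-1))``.
    """
    if n_tasks <= 0:
        raise ValueError("n_tasks must be positive")
    if k < 2:
        raise ValueError("tasks need at least 2 attributes")
    ll_null = -n_tasks * np.log(k * (k - 1))
    return FitStats(
        ll_null=ll_null,
        pseudo_r2=1.0 - ll_model / ll_null,
        aic=-2.0 * ll_model + 2.0 * K,
        bic=-2.0 * ll_model + K * np.log(n_tasks),
    )


def fit(
    dataset: SurveyDataset,
    reference: str | None = None,
    cluster: str = "respondent",
    gtol: float = 1e-6,
    maxiter: int = 500,
) -> CLMFit:
    """Fit the maxdiff conditional logit by maximum likelihood.

    Parameters
    ----------
    dataset
        Validated survey dataset.
    reference
        Attribute whose utility is fixed at 0.  Default: the attribute with
        the lowest aggregate best-minus-worst count (the least important
        one, keeping the remaining coefficients positive in typical data).
    cluster
        ``"respondent"`` (default) sums scores within respondent for the
        sandwich estimator; ``"task"`` treats every task as its own cluster
        (heteroskedasticity-robust only).
    """
    dataset.validate()
    if not dataset.responses:
        raise ValueError("dataset has no responses")
    if reference is None:
        reference = _default_reference(dataset)
    if cluster not in ("respondent", "task"):
        raise ValueError(f"unknown cluster unit {cluster!r}")

    arrays = _design_arrays(dataset, reference)
    codes = arrays.codes
    K = len(codes)
    T = arrays.n_tasks

    def objective(b: np.ndarray) -> tuple[float, np.ndarray]:
        ll, grad = _loglik_core(b, arrays)
        return -ll, -grad

    res = optimize.minimize(
        objective,
        x0=np.zeros(K),
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    beta = res.x
    ll_model, grad = _loglik_core(beta, arrays)
    converged = bool(res.success) and float(np.max(np.abs(grad))) < max(gtol * 10, 1e-4)

    diverging = tuple(codes[j] for j in np.flatnonzero(np.abs(beta) > _DIVERGENCE_BOUND))
    if diverging:
        warnings.warn(
            f"coefficients for {diverging} exceed |{_DIVERGENCE_BOUND}|: likely "
            "separation (attribute always/never picked when shown); standard "
            "errors are unreliable",
            DivergenceWarning,
            stacklevel=2,
        )

    scores, info = _scores_and_information(beta, arrays)
    try:
        bread = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        bread = np.linalg.pinv(info)
    vcov_classical = bread

    cluster_ids = arrays.clusters if cluster == "respondent" else np.arange(T)
    G = len(np.unique(cluster_ids))
    cluster_scores = np.zeros((cluster_ids.max() + 1, K))
    np.add.at(cluster_scores, cluster_ids, scores)
    meat = cluster_scores.T @ cluster_scores
    correction = G / (G - 1) if G > 1 else 1.0
    vcov_robust = correction * bread @ meat @ bread

    k_task = len(dataset.design[0].attributes)
    stats_ = fit_stats(ll_model, T, k_task, K)

    return CLMFit(
        reference=reference,
        codes=codes,
        beta=beta,
        robust_se=np.sqrt(np.diag(vcov_robust)),
        classical_se=np.sqrt(np.diag(vcov_classical)),
        ll_null=stats_.ll_null,
        ll_model=ll_model,
        pseudo_r2=stats_.pseudo_r2,
        aic=stats_.aic,
        bic=stats_.bic,
        n_obs=T,
        n_respondents=dataset.n_respondents,
        K=K,
        converged=converged,
        cluster=cluster,
        diverging=diverging,
        message=str(res.message),
        vcov_robust=vcov_robust,
        vcov_classical=vcov_classical,
    )


def _default_reference(dataset: SurveyDataset) -> str:
    bw: dict[str, int] = {c: 0 for c in dataset.attribute_codes}
    for resp in dataset.responses:
        bw[resp.best] += 1
        bw[resp.worst] -= 1
    return min(bw, key=lambda c: (bw[c], c))


def subgroup_fit(
    dataset: SurveyDataset,
    spec: SubgroupSpec,
    reference: str | None = None,
    cluster: str = "respondent",
) -> dict[str, CLMFit]:
    """Fit the model independently on each category of a demographic split.

    Returns ``{category: CLMFit}``.  A category too small for identification
    yields a fit flagged ``converged=False`` (or with diverging coefficients)
    rather than an exception; an empty category is an error.
    """
    if reference is None:
        reference = _default_reference(dataset)
    fits: dict[str, CLMFit] = {}
    for category in spec.categories:
        members = [r for r in dataset.roster if r.demographic(spec.variable) == category]
        if not members:
            raise ValueError(f"subgroup {spec.variable}={category!r} has no respondents")
        ids = {r.id for r in members}
        subset = SurveyDataset(
            roster=members,
            design=dataset.design,
            responses=[resp for resp in dataset.responses if resp.respondent_id in ids],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("always", DivergenceWarning)
            fits[category] = fit(subset, reference=reference, cluster=cluster)
    return fits


def subgroup_table(
    dataset: SurveyDataset,
    specs: Sequence[SubgroupSpec],
    reference: str | None = None,
    cluster: str = "respondent",
) -> pd.DataFrame:
    """Stacked subgroup results: one row per (variable, category, attribute).

    The long format carries coefficient, robust SE, p and stars, ready to be
    pivoted into a wide attributes-as-columns report.
    """
    rows = []
    for spec in specs:
        for category, clm in subgroup_fit(
            dataset, spec, reference=reference, cluster=cluster
        ).items():
            frame = clm.to_frame().reset_index()
            frame.insert(0, "subgroup", spec.variable)
            frame.insert(1, "category", category)
            frame.insert(2, "n_respondents", clm.n_respondents)
            rows.append(frame)
    return pd.concat(rows, ignore_index=True)
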