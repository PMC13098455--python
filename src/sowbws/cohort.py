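"""Synthetic respondent cohorts and simulated best-worst choices.

The study population is farrow-to-wean site managers answering seven
choice tasks, each showing three of seven nurse-sow selection attributes.
Real individual-level responses are not publicly available, so this module
generates cohorts with the study's demographic structure and simulates
their (best, worst) picks under a maxdiff utility model:

    P(best=b, worst=w | task) = exp(u_b - u_w) / sum_{i != j} exp(u_i - u_j)

with the sum over all ordered pairs of distinct attributes in the task.
This joint pair likelihood is the same family the estimation module fits,
and its null value for a 3-attribute task is log(1/6) per task.

Randomness is handled with one master seed plus deterministic per-respondent
substreams, so editing the cohort size does not reshuffle the choices of
respondents that were already present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .design import ChoiceTask

__all__ = [
    "Respondent",
    "UtilityProfile",
    "BWResponse",
    "SurveyDataset",
    "DEFAULT_STRATA",
    "DEFAULT_UTILITIES",
    "simulate_respondents",
    "maxdiff_pair_probabilities",
    "ordered_pairs",
    "simulate_choices",
]

#: Demographic variables, their two categories (listed smaller-share first
#: where the observed cohort was unbalanced), and the observed proportions
#: in the 51-manager cohort.
DEFAULT_STRATA: dict[str, dict[str, float]] = {
    "gender": {"female": 18 / 51, "male": 33 / 51},
    "age_band": {"18-40": 24 / 51, ">40": 27 / 51},
    "experience_band": {"<=10yr": 26 / 51, ">10yr": 25 / 51},
    "education": {"college": 15 / 51, "professional": 36 / 51},
    "herd_band": {"<=5000": 19 / 51, ">5000": 32 / 51},
}

DEMOGRAPHIC_FIELDS = tuple(DEFAULT_STRATA)

#: Illustrative generating utilities per attribute code, anchored at
#: parity (P) = 0.  These are the pooled conditional-logit point estimates
#: reported for the real cohort; here they serve only as a plausible
#: simulation scenario, not as ground truth about any population.
DEFAULT_UTILITIES: dict[str, float] = {
    "SCLH": 1.744,
    "BCS": 1.455,
    "SCLS": 0.811,
    "STN": 0.697,
    "LS": 0.485,
    "SB": 0.431,
    "P": 0.0,
}


@dataclass(frozen=True)
class Respondent:
    id: str
    gender: str
    age_band: str
    experience_band: str
    education: str
    herd_band: str

    def demographic(self, variable: str) -> str:
        if variable not in DEMOGRAPHIC_FIELDS:
            raise KeyError(f"unknown demographic variable: {variable!r}")
        return getattr(self, variable)


@dataclass(frozen=True)
class UtilityProfile:
    """Latent attribute utilities with the reference attribute fixed at 0."""

    utilities: Mapping[str, float]
    reference: str = "P"

    def __post_init__(self) -> None:
        if self.reference not in self.utilities:
            raise ValueError(f"reference {self.reference!r} absent from utilities")
        if self.utilities[self.reference] != 0.0:
            raise ValueError("reference attribute utility must be exactly 0")

    def __getitem__(self, code: str) -> float:
        try:
            return self.utilities[code]
        except KeyError:
            raise KeyError(f"attribute {code!r} has no utility entry") from None


@dataclass(frozen=True)
class BWResponse:
    respondent_id: str
    task_id: int
    best: str
    worst: str

    def __post_init__(self) -> None:
        if self.best == self.worst:
            raise ValueError(
                f"respondent {self.respondent_id}, task {self.task_id}: best == worst"
            )


@dataclass
class SurveyDataset:
    """A roster, a bound task design, and one (best, worst) pick per
    (respondent, task) pair."""

    roster: list[Respondent]
    design: list[ChoiceTask]
    responses: list[BWResponse] = field(default_factory=list)

    def validate(self) -> None:
        """Raise ValueError on any structural violation."""
        ids = [r.id for r in self.roster]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate respondent ids in roster")
        task_attrs = {t.task_id: set(t.attributes) for t in self.design}
        seen: set[tuple[str, int]] = set()
        for resp in self.responses:
            key = (resp.respondent_id, resp.task_id)
            if key in seen:
                raise ValueError(f"duplicate response for {key}")
            seen.add(key)
            if resp.task_id not in task_attrs:
                raise ValueError(f"response references unknown task {resp.task_id}")
            members = task_attrs[resp.task_id]
            if resp.best not in members or resp.worst not in members:
                raise ValueError(
                    f"respondent {resp.respondent_id}, task {resp.task_id}: "
                    f"picks ({resp.best}, {resp.worst}) not in task {sorted(members)}"
                )
        expected = len(self.roster) * len(self.design)
        if len(self.responses) != expected:
            raise ValueError(
                f"expected {expected} responses "
                f"({len(self.roster)} respondents x {len(self.design)} tasks), "
                f"got {len(self.responses)}"
            )

    @property
    def n_respondents(self) -> int:
        return len(self.roster)

    @property
    def n_tasks(self) -> int:
        return len(self.responses)

    @property
    def attribute_codes(self) -> list[str]:
        seen: dict[str, None] = {}
        for task in self.design:
            for code in task.attributes:
                seen.setdefault(code)
        return list(seen)


def _validate_strata(strata: Mapping[str, Mapping[str, float]]) -> None:
    for variable, cats in strata.items():
        total = 0.0
        for cat, p in cats.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{variable}/{cat}: proportion {p} outside [0, 1]")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{variable}: proportions sum to {total}, not 1")


def simulate_respondents(
    n: int,
    strata: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    mode: str = "quota",
) -> list[Respondent]:
    """Generate ``n`` respondents with the given demographic composition.

    In ``quota`` mode each variable independently receives exactly
    ``round(n * p)`` respondents in its first category (any rounding
    remainder goes to the larger category), shuffled so that variables are
    mutually independent.  In ``multinomial`` mode each respondent's
    category is drawn independently.  Variables are simulated independently
    of one another: only marginal shares are known for the real cohort.
    """
    if n < 0:
        raise ValueError("cohort size must be non-negative")
    if mode not in ("quota", "multinomial"):
        raise ValueError(f"unknown mode {mode!r}")
    if strata is None:
        strata = DEFAULT_STRATA
    _validate_strata(strata)
    missing = [v for v in DEMOGRAPHIC_FIELDS if v not in strata]
    if missing:
        raise ValueError(f"strata missing variables: {missing}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    assignments: dict[str, list[str]] = {}
    for variable in DEMOGRAPHIC_FIELDS:
        cats = list(strata[variable].items())
        if mode == "quota":
            # round(n*p) per category; remainder to the larger category
            counts = [round(n * p) for _, p in cats]
            remainder = n - sum(counts)
            larger = max(range(len(cats)), key=lambda i: cats[i][1])
            counts[larger] += remainder
            labels = np.repeat([c for c, _ in cats], counts)
            rng.shuffle(labels)
        else:
            labels = rng.choice(
                [c for c, _ in cats], size=n, p=[p for _, p in cats]
            )
        assignments[variable] = [str(c) for c in labels]

    width = max(len(str(n)), 3)
    return [
        Respondent(
            id=f"R{i + 1:0{width}d}",
            **{variable: assignments[variable][i] for variable in DEMOGRAPHIC_FIELDS},
        )
        for i in range(n)
    ]


def ordered_pairs(task: Sequence[str]) -> list[tuple[str, str]]:
    """All k(k-1) ordered (best, worst) pairs of a task, in a fixed order."""
    return [(b, w) for b in task for w in task if b != w]


def maxdiff_pair_probabilities(
    utilities: UtilityProfile | Mapping[str, float],
    task: Sequence[str],
) -> dict[tuple[str, str], float]:
    """Choice probabilities over the ordered (best, worst) pairs of a task.

    ``P(b, w) = exp(u_b - u_w) / sum over ordered pairs exp(u_i - u_j)``.
    The probabilities sum to 1; equal utilities give the uniform 1/(k(k-1)).
    """
    if len(task) < 2:
        raise ValueError("a task needs at least 2 attributes")
    if len(set(task)) != len(task):
        raise ValueError(f"task has duplicate attributes: {task}")
    u = {code: utilities[code] for code in task}
    pairs = ordered_pairs(task)
    # stabilise: subtracting max(diff) cancels in the ratio
    diffs = np.array([u[b] - u[w] for b, w in pairs], dtype=float)
    diffs -= diffs.max()
    weights = np.exp(diffs)
    probs = weights / weights.sum()
    return dict(zip(pairs, probs))


def _respondent_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), 1, int(index)]))


def simulate_choices(
    roster: Sequence[Respondent],
    design: Sequence[ChoiceTask],
    utilities,
    seed: int = 0,
) -> SurveyDataset:
    """Simulate one (best, worst) pick per respondent per task.

    ``utilities`` resolves each respondent to a :class:`UtilityProfile`:
    it may be a single profile (homogeneous cohort), a callable
    ``respondent -> UtilityProfile``, or a mapping from a respondent's
    category on some variable — e.g. ``{("gender", "female"): profile, ...}``.
    """

    def resolve(resp: Respondent) -> UtilityProfile:
        if isinstance(utilities, UtilityProfile):
            return utilities
        if callable(utilities):
            return utilities(resp)
        for (variable, category), profile in utilities.items():
            if resp.demographic(variable) == category:
                return profile
        raise ValueError(f"no utility profile resolves respondent {resp.id}")

    # probabilities depend only on (profile, task); cache the cumulative
    # distribution so large cohorts do not recompute per respondent
    cdf_cache: dict[tuple[int, int], tuple[list[tuple[str, str]], np.ndarray]] = {}

    def task_cdf(profile: UtilityProfile, task: ChoiceTask):
        key = (id(profile), task.task_id)
        if key not in cdf_cache:
            probs = maxdiff_pair_probabilities(profile, task.attributes)
            cdf_cache[key] = (list(probs), np.cumsum(list(probs.values())))
        return cdf_cache[key]

    responses: list[BWResponse] = []
    for i, resp in enumerate(roster):
        profile = resolve(resp)
        rng = _respondent_rng(seed, i)
        for task in design:
            pairs, cdf = task_cdf(profile, task)
            idx = int(np.searchsorted(cdf, rng.random(), side="right"))
            idx = min(idx, len(pairs) - 1)
            best, worst = pairs[idx]
            responses.append(
                BWResponse(
                    respondent_id=resp.id, task_id=task.task_id, best=best, worst=worst
                )
            )
    dataset = SurveyDataset(roster=list(roster), design=list(design), responses=responses)
    dataset.validate()
    return dataset
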