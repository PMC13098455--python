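"""Counting-approach statistics for best-worst scaling data.

For each attribute j over T tasks (T = N respondents x b tasks each):

* best count B_j, worst count W_j, and their percentages of T;
* best-worst value  BW_j = B_j - W_j  (conserved: sum_j BW_j = 0);
* standard value  BW_j / (N * r), where r is the number of tasks each
  attribute appears in, so the scale is [-1, 1];
* square-root ratio  sqrt(B_j / W_j), an individual-scale-free importance
  ratio;
* relative importance  100 * sqrt_ratio_j / max_j sqrt_ratio, so the top
  attribute scores 100;
* dense rank by relative importance, descending.

Two alternative literal min-max rescalings, ``std_minmax`` (of BW onto
[0, 1]) and ``relative_minmax`` (onto [0, 100]), are also emitted as
optional columns; they are a different normalisation sometimes quoted for
BWS tables, but the (N*r)-scaled and sqrt-ratio-scaled columns above are
the ones consistent with the published aggregate table for this survey.

Per-respondent scores s_ij = (best picks - worst picks of attribute j by
respondent i) live on {-r, ..., +r} and aggregate to BW_j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import SurveyDataset

__all__ = [
    "CountSummary",
    "ScoreDistribution",
    "tally",
    "summarize",
    "reconstruct_counts_from_percentages",
    "score_distribution",
]


@dataclass
class CountSummary:
    """Aggregate counting-approach table, one row per attribute."""

    table: pd.DataFrame  # indexed by attribute code
    n_respondents: int
    appearances: int  # r: tasks each attribute appears in
    continuity_correction: bool = False
    tied_ranks: bool = False

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        """Display table rounded half-away-from-zero to ``decimals``."""
        out = self.table.copy()
        factor = 10 ** decimals
        for col in out.columns:
            if out[col].dtype.kind == "f":
                x = out[col].to_numpy()
                out[col] = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
        return out


@dataclass
class ScoreDistribution:
    """Per-attribute histogram of respondent scores and task-level
    best / unchosen / worst counts."""

    histogram: pd.DataFrame  # index: attribute, columns: score levels -r..r
    trichotomy: pd.DataFrame  # index: attribute, columns: best, unchosen, worst
    support: tuple[int, ...] = field(default_factory=tuple)

    def to_long(self) -> pd.DataFrame:
        long = self.histogram.stack().rename("frequency").reset_index()
        long.columns = ["attribute", "score", "frequency"]
        return long


def tally(dataset: SurveyDataset) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Count best and worst picks per attribute, and per-respondent scores.

    Returns ``(B, W, scores)`` where ``B`` and ``W`` are integer Series
    indexed by attribute code and ``scores`` is the respondents x attributes
    matrix of s_ij = (best picks - worst picks).
    """
    dataset.validate()
    codes = dataset.attribute_codes
    resp_ids = [r.id for r in dataset.roster]
    B = pd.Series(0, index=codes, dtype=int)
    W = pd.Series(0, index=codes, dtype=int)
    scores = pd.DataFrame(0, index=resp_ids, columns=codes, dtype=int)
    for resp in dataset.responses:
        if resp.best not in B.index or resp.worst not in W.index:
            raise ValueError(f"response references unknown attribute: {resp}")
        B[resp.best] += 1
        W[resp.worst] += 1
        scores.loc[resp.respondent_id, resp.best] += 1
        scores.loc[resp.respondent_id, resp.worst] -= 1
    return B, W, scores


def summarize(
    B: Sequence[int] | pd.Series,
    W: Sequence[int] | pd.Series,
    n_respondents: int,
    appearances: int,
    attribute_codes: Sequence[str] | None = None,
    continuity_correction: bool = False,
) -> CountSummary:
    """Build the aggregate counting table from best/worst counts.

    ``appearances`` is r, the number of tasks each attribute appears in
    (3 under the seven-attribute triple design), so ``n_respondents *
    appearances`` bounds each attribute's |BW| value.

    A zero worst count makes the square-root ratio undefined; by default
    this is a hard error.  ``continuity_correction=True`` opts into adding
    0.5 to every B_j and W_j for the ratio columns only, and the flag is
    recorded on the returned summary.
    """
    if attribute_codes is None:
        if isinstance(B, pd.Series):
            attribute_codes = list(B.index)
        else:
            attribute_codes = [f"A{j}" for j in range(len(B))]
    B = np.asarray(B, dtype=float)
    W = np.asarray(W, dtype=float)
    if B.shape != W.shape:
        raise ValueError("B and W must have equal length")
    # Counts reconstructed from rounded printed percentages can miss exact
    # conservation by a task or two; warn rather than refuse, and use each
    # column's own total as its percentage base.
    T_best, T_worst = B.sum(), W.sum()
    if T_best != T_worst:
        warnings.warn(
            f"sum(B)={int(T_best)} != sum(W)={int(T_worst)}; "
            "percentages use per-column totals",
            UserWarning,
            stacklevel=2,
        )
    if n_respondents <= 0 or appearances <= 0:
        raise ValueError("n_respondents and appearances must be positive")

    bw = B - W
    denom = float(n_respondents * appearances)
    std = bw / denom

    if continuity_correction:
        Br, Wr = B + 0.5, W + 0.5
    else:
        if np.any(W == 0) or np.any(B == 0):
            bad = [attribute_codes[j] for j in np.flatnonzero((W == 0) | (B == 0))]
            raise ValueError(
                f"square-root ratio undefined for zero counts on {bad}; "
                "pass continuity_correction=True to add +0.5 to B and W"
            )
        Br, Wr = B, W
    sqrt_ratio = np.sqrt(Br / Wr)
    relative = 100.0 * sqrt_ratio / sqrt_ratio.max()

    # literal min-max rescalings of the BW value, kept as optional columns
    span = bw.max() - bw.min()
    if span > 0:
        std_minmax = (bw - bw.min()) / span
        rel_minmax = std_minmax * 100.0
    else:
        std_minmax = np.full_like(bw, np.nan, dtype=float)
        rel_minmax = np.full_like(bw, np.nan, dtype=float)

    order = np.argsort(-relative, kind="stable")
    rank = np.empty(len(B), dtype=int)
    next_rank = 1
    prev_val: float | None = None
    tied = False
    for pos, j in enumerate(order):
        if prev_val is not None and np.isclose(relative[j], prev_val):
            rank[j] = rank[order[pos - 1]]  # dense: ties share the smaller rank
            tied = True
        else:
            rank[j] = next_rank
        prev_val = relative[j]
        next_rank = rank[j] + 1

    table = pd.DataFrame(
        {
            "best_count": B.astype(int),
            "worst_count": W.astype(int),
            "best_pct": 100.0 * B / T_best,
            "worst_pct": 100.0 * W / T_worst,
            "bw_value": bw.astype(int),
            "std_value": std,
            "sqrt_ratio": sqrt_ratio,
            "relative_pct": relative,
            "std_minmax": std_minmax,
            "relative_minmax": rel_minmax,
            "rank": rank,
        },
        index=pd.Index(attribute_codes, name="attribute"),
    )
    return CountSummary(
        table=table,
        n_respondents=n_respondents,
        appearances=appearances,
        continuity_correction=continuity_correction,
        tied_ranks=tied,
    )


def reconstruct_counts_from_percentages(
    best_pcts: Sequence[float],
    worst_pcts: Sequence[float],
    total_tasks: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Recover integer best/worst counts from printed percentages of T tasks.

    ``B_j = round(best_pct_j * T / 100)`` with half rounded away from zero
    (printed tables round that way, unlike banker's rounding).
    """
    best_pcts = np.asarray(best_pcts, dtype=float)
    worst_pcts = np.asarray(worst_pcts, dtype=float)
    if np.any(best_pcts < 0) or np.any(worst_pcts < 0):
        raise ValueError("percentages must be non-negative")

    def _round_half_away(x: np.ndarray) -> np.ndarray:
        return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)

    B = _round_half_away(best_pcts * total_tasks / 100.0)
    W = _round_half_away(worst_pcts * total_tasks / 100.0)
    return B, W


def score_distribution(
    scores: pd.DataFrame,
    appearances: int = 3,
    dataset: SurveyDataset | None = None,
) -> ScoreDistribution:
    """Histogram the per-respondent scores s_ij over {-r, ..., +r}.

    Also derives the task-level trichotomy per attribute: across the
    ``n_respondents * r`` times it was shown, how often it was picked best,
    picked worst, or left unchosen.  Scores alone cannot distinguish a
    respondent who never touched an attribute from one who best-picked and
    worst-picked it in different tasks (both give s_ij contributions that
    cancel), so pass ``dataset`` for exact trichotomy counts; without it the
    trichotomy is reconstructed from the signed scores and is a lower bound
    on best/worst picks.
    """
    r = appearances
    vals = scores.to_numpy()
    if vals.size and (vals.min() < -r or vals.max() > r):
        raise ValueError(f"scores outside [-{r}, {r}]: did you pass the right r?")
    support = tuple(range(-r, r + 1))
    hist = pd.DataFrame(
        {level: (vals == level).sum(axis=0) for level in support},
        index=scores.columns,
    )
    hist.index.name = "attribute"
    hist.columns.name = "score"

    if dataset is not None:
        best = pd.Series(0, index=scores.columns, dtype=int)
        worst = pd.Series(0, index=scores.columns, dtype=int)
        for resp in dataset.responses:
            best[resp.best] += 1
            worst[resp.worst] += 1
    else:
        best = scores.clip(lower=0).sum(axis=0)
        worst = (-scores.clip(upper=0)).sum(axis=0)
    shown = scores.shape[0] * r
    tri = pd.DataFrame(
        {"best": best, "worst": worst, "unchosen": shown - best - worst},
        index=scores.columns,
    )
    tri.index.name = "attribute"
    return ScoreDistribution(histogram=hist, trichotomy=tri, support=support)
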