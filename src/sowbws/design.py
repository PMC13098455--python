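"""Balanced incomplete block designs for best-worst scaling choice sets.

A BWS survey shows each respondent ``b`` choice tasks, each containing ``k``
of the ``v`` attributes.  Using a BIBD guarantees equal occurrence (every
attribute appears in exactly ``r`` tasks) and equal pairwise co-occurrence
(every unordered pair of attributes is shown together in exactly ``lam``
tasks), so aggregate best/worst counts are comparable across attributes.

Designs are constructed by cyclic development of a planar difference set:
block ``i`` is ``{(d + i) mod v for d in base}``.  This is deterministic and
auditable; the (7, 3, 1) case develops {0, 1, 3} mod 7 (the Fano plane).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "AttributeSet",
    "BIBDDesign",
    "ChoiceTask",
    "ValidationReport",
    "NURSE_SOW_ATTRIBUTES",
    "construct_bibd",
    "validate_bibd",
    "bind_attributes",
    "write_design_csv",
    "read_design_csv",
    "format_survey_sheet",
]


# Cyclic (perfect) difference sets keyed by (v, k, lam).  Each base set D
# satisfies: every nonzero residue mod v arises exactly lam times as a
# difference d_i - d_j.  Developing D cyclically yields a (v, v, k, k, lam)
# symmetric BIBD.
_DIFFERENCE_SETS: dict[tuple[int, int, int], tuple[int, ...]] = {
    (7, 3, 1): (0, 1, 3),
    (11, 5, 2): (1, 3, 4, 5, 9),
    (13, 4, 1): (0, 1, 3, 9),
    (15, 7, 3): (0, 1, 2, 4, 5, 8, 10),
    (21, 5, 1): (0, 1, 6, 8, 18),
}


@dataclass(frozen=True)
class BIBDDesign:
    """A balanced incomplete block design (v, b, r, k, lam).

    ``blocks`` is an ordered list of ``b`` blocks, each a tuple of ``k``
    distinct treatment indices in ``[0, v)``.
    """

    v: int
    b: int
    r: int
    k: int
    lam: int
    blocks: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if self.b * self.k != self.v * self.r:
            raise ValueError(
                f"inconsistent parameters: b*k={self.b * self.k} != v*r={self.v * self.r}"
            )
        if self.lam * (self.v - 1) != self.r * (self.k - 1):
            raise ValueError(
                f"inconsistent parameters: lam*(v-1)={self.lam * (self.v - 1)} "
                f"!= r*(k-1)={self.r * (self.k - 1)}"
            )


@dataclass(frozen=True)
class AttributeSet:
    """Ordered attribute labels and their short codes."""

    labels: tuple[str, ...]
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.codes):
            raise ValueError("labels and codes must have equal length")
        if len(set(self.codes)) != len(self.codes) or len(set(self.labels)) != len(self.labels):
            raise ValueError("attribute labels and codes must be unique")

    def __len__(self) -> int:
        return len(self.codes)


#: The seven nurse-sow selection attributes, in the conventional reporting
#: order (most- to least-important in the aggregate counting analysis).
NURSE_SOW_ATTRIBUTES = AttributeSet(
    labels=(
        "Sow's Current Litter Health",
        "Body Condition Score",
        "Sow's Current Litter Size",
        "Sow's Teat Number",
        "Lactation Stage",
        "Sow Behavior",
        "Parity",
    ),
    codes=("SCLH", "BCS", "SCLS", "STN", "LS", "SB", "P"),
)


@dataclass(frozen=True)
class ChoiceTask:
    """One survey task: an ordered set of attribute codes shown together."""

    task_id: int
    attributes: tuple[str, ...]


@dataclass
class ValidationReport:
    """Outcome of checking the four BIBD invariants on a block list."""

    occurrence: list[int]
    co_occurrence: list[list[int]]
    violations: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations


def construct_bibd(v: int, k: int, lam: int) -> BIBDDesign:
    """Construct a symmetric BIBD by cyclic development of a difference set.

    Parameters
    ----------
    v, k, lam
        Number of treatments, block size, and pairwise co-occurrence count.
        The triple must correspond to a known cyclic difference set;
        (7, 3, 1) — seven attributes in triples, each pair shown once —
        is the canonical BWS case.

    Returns
    -------
    BIBDDesign
        With ``b = v`` blocks and ``r = k`` replications, blocks in
        cyclic-development order and ascending within each block.

    Raises
    ------
    ValueError
        If no construction is available for (v, k, lam).  There is never a
        silent fallback to an unbalanced design.
    """
    base = _DIFFERENCE_SETS.get((v, k, lam))
    if base is None:
        known = ", ".join(str(t) for t in sorted(_DIFFERENCE_SETS))
        raise ValueError(
            f"no construction available for (v={v}, k={k}, lam={lam}); "
            f"known cyclic difference sets: {known}"
        )
    blocks = tuple(tuple(sorted((d + i) % v for d in base)) for i in range(v))
    design = BIBDDesign(v=v, b=v, r=k, k=k, lam=lam, blocks=blocks)
    report = validate_bibd(design)
    if not report.passed:  # pragma: no cover - guards the difference-set table
        raise ValueError(f"internal error: constructed design invalid: {report.violations}")
    return design


def validate_bibd(design: BIBDDesign) -> ValidationReport:
    """Check the BIBD invariants, returning a report rather than raising.

    The report carries the per-treatment occurrence vector and the
    per-pair co-occurrence matrix so a failing design can be diagnosed.
    """
    v, b, r, k, lam = design.v, design.b, design.r, design.k, design.lam
    occurrence = [0] * v
    co = [[0] * v for _ in range(v)]
    violations: list[str] = []

    for idx, block in enumerate(design.blocks):
        members = tuple(block)
        if len(set(members)) != k or len(members) != k:
            violations.append(f"block {idx} does not have {k} distinct members: {members}")
            continue
        if any(not (0 <= t < v) for t in members):
            violations.append(f"block {idx} has out-of-range treatment: {members}")
            continue
        for t in members:
            occurrence[t] += 1
        for a_i, a in enumerate(members):
            for c in members[a_i + 1:]:
                co[a][c] += 1
                co[c][a] += 1

    for t in range(v):
        if occurrence[t] != r:
            violations.append(f"treatment {t} occurs {occurrence[t]} times, expected r={r}")
    for a in range(v):
        for c in range(a + 1, v):
            if co[a][c] != lam:
                violations.append(
                    f"pair ({a},{c}) co-occurs {co[a][c]} times, expected lam={lam}"
                )
    if b * k != v * r:
        violations.append(f"identity b*k == v*r violated: {b * k} != {v * r}")
    if lam * (v - 1) != r * (k - 1):
        violations.append(f"identity lam*(v-1) == r*(k-1) violated")

    return ValidationReport(occurrence=occurrence, co_occurrence=co, violations=violations)


def bind_attributes(
    design: BIBDDesign,
    attrs: AttributeSet,
    permutation: Sequence[int] | None = None,
) -> list[ChoiceTask]:
    """Map the design's treatment indices to attribute codes.

    ``permutation``, if given, must be a bijection on ``[0, v)``; treatment
    index ``t`` is rendered as ``attrs.codes[permutation[t]]``.  The default
    is the identity, i.e. index order follows the attribute set's order.
    """
    if len(attrs) != design.v:
        raise ValueError(f"attribute set has {len(attrs)} entries, design needs v={design.v}")
    if permutation is None:
        perm = list(range(design.v))
    else:
        perm = list(permutation)
        if sorted(perm) != list(range(design.v)):
            raise ValueError("permutation must be a bijection on [0, v)")
    return [
        ChoiceTask(task_id=i, attributes=tuple(attrs.codes[perm[t]] for t in block))
        for i, block in enumerate(design.blocks)
    ]


def write_design_csv(tasks: Sequence[ChoiceTask], path) -> None:
    """Write bound tasks as CSV: task_id, position_1..position_k."""
    k = len(tasks[0].attributes)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["task_id"] + [f"position_{j + 1}" for j in range(k)])
        for task in tasks:
            writer.writerow([task.task_id, *task.attributes])


def read_design_csv(path) -> list[ChoiceTask]:
    """Read a bound task list written by :func:`write_design_csv`."""
    tasks: list[ChoiceTask] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or reader.fieldnames[0] != "task_id":
            raise ValueError(f"{path}: expected a design CSV with a task_id column")
        pos_cols = [c for c in reader.fieldnames if c.startswith("position_")]
        for row in reader:
            tasks.append(
                ChoiceTask(
                    task_id=int(row["task_id"]),
                    attributes=tuple(row[c] for c in pos_cols),
                )
            )
    return tasks


def format_survey_sheet(tasks: Sequence[ChoiceTask], attrs: AttributeSet) -> str:
    """Render a printable sheet: one table per task with Most/Least columns."""
    label_of = dict(zip(attrs.codes, attrs.labels))
    lines: list[str] = []
    for task in tasks:
        lines.append(f"Choice set {task.task_id + 1}")
        lines.append(f"  {'Most Important':<16}{'Attribute':<34}{'Least Important':<16}")
        for code in task.attributes:
            lines.append(f"  {'[ ]':<16}{label_of.get(code, code):<34}{'[ ]':<16}")
        lines.append("")
    return "\n".join(lines)
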