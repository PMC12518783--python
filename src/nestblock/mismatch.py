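"""Oligo-versus-template mismatch counting with positional classes.

Two positional conventions matter for PCR suppression work:

* ``PRIMER_3PRIME`` — the five bases adjacent to a primer's 3' terminus,
  where mismatches are most disruptive to polymerase extension.
* ``BLOCKER_CENTER`` — for an elongation-arrest blocker with alternating
  LNAs, the positions more than five bases from either end; a single
  central mismatch is enough to strongly relieve blocking, so central
  mismatches against the protect-set are what keep co-blocking low.

Degenerate codes are compared optimistically: two codes match when their
base sets intersect (a blocker ``Y`` is treated as matching both C and T
templates). An alignment gap under the oligo matches nothing — an indel
disrupts annealing at least as much as a substitution — and is counted
both as a mismatch and separately as a gap.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from enum import Enum

from .alignment import GAP, TemplateAlignment
from .oligo import IUPAC_SETS, Oligo

__all__ = [
    "PositionClass",
    "MismatchProfile",
    "ProfileSetSummary",
    "iupac_compatible",
    "classify_positions",
    "profile_oligo_vs_template",
    "profile_set",
]

#: Positions within this many bases of an end are "terminal" for the
#: blocker-center rule; center = more than END_MARGIN bases from either end.
END_MARGIN = 5


class PositionClass(str, Enum):
    PRIMER_3PRIME = "PRIMER_3PRIME"
    BLOCKER_CENTER = "BLOCKER_CENTER"


@dataclass(frozen=True)
class MismatchProfile:
    """Mismatch counts of one oligo against one aligned template window."""

    template_id: str
    total: int
    in_class: int
    class_kind: PositionClass
    positions: tuple[int, ...] = ()
    alignment_gaps: int = 0

    def __post_init__(self) -> None:
        if self.in_class > self.total:
            raise ValueError("in-class mismatches cannot exceed total")
        if len(self.positions) != self.total:
            raise ValueError("positions list must have one entry per mismatch")


def iupac_compatible(a: str, b: str) -> bool:
    """True iff the IUPAC base sets of ``a`` and ``b`` intersect.

    A gap is compatible with nothing, including another gap.
    """
    if a == GAP or b == GAP:
        return False
    try:
        return bool(IUPAC_SETS[a.upper()] & IUPAC_SETS[b.upper()])
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r}") from None


def classify_positions(oligo_length: int, class_kind: PositionClass,
                       end_margin: int = END_MARGIN) -> frozenset[int]:
    """1-based oligo positions belonging to the positional class.

    ``PRIMER_3PRIME``: the ``end_margin`` positions nearest the 3' terminus
    (all positions if the oligo is shorter). ``BLOCKER_CENTER``: positions
    more than ``end_margin`` bases from either end, i.e. ``end_margin < i
    <= L - end_margin`` (empty when L <= 2*end_margin).
    """
    if oligo_length < 1:
        raise ValueError("oligo_length must be >= 1")
    if class_kind is PositionClass.PRIMER_3PRIME:
        start = max(1, oligo_length - end_margin + 1)
        return frozenset(range(start, oligo_length + 1))
    return frozenset(range(end_margin + 1, oligo_length - end_margin + 1))


def profile_oligo_vs_template(
    oligo: Oligo,
    aln: TemplateAlignment,
    template_id: str,
    window: tuple[int, int],
    class_kind: PositionClass,
    end_margin: int = END_MARGIN,
) -> MismatchProfile:
    """Profile one oligo against one template over an alignment window.

    ``window`` is a 1-based closed alignment-column interval whose width
    must equal the oligo length; the caller supplies the oligo already in
    its annealing orientation, with any linker tail removed.
    """
    start, end = window
    if not 1 <= start <= end <= aln.length:
        raise IndexError(f"window {window} outside alignment 1..{aln.length}")
    if end - start + 1 != len(oligo):
        raise ValueError(
            f"window width {end - start + 1} != oligo length {len(oligo)}"
        )
    seq = aln.sequence(template_id)
    class_pos = classify_positions(len(oligo), class_kind, end_margin)
    positions: list[int] = []
    gaps = 0
    in_class = 0
    for i, base in enumerate(oligo.bases, start=1):
        t = seq[start + i - 2]
        if t == GAP:
            gaps += 1
        if not iupac_compatible(base, t):
            positions.append(i)
            if i in class_pos:
                in_class += 1
    return MismatchProfile(template_id, len(positions), in_class, class_kind,
                           tuple(positions), gaps)


@dataclass
class ProfileSetSummary:
    """Per-group mismatch summary over a set of templates."""

    group: str
    n: int
    fraction_at_least: dict[int, float] = field(default_factory=dict)
    min_total: int = 0
    median_total: float = 0.0


def profile_set(
    oligo: Oligo,
    aln: TemplateAlignment,
    window: tuple[int, int],
    class_kind: PositionClass,
    group: str | None = None,
    max_k: int = 4,
    end_margin: int = END_MARGIN,
) -> tuple[list[MismatchProfile], list[ProfileSetSummary]]:
    """Profile every template (optionally restricted to one group).

    Returns per-template profiles plus, per group, the count/fraction of
    templates with at least 1, 2, ... ``max_k`` total mismatches and the
    min/median mismatch count — the numbers one quotes when reporting,
    e.g., what fraction of a target clade a blocker would fail on.
    """
    ids = aln.ids if group is None else aln.ids_in_group(group)
    if not ids:
        raise ValueError(f"no templates selected (group={group!r})")
    profiles = [
        profile_oligo_vs_template(oligo, aln, rid, window, class_kind, end_margin)
        for rid in ids
    ]
    by_group: dict[str, list[MismatchProfile]] = {}
    for p in profiles:
        g = aln.groups.get(p.template_id, "")
        by_group.setdefault(g, []).append(p)
    summaries = []
    for g, ps in sorted(by_group.items()):
        totals = [p.total for p in ps]
        summaries.append(ProfileSetSummary(
            group=g,
            n=len(ps),
            fraction_at_least={
                k: sum(t >= k for t in totals) / len(totals)
                for k in range(1, max_k + 1)
            },
            min_total=min(totals),
            median_total=statistics.median(totals),
        ))
    return profiles, summaries
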