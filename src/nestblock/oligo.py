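"""Oligonucleotide model: IUPAC degeneracy, LNA masks, terminal modifications.

Oligos are represented 5'->3' with 1-based positions throughout. Locked
nucleic acid (LNA) sugars are recorded as a set of positions; terminal
chemical modifications (e.g. amino linkers that render the 3' end
non-extendable) are carried as opaque vendor labels. The vendor string
notation puts ``+`` before each LNA base and wraps terminal modifications
in ``/.../`` tags, e.g. ``/5AmMC6/C+AG+TY+GA+CC+TY+GC+AA+T/3AmMO/``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "IUPAC_SETS",
    "Oligo",
    "PrimerPair",
    "OligoParseError",
    "DegeneracyOverflowError",
    "parse_modified_oligo",
    "format_modified_oligo",
    "expand_degenerate",
    "reverse_complement",
    "degeneracy",
]

#: Base sets for every IUPAC nucleotide code (U is normalised to T on parse).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: IUPAC complement map (complement of the underlying base set).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class OligoParseError(ValueError):
    """Raised when vendor-notation text cannot be parsed into an Oligo."""


class DegeneracyOverflowError(ValueError):
    """Raised when degenerate expansion would exceed the requested cap."""


@dataclass(frozen=True)
class Oligo:
    """A (possibly degenerate) oligonucleotide with LNA and terminal mods.

    Parameters
    ----------
    bases
        Upper-case IUPAC string, 5'->3'.
    lna_mask
        1-based positions carrying an LNA sugar.
    mod5, mod3
        Optional terminal-modification labels, stored without the
        surrounding slashes (e.g. ``"5AmMC6"``). Labels are opaque; the
        toolkit only interprets "mod3 present" as "3' extension blocked".
    """

    bases: str
    lna_mask: frozenset[int] = field(default_factory=frozenset)
    mod5: str | None = None
    mod3: str | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("oligo must contain at least one base")
        bad = set(self.bases) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"non-IUPAC characters in oligo: {sorted(bad)}")
        object.__setattr__(self, "lna_mask", frozenset(self.lna_mask))
        out = [p for p in self.lna_mask if not 1 <= p <= len(self.bases)]
        if out:
            raise ValueError(f"LNA positions outside 1..{len(self.bases)}: {sorted(out)}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_extension_blocked(self) -> bool:
        """True when a 3' terminal modification prevents polymerase extension."""
        return self.mod3 is not None

    def subseq(self, start: int, end: int) -> "Oligo":
        """1-based closed-interval slice; terminal mods are kept only when
        the corresponding terminus survives the slice."""
        if not 1 <= start <= end <= len(self.bases):
            raise ValueError(f"invalid slice [{start}, {end}] of length-{len(self.bases)} oligo")
        mask = frozenset(p - start + 1 for p in self.lna_mask if start <= p <= end)
        return Oligo(
            self.bases[start - 1 : end],
            mask,
            self.mod5 if start == 1 else None,
            self.mod3 if end == len(self.bases) else None,
        )


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse amplification primers with 5' linker tails.

    Tail bases are sequencing-adapter linker that never anneals to the
    template; ``forward_annealing``/``reverse_annealing`` strip them.
    """

    forward: Oligo
    reverse: Oligo
    forward_tail: int = 0
    reverse_tail: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.forward_tail < len(self.forward):
            raise ValueError("forward tail length must be < oligo length")
        if not 0 <= self.reverse_tail < len(self.reverse):
            raise ValueError("reverse tail length must be < oligo length")

    @property
    def forward_annealing(self) -> Oligo:
        return self.forward.subseq(self.forward_tail + 1, len(self.forward))

    @property
    def reverse_annealing(self) -> Oligo:
        return self.reverse.subseq(self.reverse_tail + 1, len(self.reverse))


_MOD_TAG = re.compile(r"/([^/]+)/")


def parse_modified_oligo(text: str) -> Oligo:
    """Parse vendor notation (``+`` = LNA, ``/.../`` = terminal mod).

    Whitespace is ignored (printed sequences often contain spacing
    artifacts around ``+``). ``U`` is normalised to ``T`` and lowercase to
    uppercase. At most one leading and one trailing modification tag are
    accepted.
    """
    s = text.strip()
    mod5 = mod3 = None
    m = _MOD_TAG.match(s)
    if m:
        mod5 = m.group(1)
        s = s[m.end():]
    tail = re.search(r"/([^/]+)/\s*$", s)
    if tail:
        mod3 = tail.group(1)
        s = s[: tail.start()]
    if "/" in s:
        raise OligoParseError(f"malformed modification tag near {s!r}")

    bases: list[str] = []
    mask: set[int] = set()
    pending_lna = False
    for ch in s:
        if ch.isspace():
            continue
        if ch == "+":
            if pending_lna:
                raise OligoParseError("'+' must be followed by a base, found '++'")
            pending_lna = True
            continue
        b = ch.upper()
        if b == "U":
            b = "T"
        if b not in IUPAC_SETS:
            raise OligoParseError(f"unknown base {ch!r} in oligo string")
        bases.append(b)
        if pending_lna:
            mask.add(len(bases))
            pending_lna = False
    if pending_lna:
        raise OligoParseError("trailing '+' with no base")
    if not bases:
        raise OligoParseError("empty oligo string")
    return Oligo("".join(bases), frozenset(mask), mod5, mod3)


def format_modified_oligo(o: Oligo, spacing: bool = False) -> str:
    """Canonical vendor notation: no internal whitespace unless ``spacing``."""
    parts = []
    if o.mod5:
        parts.append(f"/{o.mod5}/")
    for i, b in enumerate(o.bases, start=1):
        if i in o.lna_mask:
            parts.append("+" + b)
        else:
            parts.append(b)
    body = (" ".join if spacing else "".join)(parts[1 if o.mod5 else 0:])
    out = (parts[0] if o.mod5 else "") + body
    if o.mod3:
        out += f"/{o.mod3}/"
    return out


def degeneracy(bases: str) -> int:
    """Number of concrete A/C/G/T sequences a degenerate string represents."""
    n = 1
    for b in bases:
        n *= len(IUPAC_SETS[b])
    return n


def expand_degenerate(o: Oligo | str, cap: int = 4096) -> list[str]:
    """Enumerate all concrete A/C/G/T realisations of a degenerate oligo.

    Expansion order is lexicographic per position (sorted base sets). An
    expansion count above ``cap`` raises :class:`DegeneracyOverflowError`
    before any enumeration happens.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    bases = o.bases if isinstance(o, Oligo) else o
    n = degeneracy(bases)
    if n > cap:
        raise DegeneracyOverflowError(
            f"degenerate oligo expands to {n} sequences, above cap {cap}"
        )
    pools = [sorted(IUPAC_SETS[b]) for b in bases]
    return ["".join(p) for p in itertools.product(*pools)]


def reverse_complement(o: Oligo) -> Oligo:
    """IUPAC-aware reverse complement.

    LNA positions are mirrored (i -> L+1-i) and the terminal-modification
    labels swap ends. The mirroring of LNA sugars is a bookkeeping
    convention: an LNA stays attached to its base through the operation.
    """
    comp = "".join(IUPAC_COMPLEMENT[b] for b in reversed(o.bases))
    L = len(o.bases)
    mask = frozenset(L + 1 - p for p in o.lna_mask)
    return Oligo(comp, mask, o.mod3, o.mod5)
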