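"""Blocking-oligonucleotide design over an aligned template set.

The design problem: given a multiple alignment of COI (or similar)
fragments split into a *block-set* (the abundant nest-builder clade to
suppress) and a *protect-set* (everything whose amplification must
survive), find inter-primer windows that are

* conserved within the block-set — the blocker must perfectly match the
  templates it is meant to arrest — and
* divergent from the protect-set, with the divergence concentrated in the
  window center, because with alternating LNAs a single central mismatch
  is enough to strongly relieve blocking.

Candidates carry alternating LNA sugars, 5'/3' terminal modifications
(the 3' modification makes the oligo non-extendable, giving elongation
arrest rather than amplification), and are length-tuned toward a target
melting-temperature offset above the primers so the blocker anneals
first.

The scan is exhaustive: inter-primer barcode regions are a few hundred
columns, so every (start, length) window is scored deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from .alignment import GAP, TemplateAlignment
from .mismatch import (MismatchProfile, PositionClass, classify_positions,
                       profile_oligo_vs_template)
from .oligo import IUPAC_SETS, Oligo, PrimerPair, degeneracy, reverse_complement
from .thermo import ThermoParams, melting_temperature

__all__ = [
    "DesignConfig",
    "LnaPhase",
    "TrimMode",
    "BlockerCandidate",
    "ConsensusError",
    "degenerate_consensus",
    "scan_windows",
    "build_candidate",
    "design_blockers",
    "locate_primer",
]

_CODE_BY_SET = {s: code for code, s in IUPAC_SETS.items()}


class ConsensusError(ValueError):
    """Raised when a window cannot yield a usable degenerate consensus."""

    def __init__(self, message: str, column: int | None = None):
        super().__init__(message)
        self.column = column


class LnaPhase(str, Enum):
    START_PLAIN = "start_plain"   # LNAs at positions 2, 4, 6, ...
    START_LNA = "start_lna"       # LNAs at positions 1, 3, 5, ...
    AUTO = "auto"                 # phase putting more LNAs in the center


class TrimMode(str, Enum):
    SYMMETRIC = "symmetric"
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


@dataclass
class DesignConfig:
    """Tunable design parameters.

    ``center_weight`` multiplies protect-set *central* mismatches in the
    divergence score (default 2.0: a central mismatch does roughly the
    protective work of two terminal ones). ``min_protect_center_mismatches``
    drops windows where any protect-set template lacks that many central
    mismatches, i.e. would risk co-blocking.
    """

    min_length: int = 14
    max_length: int = 22
    tm_offset: float = 7.0
    max_degeneracy: int = 4
    lna_phase: LnaPhase = LnaPhase.AUTO
    trim_mode: TrimMode = TrimMode.SYMMETRIC
    center_weight: float = 2.0
    min_protect_center_mismatches: int = 1
    weight_conservation: float = 1.0
    weight_divergence: float = 1.0
    weight_tm_gap: float = 0.0
    mod5: str | None = "5AmMC6"
    mod3: str | None = "3AmMO"
    end_margin: int = 5

    def __post_init__(self) -> None:
        if self.min_length < 12:
            raise ValueError("min_length must be >= 12")
        if self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")
        for w in (self.weight_conservation, self.weight_divergence, self.weight_tm_gap):
            if w < 0:
                raise ValueError("rank weights must be >= 0")


@dataclass
class ScoredWindow:
    start: int          # 1-based alignment column, closed interval
    length: int
    consensus: str
    conservation: float
    divergence: float   # min over protect of total + (cw-1)*center
    min_protect_center: int

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class BlockerCandidate:
    oligo: Oligo
    window: tuple[int, int]
    conservation: float
    divergence: float | None   # None when there is no protect-set
    tm: float
    tm_gap: float
    profiles: list[MismatchProfile] = field(default_factory=list)
    block_set_outliers: list[str] = field(default_factory=list)

    def score(self, cfg: DesignConfig) -> float:
        div = self.divergence if self.divergence is not None else 0.0
        return (cfg.weight_conservation * self.conservation
                + cfg.weight_divergence * div
                - cfg.weight_tm_gap * abs(self.tm_gap))


def degenerate_consensus(aln: TemplateAlignment, ids: list[str],
                         window: tuple[int, int], max_code_size: int = 2) -> str:
    """Minimal IUPAC code covering the given templates, per column.

    Fails (``ConsensusError`` carrying the offending 1-based column) on a
    gap column or a column needing a code of more than ``max_code_size``
    bases — a blocker cannot span an indel, and over-degenerate windows
    dilute blocker concentration across too many species variants.
    """
    if not ids:
        raise ValueError("ids must be non-empty")
    start, end = window
    if not 1 <= start <= end <= aln.length:
        raise IndexError(f"window {window} outside alignment 1..{aln.length}")
    out = []
    for col in range(start, end + 1):
        observed: set[str] = set()
        for rid in ids:
            ch = aln.sequence(rid)[col - 1]
            if ch == GAP:
                raise ConsensusError(f"gap in column {col}", column=col)
            observed |= IUPAC_SETS[ch]
        if len(observed) > max_code_size:
            raise ConsensusError(
                f"column {col} needs a {len(observed)}-fold code "
                f"(max {max_code_size})", column=col)
        out.append(_CODE_BY_SET[frozenset(observed)])
    return "".join(out)


def _weighted_divergence(profile: MismatchProfile, center_weight: float) -> float:
    return profile.total + (center_weight - 1.0) * profile.in_class


def scan_windows(aln: TemplateAlignment, block_ids: list[str],
                 protect_ids: list[str], region: tuple[int, int],
                 cfg: DesignConfig | None = None) -> list[ScoredWindow]:
    """Exhaustively score every candidate window in the inter-primer region.

    conservation = fraction of block-set templates with zero mismatches
    against the window consensus; divergence = min over the protect-set of
    center-weighted mismatch counts. Windows whose consensus fails
    (gap/over-degenerate column) are skipped; windows where some protect
    template has fewer than ``min_protect_center_mismatches`` central
    mismatches are dropped (no filter when the protect-set is empty).
    """
    cfg = cfg or DesignConfig()
    if not block_ids:
        raise ValueError("block_ids must be non-empty")
    lo, hi = region
    if hi - lo + 1 < cfg.min_length:
        raise ValueError(
            f"region {region} narrower than min_length {cfg.min_length}")
    max_code = _max_code_size(cfg.max_degeneracy)
    out: list[ScoredWindow] = []
    for length in range(cfg.min_length, cfg.max_length + 1):
        for start in range(lo, hi - length + 2):
            window = (start, start + length - 1)
            try:
                consensus = degenerate_consensus(aln, block_ids, window, max_code)
            except ConsensusError:
                continue
            if degeneracy(consensus) > cfg.max_degeneracy:
                continue
            probe = Oligo(consensus)
            n_exact = 0
            for rid in block_ids:
                p = profile_oligo_vs_template(
                    probe, aln, rid, window, PositionClass.BLOCKER_CENTER,
                    cfg.end_margin)
                if p.total == 0:
                    n_exact += 1
            conservation = n_exact / len(block_ids)
            if protect_ids:
                divs, centers = [], []
                for rid in protect_ids:
                    p = profile_oligo_vs_template(
                        probe, aln, rid, window, PositionClass.BLOCKER_CENTER,
                        cfg.end_margin)
                    divs.append(_weighted_divergence(p, cfg.center_weight))
                    centers.append(p.in_class)
                min_center = min(centers)
                if min_center < cfg.min_protect_center_mismatches:
                    continue
                divergence = min(divs)
            else:
                divergence = 0.0
                min_center = 0
            out.append(ScoredWindow(start, length, consensus, conservation,
                                    divergence, min_center))
    return out


def _max_code_size(max_degeneracy: int) -> int:
    # a single column's code size can never exceed the per-candidate cap
    return min(4, max(1, max_degeneracy))


def alternating_lna_mask(length: int, phase: LnaPhase,
                         end_margin: int = 5) -> frozenset[int]:
    """Every-other-base LNA mask. ``AUTO`` picks the phase placing more
    LNAs among center positions; ties go to ``START_PLAIN``."""
    plain = frozenset(range(2, length + 1, 2))
    lna_first = frozenset(range(1, length + 1, 2))
    if phase is LnaPhase.START_PLAIN:
        return plain
    if phase is LnaPhase.START_LNA:
        return lna_first
    center = classify_positions(length, PositionClass.BLOCKER_CENTER, end_margin)
    if len(lna_first & center) > len(plain & center):
        return lna_first
    return plain


def _trim_options(start: int, end: int, cfg: DesignConfig):
    """Candidate (start, end) windows reachable by trimming, smallest trim
    first so equal |tm_gap| keeps the untrimmed window."""
    length = end - start + 1
    yield start, end
    if cfg.trim_mode is TrimMode.NONE:
        return
    max_trim = length - cfg.min_length
    for t in range(1, max_trim + 1):
        if cfg.trim_mode is TrimMode.LEFT:
            yield start + t, end
        elif cfg.trim_mode is TrimMode.RIGHT:
            yield start, end - t
        else:  # symmetric: alternate ends, left first
            left = (t + 1) // 2
            right = t // 2
            yield start + left, end - right


def build_candidate(window: ScoredWindow, aln: TemplateAlignment,
                    block_ids: list[str], protect_ids: list[str],
                    cfg: DesignConfig | None = None,
                    params: ThermoParams | None = None,
                    target_tm: float | None = None) -> BlockerCandidate:
    """Turn a scored window into a concrete blocker candidate.

    Applies the alternating LNA scheme and terminal modifications. When a
    ``target_tm`` (absolute °C, normally primer Tm + offset) is given and
    ``cfg.trim_mode`` allows it, the window is trimmed — smallest trim
    first — to minimise the absolute Tm gap; otherwise it is used as-is.
    """
    cfg = cfg or DesignConfig()
    params = params or ThermoParams()
    best: BlockerCandidate | None = None
    max_code = _max_code_size(cfg.max_degeneracy)
    options = (_trim_options(window.start, window.end, cfg)
               if target_tm is not None else [(window.start, window.end)])
    for s, e in options:
        length = e - s + 1
        try:
            consensus = degenerate_consensus(aln, block_ids, (s, e), max_code)
        except ConsensusError:
            continue
        if degeneracy(consensus) > cfg.max_degeneracy:
            continue
        mask = alternating_lna_mask(length, cfg.lna_phase, cfg.end_margin)
        oligo = Oligo(consensus, mask, cfg.mod5, cfg.mod3)
        tm = melting_temperature(oligo, params)
        cand = _evaluate(oligo, (s, e), tm, aln, block_ids, protect_ids, cfg,
                         target_tm=target_tm)
        if best is None or abs(cand.tm_gap) < abs(best.tm_gap) - 1e-12:
            best = cand
    if best is None:
        raise ConsensusError(
            f"window ({window.start}, {window.end}) lost its consensus")
    return best


def _evaluate(oligo: Oligo, window: tuple[int, int], tm: float,
              aln: TemplateAlignment, block_ids: list[str],
              protect_ids: list[str], cfg: DesignConfig,
              target_tm: float | None = None) -> BlockerCandidate:
    profiles, outliers, n_exact = [], [], 0
    for rid in block_ids:
        p = profile_oligo_vs_template(oligo, aln, rid, window,
                                      PositionClass.BLOCKER_CENTER, cfg.end_margin)
        if p.total == 0:
            n_exact += 1
        else:
            outliers.append(rid)
    conservation = n_exact / len(block_ids)
    divergence: float | None = None
    if protect_ids:
        vals = []
        for rid in protect_ids:
            p = profile_oligo_vs_template(oligo, aln, rid, window,
                                          PositionClass.BLOCKER_CENTER,
                                          cfg.end_margin)
            profiles.append(p)
            vals.append(_weighted_divergence(p, cfg.center_weight))
        divergence = min(vals)
    gap = tm - target_tm if target_tm is not None else 0.0
    return BlockerCandidate(oligo, window, conservation, divergence, tm, gap,
                            profiles, outliers)


def locate_primer(aln: TemplateAlignment, annealing: Oligo,
                  orientation: str = "forward") -> tuple[int, int]:
    """Best-match placement of a primer annealing region in the alignment.

    The reverse primer is reverse-complemented into plus-strand
    orientation first. Placement slides the oligo across all columns and
    minimises total mismatches summed over all templates (gaps count as
    mismatches); ties go to the leftmost window.
    """
    probe = annealing if orientation == "forward" else reverse_complement(annealing)
    L = len(probe)
    if L > aln.length:
        raise ValueError("primer longer than alignment")
    best_start, best_cost = 1, None
    for start in range(1, aln.length - L + 2):
        cost = 0
        for rid in aln.ids:
            p = profile_oligo_vs_template(probe, aln, rid, (start, start + L - 1),
                                          PositionClass.PRIMER_3PRIME)
            cost += p.total
        if best_cost is None or cost < best_cost:
            best_start, best_cost = start, cost
    return best_start, best_start + L - 1


@dataclass
class DesignReport:
    candidates: list[BlockerCandidate]
    region: tuple[int, int]
    n_windows_scored: int
    n_windows_passing: int
    primer_windows: dict[str, tuple[int, int]]
    diagnostics: str = ""


def design_blockers(aln: TemplateAlignment, block_ids: list[str],
                    protect_ids: list[str], primers: PrimerPair,
                    cfg: DesignConfig | None = None,
                    params: ThermoParams | None = None,
                    top_k: int = 5) -> DesignReport:
    """Full design pass: place primers, scan the inter-primer region,
    build LNA candidates and rank them.

    Ranking is by the weighted score (conservation, divergence, |Tm gap|);
    ties break to the leftmost window, then the shortest. An empty
    candidate list (nothing passes the filters) is returned with a
    diagnostic summary rather than raised.
    """
    cfg = cfg or DesignConfig()
    params = params or ThermoParams()
    if set(block_ids) & set(protect_ids):
        raise ValueError("block-set and protect-set must be disjoint")
    fwd = locate_primer(aln, primers.forward_annealing, "forward")
    rev = locate_primer(aln, primers.reverse_annealing, "reverse")
    region = (fwd[1] + 1, rev[0] - 1)
    if region[1] - region[0] + 1 < cfg.min_length:
        return DesignReport([], region, 0, 0,
                            {"forward": fwd, "reverse": rev},
                            "inter-primer region too narrow")
    windows = scan_windows(aln, block_ids, protect_ids, region, cfg)
    primer_tm = max(melting_temperature(primers.forward_annealing, params),
                    melting_temperature(primers.reverse_annealing, params))
    target_tm = primer_tm + cfg.tm_offset
    # the scan already enumerates every length, so per-window trimming
    # would only duplicate other scanned windows
    no_trim = replace(cfg, trim_mode=TrimMode.NONE)
    candidates = []
    for w in windows:
        cand = build_candidate(w, aln, block_ids, protect_ids, no_trim,
                               params, target_tm=target_tm)
        candidates.append(cand)
    candidates.sort(key=lambda c: (-c.score(cfg), c.window[0],
                                   c.window[1] - c.window[0]))
    diag = "" if candidates else (
        f"no window passed filters in region {region} "
        f"({len(windows)} scored)")
    return DesignReport(candidates[:top_k], region, len(windows),
                        len(candidates),
                        {"forward": fwd, "reverse": rev}, diag)
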