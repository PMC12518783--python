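"""Synthetic study generator: template alignments with a planted blocker
window and paired with/without-blocker read tables with known truth.

The simulator emulates the two datasets the toolkit operates on, at the
conditions of a nest-metabarcoding study of a songbird community:

* a multi-species alignment in which the block-set (the target clade) is
  invariant over a planted window while every protect-set template
  carries a fixed number of mismatches in the window center, flanked by
  indel columns so the window has sharp boundaries;
* paired read tables in which one dominant nest-builder taxon (default
  60% of template molecules) is suppressed by the blocker.

Amplification is a deterministic per-taxon weight w_i = θ_i ·
(1 + e·δ^{m3})^C — exponential PCR with efficiency e penalised by a
factor δ per 3'-terminal primer mismatch over C cycles — followed by a
multinomial draw of fixed library depth (libraries are pooled equimolar
and sequenced to depth). The blocker multiplies a taxon's weight by a
retention factor: r_strong (default 0.001, i.e. 99.9% suppression) for
templates the blocker matches perfectly in its center, r_weak (default
0.9, the ~90% read retention observed for alternating-LNA blockers with
one central mismatch) for everything else. All randomness flows from a
single seed; per-library streams are split off a SeedSequence so each
library is reproducible independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import TemplateAlignment
from .mismatch import PositionClass, classify_positions
from .reads import ReadTable

__all__ = ["TaxonSpec", "SimScenario", "simulate_template_alignment",
           "simulate_read_tables", "default_scenario", "default_community"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TaxonSpec:
    """One taxon in the simulated community.

    ``center_mismatches`` is the taxon's mismatch count in the blocker
    center (0 = fully blocked); ``primer_3p_mismatches`` feeds the
    amplification penalty; ``group`` is a free-form label; a taxon with
    ``is_nest_builder_of`` set is excluded from richness for its own
    samples, mirroring how nest-builder reads are discarded.
    """

    taxon_id: str
    proportion: float
    group: str = "animal"
    center_mismatches: int = 1
    primer_3p_mismatches: int = 0
    is_nest_builder_of: str | None = None


@dataclass
class SimScenario:
    """Study conditions for both simulators."""

    # alignment
    n_block_templates: int = 10
    n_protect_templates: int = 5
    alignment_length: int = 120
    window_start: int = 40
    window_length: int = 16
    n_center_mismatches: int = 3
    block_noise_rate: float = 0.0       # substitutions outside the window
    protect_background_rate: float = 0.05
    # community / amplification
    community: list[TaxonSpec] = field(default_factory=lambda: default_community())
    cycles: int = 50
    base_efficiency: float = 0.9
    mismatch_penalty: float = 0.5       # per-3'-mismatch efficiency factor
    r_strong: float = 0.001
    r_weak: float = 0.9
    depth: int = 100_000
    n_samples: int = 1

    def __post_init__(self) -> None:
        total = sum(t.proportion for t in self.community)
        if self.community and abs(total - 1.0) > 1e-9:
            raise ValueError(f"community proportions sum to {total}, not 1")
        if not (0 <= self.r_strong <= 1 and 0 <= self.r_weak <= 1):
            raise ValueError("retention factors must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        end = self.window_start + self.window_length - 1
        if not (2 <= self.window_start and end <= self.alignment_length - 1):
            raise ValueError("planted window (plus flanking columns) must "
                             "fit inside the alignment")


def default_community() -> list[TaxonSpec]:
    """A nest-like community: one dominant nest-builder (60% of template
    molecules, perfectly matched by the blocker), a small set of rarer
    animal taxa, and an abundant non-target background, echoing samples
    dominated by host and fungal reads."""
    taxa = [TaxonSpec("nest_builder", 0.60, "sparrow", 0, 0, "nest_builder")]
    rare = [0.004, 0.006, 0.008, 0.012, 0.02, 0.03, 0.04, 0.03, 0.02, 0.03]
    for i, p in enumerate(rare, start=1):
        taxa.append(TaxonSpec(f"animal_{i:02d}", p, "animal",
                              center_mismatches=1 + (i % 3)))
    taxa.append(TaxonSpec("fungus_1", 0.12, "fungi", 2, 1))
    taxa.append(TaxonSpec("fungus_2", 0.08, "fungi", 3, 1))
    total = sum(t.proportion for t in taxa)
    assert abs(total - 1.0) < 1e-9
    return taxa


def _mutate(seq: np.ndarray, positions: np.ndarray,
            rng: np.random.Generator) -> None:
    """Substitute each position with a uniformly drawn different base."""
    for p in positions:
        choices = _BASES[_BASES != seq[p]]
        seq[p] = rng.choice(choices)


def simulate_template_alignment(
    scenario: SimScenario, seed: int,
) -> tuple[TemplateAlignment, dict]:
    """Build the planted-window alignment; returns (alignment, truth).

    Construction: a random consensus; block-set copies of it (optional
    noise outside the window); protect-set templates that differ at
    exactly ``n_center_mismatches`` positions of the window center —
    placed at the extreme center positions first, so no shifted or
    trimmed window captures them all centrally — plus background
    substitutions away from the window. The two columns flanking the
    window are deleted in the block-set (gap characters), giving the
    planted window indel boundaries as real alignments have.
    """
    sc = scenario
    rng = np.random.default_rng(seed)
    L = sc.alignment_length
    w0 = sc.window_start
    w1 = w0 + sc.window_length - 1
    center = sorted(classify_positions(sc.window_length,
                                       PositionClass.BLOCKER_CENTER))
    if sc.n_center_mismatches > len(center):
        raise ValueError(
            f"cannot place {sc.n_center_mismatches} center mismatches in a "
            f"{sc.window_length}-base window ({len(center)} center positions)")
    # spread the planted positions across the center, extremes first
    order = []
    lo_i, hi_i = 0, len(center) - 1
    while lo_i <= hi_i:
        order.append(center[lo_i])
        if hi_i != lo_i:
            order.append(center[hi_i])
        lo_i += 1
        hi_i -= 1
    planted_offsets = sorted(order[: sc.n_center_mismatches])
    planted_cols = [w0 - 1 + off - 1 for off in planted_offsets]  # 0-based

    consensus = rng.choice(_BASES, size=L)
    records: list[tuple[str, str]] = []
    groups: dict[str, str] = {}
    window_cols = set(range(w0 - 1, w1))       # 0-based window columns
    flank_cols = [w0 - 2, w1]                  # 0-based flanking columns

    outside = np.array([i for i in range(L)
                        if i not in window_cols and i not in flank_cols])
    for b in range(scenario.n_block_templates):
        seq = consensus.copy()
        if sc.block_noise_rate > 0:
            hits = outside[rng.random(len(outside)) < sc.block_noise_rate]
            _mutate(seq, hits, rng)
        for fc in flank_cols:
            seq[fc] = "-"
        rid = f"block_{b:02d}"
        records.append((rid, "".join(seq)))
        groups[rid] = "block"
    for p in range(scenario.n_protect_templates):
        seq = consensus.copy()
        _mutate(seq, np.array(planted_cols), rng)
        if sc.protect_background_rate > 0:
            hits = outside[rng.random(len(outside)) < sc.protect_background_rate]
            _mutate(seq, hits, rng)
        rid = f"protect_{p:02d}"
        records.append((rid, "".join(seq)))
        groups[rid] = "protect"
    truth = {
        "window": (w0, w1),
        "planted_oligo_positions": planted_offsets,
        "planted_columns": [c + 1 for c in planted_cols],
        "consensus_window": "".join(consensus[w0 - 1 : w1]),
    }
    return TemplateAlignment(records, groups), truth


def _taxon_weights(sc: SimScenario, with_blocker: bool) -> np.ndarray:
    w = np.empty(len(sc.community))
    for i, t in enumerate(sc.community):
        eff = sc.base_efficiency * sc.mismatch_penalty ** t.primer_3p_mismatches
        w[i] = t.proportion * (1.0 + eff) ** sc.cycles
        if with_blocker:
            w[i] *= sc.r_strong if t.center_mismatches == 0 else sc.r_weak
    return w


def simulate_read_tables(scenario: SimScenario, seed: int) -> tuple[ReadTable, dict]:
    """Draw paired with/without-blocker read tables; returns (table, truth).

    Each sample gets one library per condition; each library is a
    multinomial of size ``depth`` over the normalised per-taxon weights.
    """
    sc = scenario
    weights = {False: _taxon_weights(sc, False), True: _taxon_weights(sc, True)}
    for w in weights.values():
        if not np.any(w > 0):
            raise ValueError("all amplification weights are zero")
    streams = np.random.SeedSequence(seed).spawn(sc.n_samples * 2)
    taxa = [t.taxon_id for t in sc.community]
    rows = []
    si = 0
    for s in range(sc.n_samples):
        sample_id = f"nest_{s:02d}"
        for cond, blocked in (("no_blocker", False), ("blocker", True)):
            rng = np.random.default_rng(streams[si])
            si += 1
            p = weights[blocked] / weights[blocked].sum()
            counts = rng.multinomial(sc.depth, p)
            for t, c in zip(taxa, counts):
                if c > 0:
                    rows.append((sample_id, cond, t, int(c)))
    df = pd.DataFrame(rows, columns=["sample_id", "condition", "taxon_id", "count"])
    annotations = {
        t.taxon_id: {"group": t.group,
                     "is_nest_builder_of": t.is_nest_builder_of}
        for t in sc.community
    }
    builders = [t.is_nest_builder_of for t in sc.community
                if t.is_nest_builder_of is not None]
    built_for = builders[0] if builders else ""
    samples = {f"nest_{s:02d}": built_for for s in range(sc.n_samples)}
    truth = {
        "expected_proportions": {
            cond: dict(zip(taxa, (weights[b] / weights[b].sum()).tolist()))
            for cond, b in (("no_blocker", False), ("blocker", True))
        },
        "blocked_taxa": [t.taxon_id for t in sc.community
                         if t.center_mismatches == 0],
        "expected_blocking_efficiency": _expected_efficiency(sc, weights),
    }
    return ReadTable(df, annotations, samples), truth


def _expected_efficiency(sc: SimScenario, weights: dict) -> float:
    """Expected blocking efficiency for the blocked taxa: 100·(1 −
    E[with]/E[without]) at equal depth, i.e. based on expected read
    *proportions* of the fully blocked taxa."""
    blocked = np.array([t.center_mismatches == 0 for t in sc.community])
    if not blocked.any():
        return 0.0
    p_no = weights[False] / weights[False].sum()
    p_yes = weights[True] / weights[True].sum()
    return 100.0 * (1.0 - p_yes[blocked].sum() / p_no[blocked].sum())


def default_scenario(**overrides) -> SimScenario:
    """The default study conditions used throughout tests and examples."""
    return SimScenario(**overrides)
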