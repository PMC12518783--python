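"""Nearest-neighbor duplex thermodynamics and melting temperature for DNA
oligos carrying locked nucleic acid (LNA) substitutions.

The DNA/DNA stack uses the unified nearest-neighbor parameter set of
SantaLucia (PNAS 1998; SantaLucia & Hicks 2004): per-dinucleotide ΔH°
(kcal/mol) and ΔS° (cal/mol·K), terminal A·T / G·C initiation terms and a
symmetry correction for self-complementary duplexes. Monovalent plus
divalent salt enters through the entropic correction ΔS' = ΔS +
0.368·(N−1)·ln[Na⁺]_eq, with the divalent contribution folded into a
monovalent equivalent as [Na⁺]_eq = [mono] + 120·√([Mg²⁺] mM) (von Ahsen
et al. 2001).

LNA sugars raise duplex stability. Each nearest-neighbor step whose 5'
base is LNA-modified receives a (ΔΔH, ΔΔS) increment. The default
increment is a single sequence-independent pair chosen to reproduce the
typical +2 to +3 °C stabilisation per LNA residue reported for short
mixed-sequence oligos; a per-step table can be supplied for
sequence-dependent work. Mismatched duplexes are not modelled — blockers
are tuned on perfect-match Tm only.

Melting temperature: Tm = ΔH / (ΔS' + R·ln(C_T/x)) with x = 4 for
non-self-complementary duplexes (neither strand in excess) and x = 1 with
the symmetry entropy term for self-complementary ones. Degenerate oligos
report the arithmetic mean Tm over their concrete expansions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .oligo import DegeneracyOverflowError, Oligo, expand_degenerate

__all__ = [
    "ThermoParams",
    "TmStats",
    "duplex_thermodynamics",
    "melting_temperature",
    "tm_stats",
    "tm_offset_gap",
    "uniform_lna_increments",
    "NN_UNIFIED",
]

R_GAS = 1.987  # cal / (mol K)

# Unified DNA/DNA nearest-neighbor parameters, 5'->3' top-strand step ->
# (dH kcal/mol, dS cal/mol·K). The ten unique duplex steps; the other six
# are filled in by reverse complement below.
_NN_CORE: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(step: str) -> str:
    return _COMP[step[1]] + _COMP[step[0]]


#: Full 16-step table (step XY == reverse complement step on the other strand).
NN_UNIFIED: dict[str, tuple[float, float]] = {
    step: _NN_CORE.get(step, _NN_CORE.get(_revcomp(step), (0.0, 0.0)))
    for step in (a + b for a in "ACGT" for b in "ACGT")
}

#: Terminal initiation terms (per terminal base pair) and symmetry term.
INIT_AT: tuple[float, float] = (2.3, 4.1)
INIT_GC: tuple[float, float] = (0.1, -2.8)
SYMMETRY: tuple[float, float] = (0.0, -1.4)


def uniform_lna_increments(dh: float = -2.5, ds: float = -5.0) -> dict[str, tuple[float, float]]:
    """A sequence-independent LNA increment applied to every step whose 5'
    base is LNA (default ΔΔG°37 ≈ −0.95 kcal/mol per residue)."""
    return {step: (dh, ds) for step in NN_UNIFIED}


@dataclass
class ThermoParams:
    """Parameter bundle for duplex thermodynamics and Tm.

    Defaults mirror a standard metabarcoding PCR: 1 µM oligo, 50 mM
    monovalent salt and 2.5 mM Mg²⁺.
    """

    nn_table: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(NN_UNIFIED))
    init_at: tuple[float, float] = INIT_AT
    init_gc: tuple[float, float] = INIT_GC
    symmetry: tuple[float, float] = SYMMETRY
    lna_increments: dict[str, tuple[float, float]] = field(
        default_factory=uniform_lna_increments)
    oligo_conc: float = 1e-6        # molar, each strand
    monovalent_salt: float = 0.05   # molar
    divalent_salt: float = 0.0025   # molar (Mg2+)
    expansion_cap: int = 512

    def __post_init__(self) -> None:
        if self.oligo_conc <= 0 or self.monovalent_salt <= 0:
            raise ValueError("concentrations must be positive")
        missing = set(NN_UNIFIED) - set(self.nn_table)
        if missing:
            raise ValueError(f"nn_table missing steps: {sorted(missing)}")


def _is_self_complementary(seq: str) -> bool:
    return seq == "".join(_COMP[b] for b in reversed(seq))


def duplex_thermodynamics(seq: str, lna_mask: frozenset[int] | set[int],
                          params: ThermoParams) -> tuple[float, float]:
    """Perfect-match duplex (ΔH kcal/mol, ΔS cal/mol·K) for a concrete
    sequence; LNA increments added for steps whose 5' base is modified."""
    if len(seq) < 2:
        raise ValueError("need at least 2 bases for a nearest-neighbor sum")
    if set(seq) - set("ACGT"):
        raise ValueError(f"degenerate or invalid base in {seq!r}; expand first")
    dh, ds = 0.0, 0.0
    for term in (seq[0], seq[-1]):
        inc = params.init_at if term in "AT" else params.init_gc
        dh += inc[0]
        ds += inc[1]
    for i in range(len(seq) - 1):
        step = seq[i : i + 2]
        h, s = params.nn_table[step]
        dh += h
        ds += s
        if (i + 1) in lna_mask:  # 5' base of this step is LNA
            lh, ls = params.lna_increments[step]
            dh += lh
            ds += ls
    if _is_self_complementary(seq):
        dh += params.symmetry[0]
        ds += params.symmetry[1]
    return dh, ds


def _salt_corrected_entropy(ds: float, n_bases: int, params: ThermoParams) -> float:
    na_eq_mm = params.monovalent_salt * 1e3 + 120.0 * math.sqrt(
        max(params.divalent_salt, 0.0) * 1e3)
    return ds + 0.368 * (n_bases - 1) * math.log(na_eq_mm / 1e3)


def _tm_concrete(seq: str, lna_mask: frozenset[int] | set[int],
                 params: ThermoParams) -> float:
    dh, ds = duplex_thermodynamics(seq, lna_mask, params)
    ds = _salt_corrected_entropy(ds, len(seq), params)
    k = params.oligo_conc if _is_self_complementary(seq) else params.oligo_conc / 2.0
    return dh * 1000.0 / (ds + R_GAS * math.log(k)) - 273.15


@dataclass(frozen=True)
class TmStats:
    """Tm over the concrete expansions of a (possibly degenerate) oligo."""

    mean: float
    min: float
    max: float
    n_expansions: int


def tm_stats(o: Oligo, params: ThermoParams | None = None) -> TmStats:
    params = params or ThermoParams()
    if len(o) < 2:
        raise ValueError("oligo too short for a nearest-neighbor Tm")
    try:
        seqs = expand_degenerate(o, cap=params.expansion_cap)
    except DegeneracyOverflowError:
        raise
    tms = [_tm_concrete(s, o.lna_mask, params) for s in seqs]
    return TmStats(sum(tms) / len(tms), min(tms), max(tms), len(tms))


def melting_temperature(o: Oligo, params: ThermoParams | None = None) -> float:
    """Tm in °C; degenerate oligos return the mean over expansions."""
    return tm_stats(o, params).mean


def tm_offset_gap(blocker: Oligo, primers, target_offset: float = 7.0,
                  params: ThermoParams | None = None) -> float:
    """Signed gap Tm(blocker) − max(primer annealing Tms) − target_offset.

    Zero means the blocker sits exactly ``target_offset`` °C above the
    hotter primer, the condition for the blocker to anneal first during
    cycling. Primer Tms are computed on annealing regions only (linker
    tails do not hybridise to template).
    """
    params = params or ThermoParams()
    tm_b = melting_temperature(blocker, params)
    tm_f = melting_temperature(primers.forward_annealing, params)
    tm_r = melting_temperature(primers.reverse_annealing, params)
    return tm_b - max(tm_f, tm_r) - target_offset
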