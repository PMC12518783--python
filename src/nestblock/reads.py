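"""Analytics over paired with/without-blocker metabarcoding read tables.

Input is a long-format table with one row per (sample, condition, taxon)
and a non-negative integer read count, where condition is ``blocker`` or
``no_blocker``. Taxon annotations carry a free-form group label (e.g.
"sparrow", "predator", "ectoparasite") and, for nest-builder species, the
identity they build for; sample annotations name each sample's
nest-builder. From these the module computes the quantities used to judge
a blocking oligonucleotide in the field:

* blocking efficiency — the percent reduction in target-taxon reads;
* species richness under minimum-read or relative-read-abundance (RRA)
  thresholds, per sample or site-wide, with percent change;
* species accumulation curves by repeated random permutation of samples
  (subsampling without replacement);
* paired t-tests on per-sample richness;
* detection summaries (fraction of samples where a taxon group appears).

Printed percentages round half away from zero, matching how such numbers
are conventionally reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CONDITIONS",
    "ReadTable",
    "Scope",
    "ThresholdKind",
    "RichnessResult",
    "blocking_efficiency",
    "percent_change",
    "round_half_away",
    "richness",
    "per_sample_richness",
    "threshold_sweep",
    "species_accumulation",
    "paired_mean_difference_test",
    "detection_summary",
]

CONDITIONS = ("blocker", "no_blocker")
POOLED = "pooled"

REQUIRED_COLUMNS = ["sample_id", "condition", "taxon_id", "count"]


class Scope(str, Enum):
    PER_SAMPLE = "per_sample"
    SITE_WIDE = "site_wide"


class ThresholdKind(str, Enum):
    MIN_READS = "min_reads"
    MIN_RRA = "min_rra"


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (so 6.5 -> 7,
    -6.5 -> -7); this is the convention behind reported whole percents."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class ReadTable:
    """Long-format read counts plus taxon and sample annotations.

    ``taxa`` maps taxon_id -> {"group": label, "is_nest_builder_of":
    species-or-None}; ``samples`` maps sample_id -> nest-builder species.
    """

    counts: pd.DataFrame
    taxa: dict[str, dict] | None = None
    samples: dict[str, str] | None = None

    def __post_init__(self) -> None:
        df = self.counts
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"read table missing columns {missing}")
        if df.empty:
            raise ValueError("read table is empty")
        bad = set(df["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")
        if (df["count"] < 0).any():
            raise ValueError("negative read counts")
        if df.duplicated(["sample_id", "condition", "taxon_id"]).any():
            raise ValueError("duplicate (sample, condition, taxon) rows")
        self.counts = df.astype({"count": "int64"})
        self.taxa = self.taxa or {}
        self.samples = self.samples or {}

    # -- views -----------------------------------------------------------
    def condition_slice(self, condition: str) -> pd.DataFrame:
        """Rows for one condition, or counts pooled (summed) across
        conditions per (sample, taxon) when condition == "pooled"."""
        if condition == POOLED:
            return (self.counts.groupby(["sample_id", "taxon_id"], as_index=False)
                    ["count"].sum().assign(condition=POOLED))
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return self.counts[self.counts["condition"] == condition]

    def without_nest_builders(self) -> "ReadTable":
        """Drop rows where the taxon is the nest-builder of that sample.

        The exclusion is per-sample: the same species detected in another
        species' nest still counts as a detection there.
        """
        if not self.taxa or not self.samples:
            return self
        builder_of = {t: a.get("is_nest_builder_of")
                      for t, a in self.taxa.items()}
        df = self.counts
        drop = df.apply(
            lambda r: builder_of.get(r["taxon_id"]) is not None
            and self.samples.get(r["sample_id"]) == builder_of[r["taxon_id"]],
            axis=1,
        )
        kept = df[~drop]
        if kept.empty:
            raise ValueError("nest-builder exclusion removed every row")
        return ReadTable(kept.copy(), self.taxa, self.samples)

    def taxa_in_group(self, label: str) -> set[str]:
        found = {t for t, a in (self.taxa or {}).items()
                 if a.get("group") == label}
        if not found:
            raise ValueError(f"no taxa annotated with group {label!r}")
        return found


# -- headline arithmetic -------------------------------------------------

def blocking_efficiency(reads_with: int, reads_without: int) -> float:
    """Percent reduction in reads attributable to the blocker:
    100·(1 − with/without). Negative when reads increased."""
    if reads_without <= 0:
        raise ValueError("blocking efficiency undefined without baseline reads")
    if reads_with < 0:
        raise ValueError("read counts must be non-negative")
    return 100.0 * (1.0 - reads_with / reads_without)


def percent_change(before: int, after: int) -> int:
    """Whole-percent change 100·(after − before)/before, half away from 0."""
    if before <= 0:
        raise ValueError("percent change undefined for before <= 0")
    return round_half_away(100.0 * (after - before) / before)


# -- richness ------------------------------------------------------------

def _apply_threshold(df: pd.DataFrame, kind: ThresholdKind, threshold: float,
                     scope: Scope) -> pd.DataFrame:
    """Retain rows meeting the threshold.

    min_reads compares raw counts (per library for per-sample scope, or
    summed across samples for site-wide scope). RRA denominators are per
    sample x condition library totals over *all* taxa; site-wide RRA uses
    the condition-wide total.
    """
    if kind is ThresholdKind.MIN_READS:
        if threshold < 0:
            raise ValueError("min_reads threshold must be >= 0")
        cut = max(1.0, float(threshold))  # 0 reads never count as presence
        if scope is Scope.SITE_WIDE:
            sums = df.groupby("taxon_id")["count"].sum()
            return sums[sums >= cut].reset_index()
        return df[df["count"] >= cut]
    if not 0 <= threshold <= 1:
        raise ValueError("min_rra threshold must be in [0, 1]")
    if scope is Scope.SITE_WIDE:
        sums = df.groupby("taxon_id")["count"].sum()
        total = sums.sum()
        if total == 0:
            return sums[sums > 0].reset_index()
        keep = sums[(sums / total >= threshold) & (sums > 0)]
        return keep.reset_index()
    totals = df.groupby(["sample_id", "condition"])["count"].transform("sum")
    rra = df["count"] / totals.replace(0, np.nan)
    return df[(rra >= threshold) & (df["count"] > 0)]


def richness(table: ReadTable, condition: str,
             threshold_kind: ThresholdKind = ThresholdKind.MIN_READS,
             threshold: float = 1, scope: Scope = Scope.SITE_WIDE,
             exclude_nest_builders: bool = False) -> int:
    """Distinct retained taxa, site-wide, for one condition (or "pooled")."""
    if scope is not Scope.SITE_WIDE:
        raise ValueError("use per_sample_richness() for per-sample scope")
    t = table.without_nest_builders() if exclude_nest_builders else table
    df = t.condition_slice(condition)
    kept = _apply_threshold(df, threshold_kind, threshold, Scope.SITE_WIDE)
    return int(kept["taxon_id"].nunique())


def per_sample_richness(table: ReadTable, condition: str,
                        threshold_kind: ThresholdKind = ThresholdKind.MIN_READS,
                        threshold: float = 1,
                        exclude_nest_builders: bool = False) -> pd.Series:
    """Retained-taxon count per sample (index: sample_id), including
    zero-richness samples that had reads in the other condition."""
    t = table.without_nest_builders() if exclude_nest_builders else table
    df = t.condition_slice(condition)
    kept = _apply_threshold(df, threshold_kind, threshold, Scope.PER_SAMPLE)
    counts = kept.groupby("sample_id")["taxon_id"].nunique()
    all_samples = sorted(t.counts["sample_id"].unique())
    return counts.reindex(all_samples, fill_value=0).astype(int)


@dataclass(frozen=True)
class RichnessResult:
    scope: Scope
    threshold_kind: ThresholdKind
    threshold: float
    richness_without: int
    richness_with: int
    percent_change: int | None

    @staticmethod
    def from_pair(scope: Scope, kind: ThresholdKind, threshold: float,
                  without: int, with_: int) -> "RichnessResult":
        pc = percent_change(without, with_) if without > 0 else None
        return RichnessResult(scope, kind, threshold, without, with_, pc)


def threshold_sweep(table: ReadTable, thresholds: list[float],
                    scope: Scope = Scope.SITE_WIDE,
                    threshold_kind: ThresholdKind = ThresholdKind.MIN_READS,
                    exclude_nest_builders: bool = False) -> list[RichnessResult]:
    """Richness with/without blocker at each threshold. For per-sample
    scope the reported number is the summed per-sample richness."""
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    out = []
    for thr in thresholds:
        vals = {}
        for cond in CONDITIONS:
            if scope is Scope.SITE_WIDE:
                vals[cond] = richness(table, cond, threshold_kind, thr,
                                      exclude_nest_builders=exclude_nest_builders)
            else:
                vals[cond] = int(per_sample_richness(
                    table, cond, threshold_kind, thr,
                    exclude_nest_builders=exclude_nest_builders).sum())
        out.append(RichnessResult.from_pair(
            scope, threshold_kind, thr, vals["no_blocker"], vals["blocker"]))
    return out


# -- accumulation curves --------------------------------------------------

def species_accumulation(table: ReadTable, condition: str,
                         n_permutations: int = 100, seed: int | None = None,
                         min_reads: float = 1,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample-based species accumulation by random permutation.

    For each of ``n_permutations`` random orderings of the samples
    (subsampling without replacement), the cumulative number of distinct
    taxa over the first k samples is recorded; returns a frame with
    columns k, mean, sd.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if rng is None:
        if seed is None:
            raise ValueError("provide an explicit seed (or a Generator)")
        rng = np.random.default_rng(seed)
    df = table.condition_slice(condition)
    present = df[df["count"] >= max(1.0, float(min_reads))]
    samples = sorted(df["sample_id"].unique())
    if not samples:
        raise ValueError(f"no samples in condition {condition!r}")
    taxa = sorted(present["taxon_id"].unique())
    tindex = {t: j for j, t in enumerate(taxa)}
    inc = np.zeros((len(samples), len(taxa)), dtype=bool)
    for i, s in enumerate(samples):
        for t in present.loc[present["sample_id"] == s, "taxon_id"]:
            inc[i, tindex[t]] = True
    n = len(samples)
    curves = np.empty((n_permutations, n), dtype=np.int64)
    for p in range(n_permutations):
        order = rng.permutation(n)
        seen = np.cumsum(inc[order], axis=0) > 0  # taxon seen by step k
        curves[p] = seen.sum(axis=1)
    return pd.DataFrame({
        "k": np.arange(1, n + 1),
        "mean": curves.mean(axis=0),
        "sd": curves.std(axis=0, ddof=1) if n_permutations > 1
              else np.zeros(n),
    })


def expected_accumulation(table: ReadTable, condition: str,
                          min_reads: float = 1) -> np.ndarray:
    """Closed-form expectation of the accumulation curve:
    E[S_k] = sum_t (1 − C(N−n_t, k)/C(N, k)) with N samples and n_t the
    number of samples containing taxon t."""
    df = table.condition_slice(condition)
    present = df[df["count"] >= max(1.0, float(min_reads))]
    samples = sorted(df["sample_id"].unique())
    n = len(samples)
    occ = present.groupby("taxon_id")["sample_id"].nunique().to_numpy()
    ks = np.arange(1, n + 1)
    out = np.zeros(n)
    for k_i, k in enumerate(ks):
        miss = np.array([
            math.comb(n - nt, k) / math.comb(n, k) if n - nt >= k else 0.0
            for nt in occ
        ])
        out[k_i] = np.sum(1.0 - miss)
    return out


def relative_retention(table: ReadTable, target_taxa: set[str],
                       reference_taxa: set[str],
                       reference_retention: float = 1.0) -> float:
    """Estimate the blocker's read-retention factor for ``target_taxa``.

    Libraries are sequenced to a fixed depth, so suppressing an abundant
    taxon frees depth and inflates every other taxon's reads; the naive
    with/without ratio therefore overestimates retention. Normalising by
    a set of reference taxa with known retention removes the shared
    renormalisation:

        r_target = (T_with/T_without) / (R_with/R_without) · r_reference

    with T and R summed reads of target and reference taxa per condition.
    """
    if not target_taxa or not reference_taxa:
        raise ValueError("target and reference taxon sets must be non-empty")
    if target_taxa & reference_taxa:
        raise ValueError("target and reference taxa must be disjoint")
    sums = {}
    for cond in CONDITIONS:
        df = table.condition_slice(cond)
        sums[cond] = {
            "target": int(df[df["taxon_id"].isin(target_taxa)]["count"].sum()),
            "ref": int(df[df["taxon_id"].isin(reference_taxa)]["count"].sum()),
        }
    if sums["no_blocker"]["target"] == 0 or sums["no_blocker"]["ref"] == 0 \
            or sums["blocker"]["ref"] == 0:
        raise ValueError("zero baseline reads; retention undefined")
    t_ratio = sums["blocker"]["target"] / sums["no_blocker"]["target"]
    r_ratio = sums["blocker"]["ref"] / sums["no_blocker"]["ref"]
    return t_ratio / r_ratio * reference_retention


# -- tests and summaries --------------------------------------------------

def paired_mean_difference_test(with_values, without_values) -> tuple[float, int, float]:
    """Paired t-test on per-sample values: d = with − without,
    t = mean(d)/(sd(d)/sqrt(n)), df = n−1, two-sided p.

    Degenerate inputs: all differences zero -> (0, n−1, 1); zero variance
    with nonzero mean -> t = ±inf, p = 0 (flagged by the infinity).
    """
    w = np.asarray(with_values, dtype=float)
    wo = np.asarray(without_values, dtype=float)
    if w.shape != wo.shape or w.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    n = len(w)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = w - wo
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if d.mean() == 0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, d.mean()), df, 0.0
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def detection_summary(table: ReadTable, label: str,
                      min_reads: float = 1) -> tuple[int, int, int]:
    """(n detected, n total samples, whole percent) for a taxon group.

    A sample counts as detected when any taxon carrying the group label
    reaches ``min_reads`` with conditions pooled (summed per taxon).
    """
    group = table.taxa_in_group(label)
    pooled = table.condition_slice(POOLED)
    hits = pooled[(pooled["taxon_id"].isin(group))
                  & (pooled["count"] >= max(1.0, float(min_reads)))]
    n_total = int(table.counts["sample_id"].nunique())
    n_det = int(hits["sample_id"].nunique())
    pct = round_half_away(100.0 * n_det / n_total) if n_total else 0
    return n_det, n_total, pct


# -- I/O -------------------------------------------------------------------

def read_table_from_files(reads: str | Path,
                          annotations: str | Path | None = None,
                          samples: str | Path | None = None) -> ReadTable:
    """Load a ReadTable from delimited files.

    ``reads``: TSV/CSV (or XLSX for supplementary-style spreadsheets) with
    columns sample_id, condition, taxon_id, count. ``annotations``: TSV
    with taxon_id, group[, is_nest_builder_of]. ``samples``: TSV with
    sample_id, nest_builder.
    """
    reads = Path(reads)
    if reads.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(reads)
    else:
        sep = "," if reads.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(reads, sep=sep)
    taxa = None
    if annotations is not None:
        ann = pd.read_csv(annotations, sep="\t")
        taxa = {}
        for _, row in ann.iterrows():
            builder = row.get("is_nest_builder_of")
            taxa[str(row["taxon_id"])] = {
                "group": row["group"],
                "is_nest_builder_of": None if pd.isna(builder) else str(builder),
            }
    sample_map = None
    if samples is not None:
        smp = pd.read_csv(samples, sep="\t")
        sample_map = dict(zip(smp["sample_id"].astype(str),
                              smp["nest_builder"].astype(str)))
    return ReadTable(df, taxa, sample_map)
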