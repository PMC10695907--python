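"""Group comparison statistics and in vivo success-rate summaries.

The central test is a two-sided Mann–Whitney U test.  The exact branch
computes the permutation null distribution of the rank-sum statistic by
dynamic programming over the pooled (mid)ranks, which is feasible whenever
the number of group assignments ``C(n_a + n_b, n_a)`` is below a
configurable cap; otherwise a normal approximation with tie-corrected
variance and continuity correction is used.  Two-sided p-values are formed
by doubling the smaller tail, capped at 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "FeatureSample",
    "GroupComparison",
    "ProcedureRecord",
    "PoolabilityDecision",
    "SuccessSummary",
    "mann_whitney",
    "check_set_poolability",
    "cutting_success",
    "procedural_success",
    "load_procedure_records",
]

#: default cap on the number of enumerable group assignments for the exact test
DEFAULT_EXACT_CAP = 200_000


@dataclass(frozen=True)
class FeatureSample:
    """One group's (or one set's) values of a single feature."""

    group: str
    values: tuple[float, ...]
    set_id: int | None = None

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError(f"FeatureSample for group {self.group!r} is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in group {self.group!r}")


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group Mann–Whitney comparison.

    ``u_statistic`` is the U of the first group; swapping the groups maps it
    to ``n_a * n_b - U`` and leaves the p-value unchanged.
    """

    u_statistic: float
    p_two_sided: float
    n_a: int
    n_b: int
    method: str  # "exact" | "normal_approx"
    tie_corrected: bool


@dataclass(frozen=True)
class ProcedureRecord:
    """In vivo counts for one animal: cutting manoeuvres, biopsies, complications."""

    animal_id: str
    bioptome: str
    n_manoeuvres: int
    n_biopsies: int
    major_complication: bool = False

    def __post_init__(self) -> None:
        if self.n_manoeuvres < 1:
            raise ValueError(
                f"animal {self.animal_id!r}: n_manoeuvres must be >= 1")
        if self.n_biopsies < 0:
            raise ValueError(f"animal {self.animal_id!r}: n_biopsies must be >= 0")
        if self.n_biopsies > self.n_manoeuvres:
            raise ValueError(
                f"animal {self.animal_id!r}: n_biopsies ({self.n_biopsies}) exceeds "
                f"n_manoeuvres ({self.n_manoeuvres})")


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=128)
def _rank_sum_distribution(n_a: int, doubled_ranks: tuple[int, ...]):
    """Exact null distribution of the doubled rank sum of a size-``n_a`` subset.

    Midranks are multiples of 1/2, so doubling makes them integers and the
    distribution is computed by subset-sum dynamic programming.  Returns
    ``(sums, counts)`` over all ``C(len(doubled_ranks), n_a)`` subsets.
    """
    max_sum = sum(sorted(doubled_ranks)[-n_a:])
    ways = np.zeros((n_a + 1, max_sum + 1), dtype=np.int64)
    ways[0, 0] = 1
    for w in doubled_ranks:
        for k in range(n_a, 0, -1):
            ways[k, w:] = ways[k, w:] + ways[k - 1, :max_sum + 1 - w]
    sums = np.flatnonzero(ways[n_a])
    return tuple(int(s) for s in sums), tuple(int(c) for c in ways[n_a, sums])


def mann_whitney(a, b, method: str = "auto",
                 exact_cap: int = DEFAULT_EXACT_CAP) -> GroupComparison:
    """Two-sided Mann–Whitney U test between two samples.

    Parameters
    ----------
    a, b : sequence of float
        The two groups; both non-empty.
    method : {"auto", "exact", "normal_approx"}
        "auto" uses the exact permutation distribution when
        ``C(n_a + n_b, n_a) <= exact_cap``.
    exact_cap : int
        Assignment-count threshold for the automatic choice.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if method not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown method {method!r}")

    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks for ties
    ties = len(np.unique(pooled)) < n
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)

    if method == "auto":
        method = "exact" if comb(n, n_a) <= exact_cap else "normal_approx"

    if method == "exact":
        doubled = tuple(int(round(2 * r)) for r in sorted(ranks))
        sums, counts = _rank_sum_distribution(n_a, doubled)
        # doubled U for each achievable doubled rank sum
        u2 = np.asarray(sums, dtype=np.int64) - n_a * (n_a + 1)
        counts = np.asarray(counts, dtype=np.float64)
        u2_obs = int(round(2 * u_a))
        # double the smaller observed tail; with ties the distribution is
        # not symmetric, so both tails must be evaluated directly
        tail_lo = counts[u2 <= u2_obs].sum()
        tail_hi = counts[u2 >= u2_obs].sum()
        p = min(1.0, 2.0 * min(tail_lo, tail_hi) / counts.sum())
    else:
        mean = n_a * n_b / 2.0
        tie_counts = np.asarray(list(Counter(pooled.tolist()).values()))
        tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var <= 0:  # all pooled values identical
            p = 1.0
        else:
            z = max(abs(u_a - mean) - 0.5, 0.0) / sqrt(var)
            p = min(1.0, 2.0 * float(norm.sf(z)))

    return GroupComparison(u_statistic=u_a, p_two_sided=p, n_a=n_a, n_b=n_b,
                           method=method, tie_corrected=ties)


# ---------------------------------------------------------------------------
# set poolability


@dataclass(frozen=True)
class PoolabilityDecision:
    """Pairwise within-group set comparisons and the pooling verdict.

    Pooling is approved iff no pairwise comparison of sets within a group
    rejects at ``alpha``.
    """

    approved: bool
    alpha: float
    pairwise: tuple[tuple[str, int, int, GroupComparison], ...] = field(default=())

    @property
    def p_values(self) -> tuple[float, ...]:
        return tuple(cmp.p_two_sided for _, _, _, cmp in self.pairwise)


def check_set_poolability(samples, alpha: float = 0.05,
                          method: str = "auto",
                          exact_cap: int = DEFAULT_EXACT_CAP) -> PoolabilityDecision:
    """Decide whether repeated sets within each group may be pooled.

    ``samples`` holds one :class:`FeatureSample` per (group, set) for a
    single feature.  Every pair of sets within a group is compared with
    :func:`mann_whitney`; any rejection vetoes pooling.
    """
    by_group: dict[str, list[FeatureSample]] = {}
    for s in samples:
        if s.set_id is None:
            raise ValueError(f"sample for group {s.group!r} has no set_id")
        by_group.setdefault(s.group, []).append(s)
    pairwise = []
    for group in sorted(by_group):
        sets = sorted(by_group[group], key=lambda s: s.set_id)
        if len(sets) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 sets")
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                cmp_ = mann_whitney(sets[i].values, sets[j].values,
                                    method=method, exact_cap=exact_cap)
                pairwise.append((group, sets[i].set_id, sets[j].set_id, cmp_))
    approved = all(c.p_two_sided >= alpha for _, _, _, c in pairwise)
    return PoolabilityDecision(approved=approved, alpha=alpha,
                               pairwise=tuple(pairwise))


# ---------------------------------------------------------------------------
# in vivo success rates


@dataclass(frozen=True)
class SuccessSummary:
    """Per-bioptome success percentages: mean ± sample SD over animals."""

    bioptome: str
    mean_pct: float
    sd_pct: float
    n_animals: int
    per_animal_pct: tuple[float, ...] = field(default=())


def _by_bioptome(records) -> dict[str, list[ProcedureRecord]]:
    if not records:
        raise ValueError("no procedure records supplied")
    grouped: dict[str, list[ProcedureRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.bioptome, []).append(rec)
    return grouped


def cutting_success(records) -> dict[str, SuccessSummary]:
    """Cutting success per bioptome: biopsies per cutting manoeuvre, in percent.

    The per-animal rate is ``100 * n_biopsies / n_manoeuvres``; the summary
    is the mean and sample (n-1) SD across animals (SD is NaN for a single
    animal).
    """
    out = {}
    for bioptome, recs in sorted(_by_bioptome(records).items()):
        rates = np.array([100.0 * r.n_biopsies / r.n_manoeuvres for r in recs])
        sd = float(rates.std(ddof=1)) if rates.size > 1 else float("nan")
        out[bioptome] = SuccessSummary(bioptome=bioptome,
                                       mean_pct=float(rates.mean()), sd_pct=sd,
                                       n_animals=rates.size,
                                       per_animal_pct=tuple(rates.tolist()))
    return out


def procedural_success(records, min_biopsies: int = 6) -> dict[str, float]:
    """Percent of animals per bioptome with >= ``min_biopsies`` biopsies and
    no major complication."""
    out = {}
    for bioptome, recs in sorted(_by_bioptome(records).items()):
        wins = sum(1 for r in recs
                   if r.n_biopsies >= min_biopsies and not r.major_complication)
        out[bioptome] = 100.0 * wins / len(recs)
    return out


def bundled_synthetic_records() -> list[ProcedureRecord]:
    """Synthetic in vivo procedure records bundled for demos and examples.

    Three animals per bioptome with counts emulating a real-time MR-guided
    biopsy campaign (at least six specimens per animal, no major
    complications); see ``data/invivo_records_synthetic.csv``.
    """
    from importlib.resources import files

    return load_procedure_records(files("biopsy3d.data") / "invivo_records_synthetic.csv")


def load_procedure_records(path) -> list[ProcedureRecord]:
    """Read procedure records from a CSV with columns
    ``animal_id, bioptome, n_manoeuvres, n_biopsies, major_complication``."""
    frame = pd.read_csv(path)
    required = {"animal_id", "bioptome", "n_manoeuvres", "n_biopsies",
                "major_complication"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"procedure-record CSV is missing columns {sorted(missing)}")
    return [
        ProcedureRecord(animal_id=str(row.animal_id), bioptome=str(row.bioptome),
                        n_manoeuvres=int(row.n_manoeuvres),
                        n_biopsies=int(row.n_biopsies),
                        major_complication=bool(row.major_complication))
        for row in frame.itertuples()
    ]
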