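"""Cohort orchestration: per-sample calls, group comparison, summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .distance import (
    NearestDistanceSample,
    nearest_modal_distances,
    partition_modal_rare,
)
from .errors import DegeneratePartitionError, InsufficientDataError
from .io import AlignedOtuTable, GroupTable, read_abundance_table, read_aligned_fasta
from .multimodality import (
    CommunityAssemblyCall,
    classify_assembly,
    silverman_test,
)

HYBRID, NICHE, NEUTRAL = "HYBRID", "NICHE", "NEUTRAL"


def _withheld_call(
    table: AlignedOtuTable,
    n_rare: int,
    n_modal: int,
    expected: float | None,
) -> CommunityAssemblyCall:
    return CommunityAssemblyCall(
        sample_id=table.sample_id,
        classification=None,
        silverman=None,
        primary_mode_location=None,
        expected_neutral_mean=expected,
        n_rare=n_rare,
        n_modal=n_modal,
        sufficient_data=False,
    )


def analyze_table(
    table: AlignedOtuTable, config: AnalysisConfig | None = None
) -> Tuple[CommunityAssemblyCall, NearestDistanceSample | None]:
    """Classify one in-memory community table.

    Runs partition -> nearest-modal distances -> Silverman's test ->
    classification. Degenerate partitions and samples with fewer than
    ``min_rare`` rare OTUs (or zero distance spread) yield a withheld call
    with ``sufficient_data=False`` rather than an exception, so cohort runs
    continue across samples.
    """
    config = config or AnalysisConfig()
    try:
        partition = partition_modal_rare(table, config.k, config.threshold_mode)
    except DegeneratePartitionError:
        return _withheld_call(table, 0, 0, None), None
    distances = nearest_modal_distances(table, partition)
    if distances.n < config.min_rare:
        return classify_assembly(distances, None, config), distances
    try:
        result = silverman_test(
            distances.values,
            n_null=config.n_null,
            n_boot=config.n_boot,
            seed=config.seed,
            grid_size=config.grid_size,
            tol=config.bandwidth_tol,
        )
    except InsufficientDataError:
        return classify_assembly(distances, None, config), distances
    return classify_assembly(distances, result, config), distances


def run_sample(
    fasta_path,
    abundance_path,
    config: AnalysisConfig | None = None,
    plot_path=None,
    sample_id: str | None = None,
) -> CommunityAssemblyCall:
    """End-to-end classification of one sample from its files."""
    table = read_aligned_fasta(fasta_path, sample_id=sample_id)
    table = read_abundance_table(abundance_path, table)
    call, distances = analyze_table(table, config)
    if plot_path is not None and distances is not None and distances.n > 0:
        from .plotting import plot_distance_distribution

        plot_distance_distribution(distances, call.silverman, path=plot_path)
    return call


def fisher_exact_2x2(table) -> Tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns ``(p_value, odds_ratio)``. The p-value follows the
    probability-mass convention: the sum of hypergeometric point
    probabilities, with margins fixed, of every table no more probable than
    the observed one. The odds ratio is the sample odds ratio (a*d)/(b*c),
    infinite when b*c = 0.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.all(np.equal(np.mod(t, 1), 0)):
            raise ValueError("table entries must be integers")
        t = t.astype(np.int64)
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if t.sum() == 0:
        raise ValueError("table is all zero")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(min(p, 1.0)), float(odds)


@dataclass
class GroupComparison:
    """2x2 comparison of HYBRID vs not-HYBRID calls between two groups."""

    group_labels: tuple
    counts: list  # rows = groups (sorted labels), cols = [HYBRID, not-HYBRID]
    odds_ratio: float
    p_value: float
    summaries: dict  # label -> {n_hybrid, n_total, fraction, formatted}
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "counts": [list(row) for row in self.counts],
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "summaries": self.summaries,
            "n_excluded": self.n_excluded,
        }


def summarize_calls(
    calls: Iterable[CommunityAssemblyCall], groups: GroupTable
) -> pd.DataFrame:
    """Per-group hybrid fractions, formatted as ``percent (x/n)``."""
    rows = {}
    for call in calls:
        if call.sample_id not in groups:
            raise ValueError(f"sample {call.sample_id!r} missing from group table")
        if not call.sufficient_data or call.classification is None:
            continue
        label = groups[call.sample_id]
        n_hyb, n_tot = rows.get(label, (0, 0))
        rows[label] = (n_hyb + (call.classification == HYBRID), n_tot + 1)
    out = []
    for label in sorted(rows):
        n_hyb, n_tot = rows[label]
        out.append(
            {
                "group": label,
                "n_hybrid": n_hyb,
                "n_total": n_tot,
                "fraction": n_hyb / n_tot if n_tot else float("nan"),
                "formatted": (
                    f"{100.0 * n_hyb / n_tot:.2f}% ({n_hyb}/{n_tot})"
                    if n_tot
                    else f"NA (0/0)"
                ),
            }
        )
    return pd.DataFrame(out)


def compare_groups(
    calls: Sequence[CommunityAssemblyCall], groups: GroupTable
) -> GroupComparison:
    """Fisher's exact comparison of hybrid-call rates between two groups.

    Builds the 2x2 table of HYBRID vs not-HYBRID (NICHE and NEUTRAL both
    count as not-HYBRID) by group, excluding withheld (insufficient-data)
    samples, and runs the two-sided test. Requires exactly two groups; with
    more, compare pairs explicitly.
    """
    labels = groups.labels
    if len(labels) != 2:
        raise ValueError(
            f"group comparison needs exactly 2 groups, got {len(labels)} "
            f"({labels}); run pairwise comparisons instead"
        )
    counts = {label: [0, 0] for label in labels}
    n_excluded = 0
    for call in calls:
        if call.sample_id not in groups:
            raise ValueError(f"sample {call.sample_id!r} missing from group table")
        if not call.sufficient_data or call.classification is None:
            n_excluded += 1
            continue
        col = 0 if call.classification == HYBRID else 1
        counts[groups[call.sample_id]][col] += 1
    table = [counts[labels[0]], counts[labels[1]]]
    p_value, odds = fisher_exact_2x2(table)
    summary_df = summarize_calls(
        [c for c in calls if c.sufficient_data and c.classification], groups
    )
    summaries = {
        row["group"]: {
            "n_hybrid": int(row["n_hybrid"]),
            "n_total": int(row["n_total"]),
            "fraction": float(row["fraction"]),
            "formatted": row["formatted"],
        }
        for _, row in summary_df.iterrows()
    }
    return GroupComparison(
        group_labels=tuple(labels),
        counts=table,
        odds_ratio=odds,
        p_value=p_value,
        summaries=summaries,
        n_excluded=n_excluded,
    )
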