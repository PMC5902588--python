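"""Comparison of priority rankings across extinction-probability schemes.

Rank deltas follow the convention of using one scheme as the reference:
``delta = rank_alternative - rank_reference``, so a negative delta means
the reference scheme prioritizes the species over the alternative.  A
difference of at most 10 ranks is treated as equivalent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

EQUIVALENCE_BAND = 10


def load_ranking_csv(path) -> dict[str, int]:
    """Read a two-column (species, rank) CSV into a mapping."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (species, rank)")
    species_col, rank_col = df.columns[:2]
    return dict(zip(df[species_col].astype(str), df[rank_col].astype(int)))


def rank_difference(
    reference: Mapping[str, int],
    alternative: Mapping[str, int],
    equivalence_band: int = EQUIVALENCE_BAND,
) -> pd.DataFrame:
    """Per-species signed rank difference between two rankings.

    Both rankings must cover the same species; mismatches are reported by
    name rather than silently dropped.
    """
    mismatch = set(reference) ^ set(alternative)
    if mismatch:
        raise ValueError(
            f"rankings cover different species: {sorted(mismatch)[:10]}"
            + ("..." if len(mismatch) > 10 else "")
        )
    species = sorted(reference)
    df = pd.DataFrame(
        {
            "species": species,
            "rank_reference": [reference[s] for s in species],
            "rank_alternative": [alternative[s] for s in species],
        }
    )
    df["delta"] = df["rank_alternative"] - df["rank_reference"]
    df["equivalent"] = df["delta"].abs() <= equivalence_band
    return df


@dataclass(frozen=True)
class OverlapResult:
    """Intersection of two top-k sets with a per-category breakdown."""

    k: int
    top_a: frozenset[str]
    top_b: frozenset[str]
    overlap: frozenset[str]
    breakdown: Mapping[str, int]

    @property
    def size(self) -> int:
        return len(self.overlap)


def top_k_overlap(
    ranking_a: Mapping[str, int],
    ranking_b: Mapping[str, int],
    k: int,
    categories: Mapping[str, str] | None = None,
) -> OverlapResult:
    """Overlap of the two top-k sets under competition ranking.

    The top-k set is every species with rank <= k; boundary ties are
    included, so a top-k set can exceed k members.  ``categories`` (raw
    IUCN codes) adds a per-category count of the overlapping species.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    top_a = frozenset(s for s, r in ranking_a.items() if r <= k)
    top_b = frozenset(s for s, r in ranking_b.items() if r <= k)
    overlap = top_a & top_b
    breakdown: Counter[str] = Counter()
    if categories is not None:
        for s in overlap:
            breakdown[str(categories[s])] += 1
    return OverlapResult(
        k=k,
        top_a=top_a,
        top_b=top_b,
        overlap=overlap,
        breakdown=dict(sorted(breakdown.items())),
    )


def overlap_report(result: OverlapResult) -> str:
    """Human-readable summary of a top-k overlap."""
    lines = [
        f"top-{result.k} set sizes: {len(result.top_a)} vs {len(result.top_b)}"
        " (boundary ties included)",
        f"overlap: {result.size} species",
    ]
    if result.breakdown:
        parts = ", ".join(f"{n} {cat}" for cat, n in result.breakdown.items())
        lines.append(f"overlap by category: {parts}")
    return "\n".join(lines)
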