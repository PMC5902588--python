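"""Regional over/under-representation of top-ranked species.

For each region the number of top-set species occurring there is compared
with the expectation under proportionality to the region's species
richness, using the exact binomial test (two-sided, method of small
p-values).  A species occurring in several regions counts once in each;
the null probability for a region is its richness divided by the total
number of species, which makes the proportionality assumption an
approximation under multi-region occurrences.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats


def presence_from_regions_column(table: pd.DataFrame) -> pd.DataFrame:
    """Explode a species table's ';'-separated ``regions`` column into a
    long (species, region) presence table."""
    rows = []
    for rec in table.itertuples():
        for region in str(rec.regions).split(";"):
            region = region.strip()
            if region:
                rows.append((rec.species, region))
    return pd.DataFrame(rows, columns=["species", "region"])


def region_counts(
    presence: pd.DataFrame, top_set: Iterable[str]
) -> pd.DataFrame:
    """Per-region species richness and count of top-set species.

    ``presence`` is a long table with ``species`` and ``region`` columns.
    """
    top_set = set(top_set)
    known = set(presence["species"])
    unknown = top_set - known
    if unknown:
        raise ValueError(
            f"top-set species absent from presence table: {sorted(unknown)[:10]}"
        )
    dedup = presence.drop_duplicates(["species", "region"])
    richness = dedup.groupby("region").size()
    top = (
        dedup[dedup["species"].isin(top_set)].groupby("region").size()
    )
    df = pd.DataFrame(
        {
            "region": richness.index,
            "richness": richness.values,
            "top_count": top.reindex(richness.index, fill_value=0).values,
        }
    ).sort_values("region", kind="mergesort").reset_index(drop=True)
    return df


def exact_binomial_test(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p-value by the method of small p-values.

    The p-value is the sum of the point probabilities of all outcomes no
    more likely than the observed count.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0,1]")
    return float(stats.binomtest(k, n, p, alternative="two-sided").pvalue)


def hotspot_classification(
    counts: pd.DataFrame,
    k_total: int,
    total_species: int,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Classify regions as holding more or fewer top species than expected.

    For region r with richness n_r, the null probability is
    ``p_r = n_r / total_species`` and the observed top count is tested
    against Binomial(k_total, p_r).  Direction compares the observed count
    with its expectation ``k_total * p_r``.  No multiple-testing
    correction is applied by default (set ``bh_correct`` for
    Benjamini-Hochberg adjusted p-values).
    """
    if total_species <= 0:
        raise ValueError("total_species must be positive")
    rows = []
    for rec in counts.itertuples():
        p_r = rec.richness / total_species
        expected = k_total * p_r
        pval = exact_binomial_test(int(rec.top_count), int(k_total), p_r)
        if rec.top_count > expected:
            direction = "more"
        elif rec.top_count < expected:
            direction = "fewer"
        else:
            direction = "neither"
        rows.append(
            {
                "region": rec.region,
                "richness": int(rec.richness),
                "top_count": int(rec.top_count),
                "k_total": int(k_total),
                "null_p": p_r,
                "expected": expected,
                "p_value": pval,
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows)
    if bh_correct and not df.empty:
        df["p_adjusted"] = stats.false_discovery_control(df["p_value"], method="bh")
        df["significant"] = df["p_adjusted"] < alpha
    elif not df.empty:
        df["significant"] = df["p_value"] < alpha
    return df
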