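"""IUCN category handling, EDGE scores, rankings and assessment summaries.

Two category-to-extinction-probability transformations are built in:

* ``ISAAC`` — the original logarithmic scheme.  Scores use the GE form
  ``EDGE = ln(1 + ED) + GE * ln 2`` with GE = 0..4 for LC..CR; the
  equivalent probability table (LC 0.025 doubling to CR 0.4) is also kept
  so the two forms can be cross-checked.
* ``IUCN50`` — 50-year extinction probabilities (LC 0.00005, NT 0.004,
  VU 0.05, EN 0.42, CR 0.97).  Scores are the log expected PD loss,
  ``EDGE = ln(1 + ED * p_ext)``.

Data Deficient (DD) and Not Evaluated (NE) species are scored as
Critically Endangered (a worst-case assumption so they cannot be
overlooked); Extinct in the Wild (EW) is likewise scored with the CR
probability since no scheme defines an EW value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd


class IUCNCategory(str, Enum):
    LC = "LC"
    NT = "NT"
    VU = "VU"
    EN = "EN"
    CR = "CR"
    EW = "EW"
    DD = "DD"
    NE = "NE"


GE_INDEX: dict[IUCNCategory, int] = {
    IUCNCategory.LC: 0,
    IUCNCategory.NT: 1,
    IUCNCategory.VU: 2,
    IUCNCategory.EN: 3,
    IUCNCategory.CR: 4,
}

#: categories counted as threatened in assessment summaries
THREATENED = frozenset(
    {IUCNCategory.VU, IUCNCategory.EN, IUCNCategory.CR, IUCNCategory.EW}
)
NON_THREATENED = frozenset({IUCNCategory.LC, IUCNCategory.NT})

#: raw categories eligible for the threatened-ED ranking (DD/NE included
#: because they are scored as CR; EW included as at least as extinction-
#: prone as CR)
THREATENED_ED_SUBSET = frozenset(
    {
        IUCNCategory.VU,
        IUCNCategory.EN,
        IUCNCategory.CR,
        IUCNCategory.EW,
        IUCNCategory.DD,
        IUCNCategory.NE,
    }
)

_PROB_ORDER = (
    IUCNCategory.LC,
    IUCNCategory.NT,
    IUCNCategory.VU,
    IUCNCategory.EN,
    IUCNCategory.CR,
)


@dataclass(frozen=True)
class TransformationScheme:
    """Named mapping from effective IUCN category to extinction probability.

    ``formula`` selects the EDGE equation: ``"ge"`` uses
    ``ln(1+ED) + GE*ln2`` (the probability table is then informational),
    ``"probability"`` uses ``ln(1 + ED*p_ext)``.
    """

    name: str
    p_ext: Mapping[IUCNCategory, float] = field(default_factory=dict)
    formula: str = "probability"

    def __post_init__(self):
        if self.formula not in ("ge", "probability"):
            raise ValueError(f"unknown formula {self.formula!r}")
        probs = [self.p_ext[c] for c in _PROB_ORDER if c in self.p_ext]
        if len(probs) != len(_PROB_ORDER):
            raise ValueError(f"scheme {self.name}: p_ext must map LC..CR")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError(f"scheme {self.name}: probabilities outside [0,1]")
        if any(b < a for a, b in zip(probs, probs[1:])):
            raise ValueError(
                f"scheme {self.name}: p_ext must be non-decreasing LC->CR"
            )


ISAAC = TransformationScheme(
    name="ISAAC",
    p_ext={
        IUCNCategory.LC: 0.025,
        IUCNCategory.NT: 0.05,
        IUCNCategory.VU: 0.1,
        IUCNCategory.EN: 0.2,
        IUCNCategory.CR: 0.4,
    },
    formula="ge",
)

IUCN50 = TransformationScheme(
    name="IUCN50",
    p_ext={
        IUCNCategory.LC: 0.00005,
        IUCNCategory.NT: 0.004,
        IUCNCategory.VU: 0.05,
        IUCNCategory.EN: 0.42,
        IUCNCategory.CR: 0.97,
    },
    formula="probability",
)

BUILTIN_SCHEMES: dict[str, TransformationScheme] = {
    "ISAAC": ISAAC,
    "IUCN50": IUCN50,
}


def scheme_from_config(spec: Mapping) -> TransformationScheme:
    """Build a user-defined scheme from a JSON-style mapping.

    Expected keys: ``name``, ``p_ext`` (category code -> probability) and
    optional ``formula``.
    """
    p_ext = {IUCNCategory(k): float(v) for k, v in spec["p_ext"].items()}
    return TransformationScheme(
        name=str(spec["name"]),
        p_ext=p_ext,
        formula=str(spec.get("formula", "probability")),
    )


def effective_category(raw: IUCNCategory | str) -> IUCNCategory:
    """Category used for scoring: DD, NE and EW are treated as CR."""
    raw = IUCNCategory(raw)
    if raw in (IUCNCategory.DD, IUCNCategory.NE, IUCNCategory.EW):
        return IUCNCategory.CR
    return raw


def extinction_probability(
    category: IUCNCategory | str, scheme: TransformationScheme
) -> float:
    """Probability of extinction for an effective category (LC..CR only)."""
    category = IUCNCategory(category)
    if category not in scheme.p_ext:
        raise KeyError(
            f"category {category.value} has no probability under "
            f"{scheme.name}; convert with effective_category() first"
        )
    return scheme.p_ext[category]


def edge_score(
    median_ed: float,
    category: IUCNCategory | str,
    scheme: TransformationScheme,
) -> float:
    """EDGE score for a species from its median ED and effective category."""
    if median_ed < 0:
        raise ValueError(f"negative ED: {median_ed}")
    category = IUCNCategory(category)
    if scheme.formula == "ge":
        if category not in GE_INDEX:
            raise KeyError(
                f"category {category.value} has no GE index; convert with "
                "effective_category() first"
            )
        return math.log1p(median_ed) + GE_INDEX[category] * math.log(2.0)
    p = extinction_probability(category, scheme)
    return math.log1p(median_ed * p)


def rank_competition(
    scores: Mapping[str, float], descending: bool = True
) -> dict[str, int]:
    """Competition ("1-2-2-4") ranks; exact-value ties share a rank."""
    s = pd.Series(dict(scores), dtype=float)
    if not s.map(math.isfinite).all():
        raise ValueError("scores must be finite")
    ranks = s.rank(method="min", ascending=not descending).astype(int)
    return ranks.to_dict()


def threatened_ed_ranking(score_table: pd.DataFrame) -> pd.DataFrame:
    """Rank threatened species (raw CR/EN/VU plus DD/NE/EW) by median ED.

    Returns the subset of the score table ordered by decreasing
    ``median_ed`` with a ``threatened_ed_rank`` column (competition ranks).
    """
    raw = score_table["raw_category"].map(IUCNCategory)
    sub = score_table[raw.isin(THREATENED_ED_SUBSET)].copy()
    if sub.empty:
        sub["threatened_ed_rank"] = pd.Series(dtype=int)
        return sub
    ranks = rank_competition(
        dict(zip(sub["species"], sub["median_ed"])), descending=True
    )
    sub["threatened_ed_rank"] = sub["species"].map(ranks)
    return sub.sort_values(
        ["threatened_ed_rank", "species"], kind="mergesort"
    ).reset_index(drop=True)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (report convention for percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AssessmentSummary:
    """Counts and percentages of Red List categories in a species set.

    ``assessed`` excludes only NE (DD species have been through the
    assessment process).  Percentage fields are rounded half-up to one
    decimal and are None when the denominator is zero.
    """

    counts: Mapping[str, int]
    total: int
    assessed: int
    threatened: int
    non_threatened: int
    pct_assessed_of_total: float | None
    pct_threatened_of_assessed: float | None


def summarize_assessments(records: Iterable) -> AssessmentSummary:
    """Tally categories from records (objects with ``.iucn_category``) or
    plain category codes."""
    counts = {c.value: 0 for c in IUCNCategory}
    total = 0
    for rec in records:
        raw = getattr(rec, "iucn_category", rec)
        cat = IUCNCategory(raw)
        counts[cat.value] += 1
        total += 1
    assessed = total - counts["NE"]
    threatened = sum(counts[c.value] for c in THREATENED)
    non_threatened = sum(counts[c.value] for c in NON_THREATENED)
    pct_assessed = round_half_up(100.0 * assessed / total) if total else None
    pct_threat = (
        round_half_up(100.0 * threatened / assessed) if assessed else None
    )
    return AssessmentSummary(
        counts=counts,
        total=total,
        assessed=assessed,
        threatened=threatened,
        non_threatened=non_threatened,
        pct_assessed_of_total=pct_assessed,
        pct_threatened_of_assessed=pct_threat,
    )


@dataclass(frozen=True)
class CoverageSummary:
    """Sampling coverage of a species set, as counts and percentages."""

    n_total: int
    n_sampled: int
    n_missing: int
    n_assessed: int
    n_sampled_assessed: int
    pct_sampled_of_total: float | None
    pct_sampled_of_assessed: float | None


def summarize_coverage(records: Iterable) -> CoverageSummary:
    """Tally molecular sampling coverage from species records.

    Records need ``.sampled`` (truthy flag) and ``.iucn_category``;
    "assessed" excludes NE.
    """
    n_total = n_sampled = n_assessed = n_sampled_assessed = 0
    for rec in records:
        n_total += 1
        sampled = bool(int(rec.sampled))
        assessed = IUCNCategory(rec.iucn_category) is not IUCNCategory.NE
        n_sampled += sampled
        n_assessed += assessed
        n_sampled_assessed += sampled and assessed
    return CoverageSummary(
        n_total=n_total,
        n_sampled=n_sampled,
        n_missing=n_total - n_sampled,
        n_assessed=n_assessed,
        n_sampled_assessed=n_sampled_assessed,
        pct_sampled_of_total=(
            round_half_up(100.0 * n_sampled / n_total) if n_total else None
        ),
        pct_sampled_of_assessed=(
            round_half_up(100.0 * n_sampled_assessed / n_assessed)
            if n_assessed
            else None
        ),
    )


def build_score_table(
    median_ed: Mapping[str, float],
    categories: Mapping[str, IUCNCategory | str],
    schemes: Sequence[TransformationScheme] = (ISAAC, IUCN50),
    genera: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-species score table.

    Columns: species, genus (if given), raw_category, effective_category,
    median_ed, ed_rank, then per scheme ``edge_<name>`` /
    ``edge_<name>_rank`` / ``p_ext_<name>``, and threatened_ed_rank
    (nullable).  All ranks are competition ranks on exact values.
    """
    missing = set(median_ed) ^ set(categories)
    if missing:
        raise ValueError(
            f"median_ed and categories key sets differ: {sorted(missing)[:10]}"
        )
    species = sorted(median_ed)
    df = pd.DataFrame({"species": species})
    if genera is not None:
        df["genus"] = [genera.get(s) for s in species]
    df["raw_category"] = [IUCNCategory(categories[s]).value for s in species]
    df["effective_category"] = [
        effective_category(categories[s]).value for s in species
    ]
    df["median_ed"] = [float(median_ed[s]) for s in species]
    ed_ranks = rank_competition(dict(zip(species, df["median_ed"])))
    df["ed_rank"] = df["species"].map(ed_ranks)
    for scheme in schemes:
        col = f"edge_{scheme.name.lower()}"
        eff = df["effective_category"].map(IUCNCategory)
        df[f"p_ext_{scheme.name.lower()}"] = [
            extinction_probability(c, scheme) for c in eff
        ]
        df[col] = [
            edge_score(ed, c, scheme) for ed, c in zip(df["median_ed"], eff)
        ]
        ranks = rank_competition(dict(zip(df["species"], df[col])))
        df[f"{col}_rank"] = df["species"].map(ranks)
    ted = threatened_ed_ranking(df)
    df["threatened_ed_rank"] = df["species"].map(
        dict(zip(ted["species"], ted["threatened_ed_rank"]))
    ).astype("Int64")
    return df
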