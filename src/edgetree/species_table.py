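"""Species table records and CSV I/O.

The table joins the tree to the assessment and occurrence data.  CSV
columns: ``species,genus,iucn_category,sampled,regions`` with regions a
";"-separated list of codes and sampled in {0,1}.  Species names are
exact-string keys; no normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from edgetree.scoring import IUCNCategory

COLUMNS = ["species", "genus", "iucn_category", "sampled", "regions"]


@dataclass(frozen=True)
class SpeciesRecord:
    species: str
    genus: str
    iucn_category: IUCNCategory
    sampled: bool
    regions: tuple[str, ...]


def read_species_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["sampled"] = df["sampled"].astype(int)
    bad = df[~df["iucn_category"].isin([c.value for c in IUCNCategory])]
    if not bad.empty:
        raise ValueError(
            f"{path}: unknown IUCN categories: "
            f"{sorted(bad['iucn_category'].unique())}"
        )
    dup = df["species"][df["species"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate species: {sorted(dup.unique())[:10]}")
    return df[COLUMNS]


def write_species_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=COLUMNS)


def records_from_dataframe(df: pd.DataFrame) -> list[SpeciesRecord]:
    return [
        SpeciesRecord(
            species=str(r.species),
            genus=str(r.genus),
            iucn_category=IUCNCategory(r.iucn_category),
            sampled=bool(int(r.sampled)),
            regions=tuple(
                x.strip() for x in str(r.regions).split(";") if x.strip()
            ),
        )
        for r in df.itertuples()
    ]
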