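"""Enzyme-specific taxonomic dominance (ECs_D) from species abundance.

For an enzyme (an EC number) carried by N individuals across species
with per-species counts n, the Simpson dominance is

    D(EC) = sum_species n(n-1) / (N(N-1))

and the reported score is ECs_D = 1 - D(EC). A function carried by a
single dominant species scores near 0 (easy to target, little community
redundancy); a function spread evenly across many species scores near
1 - 1/k for k species (taxonomically diverse, hard to knock out).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class NotScoreableError(ValueError):
    """Fewer than two individuals: the unbiased Simpson form is undefined."""


@dataclass(frozen=True)
class EnzymeTaxonAbundance:
    """Per-species counts of individuals carrying one enzyme.

    Species with count 0 contribute nothing to either sum and are
    ignored, so zero-padded tables score identically to sparse ones.
    """

    enzyme_id: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for sp, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count {n} for species {sp!r}")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class ECsDScore:
    enzyme_id: str
    dominance: float
    ecsd: float


def simpson_dominance(table: EnzymeTaxonAbundance) -> float:
    """Unbiased Simpson dominance D = Σ n(n−1) / (N(N−1)); needs N ≥ 2."""
    n = np.array([c for c in table.counts.values() if c > 0], dtype=np.int64)
    total = int(n.sum())
    if total < 2:
        raise NotScoreableError(
            f"enzyme {table.enzyme_id}: N={total} < 2, dominance undefined"
        )
    return float((n * (n - 1)).sum() / (total * (total - 1)))


def ecsd(table: EnzymeTaxonAbundance) -> ECsDScore:
    d = simpson_dominance(table)
    return ECsDScore(enzyme_id=table.enzyme_id, dominance=d, ecsd=1.0 - d)


def ecsd_table(tables: Sequence[EnzymeTaxonAbundance]) -> pd.DataFrame:
    """Score a cohort of enzymes and classify against the cohort mean.

    Returns one row per enzyme with ``dominance``, ``ecsd`` and a
    ``classification``: ``high_dominance`` when the score falls below the
    cohort mean ECs_D (few-species function), ``diverse`` otherwise, and
    ``not_scoreable`` for N < 2. The threshold is recomputed from the
    input cohort — it is a dataset property, not a constant. The frame's
    ``attrs`` carry the cohort ``mean``, ``sd`` and the ±1 sd band.
    """
    rows = []
    for table in tables:
        try:
            score = ecsd(table)
            rows.append(
                {
                    "ec_number": table.enzyme_id,
                    "dominance": score.dominance,
                    "ecsd": score.ecsd,
                }
            )
        except NotScoreableError:
            rows.append(
                {
                    "ec_number": table.enzyme_id,
                    "dominance": np.nan,
                    "ecsd": np.nan,
                }
            )
    df = pd.DataFrame(rows, columns=["ec_number", "dominance", "ecsd"])
    scored = df["ecsd"].dropna()
    if scored.empty:
        raise NotScoreableError("no scoreable enzyme in cohort")
    mean = float(scored.mean())
    sd = float(scored.std(ddof=1)) if len(scored) > 1 else 0.0
    df["classification"] = np.where(
        df["ecsd"].isna(),
        "not_scoreable",
        np.where(df["ecsd"] < mean, "high_dominance", "diverse"),
    )
    df.attrs.update(
        {"mean": mean, "sd": sd, "band": (mean - sd, mean + sd)}
    )
    return df


def read_abundance(path) -> list[EnzymeTaxonAbundance]:
    """Read an abundance TSV: ``ec_number species_id count``."""
    df = pd.read_csv(
        path, sep="\t", dtype={"ec_number": str, "species_id": str, "count": int}
    )
    required = {"ec_number", "species_id", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    tables = []
    for ec, grp in df.groupby("ec_number", sort=True):
        if grp["species_id"].duplicated().any():
            raise ValueError(f"duplicate species rows for enzyme {ec}")
        tables.append(
            EnzymeTaxonAbundance(
                enzyme_id=ec,
                counts=dict(zip(grp["species_id"], grp["count"])),
            )
        )
    return tables


def write_scores(df: pd.DataFrame, path) -> None:
    """Write the score TSV: ``ec_number dominance ecsd classification``."""
    df.to_csv(path, sep="\t", index=False)
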