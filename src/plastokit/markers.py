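"""Marker allele-diversity summaries over accession groups.

Genotypes are integer fragment lengths (capillary sizing); alleles compare
exactly by default, with an optional binning tolerance for sizing noise.
Groups may be nested (e.g. family ⊇ section ⊇ species ⊇ chloroplast group),
in which case distinct-allele counts are monotone non-increasing down the
nesting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .codons import round_half_up

__all__ = ["GenotypeTable", "tally_alleles", "read_genotype_csv", "write_genotype_csv"]


@dataclass
class GenotypeTable:
    """Accessions × markers table of integer allele sizes (NaN = missing)."""

    data: pd.DataFrame  # index: accession, columns: marker
    groups: dict[str, set]  # group name -> accession set

    def __post_init__(self) -> None:
        for name, members in self.groups.items():
            if not members:
                raise ValueError(f"group {name!r} is empty")
            missing = members - set(self.data.index)
            if missing:
                raise ValueError(f"group {name!r}: unknown accessions {sorted(missing)}")


def _distinct(values: pd.Series, tolerance: int = 0) -> int:
    vals = sorted(int(v) for v in values.dropna())
    if not vals:
        return 0
    if tolerance <= 0:
        return len(set(vals))
    # cluster alleles whose sizes differ by ≤ tolerance
    clusters = 1
    last = vals[0]
    for v in vals[1:]:
        if v - last > tolerance:
            clusters += 1
        last = v
    return clusters


def tally_alleles(
    table: GenotypeTable,
    groups: list[str] | None = None,
    tolerance: int = 0,
) -> pd.DataFrame:
    """Distinct non-missing alleles per marker per group, plus group means.

    Means are over markers, rounded to 2 decimals (half away from zero).
    Markers with all-missing data in a group count 0 and are flagged in the
    returned frame's attrs.
    """
    names = groups or list(table.groups)
    rows = {}
    flagged = []
    for marker in table.data.columns:
        counts = {}
        for g in names:
            sub = table.data.loc[sorted(table.groups[g]), marker]
            c = _distinct(sub, tolerance)
            if c == 0:
                flagged.append((marker, g))
            counts[g] = c
        rows[marker] = counts
    df = pd.DataFrame.from_dict(rows, orient="index")[names]
    means = {g: round_half_up(float(df[g].mean()), 2) for g in names}
    df.loc["mean_per_marker"] = pd.Series(means)
    df.attrs["all_missing"] = flagged
    return df


def read_genotype_csv(path) -> GenotypeTable:
    """CSV with an ``accession`` column, a ``groups`` column of
    ;-separated group names, and one column per marker."""
    raw = pd.read_csv(path)
    if "accession" not in raw.columns or "groups" not in raw.columns:
        raise ValueError("genotype CSV needs 'accession' and 'groups' columns")
    raw = raw.set_index("accession")
    groups: dict[str, set] = {}
    for acc, gs in raw["groups"].items():
        for g in str(gs).split(";"):
            if g:
                groups.setdefault(g, set()).add(acc)
    data = raw.drop(columns=["groups"]).astype("float64")
    return GenotypeTable(data=data, groups=groups)


def write_genotype_csv(path, table: GenotypeTable) -> None:
    df = table.data.copy()
    member_of = {
        acc: ";".join(sorted(g for g, m in table.groups.items() if acc in m))
        for acc in df.index
    }
    df.insert(0, "groups", pd.Series(member_of))
    df.index.name = "accession"
    df.to_csv(path)
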