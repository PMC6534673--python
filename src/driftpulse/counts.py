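"""Population haplogroup count tables: read, validate, pool, and convert.

The canonical format is tab-separated UTF-8 text with a header and four
columns: ``population`` (unique label), ``group`` (analysis pool the
population belongs to), ``n`` (sample size) and ``carriers`` (haplogroup
carrier count).  Pooling sums ``n`` and ``carriers`` within a group; the
pooled rows are what the model framework consumes as observed populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .models import ObservedPopulation

__all__ = ["CountTable", "read_counts", "write_counts", "pool", "to_observed"]

COLUMNS = ("population", "group", "n", "carriers")


@dataclass(frozen=True)
class CountTable:
    """A validated population x haplogroup-count table."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        for col in ("n", "carriers"):
            if not pd.api.types.is_integer_dtype(df[col]):
                raise ValueError(f"column {col!r} must be integer, got {df[col].dtype}")
        bad_n = df.index[df["n"] < 1]
        if len(bad_n):
            raise ValueError(f"sample size n must be >= 1 (rows {list(bad_n)})")
        bad = df.index[(df["carriers"] < 0) | (df["carriers"] > df["n"])]
        if len(bad):
            raise ValueError(
                f"carriers must satisfy 0 <= carriers <= n (rows {list(bad)})"
            )
        dup = df["population"][df["population"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate population labels: {sorted(set(dup))}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def frequencies(self) -> pd.Series:
        """Per-row carrier frequency carriers/n."""
        return self.data["carriers"] / self.data["n"]


def read_counts(path, sep: str = "\t") -> CountTable:
    """Read and validate a count table from tab-separated text.

    Pass ``sep=","`` for comma-separated input.  Malformed rows raise a
    ``ValueError`` naming the offending row.
    """
    try:
        df = pd.read_csv(path, sep=sep, dtype={"population": str, "group": str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"count table {path!s} is empty") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table {path!s} missing columns: {missing}")
    for col in ("n", "carriers"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() | (numeric != numeric.round())]
        if len(bad):
            # +2: header line plus 1-based numbering
            lines = [int(i) + 2 for i in bad]
            raise ValueError(
                f"count table {path!s}: non-integer values in column {col!r} "
                f"at line(s) {lines}"
            )
        df[col] = numeric.astype(int)
    return CountTable(df[list(COLUMNS)])


def write_counts(table: CountTable, path, sep: str = "\t") -> None:
    """Write a count table as tab-separated text (canonical formatting)."""
    table.data.to_csv(path, sep=sep, index=False)


def pool(table: CountTable, by: str = "group") -> CountTable:
    """Aggregate sample sizes and carrier counts within each group.

    The pooled table uses the group label as both population and group, so
    pooling is idempotent.  Pooled frequency = pooled carriers / pooled n.
    """
    if by not in table.data.columns:
        raise ValueError(f"grouping column {by!r} not present")
    agg = (
        table.data.groupby(by, sort=False)[["n", "carriers"]]
        .sum()
        .reset_index()
        .rename(columns={by: "population"})
    )
    agg["group"] = agg["population"]
    return CountTable(agg[list(COLUMNS)])


def to_observed(table: CountTable, tolerance_variant: str = "paper") -> list[ObservedPopulation]:
    """Build observed-population match bands from a pooled table, one per row."""
    return [
        ObservedPopulation(
            label=row.population,
            n=int(row.n),
            carriers=int(row.carriers),
            tolerance_variant=tolerance_variant,
        )
        for row in table.data.itertuples()
    ]
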