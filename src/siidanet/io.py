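"""Validated readers/writers for the tabular interchange formats, plus the
gift ledger and its currency accounting.

All tables are plain UTF-8 CSV with explicit headers and opaque string ids;
indicator columns use 0/1 rather than booleans. Monetary amounts are kept in
exact decimal arithmetic (the petrol endowment is priced at a fixed
15 NOK per litre), so printed totals reproduce bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path
from statistics import median

import pandas as pd

__all__ = [
    "Roster",
    "GiftRecord",
    "GiftLedger",
    "SchemaError",
    "read_roster",
    "read_edges",
    "read_kin",
    "read_gifts",
    "write_roster",
    "write_edges",
    "write_kin",
    "write_gifts",
    "PRICE_NOK_PER_LITRE",
    "litres_to_nok",
    "gift_summary",
]

logger = logging.getLogger(__name__)

#: Fixed price of the experimental endowment commodity.
PRICE_NOK_PER_LITRE = Decimal("15")


class SchemaError(ValueError):
    """Raised when an input table violates its declared schema."""


@dataclass
class Roster:
    """The community roster: one row per individual.

    Columns: ``id`` (opaque string), ``siida`` (herding-group label),
    ``interviewed`` (0/1), ``licence`` (0/1). Every interviewed individual
    holds a licence.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "siida", "interviewed", "licence"}
        missing = required - set(self.table.columns)
        if missing:
            raise SchemaError(f"roster is missing columns: {sorted(missing)}")
        t = self.table.copy()
        t["id"] = t["id"].astype(str)
        t["siida"] = t["siida"].astype(str)
        t["interviewed"] = t["interviewed"].astype(int)
        t["licence"] = t["licence"].astype(int)
        if t["id"].duplicated().any():
            dupes = t.loc[t["id"].duplicated(), "id"].tolist()
            raise SchemaError(f"duplicate roster ids: {dupes}")
        bad = t[(t["interviewed"] == 1) & (t["licence"] == 0)]
        if len(bad):
            raise SchemaError(
                f"interviewed individuals without a licence: {bad['id'].tolist()}"
            )
        self.table = t.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def interviewed_ids(self) -> list[str]:
        return self.table.loc[self.table["interviewed"] == 1, "id"].tolist()

    @property
    def licensed_ids(self) -> list[str]:
        return self.table.loc[self.table["licence"] == 1, "id"].tolist()

    def siida_of(self) -> dict[str, str]:
        return dict(zip(self.table["id"], self.table["siida"]))

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class GiftRecord:
    giver: str
    recipient: str
    litres: Decimal

    def __post_init__(self) -> None:
        if self.giver == self.recipient:
            raise ValueError(f"self-gift by {self.giver!r}")
        if self.litres <= 0:
            raise ValueError(f"gift of {self.litres} litres must be positive")


@dataclass
class GiftLedger:
    """Allocations from an economic gift game.

    Each playing giver splits a fixed endowment (default 35 litres of
    petrol) among one or more recipients; per-giver totals must equal the
    endowment exactly, which is why amounts are ``Decimal``.
    """

    records: list[GiftRecord]
    endowment_litres: Decimal = Decimal("35")

    def __post_init__(self) -> None:
        self.endowment_litres = Decimal(str(self.endowment_litres))
        for giver, total in self.totals_given().items():
            if total != self.endowment_litres:
                raise ValueError(
                    f"giver {giver!r} allocated {total} litres, expected "
                    f"{self.endowment_litres}"
                )

    def totals_given(self) -> dict[str, Decimal]:
        out: dict[str, Decimal] = {}
        for rec in self.records:
            out[rec.giver] = out.get(rec.giver, Decimal(0)) + rec.litres
        return out

    def totals_received(self) -> dict[str, Decimal]:
        out: dict[str, Decimal] = {}
        for rec in self.records:
            out[rec.recipient] = out.get(rec.recipient, Decimal(0)) + rec.litres
        return out

    @property
    def givers(self) -> set[str]:
        return {rec.giver for rec in self.records}

    @property
    def recipients(self) -> set[str]:
        return {rec.recipient for rec in self.records}

    def gift_counts_received(self) -> dict[str, int]:
        """Number of gift events received per recipient."""
        out: dict[str, int] = {}
        for rec in self.records:
            out[rec.recipient] = out.get(rec.recipient, 0) + 1
        return out

    def distinct_giver_counts(self) -> dict[str, int]:
        """Number of distinct givers per recipient."""
        pairs = {(rec.giver, rec.recipient) for rec in self.records}
        out: dict[str, int] = {}
        for _, recipient in pairs:
            out[recipient] = out.get(recipient, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.giver, r.recipient, str(r.litres)) for r in self.records],
            columns=["giver", "recipient", "litres"],
        )

    def __len__(self) -> int:
        return len(self.records)


def litres_to_nok(litres) -> Decimal:
    """Convert litres of petrol to NOK at the fixed 15 NOK/litre price.

    Exact decimal arithmetic: 35 l -> 525 NOK, 8.75 l -> 131.25 NOK.
    Floats are converted through their string form so 18.12 means 18.12.
    """
    amount = Decimal(str(litres))
    if amount < 0:
        raise ValueError(f"litres must be non-negative, got {amount}")
    return amount * PRICE_NOK_PER_LITRE


def gift_summary(ledger: GiftLedger) -> dict:
    """Headline accounting of a gift ledger.

    Medians of the amount *given* are over gift records; medians of the
    amount *received* are over per-recipient totals. NOK equivalents use the
    fixed price.
    """
    if not ledger.records:
        raise ValueError("cannot summarize an empty gift ledger")
    given = sorted(rec.litres for rec in ledger.records)
    received = sorted(ledger.totals_received().values())
    med_given = median(given)
    med_received = median(received)
    max_received = max(received)
    return {
        "n_gifts": len(ledger.records),
        "n_recipients": len(ledger.recipients),
        "n_givers": len(ledger.givers),
        "total_litres": sum(given, Decimal(0)),
        "median_given_litres": med_given,
        "median_given_nok": litres_to_nok(med_given),
        "median_received_litres": med_received,
        "median_received_nok": litres_to_nok(med_received),
        "max_received_litres": max_received,
        "max_received_nok": litres_to_nok(max_received),
    }


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, cols: list[str], what: str, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file {path} is missing columns: {missing}")


def read_roster(path) -> Roster:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["id", "siida", "interviewed", "licence"], "roster", path)
    return Roster(df)


def write_roster(roster: Roster, path) -> None:
    roster.table.to_csv(path, index=False)


def read_edges(path, roster: Roster | None = None) -> pd.DataFrame:
    """Read a directed edge list with columns ``ego``, ``alter``, ``layer``.

    Self-edges and duplicate (ego, alter, layer) rows are schema errors. If
    a roster is supplied, edges whose alter is not a licence owner (e.g.
    collective alters such as named groups of people) are dropped with a
    logged count, mirroring the field convention of excluding non-individual
    nominees from quantitative analysis.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["ego", "alter", "layer"], "edges", path)
    self_rows = df.index[df["ego"] == df["alter"]].tolist()
    if self_rows:
        raise SchemaError(f"self-edges in {path} at rows {self_rows}")
    dup = df.duplicated(subset=["ego", "alter", "layer"])
    if dup.any():
        raise SchemaError(
            f"duplicate (ego, alter, layer) rows in {path} at rows "
            f"{df.index[dup].tolist()}"
        )
    if roster is not None:
        licensed = set(roster.licensed_ids)
        keep = df["alter"].isin(licensed)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning(
                "dropped %d edge(s) whose alter is not a licence owner "
                "(collective or out-of-scope alters)", n_dropped,
            )
        df = df[keep]
    return df.reset_index(drop=True)


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, index=False)


def read_kin(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["ego", "alter", "path"], "kin", path)
    df["path"] = df["path"].fillna("")
    return df


def write_kin(kin: pd.DataFrame, path) -> None:
    kin.to_csv(path, index=False)


def read_gifts(path, endowment_litres="35") -> GiftLedger:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["giver", "recipient", "litres"], "gifts", path)
    records = [
        GiftRecord(str(r.giver), str(r.recipient), Decimal(str(r.litres)))
        for r in df.itertuples(index=False)
    ]
    return GiftLedger(records, endowment_litres=Decimal(str(endowment_litres)))


def write_gifts(ledger: GiftLedger, path) -> None:
    ledger.to_frame().to_csv(path, index=False)
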