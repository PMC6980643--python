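"""Data model, validation and readers/writers for invoices, labeled items and
manufacturer class records.

The canonical invoice schema is the seven-column CSV
``invoice_id,date,vendor_id,vendee_id,item_name,amount,quantity``; an empty
``quantity`` field means the line did not list one. The same records round-trip
through JSON lines. Item names are stored verbatim — normalization is the text
sieve's business, not the store's.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

INVOICE_COLUMNS = [
    "invoice_id",
    "date",
    "vendor_id",
    "vendee_id",
    "item_name",
    "amount",
    "quantity",
]

__all__ = [
    "Invoice",
    "ManufacturerRecord",
    "LabeledItem",
    "INVOICE_COLUMNS",
    "SchemaError",
    "RowError",
    "read_invoices",
    "write_invoices",
    "invoices_to_frame",
    "frame_to_invoices",
    "read_labeled_items",
    "write_labeled_items",
]


class SchemaError(ValueError):
    """The file's header does not match the expected schema."""


class RowError(ValueError):
    """One or more data rows failed validation (message carries line numbers)."""


class Invoice(BaseModel):
    """One B2B transaction line.

    The vendor is the selling party (the manufacturer's *upstream* side when it
    sells), the vendee the buying party (*downstream* side when it purchases).
    Quantity is optional because source data does not always list it.
    """

    invoice_id: str
    date: _dt.date
    vendor_id: str
    vendee_id: str
    item_name: str
    amount: float = Field(ge=0)
    quantity: float | None = None

    @model_validator(mode="after")
    def _distinct_parties(self) -> "Invoice":
        if self.vendor_id == self.vendee_id:
            raise ValueError("vendor_id and vendee_id must differ (no self-dealing lines)")
        return self


class ManufacturerRecord(BaseModel):
    """Regulator-assigned class label for one manufacturer: A benchmark,
    B problematic, C unspecified."""

    manufacturer_id: str
    class_label: Literal["A", "B", "C"]


class LabeledItem(BaseModel):
    """An item name with its binary edible-oil-related label (1 = related)."""

    item_name: str
    label: int

    @field_validator("label")
    @classmethod
    def _binary(cls, v: int) -> int:
        if v not in (0, 1):
            raise ValueError("label must be 0 or 1")
        return v


def invoices_to_frame(records: Sequence[Invoice]) -> pd.DataFrame:
    """Invoice records as a DataFrame in canonical column order."""
    if not records:
        return pd.DataFrame(columns=INVOICE_COLUMNS)
    df = pd.DataFrame([r.model_dump() for r in records])
    df["date"] = pd.to_datetime(df["date"])
    return df[INVOICE_COLUMNS]


def frame_to_invoices(df: pd.DataFrame, strict: bool = True) -> list[Invoice]:
    """Validate a DataFrame row-wise into Invoice records.

    In strict mode any invalid row aborts with a :class:`RowError` listing the
    offending row numbers; in lenient mode invalid rows are skipped and logged.
    """
    missing = [c for c in INVOICE_COLUMNS if c not in df.columns and c != "quantity"]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records: list[Invoice] = []
    errors: list[str] = []
    has_qty = "quantity" in df.columns
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        qty = d.get("quantity") if has_qty else None
        if qty is not None and (pd.isna(qty) or qty == ""):
            qty = None
        try:
            records.append(
                Invoice(
                    invoice_id=str(d["invoice_id"]),
                    date=_coerce_date(d["date"]),
                    vendor_id=str(d["vendor_id"]),
                    vendee_id=str(d["vendee_id"]),
                    item_name=str(d["item_name"]),
                    amount=float(d["amount"]),
                    quantity=None if qty is None else float(qty),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {pos}: {exc}")
    if errors:
        if strict:
            raise RowError(f"{len(errors)} invalid row(s):\n" + "\n".join(errors))
        for msg in errors:
            logger.warning("skipping invalid invoice %s", msg)
    return records


def _coerce_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    ts = pd.Timestamp(str(value))
    return ts.date()


def read_invoices(
    path: str | Path, format: Literal["csv", "jsonl"] = "csv", strict: bool = True
) -> list[Invoice]:
    """Read and validate invoices from CSV or JSON lines.

    Row count is preserved in strict mode (any malformed row aborts, with line
    numbers in the error message); lenient mode skips and logs bad rows.
    """
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path, dtype={"invoice_id": str, "vendor_id": str, "vendee_id": str})
    elif format == "jsonl":
        df = pd.read_json(path, lines=True, dtype={"invoice_id": str, "vendor_id": str, "vendee_id": str})
        if df.empty:
            df = pd.DataFrame(columns=INVOICE_COLUMNS)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'jsonl'")
    return frame_to_invoices(df, strict=strict)


def write_invoices(
    records: Sequence[Invoice], path: str | Path, format: Literal["csv", "jsonl"] = "csv"
) -> Path:
    """Write invoices in stable column order, UTF-8; inverse of read_invoices."""
    path = Path(path)
    df = invoices_to_frame(records)
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    if format == "csv":
        df.to_csv(path, index=False, encoding="utf-8")
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in df.to_dict(orient="records"):
                if rec.get("quantity") is not None and pd.isna(rec["quantity"]):
                    rec["quantity"] = None
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'jsonl'")
    return path


def read_labeled_items(path: str | Path) -> list[LabeledItem]:
    """Read the two-column labeled-item table (item_name,label)."""
    df = pd.read_csv(path)
    for col in ("item_name", "label"):
        if col not in df.columns:
            raise SchemaError(f"missing required column(s): {col}")
    return [LabeledItem(item_name=str(r.item_name), label=int(r.label)) for r in df.itertuples()]


def write_labeled_items(items: Iterable[LabeledItem], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([{"item_name": it.item_name, "label": it.label} for it in items])
    df.to_csv(path, index=False, encoding="utf-8")
    return path
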