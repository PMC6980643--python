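"""Stage 2 preprocessing: monthly purchase/sales aggregation per manufacturer,
3-month moving-average smoothing, and the two log-turnover features.

For manufacturer month *i*, ``Pur_i`` sums amounts on lines where the
manufacturer is the vendee (its *downstream*, D side) and ``Sale_i`` where it
is the vendor (*upstream*, U side). Smoothing blurs the artificial month
boundary:

    D_i = (Pur_{i-2} + Pur_{i-1} + Pur_i) / 3
    U_i = (Sale_{i-2} + Sale_{i-1} + Sale_i) / 3

emitted only for full windows (the first two months are warm-up). The alarm
features are natural-log turnover ratios

    X1 = ln(U_i / D_i)        same-month turnover
    X2 = ln(U_i / D_{i-1})    turnover against the lagged purchase window

X2 is absent for the first emitted month (no lagged full window). A zero
denominator with a positive numerator is conceptually +inf — maximally
suspicious — and is clamped to ``+clamp`` (default 20, far above the alarm
threshold of 6) with the record flagged; the mirror case clamps to ``-clamp``.
A record with both window sums zero is marked invalid.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import Invoice, invoices_to_frame

__all__ = [
    "aggregate_monthly",
    "smooth",
    "compute_features",
    "feature_table",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "manufacturer_id", "month", "Pur", "Sale", "D", "U", "X1", "X2", "clamped", "valid",
]


def _as_frame(invoices) -> pd.DataFrame:
    if isinstance(invoices, pd.DataFrame):
        df = invoices.copy()
        df["date"] = pd.to_datetime(df["date"])
        return df
    return invoices_to_frame(list(invoices))


def aggregate_monthly(
    invoices: Sequence[Invoice] | pd.DataFrame,
    manufacturer_id: str,
    months: pd.PeriodIndex | None = None,
) -> pd.DataFrame:
    """Monthly purchase and sales totals for one manufacturer.

    Lines where the manufacturer is neither party are ignored. The output
    month index is contiguous (calendar months from first to last activity,
    or the explicit ``months`` index), with inactive months zero-filled —
    the absence of invoices is itself informative.
    """
    df = _as_frame(invoices)
    mine = df[(df["vendor_id"] == manufacturer_id) | (df["vendee_id"] == manufacturer_id)]
    if months is None:
        if mine.empty:
            return pd.DataFrame({"month": pd.PeriodIndex([], freq="M"), "Pur": [], "Sale": []})
        periods = mine["date"].dt.to_period("M")
        months = pd.period_range(periods.min(), periods.max(), freq="M")
    out = pd.DataFrame(index=months)
    if mine.empty:
        out["Pur"] = 0.0
        out["Sale"] = 0.0
    else:
        periods = mine["date"].dt.to_period("M")
        pur = mine.loc[mine["vendee_id"] == manufacturer_id, "amount"].groupby(
            periods[mine["vendee_id"] == manufacturer_id]
        ).sum()
        sale = mine.loc[mine["vendor_id"] == manufacturer_id, "amount"].groupby(
            periods[mine["vendor_id"] == manufacturer_id]
        ).sum()
        out["Pur"] = pur.reindex(months).fillna(0.0)
        out["Sale"] = sale.reindex(months).fillna(0.0)
    out.index.name = "month"
    return out.reset_index()


def smooth(agg: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """3-month moving averages D (purchases) and U (sales), full windows only.

    The input must be a contiguous monthly series as produced by
    :func:`aggregate_monthly`; fewer than ``window`` months is an error.
    """
    if len(agg) < window:
        raise ValueError(f"need at least {window} months to smooth, got {len(agg)}")
    months = pd.PeriodIndex(agg["month"], freq="M")
    if len(months) > 1 and not (np.diff(months.asi8) == 1).all():
        raise ValueError("month index must be contiguous (zero-fill gaps first)")
    D = agg["Pur"].rolling(window).mean()
    U = agg["Sale"].rolling(window).mean()
    out = pd.DataFrame({"month": months, "D": D, "U": U}).iloc[window - 1 :]
    return out.reset_index(drop=True)


def compute_features(smoothed: pd.DataFrame, clamp: float = 20.0) -> pd.DataFrame:
    """Log-turnover features X1 = ln(U_i/D_i), X2 = ln(U_i/D_{i-1}).

    X2 is NaN for the first emitted month. Zero-denominator records are
    clamped to ±clamp and flagged ``clamped``; records with U and D both zero
    are ``valid=False``.
    """
    if smoothed.empty:
        raise ValueError("smoothed series is empty")
    D = smoothed["D"].to_numpy(dtype=float)
    U = smoothed["U"].to_numpy(dtype=float)
    D_lag = np.concatenate([[np.nan], D[:-1]])

    def _logratio(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.full(len(num), np.nan)
        flag = np.zeros(len(num), dtype=bool)
        with np.errstate(divide="ignore", invalid="ignore"):
            ok = (num > 0) & (den > 0)
            x[ok] = np.log(num[ok] / den[ok])
            pos_inf = (num > 0) & (den == 0)
            neg_inf = (num == 0) & (den > 0)
            x[pos_inf] = clamp
            x[neg_inf] = -clamp
            flag |= pos_inf | neg_inf
        return x, flag

    x1, c1 = _logratio(U, D)
    x2, c2 = _logratio(U, D_lag)
    x2[0] = np.nan
    c2[0] = False
    both_zero = (U == 0) & (D == 0)
    out = smoothed.copy()
    out["X1"] = x1
    out["X2"] = x2
    out["clamped"] = c1 | c2
    out["valid"] = ~both_zero
    return out


def feature_table(
    invoices: Sequence[Invoice] | pd.DataFrame,
    manufacturer_ids: Sequence[str],
    months: pd.PeriodIndex | None = None,
    clamp: float = 20.0,
) -> pd.DataFrame:
    """Full per-manufacturer-month feature table for the alarm stage.

    Columns: manufacturer_id, month, Pur, Sale, D, U, X1, X2, clamped, valid.
    """
    df = _as_frame(invoices)
    frames = []
    for mid in manufacturer_ids:
        agg = aggregate_monthly(df, mid, months=months)
        if len(agg) < 3:
            continue
        feats = compute_features(smooth(agg), clamp=clamp)
        feats = feats.merge(agg, on="month")
        feats.insert(0, "manufacturer_id", mid)
        frames.append(feats)
    if not frames:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out[FEATURE_COLUMNS]
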