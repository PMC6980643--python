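"""Synthetic invoice corpora with the statistical structure the alarm pipeline
assumes, so every stage is testable without restricted transaction data.

The generator emulates a population of edible-oil manufacturers observed over
monthly B2B e-invoices. Item names come in three strata: edible-oil products
(label 1), "oil"-keyword confounders such as motor oil or oil paint (label 0),
and unrelated goods (label 0). Each manufacturer trades edible-oil items plus
non-edible distractor lines, so the text sieve is load-bearing.

Monthly money flows follow a multiplicative model: a benchmark month draws
``log(sales / purchases) ~ Normal(0, sigma_log)``. A *suppressed* month of a
problematic manufacturer keeps its sales but scales recorded purchases down by
``exp(-b_shift)`` — the signature of material bought off the books — so the raw
log turnover ratio shifts by ``b_shift`` (default 8, well past the alarm
threshold of 6). Unspecified manufacturers mix the two regimes.

Everything is driven by one integer seed; per-manufacturer sub-streams are
derived by stable hashing of the manufacturer id, so output is byte-identical
for an identical (config, seed) across runs and platforms.
"""

from __future__ import annotations

import calendar
import hashlib
import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .io import Invoice, LabeledItem, ManufacturerRecord

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_item_catalog",
    "generate_invoices",
    "generate_corpus",
    "feature_truth_labels",
]

# Word pools for the three item-name strata. Token vocabularies are pairwise
# disjoint except for "oil", which the confounder stratum shares by design
# (that is exactly what makes the keyword filter insufficient on its own).
_OIL_MODIFIERS = [
    "refined", "cold pressed", "organic", "extra virgin", "pure", "premium",
    "unrefined", "expeller pressed", "filtered", "blended", "roasted", "firstpress",
]
_OIL_BASES = [
    "soybean oil", "olive oil", "peanut oil", "sesame oil", "canola oil",
    "sunflower oil", "palm oil", "ricebran oil", "grapeseed oil", "corn oil",
    "camellia oil", "lard oil", "cooking oil", "salad oil", "frying oil",
    "vegetable oil",
]
_CONFOUNDER_MODIFIERS = [
    "industrial", "synthetic", "heavy duty", "aromatic", "scented", "automotive",
    "marine", "workshop", "mineral", "multi purpose", "two stroke", "antiwear",
]
_CONFOUNDER_BASES = [
    "motor oil", "engine oil", "gear oil", "hydraulic oil", "lamp oil",
    "crude oil", "essential oil", "massage oil", "baby oil", "hair oil",
    "bath oil", "oil paint", "oil pastel", "oil filter", "oil seal",
    "fuel oil", "lubricating oil", "cutting oil",
]
_UNRELATED_MODIFIERS = [
    "classic", "family pack", "deluxe", "golden", "island", "mountain",
    "spring", "valley", "harvest", "traditional", "signature", "jumbo",
]
_UNRELATED_BASES = [
    "rice vinegar", "soy sauce", "wheat flour", "brown sugar", "green tea",
    "instant noodles", "dried mushroom", "canned tuna", "tomato ketchup",
    "chili paste", "barley drink", "milk powder", "egg rolls", "seaweed snack",
    "mung beans", "sweetpotato starch",
]
# Invented brand words, distinct across strata.
_OIL_BRANDS = [
    "solenna", "tavira", "orvello", "miravex", "lunaris", "calvena", "dorente",
    "avelio", "sorvina", "eldoria", "naviron", "tessara", "velmora", "ostrava",
    "quillon", "rivenna", "maldero", "cinqua", "bellvara", "trusole", "farendi",
    "lomesta", "virdano", "pellara",
]
_CONFOUNDER_BRANDS = [
    "droxel", "karbex", "mechtor", "fulgan", "straven", "polmek", "garrod",
    "zintek", "welbron", "hadrex", "crovan", "durmek", "valcor", "brenmak",
    "sortek", "quorvan", "maxtren", "ferrodal", "ulgrim", "typhron", "vandrek",
    "holmar", "greptor", "silzor",
]
_UNRELATED_BRANDS = [
    "amaya", "kinosa", "herunda", "waseki", "toluma", "eriyo", "sanomi",
    "fujara", "mikuni", "hoshida", "narumi", "okabe", "tsubara", "yonaka",
    "imaro", "kazuni", "serota", "uchima", "noburi", "hatama", "rikuna",
    "osette", "minawa", "ebisa",
]


class GeneratorConfig(BaseModel):
    """Parameters of the stated synthetic world.

    Defaults mirror the surveillance setting the pipeline targets: 21 benchmark
    (A), 6 problematic (B) and 568 unspecified (C) manufacturers observed over
    46 calendar months starting January 2014; benchmark log-turnover noise of
    0.5; suppressed months shifted by 8 on the log scale; half of a problematic
    manufacturer's months suppressed.
    """

    seed: int = 0
    n_A: int = Field(default=21, ge=0)
    n_B: int = Field(default=6, ge=0)
    n_C: int = Field(default=568, ge=0)
    n_months: int = Field(default=46, ge=1)
    start_month: str = "2014-01"
    n_oil_items: int = Field(default=350, ge=1)
    n_confounder_items: int = Field(default=250, ge=1)
    n_unrelated_items: int = Field(default=400, ge=1)
    sigma_log: float = Field(default=0.5, gt=0)
    b_shift: float = Field(default=8.0, ge=0)
    p_suspicious: float = Field(default=0.5, ge=0, le=1)
    p_c_suspicious: float = Field(default=0.02, ge=0, le=1)
    invoices_per_month: float = Field(default=6.0, gt=0)
    amount_scale: float = Field(default=1e5, gt=0)
    # within-manufacturer lognormal sd of monthly purchase scale
    sigma_amount: float = Field(default=0.3, ge=0)

    @model_validator(mode="after")
    def _check_start(self) -> "GeneratorConfig":
        try:
            pd.Period(self.start_month, freq="M")
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"start_month: not a parseable YYYY-MM month ({exc})")
        return self


@dataclass
class GroundTruth:
    """What the generator actually did: class labels, the month index, and the
    raw per-month purchase-suppression flags per manufacturer."""

    classes: dict[str, str]
    months: list[str]
    suspicious_months: dict[str, list[str]] = field(default_factory=dict)

    def manufacturer_records(self) -> list[ManufacturerRecord]:
        return [
            ManufacturerRecord(manufacturer_id=m, class_label=c)
            for m, c in self.classes.items()
        ]

    def flags(self, manufacturer_id: str) -> np.ndarray:
        """Boolean raw-month suppression flags aligned to ``months``."""
        susp = set(self.suspicious_months.get(manufacturer_id, ()))
        return np.array([m in susp for m in self.months], dtype=bool)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "classes": self.classes,
            "months": self.months,
            "suspicious_months": self.suspicious_months,
        }
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            classes=d["classes"],
            months=d["months"],
            suspicious_months=d["suspicious_months"],
        )


def _stable_hash(text: str) -> int:
    """Platform-independent 32-bit hash for deriving RNG sub-streams."""
    return int.from_bytes(hashlib.blake2s(text.encode("utf-8"), digest_size=4).digest(), "big")


def _stratum_names(
    modifiers: list[str], bases: list[str], brands: list[str], n: int, rng: np.random.Generator,
    field_name: str,
) -> list[str]:
    combos = [f"{brand} {mod} {base}" for brand, mod, base in product(brands, modifiers, bases)]
    if n > len(combos):
        raise ValueError(
            f"{field_name}: requested {n} names but only {len(combos)} templates available"
        )
    order = rng.permutation(len(combos))[:n]
    return [combos[i] for i in order]


def generate_item_catalog(config: GeneratorConfig) -> list[LabeledItem]:
    """Build the labeled item catalog in three strata.

    Edible-oil names (label 1) all contain an oil-food term; confounders
    (label 0) contain the keyword "oil" in a non-edible sense; unrelated names
    (label 0) avoid the keyword entirely. All names are unique.
    """
    out: list[LabeledItem] = []
    specs = [
        (_OIL_MODIFIERS, _OIL_BASES, _OIL_BRANDS, config.n_oil_items, 1, "n_oil_items"),
        (_CONFOUNDER_MODIFIERS, _CONFOUNDER_BASES, _CONFOUNDER_BRANDS,
         config.n_confounder_items, 0, "n_confounder_items"),
        (_UNRELATED_MODIFIERS, _UNRELATED_BASES, _UNRELATED_BRANDS,
         config.n_unrelated_items, 0, "n_unrelated_items"),
    ]
    for k, (mods, bases, brands, n, label, fname) in enumerate(specs):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + k]))
        for name in _stratum_names(mods, bases, brands, n, rng, fname):
            out.append(LabeledItem(item_name=name, label=label))
    return out


def _month_days(period: pd.Period) -> int:
    return calendar.monthrange(period.year, period.month)[1]


def _split_amount(total: float, k: int, rng: np.random.Generator) -> np.ndarray:
    """Split a positive total into k strictly positive parts."""
    w = rng.dirichlet(np.ones(k))
    return total * w


def generate_invoices(
    config: GeneratorConfig, catalog: list[LabeledItem]
) -> tuple[list[Invoice], GroundTruth]:
    """Emit the invoice stream and its ground truth.

    For each manufacturer and month the generator draws a purchase total and a
    sales total on the multiplicative model above, splits each into a Poisson
    number of invoice lines over edible-oil items, and adds non-edible
    distractor lines. The manufacturer is the vendee on purchase lines and the
    vendor on sales lines; counterparties are anonymous external ids.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    if config.n_months < 3:
        raise ValueError(
            f"n_months={config.n_months} < 3: the 3-month smoothing window is unsatisfiable"
        )
    oil_names = [it.item_name for it in catalog if it.label == 1]
    other_names = [it.item_name for it in catalog if it.label == 0]
    if not oil_names:
        raise ValueError("catalog contains no edible-oil (label 1) items")

    months = pd.period_range(config.start_month, periods=config.n_months, freq="M")
    month_strs = [str(m) for m in months]
    mids = (
        [f"A{i + 1:03d}" for i in range(config.n_A)]
        + [f"B{i + 1:03d}" for i in range(config.n_B)]
        + [f"C{i + 1:03d}" for i in range(config.n_C)]
    )
    classes = {m: m[0] for m in mids}
    p_by_class = {"A": 0.0, "B": config.p_suspicious, "C": config.p_c_suspicious}

    invoices: list[Invoice] = []
    suspicious: dict[str, list[str]] = {}
    ipm = config.invoices_per_month

    for mid in mids:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, _stable_hash(mid)]))
        flags = rng.random(config.n_months) < p_by_class[classes[mid]]
        base = config.amount_scale * np.exp(rng.normal(0.0, config.sigma_amount, config.n_months))
        ratio = rng.normal(0.0, config.sigma_log, config.n_months)
        sales = base * np.exp(ratio)
        purchases = base * np.where(flags, np.exp(-config.b_shift), 1.0)
        suspicious[mid] = [month_strs[i] for i in range(config.n_months) if flags[i]]

        counter = 0
        for i, period in enumerate(months):
            days = _month_days(period)
            # edible-oil purchase lines (manufacturer buys material)
            n_pur = 1 + rng.poisson(max(ipm - 1.0, 0.0))
            for amt in _split_amount(purchases[i], n_pur, rng):
                counter += 1
                invoices.append(Invoice.model_construct(
                    invoice_id=f"{mid}-{counter:06d}",
                    date=period.to_timestamp().date().replace(day=int(rng.integers(1, days + 1))),
                    vendor_id=f"EXT{rng.integers(0, 400):04d}",
                    vendee_id=mid,
                    item_name=oil_names[rng.integers(len(oil_names))],
                    amount=float(amt),
                    quantity=None,
                ))
            # edible-oil sales lines (manufacturer sells product)
            n_sale = 1 + rng.poisson(max(ipm - 1.0, 0.0))
            for amt in _split_amount(sales[i], n_sale, rng):
                counter += 1
                invoices.append(Invoice.model_construct(
                    invoice_id=f"{mid}-{counter:06d}",
                    date=period.to_timestamp().date().replace(day=int(rng.integers(1, days + 1))),
                    vendor_id=mid,
                    vendee_id=f"EXT{rng.integers(0, 400):04d}",
                    item_name=oil_names[rng.integers(len(oil_names))],
                    amount=float(amt),
                    quantity=None,
                ))
            # non-edible distractor lines, either direction
            if other_names:
                n_dis = rng.poisson(ipm / 2.0)
                for _ in range(n_dis):
                    counter += 1
                    amt = config.amount_scale * float(np.exp(rng.normal(-1.0, 0.7)))
                    sell = rng.random() < 0.5
                    ext = f"EXT{rng.integers(0, 400):04d}"
                    invoices.append(Invoice.model_construct(
                        invoice_id=f"{mid}-{counter:06d}",
                        date=period.to_timestamp().date().replace(day=int(rng.integers(1, days + 1))),
                        vendor_id=mid if sell else ext,
                        vendee_id=ext if sell else mid,
                        item_name=other_names[rng.integers(len(other_names))],
                        amount=amt,
                        quantity=None,
                    ))

    truth = GroundTruth(classes=classes, months=month_strs, suspicious_months=suspicious)
    return invoices, truth


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[LabeledItem], list[Invoice], GroundTruth]:
    """Convenience wrapper: catalog plus invoices plus ground truth."""
    catalog = generate_item_catalog(config)
    invoices, truth = generate_invoices(config, catalog)
    return catalog, invoices, truth


def feature_truth_labels(
    truth: GroundTruth, manufacturer_id: str, feature_months: list[str] | pd.Index
) -> np.ndarray:
    """Ground-truth labels for smoothed feature records.

    A smoothed month *i* is labeled suspicious iff the four raw months feeding
    its current and lagged purchase windows (i-3 .. i) were all suppressed:
    only sustained suppression survives 3-month moving-average smoothing, and
    the alarm's lag feature deliberately looks across a two-month span. Records
    whose lag window reaches before the start of the series are benchmark.
    """
    flags = truth.flags(manufacturer_id)
    pos = {m: j for j, m in enumerate(truth.months)}
    out = np.zeros(len(feature_months), dtype=bool)
    for j, m in enumerate(feature_months):
        i = pos.get(str(m))
        if i is None or i < 3:
            continue
        out[j] = bool(flags[i - 3 : i + 1].all())
    return out
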