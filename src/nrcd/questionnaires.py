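"""Scoring of the clinical instruments used in celiac-disease follow-up.

Four validated questionnaires are supported:

* **GSRS-CD** — Gastrointestinal Symptom Rating Scale (celiac version):
  15 items on a 0-10 Likert scale, five symptom subscales (indigestion,
  diarrhea, abdominal pain, reflux, constipation). Subscale scores and the
  total are item means.
* **CeD-Pro** — Celiac Disease Patient-Reported Outcome: 10 items, 0-10
  scale, scored as item means.
* **CD-QOL** — Celiac Disease Quality of Life: 20 items, 0-5 scale, four
  subscales (limitations, dysphoria, health concerns, inadequate
  treatment), scored as item means.
* **CDAT** — Celiac Dietary Adherence Test: 7 items, 1-5 scale. The total
  is the item sum (range 7-35) and maps onto an adherence category:
  7 = excellent, 8-12 = very good, 13-17 = insufficient, >17 = poor.

The validated item-to-subscale keys are not redistributed here, so
subscale maps are caller-supplied configuration; sensible equal-block
defaults are provided for convenience.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InstrumentScore",
    "INSTRUMENT_SPECS",
    "default_subscale_map",
    "score_gsrs",
    "score_cdat",
    "score_likert_mean",
    "score_metadata",
]

#: Per-instrument (n_items, min_value, max_value, column_prefix).
INSTRUMENT_SPECS: dict[str, tuple[int, int, int, str]] = {
    "GSRS-CD": (15, 0, 10, "gsrs"),
    "CeD-Pro": (10, 0, 10, "cedpro"),
    "CD-QOL": (20, 0, 5, "cdqol"),
    "CDAT": (7, 1, 5, "cdat"),
}

_GSRS_SUBSCALES = ("indigestion", "diarrhea", "abdominal pain", "reflux", "constipation")

_CDQOL_SUBSCALES = ("limitations", "dysphoria", "health concerns", "inadequate treatment")


@dataclass
class InstrumentScore:
    """Scored instrument: total, per-subscale means, optional category."""

    instrument: str
    total: float
    subscale_scores: dict[str, float] = field(default_factory=dict)
    category: str | None = None


def default_subscale_map(instrument: str) -> dict[int, str]:
    """Equal-block default item→subscale assignment (0-based item index).

    These are placeholders for the validated instrument keys, which must be
    supplied by the caller for real scoring; they only guarantee that every
    item belongs to exactly one subscale.
    """
    if instrument == "GSRS-CD":
        names = _GSRS_SUBSCALES
        n = 15
    elif instrument == "CD-QOL":
        names = _CDQOL_SUBSCALES
        n = 20
    elif instrument == "CeD-Pro":
        return {i: "total" for i in range(10)}
    else:
        raise ValueError(f"no default subscale map for {instrument!r}")
    block = n // len(names)
    return {i: names[min(i // block, len(names) - 1)] for i in range(n)}


def _validate_items(instrument: str, items) -> np.ndarray:
    n, lo, hi, _ = INSTRUMENT_SPECS[instrument]
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 1 or arr.size != n:
        raise ValueError(f"{instrument} requires exactly {n} items, got {arr.size}")
    if np.isnan(arr).any():
        raise ValueError(f"{instrument} items contain missing values; prorating is not supported")
    if (arr < lo).any() or (arr > hi).any():
        raise ValueError(f"{instrument} items must lie in [{lo}, {hi}]")
    return arr


def _mean_scored(instrument: str, items, subscale_map: dict[int, str] | None) -> InstrumentScore:
    arr = _validate_items(instrument, items)
    if subscale_map is None:
        subscale_map = default_subscale_map(instrument)
    if sorted(subscale_map) != list(range(arr.size)):
        raise ValueError("subscale_map must assign every item index exactly once")
    sub: dict[str, float] = {}
    for name in dict.fromkeys(subscale_map.values()):
        idx = [i for i, s in subscale_map.items() if s == name]
        sub[name] = float(np.mean(arr[idx]))
    return InstrumentScore(instrument=instrument, total=float(arr.mean()), subscale_scores=sub)


def score_gsrs(items, subscale_map: dict[int, str] | None = None) -> InstrumentScore:
    """Score the 15-item GSRS-CD: subscale means plus the grand item mean."""
    return _mean_scored("GSRS-CD", items, subscale_map)


def score_likert_mean(instrument: str, items, subscale_map: dict[int, str] | None = None) -> InstrumentScore:
    """Score CeD-Pro or CD-QOL as plain item means (total and subscales)."""
    if instrument not in ("CeD-Pro", "CD-QOL"):
        raise ValueError("score_likert_mean handles CeD-Pro and CD-QOL only")
    return _mean_scored(instrument, items, subscale_map)


def cdat_category(total: int) -> str:
    """Adherence category for a CDAT total (7-35)."""
    if total <= 7:
        return "excellent"
    if total <= 12:
        return "very good"
    if total <= 17:
        return "insufficient"
    return "poor"


def score_cdat(items) -> InstrumentScore:
    """Score the 7-item CDAT: integer sum in [7, 35] plus adherence category."""
    arr = _validate_items("CDAT", items)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("CDAT items must be integers in [1, 5]")
    total = int(arr.sum())
    return InstrumentScore(instrument="CDAT", total=float(total), category=cdat_category(total))


def score_metadata(metadata: pd.DataFrame, instrument: str,
                   subscale_map: dict[int, str] | None = None) -> pd.DataFrame:
    """Score one instrument for every row of a metadata table.

    Items are read from columns named ``<prefix>_01 .. <prefix>_NN``
    (e.g. ``cdat_01 .. cdat_07``). Returns one row per sample with the
    total, subscale scores and (for CDAT) the adherence category.
    """
    n, _, _, prefix = INSTRUMENT_SPECS[instrument]
    cols = [f"{prefix}_{i:02d}" for i in range(1, n + 1)]
    missing = [c for c in cols if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata lacks item columns: {missing}")
    rows = []
    for sample, vals in metadata[cols].iterrows():
        if instrument == "CDAT":
            sc = score_cdat(vals.to_numpy())
        elif instrument == "GSRS-CD":
            sc = score_gsrs(vals.to_numpy(), subscale_map)
        else:
            sc = score_likert_mean(instrument, vals.to_numpy(), subscale_map)
        row = {"sample": sample, "total": sc.total, **sc.subscale_scores}
        if sc.category is not None:
            row["category"] = sc.category
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")
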