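"""BITSEA questionnaire scoring: domains, sleep-items-removed variant, alpha.

The Brief Infant-Toddler Social and Emotional Assessment has 42 items rated
0 (not true/rarely), 1 (somewhat true/sometimes), 2 (very true/always): 31
problem items and 11 competence items.  Four analysis domains are scored as
item sums — internalizing, externalizing, dysregulation, competence — plus a
dysregulation variant with the two sleep items removed (used to rule out
circularity when groups are defined by night awakenings).

The licensed item-to-domain map is proprietary, so the packaged default
instrument is synthetic: invented item texts honoring every published count
constraint (42 items; 11 competence; 31 problem split 8 internalizing, 6
externalizing, 8 dysregulation, 9 other; exactly 2 sleep items inside
dysregulation, with the published wording).  Users holding the licensed
instrument can load their own mapping from a tab-delimited config.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DOMAINS = ("internalizing", "externalizing", "dysregulation", "competence", "other_problem")
SCORED_DOMAINS = ("internalizing", "externalizing", "dysregulation", "competence")

SLEEP_ITEM_TEXTS = (
    "Wakes up at night and needs help to fall asleep again",
    "Has trouble falling asleep or staying asleep",
)

#: published domain sizes the synthetic default honors
DOMAIN_SIZES = {
    "internalizing": 8,
    "externalizing": 6,
    "dysregulation": 8,
    "competence": 11,
    "other_problem": 9,
}


class InstrumentError(ValueError):
    """Instrument config violating a published count constraint."""


class ResponseError(ValueError):
    """Out-of-range questionnaire response."""


@dataclass(frozen=True)
class Item:
    item_id: str
    text: str
    domain: str
    is_sleep_item: bool = False


@dataclass(frozen=True)
class BITSEAInstrument:
    items: tuple[Item, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 42:
            raise InstrumentError(f"instrument must have 42 items, got {len(self.items)}")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise InstrumentError("duplicate item ids")
        for it in self.items:
            if it.domain not in DOMAINS:
                raise InstrumentError(f"unknown domain {it.domain!r} on item {it.item_id}")
        n_comp = sum(it.domain == "competence" for it in self.items)
        if n_comp != 11:
            raise InstrumentError(f"expected 11 competence items, got {n_comp}")
        n_prob = sum(it.domain != "competence" for it in self.items)
        if n_prob != 31:
            raise InstrumentError(f"expected 31 problem items, got {n_prob}")
        sleep = [it for it in self.items if it.is_sleep_item]
        if len(sleep) != 2:
            raise InstrumentError(f"expected exactly 2 sleep items, got {len(sleep)}")
        if any(it.domain != "dysregulation" for it in sleep):
            raise InstrumentError("sleep items must belong to dysregulation")
        if set(it.text for it in sleep) != set(SLEEP_ITEM_TEXTS):
            raise InstrumentError("sleep-item texts do not match the published wording")

    def item_ids(self, domain: str, include_sleep: bool = True) -> list[str]:
        return [
            it.item_id
            for it in self.items
            if it.domain == domain and (include_sleep or not it.is_sleep_item)
        ]

    @property
    def all_ids(self) -> list[str]:
        return [it.item_id for it in self.items]


def _default_items() -> tuple[Item, ...]:
    """Synthetic default mapping (invented wording except the two published
    sleep items and three published dysregulation examples)."""
    texts = {
        "internalizing": [
            "Seems nervous or fearful in new situations",
            "Is worried or anxious much of the time",
            "Seems unhappy or sad without clear reason",
            "Clings to caregiver in unfamiliar places",
            "Is afraid of everyday objects or sounds",
            "Withdraws from other children",
            "Seems shut down or unresponsive when upset",
            "Startles easily at noises",
        ],
        "externalizing": [
            "Hits, bites, or kicks other children",
            "Is restless and cannot sit still",
            "Acts without thinking about danger",
            "Breaks or throws things when angry",
            "Is defiant when asked to do something",
            "Grabs toys from other children",
        ],
        "dysregulation": [
            "Cries or tantrums until s/he is exhausted",
            "Has trouble adjusting to changes",
            "Often gets very upset",
            SLEEP_ITEM_TEXTS[0],
            SLEEP_ITEM_TEXTS[1],
            "Is very picky or irregular about eating",
            "Is hard to soothe once upset",
            "Overreacts to minor frustrations",
        ],
        "competence": [
            "Looks at caregiver when hearing own name",
            "Imitates simple actions of adults",
            "Shows toys or objects to share interest",
            "Tries to comfort others who are upset",
            "Follows simple one-step instructions",
            "Plays pretend games with toys",
            "Greets familiar people with enthusiasm",
            "Helps with simple household routines",
            "Points to show things of interest",
            "Takes turns in simple games",
            "Shows affection toward familiar people",
        ],
        "other_problem": [
            "Avoids eye contact with familiar people",
            "Repeats the same movement over and over",
            "Does not react when spoken to",
            "Puts inedible things in mouth repeatedly",
            "Seems insensitive to pain",
            "Stares into space for long periods",
            "Uses odd or flat tone of voice",
            "Is unusually attached to one object",
            "Hurts self on purpose",
        ],
    }
    items = []
    k = 0
    for domain in DOMAINS:
        for text in texts[domain]:
            k += 1
            items.append(
                Item(
                    item_id=f"item{k:02d}",
                    text=text,
                    domain=domain,
                    is_sleep_item=text in SLEEP_ITEM_TEXTS,
                )
            )
    return tuple(items)


def default_instrument() -> BITSEAInstrument:
    return BITSEAInstrument(items=_default_items())


def load_instrument(path: str | Path) -> BITSEAInstrument:
    """Load an item->domain map from a tab-delimited config with columns
    item_id, text, domain, is_sleep_item (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"item_id", "text", "domain", "is_sleep_item"}
    if not required.issubset(df.columns):
        raise InstrumentError(
            f"instrument config missing columns {sorted(required - set(df.columns))}"
        )
    items = tuple(
        Item(
            item_id=str(r.item_id),
            text=str(r.text),
            domain=str(r.domain),
            is_sleep_item=str(r.is_sleep_item).strip().lower() in ("1", "true"),
        )
        for r in df.itertuples()
    )
    return BITSEAInstrument(items=items)


def write_instrument(instrument: BITSEAInstrument, path: str | Path) -> None:
    pd.DataFrame(
        [(it.item_id, it.text, it.domain, int(it.is_sleep_item)) for it in instrument.items],
        columns=["item_id", "text", "domain", "is_sleep_item"],
    ).to_csv(path, sep="\t", index=False)


def _domain_sum(
    responses: pd.DataFrame, ids: Sequence[str], impute: bool
) -> pd.Series:
    block = responses[list(ids)]
    if impute:
        frac_missing = block.isna().mean(axis=1)
        means = block.mean(axis=1)
        filled = block.apply(lambda col: col.fillna(means))
        out = filled.sum(axis=1, min_count=len(ids))
        out[frac_missing > 0.25] = np.nan
        return out
    return block.sum(axis=1, min_count=len(ids))  # any missing -> NaN


def score_domains(
    responses: pd.DataFrame,
    instrument: BITSEAInstrument | None = None,
    impute: bool = False,
) -> pd.DataFrame:
    """Per-participant domain sums (rows indexed by participant).

    ``responses`` is a participant x item table restricted to {0, 1, 2, NaN}.
    Default missing handling requires complete domains; with ``impute=True``
    person-mean imputation within a domain is applied when at most 25% of the
    domain's items are missing.
    """
    if instrument is None:
        instrument = default_instrument()
    missing_items = [i for i in instrument.all_ids if i not in responses.columns]
    if missing_items:
        raise ResponseError(f"response table missing items {missing_items}")
    vals = responses[instrument.all_ids]
    bad = ~(vals.isin([0, 1, 2]) | vals.isna())
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise ResponseError(
            f"out-of-range response {vals.loc[row, col]!r} for participant "
            f"{row!r}, item {col!r}"
        )
    out = pd.DataFrame(index=responses.index)
    for domain in SCORED_DOMAINS:
        out[domain] = _domain_sum(vals, instrument.item_ids(domain), impute)
    out["dysregulation_no_sleep"] = _domain_sum(
        vals, instrument.item_ids("dysregulation", include_sleep=False), impute
    )
    return out


def cronbach_alpha(item_matrix: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum item variances / total variance).

    Rows are respondents, columns items; incomplete rows are dropped.
    Raises on fewer than 2 items, fewer than 2 complete respondents, or zero
    total-score variance.
    """
    X = pd.DataFrame(item_matrix).dropna().to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("alpha requires at least 2 items")
    if X.shape[0] < 2:
        raise ValueError("alpha requires at least 2 complete respondents")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("alpha undefined: zero variance of the total score")
    return float(k / (k - 1) * (1 - item_var / total_var))


__all__ = [
    "DOMAINS",
    "SCORED_DOMAINS",
    "SLEEP_ITEM_TEXTS",
    "DOMAIN_SIZES",
    "Item",
    "BITSEAInstrument",
    "InstrumentError",
    "ResponseError",
    "default_instrument",
    "load_instrument",
    "write_instrument",
    "score_domains",
    "cronbach_alpha",
]
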