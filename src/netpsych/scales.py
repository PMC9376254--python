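"""Questionnaire scoring and screening.

Three instruments, all on 5-point Likert items (1..5):

* IAT  — Young's Internet Addiction Test, 20 items; the total is the plain
  sum, range 20..100, and a total strictly greater than 50 flags probable
  internet addiction.
* TAS-20 — Toronto Alexithymia Scale, 20 items in three factors (DIF, DDF,
  EOTS); reverse-keyed items are transformed ``x -> 6 - x`` before summing.
* CERQ — Cognitive Emotion Regulation Questionnaire, 36 items in nine
  4-item strategy subscales, each subscale the sum of its items (4..20).

Scoring keys are shipped as defaults but fully overridable, since
translated versions of the instruments can differ in item assignment.
Rows with any missing or out-of-range item are flagged invalid and dropped
listwise, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datasets import NODE_LABELS

logger = logging.getLogger(__name__)

ADDICTION_CUTOFF = 50

#: CERQ subscale order used throughout (first nine entries of NODE_LABELS).
CERQ_SUBSCALES: tuple[str, ...] = NODE_LABELS[:9]
TAS_FACTORS: tuple[str, ...] = ("DIF", "DDF", "EOTS")


@dataclass(frozen=True)
class TasKey:
    """Item-to-factor assignment and reverse-keyed item set for the TAS-20.

    Defaults are the published key: DIF 7 items, DDF 5, EOTS 8; items
    4, 5, 10, 18, 19 reverse-keyed.
    """

    dif: tuple[int, ...] = (1, 3, 6, 7, 9, 13, 14)
    ddf: tuple[int, ...] = (2, 4, 11, 12, 17)
    eots: tuple[int, ...] = (5, 8, 10, 15, 16, 18, 19, 20)
    reverse: tuple[int, ...] = (4, 5, 10, 18, 19)

    def __post_init__(self) -> None:
        items = sorted(self.dif + self.ddf + self.eots)
        if items != list(range(1, 21)):
            raise ValueError(
                "TAS key must assign items 1..20 to exactly one factor each")
        if not set(self.reverse) <= set(range(1, 21)):
            raise ValueError("reverse-keyed items must be in 1..20")

    @property
    def factors(self) -> dict[str, tuple[int, ...]]:
        return {"DIF": self.dif, "DDF": self.ddf, "EOTS": self.eots}


@dataclass(frozen=True)
class CerqKey:
    """Item blocks for the nine CERQ subscales (4 items each).

    Default: consecutive blocks in the canonical subscale order.
    """

    blocks: dict[str, tuple[int, ...]] = field(default_factory=lambda: {
        sub: tuple(range(4 * i + 1, 4 * i + 5))
        for i, sub in enumerate(CERQ_SUBSCALES)
    })

    def __post_init__(self) -> None:
        if sorted(self.blocks) != sorted(CERQ_SUBSCALES):
            raise ValueError(f"CERQ key must define exactly the subscales "
                             f"{CERQ_SUBSCALES}")
        items = [i for block in self.blocks.values() for i in block]
        if len(items) != len(set(items)):
            raise ValueError("duplicate item assignment in CERQ key")
        if sorted(items) != list(range(1, 37)):
            raise ValueError("CERQ key must cover items 1..36 exactly once")
        if any(len(b) != 4 for b in self.blocks.values()):
            raise ValueError("each CERQ subscale must have exactly 4 items")


DEFAULT_TAS_KEY = TasKey()
DEFAULT_CERQ_KEY = CerqKey()


def keys_to_yaml() -> str:
    """Default scoring keys as a YAML config block (for run configs)."""
    return yaml.safe_dump({
        "tas_key": {
            "dif": list(DEFAULT_TAS_KEY.dif),
            "ddf": list(DEFAULT_TAS_KEY.ddf),
            "eots": list(DEFAULT_TAS_KEY.eots),
            "reverse": list(DEFAULT_TAS_KEY.reverse),
        },
        "cerq_key": {k: list(v) for k, v in DEFAULT_CERQ_KEY.blocks.items()},
    }, sort_keys=False)


def keys_from_config(cfg: dict) -> tuple[TasKey, CerqKey]:
    """Build scoring keys from a parsed YAML config; missing keys default."""
    tas = DEFAULT_TAS_KEY
    if "tas_key" in cfg:
        k = cfg["tas_key"]
        tas = TasKey(dif=tuple(k["dif"]), ddf=tuple(k["ddf"]),
                     eots=tuple(k["eots"]), reverse=tuple(k["reverse"]))
    cerq = DEFAULT_CERQ_KEY
    if "cerq_key" in cfg:
        cerq = CerqKey(blocks={s: tuple(v)
                               for s, v in cfg["cerq_key"].items()})
    return tas, cerq


# ---------------------------------------------------------------------------
# Item validation
# ---------------------------------------------------------------------------

def _item_columns(df: pd.DataFrame, prefix: str, n_items: int) -> list[str]:
    cols = [f"{prefix}_{k}" for k in range(1, n_items + 1)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing item columns: {missing}")
    return cols


def valid_response_mask(df: pd.DataFrame, prefix: str, n_items: int,
                        ) -> pd.Series:
    """True for rows whose items are all integers in 1..5 with no missing.

    Invalid rows are flagged here and excluded by the callers (listwise
    deletion) — never silently imputed.
    """
    cols = _item_columns(df, prefix, n_items)
    x = df[cols].to_numpy(dtype=float)
    ok = np.isfinite(x) & (x >= 1) & (x <= 5) & (x == np.round(x))
    mask = pd.Series(ok.all(axis=1), index=df.index)
    n_bad = int((~mask).sum())
    if n_bad:
        logger.warning("%d row(s) with missing/out-of-range %s items "
                       "flagged invalid", n_bad, prefix)
    return mask


# ---------------------------------------------------------------------------
# Scoring operations
# ---------------------------------------------------------------------------

def score_iat(items: pd.DataFrame) -> pd.Series:
    """Total IAT score: the arithmetic sum of the 20 items (range 20..100).

    Rows with invalid items score NaN (they are flagged, not imputed).
    """
    cols = _item_columns(items, "IAT", 20)
    mask = valid_response_mask(items, "IAT", 20)
    total = items[cols].sum(axis=1).astype(float)
    total[~mask] = np.nan
    return total.rename("iat_total")


def screen_addiction(totals: pd.Series | np.ndarray,
                     cutoff: int = ADDICTION_CUTOFF) -> np.ndarray:
    """Inclusion mask: total strictly greater than the cutoff (default 50)."""
    t = np.asarray(totals, dtype=float)
    return np.where(np.isfinite(t), t > cutoff, False)


def score_tas(items: pd.DataFrame, key: TasKey = DEFAULT_TAS_KEY,
              ) -> pd.DataFrame:
    """Three TAS-20 factor scores (DIF, DDF, EOTS) per participant.

    Reverse-keyed items are transformed ``x -> 6 - x`` before summation;
    invalid rows score NaN in all three factors.
    """
    cols = _item_columns(items, "TAS", 20)
    mask = valid_response_mask(items, "TAS", 20)
    x = items[cols].to_numpy(dtype=float)
    rev = [k - 1 for k in key.reverse]
    x[:, rev] = 6.0 - x[:, rev]
    out = pd.DataFrame(index=items.index)
    for factor, its in key.factors.items():
        out[factor] = x[:, [k - 1 for k in its]].sum(axis=1)
    out.loc[~mask, :] = np.nan
    return out


def score_cerq(items: pd.DataFrame, key: CerqKey = DEFAULT_CERQ_KEY,
               ) -> pd.DataFrame:
    """Nine CERQ subscale scores (each the sum of its 4 items, range 4..20)."""
    cols = _item_columns(items, "CERQ", 36)
    mask = valid_response_mask(items, "CERQ", 36)
    x = items[cols].to_numpy(dtype=float)
    out = pd.DataFrame(index=items.index)
    for sub in CERQ_SUBSCALES:
        out[sub] = x[:, [k - 1 for k in key.blocks[sub]]].sum(axis=1)
    out.loc[~mask, :] = np.nan
    return out


def build_score_table(iat: pd.DataFrame, tas: pd.DataFrame,
                      cerq: pd.DataFrame,
                      tas_key: TasKey = DEFAULT_TAS_KEY,
                      cerq_key: CerqKey = DEFAULT_CERQ_KEY,
                      cutoff: int = ADDICTION_CUTOFF,
                      id_column: str = "participant_id") -> pd.DataFrame:
    """Score all three instruments, screen on IAT > cutoff, and assemble
    the 12-variable analysis table.

    Each input frame carries raw item columns (``IAT_1..IAT_20`` etc.) and
    a participant identifier column. Participants absent from any
    instrument, or with any invalid item, are excluded with a logged
    warning (listwise deletion). Rows are sorted by participant id.

    Returns a frame indexed by participant id with ``iat_total`` plus the
    12 subscale columns in canonical node order.
    """
    frames = []
    for name, df in (("IAT", iat), ("TAS", tas), ("CERQ", cerq)):
        if id_column not in df.columns:
            raise ValueError(f"{name} table lacks id column {id_column!r}")
        if df[id_column].duplicated().any():
            raise ValueError(f"duplicate participant ids in {name} table")
        frames.append(df.set_index(id_column))
    iat_i, tas_i, cerq_i = frames
    common = iat_i.index.intersection(tas_i.index).intersection(cerq_i.index)
    n_union = len(iat_i.index.union(tas_i.index).union(cerq_i.index))
    if len(common) < n_union:
        logger.warning("%d participant(s) not present in all three "
                       "instruments; excluded", n_union - len(common))
    common = common.sort_values()

    totals = score_iat(iat_i.loc[common])
    tas_scores = score_tas(tas_i.loc[common], tas_key)
    cerq_scores = score_cerq(cerq_i.loc[common], cerq_key)

    table = pd.concat([totals, cerq_scores, tas_scores], axis=1)
    complete = table.notna().all(axis=1)
    if (~complete).any():
        logger.warning("%d participant(s) dropped listwise for invalid or "
                       "missing items", int((~complete).sum()))
    table = table[complete]
    included = screen_addiction(table["iat_total"], cutoff=cutoff)
    table = table[included]
    table.index.name = id_column
    return table[["iat_total", *NODE_LABELS]]


def analysis_columns(score_table: pd.DataFrame) -> pd.DataFrame:
    """The 12 subscale columns in canonical node order."""
    return score_table[list(NODE_LABELS)]
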