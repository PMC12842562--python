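"""Item banks, scale definitions and the packaged GDS reference calibration.

An :class:`ItemBank` holds per-item two-parameter-logistic (2PL) parameters:
the discrimination ``a`` (slope; how sharply the item separates subjects above
vs below its difficulty) and the difficulty ``b`` (latent-trait level at which
the item is endorsed with probability one half).  The packaged reference bank
is a published calibration of the 30-item Geriatric Depression Scale (GDS30)
on a large Korean community + clinic cohort of adults aged 60+, together with
the membership of the standard abbreviated forms (GDS15, GDS4) and the
IRT-optimised 10-item form (GDS10-IRT).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ItemBank",
    "ScaleDefinition",
    "REVERSE_KEYED_ITEMS",
    "reference_bank",
    "reference_scales",
    "load_scale_definitions",
]

#: GDS items worded in the positive direction; a "yes" on these is
#: *non*-depressive and must be flipped when scoring raw questionnaires.
REVERSE_KEYED_ITEMS: tuple[int, ...] = (1, 5, 7, 9, 15, 19, 21, 27, 29, 30)


@dataclass
class ItemBank:
    """Per-item 2PL parameters with optional standard errors and diagnostics.

    Parameters
    ----------
    items : array of int
        1-based item indices (GDS30 numbering for the packaged bank).
    a, b : arrays of float
        Discrimination (> 0, unitless) and difficulty (latent-trait units).
    """

    items: np.ndarray
    a: np.ndarray
    b: np.ndarray
    se_a: np.ndarray | None = None
    se_b: np.ndarray | None = None
    item_auc: np.ndarray | None = None
    labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=int)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.items.shape != self.a.shape or self.a.shape != self.b.shape:
            raise ValueError("items, a and b must have identical shapes")
        if np.any(self.a <= 0):
            raise ValueError("discrimination parameters must be positive")
        if not np.all(np.isfinite(self.b)):
            raise ValueError("difficulty parameters must be finite")
        for attr in ("se_a", "se_b", "item_auc"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, dtype=float))

    def __len__(self) -> int:
        return len(self.items)

    def index_of(self, item_ids) -> np.ndarray:
        """Positions of ``item_ids`` within the bank (raises on unknown id)."""
        pos = {it: i for i, it in enumerate(self.items)}
        try:
            return np.array([pos[i] for i in np.atleast_1d(item_ids)], dtype=int)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"item {e.args[0]} not present in bank") from None

    def subset(self, item_ids) -> "ItemBank":
        idx = self.index_of(item_ids)
        return ItemBank(
            items=self.items[idx],
            a=self.a[idx],
            b=self.b[idx],
            se_a=None if self.se_a is None else self.se_a[idx],
            se_b=None if self.se_b is None else self.se_b[idx],
            item_auc=None if self.item_auc is None else self.item_auc[idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"item_id": self.items, "a": self.a, "b": self.b})
        if self.se_a is not None:
            df["se_a"] = self.se_a
        if self.se_b is not None:
            df["se_b"] = self.se_b
        if self.item_auc is not None:
            df["item_auc"] = self.item_auc
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemBank":
        return cls(
            items=df["item_id"].to_numpy(),
            a=df["a"].to_numpy(),
            b=df["b"].to_numpy(),
            se_a=df["se_a"].to_numpy() if "se_a" in df else None,
            se_b=df["se_b"].to_numpy() if "se_b" in df else None,
            item_auc=df["item_auc"].to_numpy() if "item_auc" in df else None,
            labels=df["label"].tolist() if "label" in df else None,
        )

    @classmethod
    def from_csv(cls, path) -> "ItemBank":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class ScaleDefinition:
    """A named, ordered subset of item indices (1-based GDS30 numbering)."""

    name: str
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        items = tuple(int(i) for i in self.items)
        if len(set(items)) != len(items):
            raise ValueError(f"scale {self.name!r} has duplicate item indices")
        if any(i < 1 for i in items):
            raise ValueError("item indices are 1-based and must be >= 1")
        object.__setattr__(self, "items", items)

    def __len__(self) -> int:
        return len(self.items)


def _data_path(name: str):
    return importlib.resources.files("gdsirt.data") / name


def reference_bank() -> ItemBank:
    """The packaged GDS30 2PL calibration (30 items, a, b, per-item AUC)."""
    with importlib.resources.as_file(_data_path("reference_bank.csv")) as p:
        df = pd.read_csv(p)
    return ItemBank.from_frame(df)


def load_scale_definitions(path) -> dict[str, ScaleDefinition]:
    """Read a two-column CSV ``scale_name,item_index`` into scale definitions."""
    df = pd.read_csv(path)
    out: dict[str, ScaleDefinition] = {}
    for name, grp in df.groupby("scale_name", sort=False):
        out[name] = ScaleDefinition(name, tuple(grp["item_index"].astype(int)))
    return out


def reference_scales() -> dict[str, ScaleDefinition]:
    """Packaged scale memberships: GDS30, GDS15, GDS4 and GDS10-IRT."""
    with importlib.resources.as_file(_data_path("scale_definitions.csv")) as p:
        return load_scale_definitions(p)
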