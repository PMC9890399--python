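"""Item-bank containers for graded-response-model instruments.

An :class:`ItemBank` holds the per-item discrimination and ordered category
thresholds for a polytomous instrument (65 items with four 0-3 response
categories for the full SRS), plus the masks that define the 16-item short
form and the reverse-coded items, and optional group-specific parameter sets
(group = form and/or sex) for instruments calibrated with differential item
functioning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import SrsCatError


@dataclass(frozen=True)
class ItemParameters:
    """One graded-response item: logistic slope plus K-1 ordered thresholds.

    Parameters
    ----------
    item_id : int or str
        Item label; 1-based integers matching instrument item order.
    discrimination : float
        Common logistic slope ``a`` (latent-trait units^-1); must be positive.
    thresholds : sequence of float
        Strictly increasing boundary locations ``b_1 < ... < b_{K-1}`` on the
        latent-trait scale, one per cumulative category boundary.
    group : str, optional
        Calibration group this parameter set belongs to (e.g. ``"school|male"``).
    """

    item_id: int | str
    discrimination: float
    thresholds: tuple[float, ...]
    group: str | None = None

    def __post_init__(self):
        thr = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", thr)
        if not np.isfinite(self.discrimination) or self.discrimination <= 0:
            raise SrsCatError(
                f"item {self.item_id}: discrimination must be positive, "
                f"got {self.discrimination}"
            )
        if len(thr) < 1:
            raise SrsCatError(f"item {self.item_id}: need K >= 2 categories")
        if not all(np.isfinite(thr)):
            raise SrsCatError(f"item {self.item_id}: non-finite threshold")
        if any(b2 <= b1 for b1, b2 in zip(thr, thr[1:])):
            raise SrsCatError(
                f"item {self.item_id}: thresholds must be strictly increasing: {thr}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


class ItemBank:
    """Ordered collection of :class:`ItemParameters` with form/reverse masks.

    Parameters
    ----------
    items : sequence of ItemParameters
        The default (reference-group) parameter set, in instrument order.
    short_mask : iterable of item ids
        Items forming the short form.
    reverse_mask : iterable of item ids
        Items whose raw responses are reverse-coded (k -> K-1-k) before use.
    group_items : mapping of group label -> sequence of ItemParameters, optional
        Complete alternative parameter sets for calibration groups.
    """

    def __init__(
        self,
        items: Sequence[ItemParameters],
        short_mask: Iterable[int | str] = (),
        reverse_mask: Iterable[int | str] = (),
        group_items: Mapping[str, Sequence[ItemParameters]] | None = None,
    ):
        if not items:
            raise SrsCatError("item bank must contain at least one item")
        self._items = list(items)
        self._by_id = {it.item_id: it for it in self._items}
        if len(self._by_id) != len(self._items):
            raise SrsCatError("duplicate item ids in bank")
        ks = {it.n_categories for it in self._items}
        if len(ks) != 1:
            raise SrsCatError("all bank items must share a category count")
        self.n_categories = ks.pop()

        self.short_mask = tuple(short_mask)
        self.reverse_mask = frozenset(reverse_mask)
        for label, mask in (("short", self.short_mask), ("reverse", self.reverse_mask)):
            unknown = [i for i in mask if i not in self._by_id]
            if unknown:
                raise SrsCatError(f"{label}_mask references unknown items: {unknown}")
        if len(set(self.short_mask)) != len(self.short_mask):
            raise SrsCatError("short_mask contains duplicates")

        self._group_items: dict[str, dict] = {}
        for grp, g_items in (group_items or {}).items():
            g_by_id = {it.item_id: it for it in g_items}
            if set(g_by_id) != set(self._by_id):
                raise SrsCatError(
                    f"group '{grp}' parameter set does not cover the full bank"
                )
            if any(it.n_categories != self.n_categories for it in g_items):
                raise SrsCatError(f"group '{grp}' has mismatched category counts")
            self._group_items[grp] = g_by_id

    # -- access ------------------------------------------------------------

    @property
    def item_ids(self) -> tuple:
        return tuple(it.item_id for it in self._items)

    @property
    def n_items(self) -> int:
        return len(self._items)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self._group_items)

    def item(self, item_id, group: str | None = None) -> ItemParameters:
        if item_id not in self._by_id:
            raise SrsCatError(f"unknown item id {item_id!r}")
        if group is not None and group in self._group_items:
            return self._group_items[group][item_id]
        if group is not None and self._group_items:
            warnings.warn(
                f"no parameter set for group '{group}'; using default set",
                stacklevel=2,
            )
        return self._by_id[item_id]

    def params(self, group: str | None = None) -> list[ItemParameters]:
        """The full parameter set for ``group`` in instrument order.

        Falls back to the default set (with a warning) when group-specific
        parameters were never calibrated for ``group``.
        """
        if group is not None and group in self._group_items:
            g = self._group_items[group]
            return [g[it.item_id] for it in self._items]
        if group is not None and self._group_items:
            warnings.warn(
                f"no parameter set for group '{group}'; using default set",
                stacklevel=2,
            )
        return list(self._items)

    def arrays(self, group: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(discriminations, thresholds) as arrays of shape (n,) and (n, K-1)."""
        items = self.params(group)
        a = np.array([it.discrimination for it in items])
        b = np.array([it.thresholds for it in items])
        return a, b

    def item_ids_for(self, form: str = "full") -> tuple:
        if form == "full":
            return self.item_ids
        if form == "short":
            return self.short_mask
        raise SrsCatError(f"unknown form {form!r}; expected 'full' or 'short'")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        entries = [
            {"id": it.item_id, "a": it.discrimination, "b": list(it.thresholds),
             "group": None}
            for it in self._items
        ]
        for grp, by_id in self._group_items.items():
            entries.extend(
                {"id": it.item_id, "a": it.discrimination, "b": list(it.thresholds),
                 "group": grp}
                for it in (by_id[i] for i in self.item_ids)
            )
        return {
            "items": entries,
            "short_mask": list(self.short_mask),
            "reverse_mask": sorted(self.reverse_mask),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ItemBank":
        default, grouped = [], {}
        for entry in payload["items"]:
            item = ItemParameters(
                item_id=entry["id"],
                discrimination=entry["a"],
                thresholds=tuple(entry["b"]),
                group=entry.get("group"),
            )
            if item.group is None:
                default.append(item)
            else:
                grouped.setdefault(item.group, []).append(item)
        return cls(
            default,
            short_mask=payload.get("short_mask", ()),
            reverse_mask=payload.get("reverse_mask", ()),
            group_items=grouped or None,
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ItemBank":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
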