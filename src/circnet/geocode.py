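"""Offline resolution of free-text addresses to administrative units.

Addresses are matched against a gazetteer of provinces and cities by keyword
search (longest key first, then leftmost occurrence), replacing a remote
geocoding service with a deterministic, reproducible lookup. Only the
administrative identity (province, city) enters the downstream analysis;
centroid coordinates are carried along for display only. A plugin interface
lets a remote geocoder be substituted, with results cached to CSV so repeated
runs stay reproducible.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd

from circnet.records import RecordSet, normalize_text

logger = logging.getLogger(__name__)

PROVINCE = "province"
CITY = "city"


@dataclass(frozen=True)
class AdminUnit:
    """A hierarchical administrative unit (province or city).

    Direct-administered municipalities appear twice — once as a province-level
    and once as a city-level unit with the same name — so they participate in
    both network levels.
    """

    unit_id: str
    name: str
    level: str
    parent_id: str | None = None
    centroid: tuple[float, float] | None = None  # (lng, lat), display only

    def __post_init__(self):
        if self.level not in (PROVINCE, CITY):
            raise ValueError(f"level must be {PROVINCE!r} or {CITY!r}")
        if self.level == CITY and self.parent_id is None:
            raise ValueError(f"city unit {self.unit_id!r} needs a province parent")
        if self.level == PROVINCE and self.parent_id is not None:
            raise ValueError(f"province unit {self.unit_id!r} cannot have a parent")
        if self.centroid is not None:
            lng, lat = self.centroid
            if not (-180 <= lng <= 180 and -90 <= lat <= 90):
                raise ValueError(f"centroid out of range for {self.unit_id!r}: {self.centroid}")


class Gazetteer:
    """Administrative units plus their address-matching keys.

    Each unit has one or more match keys (its name and any aliases); every
    key maps to exactly one unit. Matching prefers the longest key, then the
    leftmost occurrence in the address; any remaining tie between distinct
    units is treated as unresolvable.
    """

    def __init__(self, units: Iterable[AdminUnit], aliases: dict[str, list[str]] | None = None):
        self.units: dict[str, AdminUnit] = {}
        aliases = aliases or {}
        for u in units:
            if u.unit_id in self.units:
                raise ValueError(f"duplicate unit_id {u.unit_id!r}")
            self.units[u.unit_id] = u
        # name uniqueness within a level under the same parent
        seen = set()
        for u in self.units.values():
            key = (u.level, u.parent_id, u.name)
            if key in seen:
                raise ValueError(f"duplicate unit name {u.name!r} at level {u.level}")
            seen.add(key)
        for u in self.units.values():
            if u.level == CITY and u.parent_id not in self.units:
                raise ValueError(f"city {u.unit_id!r} references unknown province {u.parent_id!r}")
        # match keys are unique within a level: a direct-administered
        # municipality legitimately owns the same key at both levels
        self._keys: dict[str, list[tuple[str, str]]] = {PROVINCE: [], CITY: []}
        key_owner: dict[tuple[str, str], str] = {}
        for u in self.units.values():
            for k in [u.name, *aliases.get(u.unit_id, [])]:
                k = normalize_text(k)
                if not k:
                    continue
                if (u.level, k) in key_owner and key_owner[(u.level, k)] != u.unit_id:
                    raise ValueError(f"match key {k!r} maps to two {u.level} units")
                key_owner[(u.level, k)] = u.unit_id
                self._keys[u.level].append((k, u.unit_id))
        for level in self._keys:
            self._keys[level].sort(key=lambda kv: (-len(kv[0]), kv[0]))
        self.aliases = {uid: list(al) for uid, al in aliases.items()}

    def __len__(self) -> int:
        return len(self.units)

    def provinces(self) -> list[AdminUnit]:
        return [u for u in self.units.values() if u.level == PROVINCE]

    def cities(self) -> list[AdminUnit]:
        return [u for u in self.units.values() if u.level == CITY]

    def parent(self, unit: AdminUnit) -> AdminUnit | None:
        return self.units.get(unit.parent_id) if unit.parent_id else None

    def match_keys(self, level: str) -> list[tuple[str, str]]:
        """(key, unit_id) pairs for a level, longest key first."""
        return list(self._keys[level])

    # ---- CSV round-trip -------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "Gazetteer":
        """Read a gazetteer CSV: unit_id, name, level, parent_id, lng, lat, aliases."""
        units, aliases = [], {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                centroid = None
                if row.get("lng") and row.get("lat"):
                    centroid = (float(row["lng"]), float(row["lat"]))
                units.append(
                    AdminUnit(
                        unit_id=row["unit_id"],
                        name=row["name"],
                        level=row["level"],
                        parent_id=row.get("parent_id") or None,
                        centroid=centroid,
                    )
                )
                if row.get("aliases"):
                    aliases[row["unit_id"]] = row["aliases"].split("|")
        return cls(units, aliases)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["unit_id", "name", "level", "parent_id", "lng", "lat", "aliases"])
            for u in sorted(self.units.values(), key=lambda u: u.unit_id):
                lng, lat = u.centroid if u.centroid else ("", "")
                writer.writerow(
                    [u.unit_id, u.name, u.level, u.parent_id or "", lng, lat,
                     "|".join(self.aliases.get(u.unit_id, []))]
                )


@dataclass(frozen=True)
class ResolvedAddress:
    """Outcome of resolving one address: units or a reason for failure."""

    province: AdminUnit | None
    city: AdminUnit | None
    reason: str | None = None  # set when unresolved

    @property
    def resolved(self) -> bool:
        return self.city is not None and self.province is not None


@dataclass
class GeoResolution:
    """Province/city assignment of both parties of one record."""

    record_id: str
    manufacturer: ResolvedAddress
    distributor: ResolvedAddress
    method: str = "gazetteer"

    @property
    def unresolved(self) -> bool:
        return not (self.manufacturer.resolved and self.distributor.resolved)


def _best_match(address: str, keys: list[tuple[str, str]]) -> tuple[str | None, str | None]:
    """Return (unit_id, None) for the longest-then-leftmost key match.

    Ties between distinct units at the same (length, position) are refused.
    """
    best = None  # (key_len_neg, position, key, unit_id)
    tied = False
    for key, unit_id in keys:
        pos = address.find(key)
        if pos < 0:
            continue
        cand = (-len(key), pos)
        if best is None or cand < best[:2]:
            best = (*cand, key, unit_id)
            tied = False
        elif cand == best[:2] and unit_id != best[3]:
            tied = True
    if best is None:
        return None, "no gazetteer key found"
    if tied:
        return None, f"ambiguous match at {best[2]!r}"
    return best[3], None


def resolve_address(address: str, gaz: Gazetteer) -> ResolvedAddress:
    """Resolve one free-text address to its (province, city) pair.

    The city is matched first; the province is taken from the city's parent
    and checked against any province keyword present in the address. Any
    conflict — two distinct province keywords, or a province keyword
    disagreeing with the matched city's parent — yields unresolved rather
    than a guess.
    """
    address = normalize_text(address)
    if not address:
        return ResolvedAddress(None, None, "empty address")

    province_hits = {
        uid for key, uid in gaz.match_keys(PROVINCE) if key in address
    }
    if len(province_hits) > 1:
        names = sorted(gaz.units[u].name for u in province_hits)
        return ResolvedAddress(None, None, f"conflict: multiple provinces match {names}")
    province_hint = gaz.units[next(iter(province_hits))] if province_hits else None

    city_id, why = _best_match(address, gaz.match_keys(CITY))
    if city_id is None:
        if province_hint is not None:
            return ResolvedAddress(province_hint, None, f"city unresolved: {why}")
        return ResolvedAddress(None, None, why)
    city = gaz.units[city_id]
    parent = gaz.parent(city)
    if province_hint is not None and province_hint.unit_id != parent.unit_id:
        return ResolvedAddress(
            None, None,
            f"conflict: city {city.name!r} belongs to {parent.name!r} "
            f"but address names {province_hint.name!r}",
        )
    return ResolvedAddress(parent, city, None)


GeocoderPlugin = Callable[[str], tuple[float, float, str, str]]
"""Remote-geocoder contract: address -> (lng, lat, province name, city name)."""


def resolve_records(
    rs: RecordSet,
    gaz: Gazetteer,
    plugin: GeocoderPlugin | None = None,
    cache_path=None,
) -> list[GeoResolution]:
    """Resolve both parties of every record; log the resolution rate.

    A plugin geocoder, when given, is consulted only for addresses the
    gazetteer cannot resolve; its answers are mapped back to gazetteer units
    by name and cached to ``cache_path`` (CSV) for reproducibility.
    """
    cache: dict[str, tuple[str, str]] = {}
    if cache_path and Path(cache_path).exists():
        cached = pd.read_csv(cache_path, dtype=str)
        cache = {r.address: (r.province, r.city) for r in cached.itertuples(index=False)}

    name_index = {(u.level, u.name): u for u in gaz.units.values()}

    def _resolve(address: str) -> ResolvedAddress:
        res = resolve_address(address, gaz)
        if res.resolved or plugin is None:
            return res
        address_n = normalize_text(address)
        if address_n in cache:
            pname, cname = cache[address_n]
        else:
            try:
                _lng, _lat, pname, cname = plugin(address_n)
            except Exception as exc:  # plugin failures degrade to unresolved
                return ResolvedAddress(None, None, f"plugin error: {exc}")
            cache[address_n] = (pname, cname)
        province = name_index.get((PROVINCE, pname))
        city = name_index.get((CITY, cname))
        if city is None or province is None or city.parent_id != province.unit_id:
            return ResolvedAddress(None, None, "plugin result outside gazetteer")
        return ResolvedAddress(province, city, None, )

    resolutions = []
    for row in rs.frame.itertuples(index=False):
        manu = _resolve(row.manufacturer_address)
        dist = _resolve(row.distributor_address)
        method = "gazetteer" if plugin is None else "plugin"
        resolutions.append(GeoResolution(row.record_id, manu, dist, method))

    if cache_path and cache:
        pd.DataFrame(
            [(a, p, c) for a, (p, c) in sorted(cache.items())],
            columns=["address", "province", "city"],
        ).to_csv(cache_path, index=False)

    n_unres = sum(r.unresolved for r in resolutions)
    logger.info(
        "resolved %d/%d records at city level (%d unresolved, excluded downstream)",
        len(resolutions) - n_unres, len(resolutions), n_unres,
    )
    return resolutions


def resolutions_to_frame(resolutions: list[GeoResolution]) -> pd.DataFrame:
    """Tabular view of resolutions for CSV export."""
    rows = []
    for r in resolutions:
        rows.append(
            {
                "record_id": r.record_id,
                "manufacturer_province": r.manufacturer.province.name if r.manufacturer.province else "",
                "manufacturer_city": r.manufacturer.city.name if r.manufacturer.city else "",
                "distributor_province": r.distributor.province.name if r.distributor.province else "",
                "distributor_city": r.distributor.city.name if r.distributor.city else "",
                "unresolved": r.unresolved,
                "note": r.manufacturer.reason or r.distributor.reason or "",
            }
        )
    return pd.DataFrame(rows)
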