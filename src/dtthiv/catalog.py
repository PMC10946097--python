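"""Antiretroviral drug catalog.

Every classification rule that counts drugs or spans drug classes resolves
drug codes through a :class:`DrugCatalog`. Pharmacokinetic boosters
(ritonavir-as-booster, cobicistat) carry ``is_booster=True`` and are excluded
from all drug counts. The catalog ships as an editable YAML file so that
register-specific drug lists can be swapped in without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Iterator

import yaml

DRUG_CLASSES = frozenset({"NRTI", "NNRTI", "PI", "INSTI", "ENTRY", "CAPSID", "OTHER"})


class UnknownDrugError(KeyError):
    """A drug code was not found in the catalog."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"unknown drug code: {self.code!r}"


@dataclass(frozen=True)
class DrugCatalogEntry:
    drug_code: str
    name: str
    drug_class: str
    is_booster: bool = False

    def __post_init__(self):
        if self.drug_class not in DRUG_CLASSES:
            raise ValueError(
                f"{self.drug_code}: invalid drug class {self.drug_class!r}"
            )


class DrugCatalog:
    """Immutable mapping from drug code to :class:`DrugCatalogEntry`."""

    def __init__(self, entries: Iterable[DrugCatalogEntry]):
        self._entries: dict[str, DrugCatalogEntry] = {}
        for e in entries:
            if e.drug_code in self._entries:
                raise ValueError(f"duplicate drug code in catalog: {e.drug_code}")
            self._entries[e.drug_code] = e

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __getitem__(self, code: str) -> DrugCatalogEntry:
        try:
            return self._entries[code]
        except KeyError:
            raise UnknownDrugError(code) from None

    def __iter__(self) -> Iterator[DrugCatalogEntry]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def drug_class(self, code: str) -> str:
        return self[code].drug_class

    def is_booster(self, code: str) -> bool:
        return self[code].is_booster

    @classmethod
    def from_mapping(cls, payload: dict) -> "DrugCatalog":
        entries = [
            DrugCatalogEntry(
                drug_code=str(d["code"]),
                name=str(d.get("name", d["code"])),
                drug_class=str(d["class"]),
                is_booster=bool(d.get("booster", False)),
            )
            for d in payload["drugs"]
        ]
        return cls(entries)

    @classmethod
    def from_yaml(cls, path) -> "DrugCatalog":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "DrugCatalog":
        """The catalog bundled with the package (~30 antiretrovirals)."""
        ref = resources.files("dtthiv").joinpath("data/catalog.yaml")
        return cls.from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))


def default_catalog() -> DrugCatalog:
    return DrugCatalog.default()
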