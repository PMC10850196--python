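"""Mapping MedDRA preferred terms (PTs) to target diseases.

Label revisions name a clinically significant adverse reaction (CSAR) at the
disease level, while individual reports carry MedDRA preferred terms.  Several
PTs may describe the same target disease (e.g. "Blood potassium increased"
reports count toward the "Hyperkaliemia" tally), so tabulation first groups
PTs into diseases via an editable two-column CSV (``disease,pt``).  The
packaged default covers the 75 target diseases used as prediction outcomes.

Matching is exact-string after case-folding and whitespace/dash
normalisation — no fuzzy matching, mirroring how label wording is matched to
PT names in practice.
"""

from __future__ import annotations

import csv
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional


class GroupingError(ValueError):
    """Invalid grouping file (duplicate PT, empty entry, bad header)."""


_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Case-fold, collapse whitespace, and unify unicode dashes."""
    t = str(term).replace("–", "-").replace("—", "-").replace("’", "'")
    return _WS.sub(" ", t).strip().lower()


class GroupingMap:
    """Disease -> set-of-PT map with unique, case-insensitive PT membership."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self._by_disease: dict[str, list[str]] = {}
        self._pt_to_disease: dict[str, str] = {}
        for disease, pt in pairs:
            disease = str(disease).strip()
            pt = str(pt).strip()
            if not disease:
                raise GroupingError(f"empty disease name for PT {pt!r}")
            if not pt:
                raise GroupingError(f"empty PT under disease {disease!r}")
            key = normalize_term(pt)
            prior = self._pt_to_disease.get(key)
            if prior is not None and prior != disease:
                raise GroupingError(
                    f"PT {pt!r} assigned to two diseases: {prior!r} and {disease!r}"
                )
            if prior is None:
                self._pt_to_disease[key] = disease
                self._by_disease.setdefault(disease, []).append(pt)

    def diseases(self) -> list[str]:
        return list(self._by_disease)

    def pts_for(self, disease: str) -> list[str]:
        return list(self._by_disease[disease])

    def __contains__(self, disease: str) -> bool:
        return disease in self._by_disease

    def __len__(self) -> int:
        return len(self._by_disease)

    @property
    def total_pts(self) -> int:
        return len(self._pt_to_disease)

    def map_pt(self, pt: str) -> Optional[str]:
        """The unique disease containing `pt`, or None if unmapped."""
        return self._pt_to_disease.get(normalize_term(pt))


def packaged_grouping_path():
    return resources.files("pvlabel.data").joinpath("grouping.csv")


def load_grouping(path: "str | Path | None" = None) -> GroupingMap:
    """Load a ``disease,pt`` CSV; defaults to the packaged 75-disease table."""
    src = packaged_grouping_path() if path is None else Path(path)
    with src.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return GroupingMap([])
        if [h.strip().lower() for h in header[:2]] != ["disease", "pt"]:
            raise GroupingError(
                f"grouping file must start with header 'disease,pt', got {header!r}"
            )
        rows = [(r[0], r[1]) for r in reader if any(cell.strip() for cell in r)]
    return GroupingMap(rows)
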