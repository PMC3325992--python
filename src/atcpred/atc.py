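"""First-level ATC taxonomy, per-drug label sets and label tables.

The WHO Anatomical Therapeutic Chemical (ATC) system assigns each drug one
or more alphanumeric codes whose first letter places it in one of 14
anatomical/therapeutic main classes (level 1).  Everything downstream of
this module works with those 14 classes only: a drug's label is the *set*
of distinct level-1 classes of its ATC codes, so a drug with codes in k
different classes contributes k "virtual" samples to per-class counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "N_CLASSES",
    "AtcClass",
    "ATC_CLASSES",
    "atc_class_from_letter",
    "atc_class_from_index",
    "atc_level1_class",
    "DrugLabelSet",
    "LabelTable",
    "build_label_table",
]

#: Number of level-1 ATC main classes.
N_CLASSES = 14

_LEVEL1 = (
    ("A", "Alimentary tract and metabolism"),
    ("B", "Blood and blood forming organs"),
    ("C", "Cardiovascular system"),
    ("D", "Dermatologicals"),
    ("G", "Genito-urinary system and sex hormones"),
    ("H", "Systemic hormonal preparations, excluding sex hormones and insulins"),
    ("J", "Antiinfectives for systemic use"),
    ("L", "Antineoplastic and immunomodulating agents"),
    ("M", "Musculo-skeletal system"),
    ("N", "Nervous system"),
    ("P", "Antiparasitic products, insecticides and repellents"),
    ("R", "Respiratory system"),
    ("S", "Sensory organs"),
    ("V", "Various"),
)


@dataclass(frozen=True)
class AtcClass:
    """One of the 14 level-1 ATC main classes.

    ``index`` is the 1-based position in the conventional A..V letter
    ordering; this ordering is also the deterministic tie-break key used
    when ranking classes of equal likelihood.
    """

    index: int
    letter: str
    name: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.letter} ({self.name})"


#: The 14 classes in fixed letter order (index 1..14).
ATC_CLASSES: tuple[AtcClass, ...] = tuple(
    AtcClass(i + 1, letter, name) for i, (letter, name) in enumerate(_LEVEL1)
)

_BY_LETTER = {c.letter: c for c in ATC_CLASSES}
_BY_INDEX = {c.index: c for c in ATC_CLASSES}


def atc_class_from_letter(letter: str) -> AtcClass:
    """Return the class for a level-1 letter (case-insensitive)."""
    cls = _BY_LETTER.get(letter.strip().upper())
    if cls is None:
        raise ValueError(f"{letter!r} is not a level-1 ATC class letter")
    return cls


def atc_class_from_index(index: int) -> AtcClass:
    """Return the class for a 1-based index in 1..14."""
    try:
        return _BY_INDEX[index]
    except KeyError:
        raise ValueError(f"ATC class index must be in 1..{N_CLASSES}, got {index!r}") from None


def atc_level1_class(atc_code: str) -> AtcClass:
    """Map an ATC code (full, e.g. ``"A10BA02"``, or a bare letter) to its
    level-1 class.

    Only the first character is consulted; it must be one of the 14
    anatomical letters.
    """
    token = atc_code.strip()
    if not token:
        raise ValueError("empty ATC code")
    letter = token[0].upper()
    cls = _BY_LETTER.get(letter)
    if cls is None:
        raise ValueError(
            f"ATC code {atc_code!r}: first letter {letter!r} is not a level-1 ATC class"
        )
    return cls


@dataclass(frozen=True)
class DrugLabelSet:
    """A drug identifier together with its set of level-1 class indices.

    The size of ``classes`` is the drug's class multiplicity T: the number
    of virtual samples it contributes to the benchmark.
    """

    drug_id: str
    classes: frozenset[int]

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be a nonempty string")
        if not isinstance(self.classes, frozenset):
            object.__setattr__(self, "classes", frozenset(self.classes))
        if not self.classes:
            raise ValueError(f"drug {self.drug_id!r}: label set must be nonempty")
        bad = [j for j in self.classes if not (1 <= j <= N_CLASSES)]
        if bad:
            raise ValueError(
                f"drug {self.drug_id!r}: class indices {bad} outside 1..{N_CLASSES}"
            )

    @property
    def multiplicity(self) -> int:
        """Number of classes the drug belongs to (its T value)."""
        return len(self.classes)


class LabelTable:
    """Immutable mapping of drug id -> :class:`DrugLabelSet` with per-class
    size bookkeeping.

    ``class_sizes[j]`` counts the drugs whose label set contains class j;
    summed over j it equals the virtual-drug count (each drug counted once
    per class it holds).
    """

    def __init__(self, records: Mapping[str, DrugLabelSet] | Iterable[DrugLabelSet]):
        if isinstance(records, Mapping):
            recs = dict(records)
        else:
            recs = {r.drug_id: r for r in records}
        for drug_id, rec in recs.items():
            if drug_id != rec.drug_id:
                raise ValueError(f"key {drug_id!r} does not match record id {rec.drug_id!r}")
        self._records: dict[str, DrugLabelSet] = recs
        sizes = {j: 0 for j in range(1, N_CLASSES + 1)}
        for rec in recs.values():
            for j in rec.classes:
                sizes[j] += 1
        self._class_sizes = sizes

    # -- mapping protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._records

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __getitem__(self, drug_id: str) -> DrugLabelSet:
        return self._records[drug_id]

    def get(self, drug_id: str) -> DrugLabelSet | None:
        return self._records.get(drug_id)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LabelTable) and self._records == other._records

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LabelTable({len(self)} drugs, {self.virtual_count()} virtual)"

    # -- accessors --------------------------------------------------------
    @property
    def records(self) -> Mapping[str, DrugLabelSet]:
        return self._records

    @property
    def class_sizes(self) -> Mapping[int, int]:
        return dict(self._class_sizes)

    def drug_ids(self) -> list[str]:
        """All drug ids in sorted order (the deterministic iteration order
        used by the jackknife driver)."""
        return sorted(self._records)

    def virtual_count(self) -> int:
        """Total number of (drug, class) memberships."""
        return sum(rec.multiplicity for rec in self._records.values())

    def multiplicities(self) -> dict[int, int]:
        """Mapping T -> number of drugs with exactly T classes."""
        out: dict[int, int] = {}
        for rec in self._records.values():
            out[rec.multiplicity] = out.get(rec.multiplicity, 0) + 1
        return out

    def without(self, drug_id: str) -> "LabelTable":
        """A copy with one drug (all its class memberships) removed."""
        if drug_id not in self._records:
            raise KeyError(drug_id)
        recs = dict(self._records)
        del recs[drug_id]
        return LabelTable(recs)

    def subset(self, drug_ids: Iterable[str]) -> "LabelTable":
        return LabelTable({d: self._records[d] for d in drug_ids})


def build_label_table(
    pairs: Sequence[tuple[str, Sequence[str]]],
    *,
    strict: bool = True,
) -> LabelTable:
    """Build a :class:`LabelTable` from ``(drug_id, [atc_code, ...])`` pairs.

    Each drug's label set is the set of distinct level-1 classes of its
    codes.  Identifiers are normalised by whitespace trimming only; no
    cross-database identifier mapping is attempted.

    With ``strict=True`` (default) any unparseable code raises; with
    ``strict=False`` bad codes are skipped, but a drug whose codes *all*
    fail to parse is still rejected rather than silently dropped.
    Duplicate drug ids are rejected unless their label sets agree exactly.
    """
    records: dict[str, DrugLabelSet] = {}
    for drug_id, codes in pairs:
        drug_id = drug_id.strip()
        if not drug_id:
            raise ValueError("empty drug identifier")
        classes: set[int] = set()
        errors: list[str] = []
        for code in codes:
            try:
                classes.add(atc_level1_class(code).index)
            except ValueError as exc:
                if strict:
                    raise ValueError(f"drug {drug_id!r}: {exc}") from None
                errors.append(str(exc))
        if not classes:
            detail = f" ({'; '.join(errors)})" if errors else ""
            raise ValueError(f"drug {drug_id!r} has no valid ATC code{detail}")
        rec = DrugLabelSet(drug_id, frozenset(classes))
        prev = records.get(drug_id)
        if prev is not None and prev.classes != rec.classes:
            raise ValueError(
                f"duplicate drug {drug_id!r} with conflicting labels: "
                f"{sorted(prev.classes)} vs {sorted(rec.classes)}"
            )
        records[drug_id] = rec
    return LabelTable(records)
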