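"""Split-pool barcode scheme: rounds of ligated tags that jointly identify a bead.

A SPIDR experiment tags every antibody bead with a string of short
oligonucleotide tags, one per split-pool round.  Rounds come in three
ligation chemistries -- ``ODD``, ``EVEN`` and ``TERMINAL`` -- and the
terminal tag, ligated last, is sequenced first.  The scheme object is the
single source of truth for demultiplexing: which tag sequences exist in
which round, how many mismatches are tolerated, where the RPM adaptor and
UMI sit, and (optionally) which round encodes the experimental condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml

DEFAULT_RPM = "ATCAGCACTTA"
_ALPHABET = set("ACGT")


class SchemeError(ValueError):
    """Raised when a barcode scheme fails validation."""


class RoundCategory(str, Enum):
    ODD = "ODD"
    EVEN = "EVEN"
    TERMINAL = "TERMINAL"


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class RoundSpec:
    """One split-pool round: a named set of same-length tag sequences."""

    name: str
    category: RoundCategory
    tags: dict[str, str]
    spacer: str = ""  # fixed sequence read after this round's tag, if any

    @property
    def tag_length(self) -> int:
        return len(next(iter(self.tags.values())))

    def validate(self, mismatch_tolerance: int) -> None:
        if len(self.tags) < 2:
            raise SchemeError(f"round {self.name!r} needs at least 2 tags")
        lengths = {len(s) for s in self.tags.values()}
        if len(lengths) != 1:
            raise SchemeError(
                f"round {self.name!r}: tag sequences have unequal lengths {sorted(lengths)}"
            )
        seqs = list(self.tags.values())
        if len(set(seqs)) != len(seqs):
            raise SchemeError(f"round {self.name!r}: duplicate tag sequence")
        for s in seqs:
            if not set(s) <= _ALPHABET:
                raise SchemeError(f"round {self.name!r}: tag {s!r} not over ACGT")
        # unambiguous correction requires pairwise distance > 2 * tolerance
        for i, a in enumerate(seqs):
            for b in seqs[i + 1 :]:
                if hamming(a, b) <= 2 * mismatch_tolerance:
                    raise SchemeError(
                        f"round {self.name!r}: tags {a!r} and {b!r} are within "
                        f"2 x mismatch_tolerance ({mismatch_tolerance}); correction ambiguous"
                    )


@dataclass(frozen=True)
class BarcodeScheme:
    """The full split-pool scheme, rounds listed in ligation order."""

    rounds: tuple[RoundSpec, ...]
    rpm_sequence: str = DEFAULT_RPM
    umi_length: int = 8
    mismatch_tolerance: int = 1
    read_order: str = "reverse_ligation"  # terminal tag is sequenced first
    sample_round_index: Optional[int] = None
    sample_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rounds:
            raise SchemeError("scheme has no rounds")
        if not self.rpm_sequence:
            raise SchemeError("rpm_sequence is required and must be non-empty")
        if not set(self.rpm_sequence) <= _ALPHABET:
            raise SchemeError("rpm_sequence must be over ACGT")
        if self.read_order not in ("reverse_ligation", "ligation"):
            raise SchemeError("read_order must be 'reverse_ligation' or 'ligation'")
        names = [r.name for r in self.rounds]
        if len(set(names)) != len(names):
            raise SchemeError("round names must be unique")
        for r in self.rounds:
            r.validate(self.mismatch_tolerance)
        for i, r in enumerate(self.rounds):
            if r.category is RoundCategory.TERMINAL and i != len(self.rounds) - 1:
                raise SchemeError(
                    f"round {r.name!r} is TERMINAL but is not the last-ligated round"
                )
        if self.sample_round_index is not None and not (
            0 <= self.sample_round_index < len(self.rounds)
        ):
            raise SchemeError("sample_round_index out of range")

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    def read_rounds(self) -> tuple[RoundSpec, ...]:
        """Rounds in the order they appear on the sequenced read."""
        if self.read_order == "reverse_ligation":
            return tuple(reversed(self.rounds))
        return self.rounds

    def round_index(self, name: str) -> int:
        for i, r in enumerate(self.rounds):
            if r.name == name:
                return i
        raise KeyError(name)

    def sample_label_for(self, tag_name: str) -> str:
        """Condition label encoded by a sample-round tag (tag name if unmapped)."""
        return self.sample_labels.get(tag_name, tag_name)


def barcode_space(scheme: BarcodeScheme) -> int:
    """Number of distinct barcode strings the scheme can produce.

    The chance that two beads collide on the same barcode is 1 over this
    value; e.g. 8 rounds of 12 tags give 12**8 = 429,981,696 strings
    (about 1 in 430 million).
    """
    n = 1
    for r in scheme.rounds:
        n *= len(r.tags)
    return n


def _parse_config(data: dict) -> BarcodeScheme:
    if "rounds" not in data or not data["rounds"]:
        raise SchemeError("scheme config must define 'rounds'")
    if "rpm_sequence" in data and not data["rpm_sequence"]:
        raise SchemeError("rpm_sequence must be non-empty")
    rounds = []
    for entry in data["rounds"]:
        try:
            category = RoundCategory(str(entry.get("category", "ODD")).upper())
        except ValueError as exc:
            raise SchemeError(f"unknown round category {entry.get('category')!r}") from exc
        rounds.append(
            RoundSpec(
                name=str(entry["name"]),
                category=category,
                tags={str(k): str(v).upper() for k, v in entry["tags"].items()},
                spacer=str(entry.get("spacer", "")),
            )
        )
    return BarcodeScheme(
        rounds=tuple(rounds),
        rpm_sequence=str(data.get("rpm_sequence", DEFAULT_RPM)).upper(),
        umi_length=int(data.get("umi_length", 8)),
        mismatch_tolerance=int(data.get("mismatch_tolerance", 1)),
        read_order=str(data.get("read_order", "reverse_ligation")),
        sample_round_index=data.get("sample_round_index"),
        sample_labels={str(k): str(v) for k, v in (data.get("sample_labels") or {}).items()},
    )


def load_scheme(config_path: str | Path) -> BarcodeScheme:
    """Load and validate a scheme from a YAML or JSON config file."""
    path = Path(config_path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemeError(f"{path}: config must be a mapping")
    return _parse_config(data)


def dump_scheme(scheme: BarcodeScheme, path: str | Path) -> None:
    """Write a scheme back to YAML (round-trips through load_scheme)."""
    data = {
        "rpm_sequence": scheme.rpm_sequence,
        "umi_length": scheme.umi_length,
        "mismatch_tolerance": scheme.mismatch_tolerance,
        "read_order": scheme.read_order,
        "sample_round_index": scheme.sample_round_index,
        "sample_labels": dict(scheme.sample_labels),
        "rounds": [
            {
                "name": r.name,
                "category": r.category.value,
                "spacer": r.spacer,
                "tags": dict(r.tags),
            }
            for r in scheme.rounds
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
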