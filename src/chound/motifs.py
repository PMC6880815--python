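"""Terpene-synthase catalytic-motif scanning and classification.

Class I terpene synthases initiate cyclisation by substrate ionisation
and carry the Mg2+-binding aspartate-rich DDxxD/E motif; class II
enzymes initiate by protonation and carry DxDD (or its DxDTT variant in
HAD-like drimane synthases).  A known class I variant substitutes the
second Asp for Asn (DNxxD/E), abolishing ionisation-dependent activity.
The QW dipeptide is associated with class II enzymes but is too short to
be diagnostic; it is reported as supporting evidence only and never
drives classification.

Patterns are data, not code: each is an ordered list of allowed residue
sets, with ``x`` meaning any residue, and can be supplied from a config
mapping of pattern strings such as ``"D,N,x,x,DE"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "MotifPattern",
    "MotifMatch",
    "DEFAULT_PATTERNS",
    "pattern_from_string",
    "load_patterns",
    "scan",
    "classify_synthase",
    "motif_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifPattern:
    """Position-wise residue-set pattern; ``None`` entries match anything."""

    name: str
    positions: tuple[frozenset | None, ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 2:
            raise ValueError(f"pattern {self.name}: length must be >= 2")

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, seq: str, start: int) -> bool:
        if start + len(self) > len(seq):
            return False
        for offset, allowed in enumerate(self.positions):
            if allowed is not None and seq[start + offset] not in allowed:
                return False
        return True


@dataclass(frozen=True)
class MotifMatch:
    protein_id: str
    pattern: str
    start: int  # 0-based
    matched: str


def pattern_from_string(name: str, text: str) -> MotifPattern:
    """Build a pattern from a comma-separated spec, e.g. ``"D,D,x,x,DE"``.

    Each comma-separated token is either ``x`` (any residue) or a string
    of allowed residues for that position.
    """
    positions: list[frozenset | None] = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            raise ValueError(f"pattern {name}: empty position in {text!r}")
        if token.lower() == "x":
            positions.append(None)
        else:
            bad = set(token.upper()) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"pattern {name}: non-residue {sorted(bad)} in {text!r}")
            positions.append(frozenset(token.upper()))
    return MotifPattern(name=name, positions=tuple(positions))


_DEFAULT_PATTERN_STRINGS = {
    "classI_DDxxDE": "D,D,x,x,DE",
    "classI_AsnVariant": "D,N,x,x,DE",
    "classII_DxDD": "D,x,D,D",
    "classII_DxDTT": "D,x,D,T,T",
    "QW": "Q,W",
}

DEFAULT_PATTERNS: tuple[MotifPattern, ...] = tuple(
    pattern_from_string(name, text) for name, text in _DEFAULT_PATTERN_STRINGS.items()
)

_CLASS_I_PATTERNS = frozenset({"classI_DDxxDE", "classI_AsnVariant"})
_CLASS_II_PATTERNS = frozenset({"classII_DxDD", "classII_DxDTT"})


def load_patterns(path) -> tuple[MotifPattern, ...]:
    """Load patterns from a JSON file mapping name -> pattern string."""
    mapping = json.loads(Path(path).read_text())
    return tuple(pattern_from_string(name, text) for name, text in mapping.items())


def scan(
    protein: str,
    patterns: tuple[MotifPattern, ...] = DEFAULT_PATTERNS,
    protein_id: str = "",
    collapse_variants: bool = False,
) -> list[MotifMatch]:
    """All (possibly overlapping) motif occurrences, left to right.

    With ``collapse_variants`` a DxDD report whose interval overlaps a
    DxDTT match is suppressed (the variant subsumes it).
    """
    protein = protein.upper()
    matches: list[MotifMatch] = []
    for pattern in patterns:
        for start in range(len(protein) - len(pattern) + 1):
            if pattern.matches_at(protein, start):
                matches.append(
                    MotifMatch(
                        protein_id=protein_id,
                        pattern=pattern.name,
                        start=start,
                        matched=protein[start : start + len(pattern)],
                    )
                )
    if collapse_variants:
        variant_spans = [
            (m.start, m.start + len(m.matched))
            for m in matches
            if m.pattern == "classII_DxDTT"
        ]
        matches = [
            m
            for m in matches
            if not (
                m.pattern == "classII_DxDD"
                and any(m.start < v1 and m.start + 4 > v0 for v0, v1 in variant_spans)
            )
        ]
    matches.sort(key=lambda m: (m.start, m.pattern))
    return matches


@dataclass(frozen=True)
class SynthaseClassification:
    label: str  # class_I | class_II | bifunctional_motifs | none
    evidence: tuple[MotifMatch, ...]
    class_i_variant_only: bool = False  # class I evidence is the Asn variant alone


def classify_synthase(matches: list[MotifMatch]) -> SynthaseClassification:
    """Classify one protein's motif evidence.

    class_I iff any DDxxD/E (or Asn-variant) match; class_II iff any
    DxDD/DxDTT match; both present -> bifunctional_motifs.  QW alone is
    supporting evidence and never sufficient for a class call.
    """
    has_class_i = any(m.pattern in _CLASS_I_PATTERNS for m in matches)
    has_class_ii = any(m.pattern in _CLASS_II_PATTERNS for m in matches)
    variant_only = (
        has_class_i
        and all(
            m.pattern == "classI_AsnVariant"
            for m in matches
            if m.pattern in _CLASS_I_PATTERNS
        )
    )
    if has_class_i and has_class_ii:
        label = "bifunctional_motifs"
    elif has_class_i:
        label = "class_I"
    elif has_class_ii:
        label = "class_II"
    else:
        label = "none"
    evidence = tuple(
        m for m in matches if m.pattern in _CLASS_I_PATTERNS | _CLASS_II_PATTERNS
    ) + tuple(m for m in matches if m.pattern == "QW")
    return SynthaseClassification(
        label=label, evidence=evidence, class_i_variant_only=variant_only
    )


def motif_table(
    proteins: dict[str, str],
    patterns: tuple[MotifPattern, ...] = DEFAULT_PATTERNS,
    collapse_variants: bool = False,
) -> pd.DataFrame:
    """Per-protein motif report: match counts, positions, classification."""
    rows = []
    pattern_names = [p.name for p in patterns]
    for pid, seq in proteins.items():
        matches = scan(seq, patterns, protein_id=pid, collapse_variants=collapse_variants)
        by_pattern: dict[str, list[int]] = {name: [] for name in pattern_names}
        for m in matches:
            by_pattern[m.pattern].append(m.start)
        row: dict = {"protein_id": pid}
        for name in pattern_names:
            row[f"{name}_count"] = len(by_pattern[name])
            row[f"{name}_positions"] = ",".join(map(str, by_pattern[name]))
        row["classification"] = classify_synthase(matches).label
        rows.append(row)
    columns = ["protein_id"]
    for name in pattern_names:
        columns += [f"{name}_count", f"{name}_positions"]
    columns.append("classification")
    return pd.DataFrame(rows, columns=columns)
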