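"""Cross-tag interactome comparison.

The headline quantities of a dual-tag pull-down: how many proteins the two
tag interactomes share once the bait's own complex (the "core" set) is set
aside, what percentage of each list is tag-specific, per-category tallies,
and the fraction of each list previously reported.

All percentages are rounded half-up to one decimal by a single shared
routine, so printed numbers are reproducible to the digit.
"""

from __future__ import annotations

import csv
import decimal
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

from dualtap.enrich import Interactome


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero-ward (half-up), e.g. 9.375 -> 9.4 at 1 digit."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _accessions(x) -> set[str]:
    if isinstance(x, Interactome):
        return x.accessions
    return set(x)


class AnnotationMap:
    """accession -> set of category strings; unknown accessions map to the empty set."""

    def __init__(self, mapping: Mapping[str, Iterable[str] | str] | None = None) -> None:
        self._map: dict[str, set[str]] = {}
        if mapping:
            for acc, cats in mapping.items():
                self.add(acc, [cats] if isinstance(cats, str) else cats)

    def add(self, accession: str, categories: Iterable[str]) -> None:
        cats = {c for c in categories if c}
        if any(not c.strip() for c in cats):
            raise ValueError("category strings must be non-empty")
        self._map.setdefault(accession, set()).update(cats)

    def get(self, accession: str) -> set[str]:
        return self._map.get(accession, set())

    def members(self, category: str) -> set[str]:
        return {a for a, cats in self._map.items() if category in cats}

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationMap":
        """Two-column TSV (accession, category); repeated accessions accumulate."""
        out = cls()
        with Path(path).open(encoding="utf-8") as fh:
            for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 2 or not row[1].strip():
                    raise ValueError(f"annotation map line {i}: expected 'accession<TAB>category'")
                out.add(row[0].strip(), [row[1].strip()])
        return out


def read_accession_list(path: str | Path) -> set[str]:
    """One-column (first column used) accession list; '#' comments ignored."""
    out = set()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split("\t")[0])
    return out


@dataclass
class ComparisonReport:
    """Cross-tag overlap and specificity, core complex excluded.

    ``specificity_X = 100 * (1 - n_common_noncore / (n_X - n_core_X))``,
    rounded half-up to one decimal: the percentage of the tag's non-core
    interactome absent from the other tag's list.
    """

    tag_A: str
    tag_B: str
    n_A: int
    n_B: int
    n_core_A: int
    n_core_B: int
    n_common_noncore: int
    specificity_A: float | None
    specificity_B: float | None
    common_noncore: list[str] = field(default_factory=list)
    categories: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=False)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def to_text(self) -> str:
        def pct(v):
            return "n/a" if v is None else f"{v}%"

        lines = [
            f"Interactome comparison: {self.tag_A} vs {self.tag_B}",
            f"  {self.tag_A}: {self.n_A} proteins ({self.n_core_A} core)",
            f"  {self.tag_B}: {self.n_B} proteins ({self.n_core_B} core)",
            f"  common outside core : {self.n_common_noncore}",
            f"  {self.tag_A} specificity    : {pct(self.specificity_A)}",
            f"  {self.tag_B} specificity    : {pct(self.specificity_B)}",
        ]
        if self.categories:
            lines.append("  per-category (count, % of non-core list; union over both lists):")
            for cat, d in self.categories.items():
                lines.append(
                    f"    {cat}: {self.tag_A} {d['count_A']} ({pct(d['pct_A'])}), "
                    f"{self.tag_B} {d['count_B']} ({pct(d['pct_B'])}), union {d['union']}"
                )
        return "\n".join(lines)


def _merged(accessions: set[str], gene_of: Mapping[str, str] | None) -> set[str]:
    # optional isoform merging: collapse accessions sharing a gene symbol
    if gene_of is None:
        return set(accessions)
    return {gene_of.get(a, a) for a in accessions}


def interactome_overlap(
    A: Interactome | Iterable[str],
    B: Interactome | Iterable[str],
    core: Iterable[str],
    tag_A: str = "A",
    tag_B: str = "B",
    annotations: AnnotationMap | None = None,
    categories: Iterable[str] = (),
    merge_isoforms_by: Mapping[str, str] | None = None,
) -> ComparisonReport:
    """Compare two interactomes on accessions, excluding the core set.

    Accessions are compared verbatim unless ``merge_isoforms_by`` maps
    accessions to gene symbols, in which case isoforms of one gene collapse to
    a single entry before any counting (useful when the core complex is
    represented by multiple isoform accessions).
    """
    if isinstance(A, Interactome) and tag_A == "A":
        tag_A = A.tag.value
    if isinstance(B, Interactome) and tag_B == "B":
        tag_B = B.tag.value
    a = _merged(_accessions(A), merge_isoforms_by)
    b = _merged(_accessions(B), merge_isoforms_by)
    core_set = _merged(set(core), merge_isoforms_by)
    a_nc, b_nc = a - core_set, b - core_set
    common = a_nc & b_nc

    def spec(noncore: set[str]) -> float | None:
        if not noncore:
            return None
        return round_half_up(100.0 * (1.0 - len(common) / len(noncore)))

    cat_block = {}
    if annotations is not None:
        for cat in categories:
            ca, pa = category_fraction(a, annotations, cat, core_set)
            cb, pb = category_fraction(b, annotations, cat, core_set)
            cat_block[cat] = {
                "count_A": ca,
                "pct_A": pa,
                "count_B": cb,
                "pct_B": pb,
                "union": category_union(a, b, annotations, cat, core_set),
            }
    return ComparisonReport(
        tag_A=tag_A,
        tag_B=tag_B,
        n_A=len(a),
        n_B=len(b),
        n_core_A=len(a & core_set),
        n_core_B=len(b & core_set),
        n_common_noncore=len(common),
        specificity_A=spec(a_nc),
        specificity_B=spec(b_nc),
        common_noncore=sorted(common),
        categories=cat_block,
    )


def category_fraction(
    X: Interactome | Iterable[str],
    annotations: AnnotationMap,
    category: str,
    core: Iterable[str],
) -> tuple[int, float | None]:
    """(count, percentage) of non-core list members carrying ``category``.

    The denominator is the list size minus its core members; if that is zero
    the percentage is undefined and returned as None.
    """
    if not category:
        raise ValueError("category must be non-empty")
    x = _accessions(X)
    core_set = set(core)
    noncore = x - core_set
    count = len(noncore & annotations.members(category))
    if not noncore:
        return count, None
    return count, round_half_up(100.0 * count / len(noncore))


def category_union(
    A: Interactome | Iterable[str],
    B: Interactome | Iterable[str],
    annotations: AnnotationMap,
    category: str,
    core: Iterable[str],
) -> int:
    """Size of the union of the two lists' non-core members in ``category``."""
    core_set = set(core)
    members = annotations.members(category)
    return len(((_accessions(A) | _accessions(B)) - core_set) & members)


def known_fraction(
    X: Interactome | Iterable[str], reference: Iterable[str]
) -> tuple[int, float | None]:
    """(count, percentage) of the list's entries found in a reference set.

    Core members are included: the denominator is the whole list.  An empty
    list yields an undefined (None) percentage; an empty reference yields 0
    with a warning.
    """
    x = _accessions(X)
    ref = set(reference)
    if not ref:
        warnings.warn("known_fraction: empty reference set", stacklevel=2)
        return 0, (None if not x else 0.0)
    if not x:
        return 0, None
    count = len(x & ref)
    return count, round_half_up(100.0 * count / len(x))
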