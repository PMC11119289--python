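"""Tabulation arithmetic behind functional-category and CAZyme-class summaries.

Counts genes per GO/COG/KEGG-style category and per CAZyme class
(GH/GT/PL/CE/AA/CBM) and converts counts to the printed-style percentages
(half-up rounding to two decimals).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

CAZYME_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")
_CLASS_RE = re.compile(r"(CBM|GH|GT|PL|CE|AA)\d")


@dataclass(frozen=True)
class CategoryTable:
    scheme: str
    rows: tuple[tuple[str, int], ...]  # (category, count), count desc then label

    @property
    def total(self) -> int:
        return sum(c for _, c in self.rows)

    def count(self, category: str) -> int:
        for label, c in self.rows:
            if label == category:
                return c
        raise KeyError(f"category {category!r} not in {self.scheme} table")


@dataclass(frozen=True)
class CazymeClassProfile:
    counts: dict[str, int]           # one entry per class in CAZYME_CLASSES
    other: int = 0                   # unrecognized prefixes (excluded below)
    # proportions over recognized classes; None when all counts are zero
    proportions: dict[str, float] | None = None


def build_category_table(
    assignments: Iterable[tuple[str, str]],
    scheme: str,
) -> CategoryTable:
    """Aggregate (gene_id, category) pairs; duplicates count once per gene."""
    seen = set()
    counter: Counter[str] = Counter()
    for gene_id, category in assignments:
        if not category:
            raise ValueError(f"empty category for gene {gene_id!r}")
        if (gene_id, category) in seen:
            continue
        seen.add((gene_id, category))
        counter[category] += 1
    rows = tuple(sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])))
    return CategoryTable(scheme=scheme, rows=rows)


def _pct(numer: int, denom: int) -> float:
    """100*numer/denom rounded half-up to 2 decimals (printed precision)."""
    frac = Decimal(numer) * 100 / Decimal(denom)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def category_share(table: CategoryTable, category: str) -> float:
    """Percentage of the table's total held by one category."""
    total = table.total
    if total <= 0:
        raise ValueError("category_share undefined for an empty table")
    return _pct(table.count(category), total)


def subcategory_share(count: int, parent_total: int) -> float:
    """Percentage of a parent category held by one subcategory."""
    if parent_total <= 0:
        raise ValueError("parent_total must be > 0")
    if not (0 <= count <= parent_total):
        raise ValueError(f"count {count} outside [0, {parent_total}]")
    return _pct(count, parent_total)


def split_family_label(label: str) -> list[str]:
    """Split compound labels like 'GH16|CBM4' or 'GH5+CBM6' into parts."""
    return [p for p in re.split(r"[|+]", label) if p]


def cazyme_class_profile(roles: Sequence) -> CazymeClassProfile:
    """Per-class gene counts from CAZyme role assignments.

    A gene whose families span k classes contributes 1 to each of those k
    classes.  Families with an unrecognized prefix go to a logged 'other'
    bucket and are excluded from the proportions.
    """
    counts = {c: 0 for c in CAZYME_CLASSES}
    other = 0
    for r in roles:
        classes = set()
        unrecognized = set()
        for fam in getattr(r, "families", ()):
            for part in split_family_label(fam):
                m = _CLASS_RE.match(part)
                if m:
                    classes.add(m.group(1))
                else:
                    unrecognized.add(part)
        for c in classes:
            counts[c] += 1
        if unrecognized and not classes:
            other += 1
        if unrecognized:
            logger.warning(
                "gene %s: unrecognized family label(s) %s counted as 'other'",
                getattr(r, "gene_id", "?"), sorted(unrecognized),
            )
    total = sum(counts.values())
    proportions = {c: counts[c] / total for c in CAZYME_CLASSES} if total else None
    return CazymeClassProfile(counts=counts, other=other, proportions=proportions)


# ---------------------------------------------------------------------------
# I/O for the category-assignment dialect


def read_category_tsv(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read 'gene_id<TAB>scheme<TAB>category' rows grouped by scheme."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, list[tuple[str, str]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if lineno == 1 and fields[:3] == ["gene_id", "scheme", "category"]:
                continue
            if len(fields) < 3:
                raise ValueError(f"{path.name} line {lineno}: need 3 columns")
            gene_id, scheme, category = fields[0], fields[1], fields[2]
            out.setdefault(scheme, []).append((gene_id, category))
    return out


def write_category_table(table: CategoryTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("scheme\tcategory\tcount\tshare_pct\n")
        for label, count in table.rows:
            fh.write(f"{table.scheme}\t{label}\t{count}\t{category_share(table, label):.2f}\n")
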