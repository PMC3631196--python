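"""Summary tables: mappable-read annotation accounting, top-N abundance and
Venn summaries.  All printed percentages use half-up rounding to 2 decimals."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .preprocess import LibraryAccounting

#: category display order for the annotation table
CATEGORY_ORDER = [
    "conserved miRNA candidates",
    "known miRNA candidates",
    "specific miRNA candidates",
    "unknown small RNAs",
]


def pct_half_up(count: int, total: int, ndigits: int = 2) -> float:
    """count / total * 100 rounded half-up to ``ndigits`` decimals."""
    if total <= 0:
        raise ValueError("total must be > 0")
    q = Decimal(count) * 100 / Decimal(total)
    return float(q.quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def annotation_summary(accounting: LibraryAccounting) -> pd.DataFrame:
    """Annotation table with per-category counts and percentages of mappable
    reads, ending in the mappable-reads total row at 100%."""
    accounting.validate()
    rows = [
        {
            "category": cat,
            "count": accounting.categories.get(cat, 0),
            "percentage": pct_half_up(
                accounting.categories.get(cat, 0), accounting.mappable_reads
            ),
        }
        for cat in CATEGORY_ORDER
        if cat in accounting.categories
    ]
    for cat, n in accounting.categories.items():
        if cat not in CATEGORY_ORDER:
            rows.append({"category": cat, "count": n,
                         "percentage": pct_half_up(n, accounting.mappable_reads)})
    rows.append({
        "category": "mappable reads",
        "count": accounting.mappable_reads,
        "percentage": 100.0,
    })
    return pd.DataFrame(rows)


def top_n_table(count_rows, n1: int, n2: int, n: int = 20) -> pd.DataFrame:
    """Top-N miRNAs by total normalized reads (CPM), ties lexicographic."""
    from .diffexp import normalize_cpm

    rows = [
        {
            "name": r.name,
            "count_female": r.count_female,
            "count_male": r.count_male,
            "cpm_female": normalize_cpm(r.count_female, n1),
            "cpm_male": normalize_cpm(r.count_male, n2),
        }
        for r in count_rows
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["cpm_total"] = df.cpm_female + df.cpm_male
    df = df.sort_values(["cpm_total", "name"],
                        ascending=[False, True], kind="mergesort")
    return df.head(n).reset_index(drop=True)


def venn_summary(venn: dict[str, list]) -> pd.DataFrame:
    """Counts and percentages of the female/male/co-expressed partition."""
    total = sum(len(v) for v in venn.values())
    rows = [
        {"set": k, "n_mirnas": len(v),
         "percentage": pct_half_up(len(v), total) if total else 0.0}
        for k, v in venn.items()
    ]
    return pd.DataFrame(rows)
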