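"""Two-library count statistics: CPM normalization, the Audic-Claverie,
Fisher exact and Pearson chi-squared tests, Bonferroni correction and
expression-status classification.

The Audic-Claverie test compares one tag's counts between two libraries of
known depths through the posterior-predictive distribution
``P(y | x) = (N2/N1)^y (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))``, which is the
negative-binomial law NB(r = x+1, p = N1/(N1+N2)); tails are therefore
evaluated with stable log-space negative-binomial sums.  The two-sided
p-value is defined symmetrically in the two libraries:
``p = min over both orientations of 2*min(P(Y<=y), P(Y>=y))``, capped at 1,
so that exchanging the libraries leaves every p-value unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

ALPHA = 1e-4


@dataclass
class TestConfig:
    alpha: float = ALPHA
    correction: str = "bonferroni"   # 'bonferroni' | 'none'
    rule: str = "all"                # all three tests must pass | 'any'

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.rule not in ("all", "any"):
            raise ValueError("rule must be 'all' or 'any'")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError("correction must be 'bonferroni' or 'none'")


@dataclass
class DERecord:
    name: str
    x: int                   # female count
    y: int                   # male count
    n1: int                  # female mappable total
    n2: int                  # male mappable total
    cpm_female: float
    cpm_male: float
    p_ac: float | None = None
    p_fisher: float | None = None
    p_chisq: float | None = None
    p_ac_corrected: float | None = None
    p_fisher_corrected: float | None = None
    p_chisq_corrected: float | None = None
    significant: bool = False
    direction: str = "NS"    # up | down | NS (male relative to female)
    venn: str = "co_expressed"


def normalize_cpm(count: int, total_mappable: int) -> float:
    """Normalized expression = (count / total mappable) * 1e6."""
    if total_mappable <= 0:
        raise ValueError("total_mappable must be > 0")
    if not 0 <= count <= total_mappable:
        raise ValueError("count must lie in [0, total_mappable]")
    return count / total_mappable * 1_000_000


def _ac_tails(x: int, y: int, n1: int, n2: int) -> tuple[float, float]:
    """(P(Y<=y | x), P(Y>=y | x)) under the NB(x+1, n1/(n1+n2)) predictive."""
    q = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, q)
    upper = stats.nbinom.sf(y - 1, x + 1, q)
    return float(lower), float(upper)


def ac_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided, library-symmetric Audic-Claverie p-value."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    lo1, up1 = _ac_tails(x, y, n1, n2)
    lo2, up2 = _ac_tails(y, x, n2, n1)
    p = 2.0 * min(lo1, up1, lo2, up2)
    # the true tail is mathematically > 0; guard against float underflow so
    # the p-value stays in (0, 1]
    return min(1.0, max(p, np.finfo(float).tiny))


def ac_pvalues(x: np.ndarray, y: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Vectorized :func:`ac_pvalue` for simulation studies."""
    x = np.asarray(x)
    y = np.asarray(y)
    q1, q2 = n1 / (n1 + n2), n2 / (n1 + n2)
    lo1 = stats.nbinom.cdf(y, x + 1, q1)
    up1 = stats.nbinom.sf(y - 1, x + 1, q1)
    lo2 = stats.nbinom.cdf(x, y + 1, q2)
    up2 = stats.nbinom.sf(x - 1, y + 1, q2)
    p = 2.0 * np.minimum.reduce([lo1, up1, lo2, up2])
    return np.minimum(1.0, np.maximum(p, np.finfo(float).tiny))


def fisher_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Fisher exact test on the table [[x, N1-x], [y, N2-y]]."""
    return float(
        stats.fisher_exact([[x, n1 - x], [y, n2 - y]], alternative="two-sided")[1]
    )


def chisq_pvalue(x: int, y: int, n1: int, n2: int) -> float | None:
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2 table;
    None (test abstains) when any expected cell is < 1."""
    obs = np.array([[x, n1 - x], [y, n2 - y]], dtype=float)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (expected < 1).any():
        return None
    statistic = ((obs - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(statistic, df=1))


def bonferroni(p: float, m: int) -> float:
    """min(1, p * m)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def venn_classify(rows) -> dict[str, list]:
    """Partition count rows into female_specific / male_specific /
    co_expressed; rows with both counts zero are excluded with a warning."""
    import warnings

    out: dict[str, list] = {
        "female_specific": [], "male_specific": [], "co_expressed": []
    }
    for row in rows:
        if row.count_female > 0 and row.count_male == 0:
            out["female_specific"].append(row)
        elif row.count_male > 0 and row.count_female == 0:
            out["male_specific"].append(row)
        elif row.count_female > 0 and row.count_male > 0:
            out["co_expressed"].append(row)
        else:
            warnings.warn(f"row {row.name} has zero counts in both libraries")
    return out


def call_de(rows, n1: int, n2: int,
            config: TestConfig | None = None) -> list[DERecord]:
    """Run the three tests on co-expressed rows with Bonferroni correction.

    ``rows`` need ``name`` / ``count_female`` / ``count_male`` attributes.
    A miRNA is significant iff all (or any, per config) non-abstaining
    corrected p-values fall below alpha; m = number of co-expressed miRNAs.
    Library-specific rows are carried through untested.  Output is sorted by
    corrected AC p ascending (untested rows last).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    config = config or TestConfig()
    venn = venn_classify(rows)
    co = venn["co_expressed"]
    m = max(1, len(co)) if config.correction == "bonferroni" else 1

    records: list[DERecord] = []
    for kind, group in venn.items():
        for row in group:
            x, y = row.count_female, row.count_male
            rec = DERecord(
                name=row.name, x=x, y=y, n1=n1, n2=n2,
                cpm_female=normalize_cpm(x, n1),
                cpm_male=normalize_cpm(y, n2),
                venn=kind,
            )
            if kind == "co_expressed":
                rec.p_ac = ac_pvalue(x, y, n1, n2)
                rec.p_fisher = fisher_pvalue(x, y, n1, n2)
                rec.p_chisq = chisq_pvalue(x, y, n1, n2)
                rec.p_ac_corrected = bonferroni(rec.p_ac, m)
                rec.p_fisher_corrected = bonferroni(rec.p_fisher, m)
                rec.p_chisq_corrected = (
                    None if rec.p_chisq is None else bonferroni(rec.p_chisq, m)
                )
                ps = [rec.p_ac_corrected, rec.p_fisher_corrected,
                      rec.p_chisq_corrected]
                ps = [p for p in ps if p is not None]
                passing = [p < config.alpha for p in ps]
                rec.significant = all(passing) if config.rule == "all" else any(passing)
                if rec.significant:
                    rec.direction = "up" if rec.cpm_male > rec.cpm_female else "down"
            records.append(rec)
    records.sort(
        key=lambda r: (r.p_ac_corrected if r.p_ac_corrected is not None else 2.0,
                       r.name)
    )
    return records
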