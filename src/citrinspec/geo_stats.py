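"""Geographic frequency-difference tests on region-stratified counts.

For every variant (or genotype) identity a carriers-vs-rest x 3-region
contingency table is formed and tested with an omnibus test: Pearson's
chi-square when every expected cell count is at least 5, otherwise a
full-enumeration Freeman-Halton exact test.  The exact two-sided p-value
follows the probability method: it sums the multivariate-hypergeometric
point probabilities of all margin-fixed tables no more probable than the
observed one (with a small relative tolerance for floating-point ties).
A significant omnibus (p < 0.05) triggers the three pairwise 2x2
comparisons, judged at the Bonferroni-adjusted threshold 0.05/3 = 0.017.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .spectrum import GenotypeSpectrum, RegionalSpectrum
from .variant_model import UNKNOWN_TOKEN

__all__ = [
    "ContingencyTable",
    "TestResult",
    "PairwiseReport",
    "freeman_halton_exact",
    "pearson_chi2",
    "omnibus_test",
    "pairwise_tests",
    "scan_spectrum",
    "scan_genotypes",
    "significant_set",
    "ALPHA_OMNIBUS",
    "ALPHA_PAIRWISE",
    "EXPECTED_MIN_RULE",
]

ALPHA_OMNIBUS = 0.05
#: Bonferroni threshold for the three pairwise region comparisons (0.05/3).
ALPHA_PAIRWISE = 0.017
#: Minimum expected cell count for the chi-square approximation.
EXPECTED_MIN_RULE = 5.0
#: Relative tolerance treating near-equal point probabilities as ties.
TIE_RTOL = 1e-7

_PAIRS = (("north", "border"), ("north", "south"), ("border", "south"))


class ContingencyTable:
    """Validated non-negative integer table with derived margins."""

    def __init__(self, cells, row_labels=None, col_labels=None):
        arr = np.asarray(cells, dtype=np.int64)
        if arr.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        if (arr < 0).any():
            raise ValueError("contingency table cells must be non-negative")
        self.cells = arr
        self.row_labels = tuple(row_labels) if row_labels else None
        self.col_labels = tuple(col_labels) if col_labels else None

    @property
    def row_margins(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.cells.sum())

    def expected(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty table has no expected counts")
        return np.outer(self.row_margins, self.col_margins) / self.total


@dataclass(frozen=True)
class TestResult:
    p: float
    method: str
    statistic: float | None = None
    expected_min: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0 + 1e-12:
            raise ValueError(f"p-value out of range: {self.p}")


@dataclass
class PairwiseReport:
    omnibus: TestResult
    pairwise: dict[tuple[str, str], TestResult] = field(default_factory=dict)
    alpha_omnibus: float = ALPHA_OMNIBUS
    alpha_pairwise: float = ALPHA_PAIRWISE

    @property
    def significant(self) -> bool:
        return self.omnibus.p < self.alpha_omnibus


def _as_table(table) -> ContingencyTable:
    return table if isinstance(table, ContingencyTable) else ContingencyTable(table)


def _log_table_prob(cells: np.ndarray, logfact_margins: float, n: int) -> float:
    # multivariate hypergeometric: prod(ri!)prod(cj!)/(n! prod(nij!))
    return logfact_margins - gammaln(n + 1) - gammaln(cells + 1).sum()


def freeman_halton_exact(table) -> TestResult:
    """Exact conditional test on an RxC table by full enumeration.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed table
    (probability method, two-sided).  Zero margins are dropped first; a
    table left with fewer than two informative rows or columns has p = 1.
    """
    t = _as_table(table)
    cells = t.cells
    cells = cells[cells.sum(axis=1) > 0][:, cells.sum(axis=0) > 0]
    if cells.size == 0 or min(cells.shape) < 2:
        return TestResult(p=1.0, method="freeman-halton-exact")
    rows = cells.sum(axis=1)
    cols = cells.sum(axis=0)
    n = int(cells.sum())
    logfact_margins = gammaln(rows + 1).sum() + gammaln(cols + 1).sum()

    log_p_obs = _log_table_prob(cells, logfact_margins, n)
    cutoff = log_p_obs + np.log1p(TIE_RTOL)

    total = 0.0
    nrow = len(rows)

    def recurse(row_idx: int, remaining_cols: np.ndarray, log_acc: float) -> None:
        nonlocal total
        if row_idx == nrow - 1:
            log_p = log_acc - gammaln(remaining_cols + 1).sum()
            if log_p <= cutoff:
                total += float(np.exp(log_p))
            return
        r = int(rows[row_idx])

        def fill(col_idx: int, left: int, row_cells: list[int]) -> None:
            if col_idx == len(remaining_cols) - 1:
                if left <= remaining_cols[col_idx]:
                    recurse(
                        row_idx + 1,
                        remaining_cols - np.array(row_cells + [left]),
                        log_acc - gammaln(np.array(row_cells + [left]) + 1).sum(),
                    )
                return
            for v in range(min(left, int(remaining_cols[col_idx])) + 1):
                fill(col_idx + 1, left - v, row_cells + [v])

        fill(0, r, [])

    base = logfact_margins - gammaln(n + 1)
    recurse(0, cols.copy(), base)
    return TestResult(p=min(total, 1.0), method="freeman-halton-exact")


def pearson_chi2(table, yates: bool = False) -> TestResult:
    """Pearson chi-square test (optional Yates continuity on 2x2 tables)."""
    t = _as_table(table)
    if (t.row_margins == 0).any() or (t.col_margins == 0).any():
        raise ValueError("chi-square test undefined with a zero margin")
    correction = bool(yates) and t.cells.shape == (2, 2)
    res = stats.chi2_contingency(t.cells, correction=correction)
    method = "pearson-chi2-yates" if correction else "pearson-chi2"
    return TestResult(
        p=float(res.pvalue),
        method=method,
        statistic=float(res.statistic),
        expected_min=float(res.expected_freq.min()),
    )


def _carrier_table(counts, totals) -> ContingencyTable:
    counts = np.asarray(counts, dtype=np.int64)
    totals = np.asarray(totals, dtype=np.int64)
    if (counts > totals).any():
        raise ValueError("carrier count exceeds region total")
    return ContingencyTable(np.column_stack([counts, totals - counts]))


def omnibus_test(counts, totals) -> TestResult:
    """Carriers-vs-rest omnibus test across regions with rule-based selection.

    Pearson's chi-square when all expected counts are >= 5, otherwise the
    Freeman-Halton exact test.  Degenerate tables (no carriers, or all
    carriers) give p = 1.
    """
    t = _carrier_table(counts, totals)
    if (t.col_margins == 0).any() or (t.row_margins == 0).any():
        return TestResult(p=1.0, method="freeman-halton-exact")
    if (t.expected() >= EXPECTED_MIN_RULE).all():
        return pearson_chi2(t, yates=False)
    return freeman_halton_exact(t)


def pairwise_tests(
    counts: dict[str, int], totals: dict[str, int]
) -> dict[tuple[str, str], TestResult]:
    """The three Bonferroni-family 2x2 comparisons between regions."""
    out = {}
    for a, b in _PAIRS:
        if a in totals and b in totals:
            out[(a, b)] = omnibus_test(
                [counts.get(a, 0), counts.get(b, 0)], [totals[a], totals[b]]
            )
    return out


def _scan(
    identities: list[str],
    count_of,
    totals: dict[str, int],
    alpha: float,
    alpha_pairwise: float,
) -> dict[str, PairwiseReport]:
    for region, n in totals.items():
        if n == 0:
            raise ValueError(f"region {region!r} has no observations")
    regions = list(totals)
    reports: dict[str, PairwiseReport] = {}
    for ident in identities:
        counts = {r: count_of(ident, r) for r in regions}
        omni = omnibus_test([counts[r] for r in regions], [totals[r] for r in regions])
        report = PairwiseReport(
            omnibus=omni, alpha_omnibus=alpha, alpha_pairwise=alpha_pairwise
        )
        if report.significant:
            report.pairwise = pairwise_tests(counts, totals)
        reports[ident] = report
    return reports


def scan_spectrum(
    spec: RegionalSpectrum,
    alpha: float = ALPHA_OMNIBUS,
    alpha_pairwise: float = ALPHA_PAIRWISE,
    include_unknown: bool = True,
) -> dict[str, PairwiseReport]:
    """Omnibus + conditional pairwise tests for every spectrum row."""
    idents = spec.identities
    if include_unknown and any(spec.unknown_counts.values()):
        idents = idents + [UNKNOWN_TOKEN]
    return _scan(idents, spec.count, dict(spec.n_alleles), alpha, alpha_pairwise)


def scan_genotypes(
    gspec: GenotypeSpectrum,
    alpha: float = ALPHA_OMNIBUS,
    alpha_pairwise: float = ALPHA_PAIRWISE,
) -> dict[str, PairwiseReport]:
    """Omnibus + conditional pairwise tests for every genotype row."""
    return _scan(
        gspec.genotypes, gspec.count, dict(gspec.n_families), alpha, alpha_pairwise
    )


def significant_set(reports: dict[str, PairwiseReport]) -> set[str]:
    return {ident for ident, rep in reports.items() if rep.significant}
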