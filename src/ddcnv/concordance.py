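"""Method-comparison statistics between the ddPCR assays and aCGH.

Covers Pearson correlation, ordinary least-squares regression of ddPCR
CN on aCGH CN, Cohen's kappa (unweighted and linear/quadratic weighted)
with the conventional agreement bands, and the 2x2 benign/pathogenic
cross-tabulation.

Cohen's kappa for a square contingency table with cell proportions
p_ij, row marginals p_i. and column marginals p_.j is

    kappa = (p_o - p_e) / (1 - p_e)

with observed agreement p_o = sum_ij w_ij p_ij and chance agreement
p_e = sum_ij w_ij p_i. p_.j under agreement weights w_ij (identity for
unweighted; 1 - |i-j|/(k-1) linear; 1 - ((i-j)/(k-1))^2 quadratic).
For a 2x2 table the linear and quadratic weights coincide with the
unweighted statistic.  The p-value tests kappa = 0 with the
large-sample standard error of Fleiss, Cohen & Everitt (1969); for 2x2
tables an exact permutation p (hypergeometric over tables with fixed
marginals) is also available.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

import statsmodels.api as sm

#: Agreement bands on kappa; lower edges inclusive.
AGREEMENT_BANDS = (
    (0.81, "almost perfect"),
    (0.61, "substantial"),
    (0.41, "moderate"),
    (0.21, "fair"),
    (-1.0, "slight"),
)


@dataclass(frozen=True)
class CrossTab2x2:
    """Benign/pathogenic cross-tab: rows ddPCR, columns aCGH.

    ``a``: both benign, ``b``: ddPCR benign / aCGH pathogenic,
    ``c``: ddPCR pathogenic / aCGH benign, ``d``: both pathogenic.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def marginals(self) -> dict[str, int]:
        return {
            "ddpcr_benign": self.a + self.b,
            "ddpcr_pathogenic": self.c + self.d,
            "acgh_benign": self.a + self.c,
            "acgh_pathogenic": self.b + self.d,
        }


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its weighting, p-value and agreement band."""

    kappa: float
    weighting: str
    p_value: float
    band: str
    se0: float
    n: int


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of ddPCR CN (response) on aCGH CN (predictor)."""

    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p_value: float
    n: int


def pearson_r(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with the t-transform p-value.

    Raises
    ------
    ValueError
        On unequal lengths, fewer than 3 pairs, or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p_value=float(res.pvalue), n=x.size)


def ols_fit(
    x: Sequence[float], y: Sequence[float], *, intercept: bool = True
) -> RegressionFit:
    """Least-squares regression of y (ddPCR CN) on x (aCGH CN).

    Reports the slope ("estimate"), multiple and adjusted R-squared,
    and the overall F-test p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x) == 0:
        raise ValueError("degenerate design: predictor has zero variance")
    design = sm.add_constant(x) if intercept else x[:, None]
    model = sm.OLS(y, design).fit()
    slope = float(model.params[-1])
    icept = float(model.params[0]) if intercept else 0.0
    return RegressionFit(
        slope=slope,
        intercept=icept,
        r_squared=float(model.rsquared),
        adj_r_squared=float(model.rsquared_adj),
        p_value=float(model.f_pvalue),
        n=x.size,
    )


def _agreement_weights(k: int, weighting: str) -> np.ndarray:
    i, j = np.indices((k, k))
    if weighting == "none":
        return (i == j).astype(float)
    if k == 1:
        return np.ones((1, 1))
    if weighting == "linear":
        return 1.0 - np.abs(i - j) / (k - 1)
    if weighting == "quadratic":
        return 1.0 - ((i - j) / (k - 1)) ** 2
    raise ValueError(f"unknown weighting: {weighting!r}")


def agreement_band(kappa: float) -> str:
    """Verbal agreement label for a kappa value (lower edges inclusive)."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must be in [-1, 1], got {kappa}")
    for lower, label in AGREEMENT_BANDS:
        if kappa >= lower:
            return label
    return "slight"


def cohen_kappa(
    table: Sequence[Sequence[float]] | np.ndarray | CrossTab2x2,
    weighting: str = "none",
    *,
    p_method: str = "normal",
) -> KappaResult:
    """Cohen's kappa for a square contingency table.

    Parameters
    ----------
    table
        Square count table (rows: method 1, columns: method 2) or a
        :class:`CrossTab2x2`.
    weighting
        "none", "linear" or "quadratic" agreement weights.
    p_method
        "normal" for the large-sample z-test of kappa = 0, or "exact"
        for the permutation p over tables with fixed marginals
        (2x2 tables only).

    Raises
    ------
    ValueError
        On a non-square or empty table, or degenerate marginals where
        chance agreement is 1 and kappa is undefined.
    """
    if isinstance(table, CrossTab2x2):
        t = table.as_table()
    else:
        t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError(f"table must be square, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table counts must be >= 0")
    n = t.sum()
    if n <= 0:
        raise ValueError("table is empty (n = 0)")

    k = t.shape[0]
    p = t / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    w = _agreement_weights(k, weighting)

    p_o = float((w * p).sum())
    p_e = float((w * np.outer(row, col)).sum())
    if p_e >= 1.0:
        raise ValueError("degenerate marginals: chance agreement is 1, kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss-Cohen-Everitt large-sample variance under H0: kappa = 0.
    wbar_row = w @ col        # wbar_i. = sum_j col_j w_ij
    wbar_col = row @ w        # wbar_.j = sum_i row_i w_ij
    expect = np.add.outer(wbar_row, wbar_col)
    var0 = (
        float((np.outer(row, col) * (w - expect) ** 2).sum()) - p_e**2
    ) / (n * (1.0 - p_e) ** 2)
    se0 = float(np.sqrt(max(var0, 0.0)))

    if p_method == "exact":
        p_value = _exact_p_2x2(t, kappa)
    elif p_method == "normal":
        if se0 > 0:
            z = kappa / se0
            p_value = float(2.0 * stats.norm.sf(abs(z)))
        else:
            p_value = float("nan")
    else:
        raise ValueError(f"unknown p_method: {p_method!r}")

    return KappaResult(
        kappa=float(kappa),
        weighting=weighting,
        p_value=p_value,
        band=agreement_band(float(np.clip(kappa, -1.0, 1.0))),
        se0=se0,
        n=int(round(n)),
    )


def _kappa_value(t: np.ndarray) -> float:
    n = t.sum()
    p = t / n
    row, col = p.sum(axis=1), p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    return (p_o - p_e) / (1.0 - p_e)


def _exact_p_2x2(t: np.ndarray, kappa_obs: float) -> float:
    """Two-sided permutation p for a 2x2 table with fixed marginals.

    Under random assignment with the observed marginals, the top-left
    cell is hypergeometric; the p-value sums the probabilities of all
    tables with |kappa| >= |kappa_obs|.
    """
    if t.shape != (2, 2):
        raise ValueError("exact p-value is implemented for 2x2 tables only")
    n = int(round(t.sum()))
    r1 = int(round(t[0].sum()))
    c1 = int(round(t[:, 0].sum()))
    rv = stats.hypergeom(n, c1, r1)
    p_value = 0.0
    for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        tab = np.array(
            [[a, r1 - a], [c1 - a, n - r1 - c1 + a]], dtype=float
        )
        try:
            kap = _kappa_value(tab)
        except ZeroDivisionError:
            continue
        if abs(kap) >= abs(kappa_obs) - 1e-12:
            p_value += float(rv.pmf(a))
    return min(p_value, 1.0)


def build_pathogenicity_crosstab(
    calls: Iterable[tuple[str | None, str | None]],
) -> tuple[CrossTab2x2, int]:
    """Cross-tabulate per-sample (ddPCR label, aCGH label) pairs.

    Samples with a missing label on either side are skipped; the count
    of skips is returned alongside the table.

    Raises
    ------
    ValueError
        If no sample carries both labels.
    """
    cells = {"a": 0, "b": 0, "c": 0, "d": 0}
    skipped = 0
    for ddpcr, acgh in calls:
        if ddpcr is None or acgh is None:
            skipped += 1
            continue
        key = {
            ("benign", "benign"): "a",
            ("benign", "pathogenic"): "b",
            ("pathogenic", "benign"): "c",
            ("pathogenic", "pathogenic"): "d",
        }.get((ddpcr, acgh))
        if key is None:
            raise ValueError(f"labels must be benign/pathogenic, got {(ddpcr, acgh)}")
        cells[key] += 1
    tab = CrossTab2x2(**cells)
    if tab.n == 0:
        raise ValueError("no samples with both labels (n = 0)")
    return tab, skipped


def kappa_from_codes(
    rater_a: Sequence[int], rater_b: Sequence[int], weighting: str = "none"
) -> KappaResult:
    """Kappa from two parallel label sequences (categories pooled from both)."""
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    cats = np.union1d(a, b)
    idx = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    table = np.zeros((k, k))
    for ai, bi in zip(a, b):
        table[idx[ai], idx[bi]] += 1
    return cohen_kappa(table, weighting)
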