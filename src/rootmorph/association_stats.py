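"""Genotype-dental-trait association statistics.

The cohort analysis relates the EDAR 370V/A genotype (rs3827760; coded as
the number of derived A alleles, VV = 0, VA = 1, AA = 2) to dichotomized
tooth-root phenotypes:

* per-tooth root codes from both sides are merged into two classes
  (:func:`dichotomize_root`), e.g. single-rooted vs multi-rooted upper
  first premolars or C-shaped vs two-rooted lower second molar roots;
* genotype x class contingency tables feed an exact Freeman-Halton r x c
  test (:func:`fisher_exact_rxc`);
* logistic regression with age, sex and region covariates estimates
  per-allele log odds ratios with Wald tests (:func:`logistic_fit`);
* ordinal trait pairs are correlated by Spearman's rho with mid-ranks for
  ties (:func:`spearman`, :func:`spearman_from_table`).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENOTYPES", "ROOT_TEETH", "ROOT_CLASSES", "CROWN_TRAITS",
    "FisherResult", "LogisticFit", "SpearmanResult",
    "dichotomize_root", "genotype_trait_table", "fisher_exact_rxc",
    "logistic_fit", "spearman", "spearman_from_table", "expand_counts",
    "cohort_analysis",
]

GENOTYPES = ("VV", "VA", "AA")

ROOT_CODES = frozenset("1234mC")

#: Unordered side-pair -> dichotomized class, per tooth.  The pair lists are
#: the observed groupings of the study: discordant pairs are already
#: assigned to the class of the rarer side phenotype (e.g. a 1|2 upper first
#: premolar counts as multi-rooted).  Pairs outside the lists are treated as
#: missing and excluded, as are individuals with an absent side.
ROOT_CLASSES: dict[str, dict[str, tuple[frozenset, ...]]] = {
    "UP1": {"1": (frozenset("1"),),
            "2<=": (frozenset("12"), frozenset("2"), frozenset("23"))},
    "UP2": {"1": (frozenset("1"), frozenset("1m")),
            "2<=": (frozenset("12"), frozenset("2"), frozenset("13"))},
    "UM2": {"<=2": (frozenset("1"), frozenset("12"), frozenset("2"),
                    frozenset("13"), frozenset("23")),
            "3<=": (frozenset("3"), frozenset("4"))},
    "LM1": {"2": (frozenset("2"),),
            "3": (frozenset("23"), frozenset("3"))},
    "LM2": {"C": (frozenset("2C"), frozenset("C")),
            "2": (frozenset("2"),)},
}

ROOT_TEETH = tuple(ROOT_CLASSES)

#: Class order used in tables and ordinal analyses (first = first column).
CLASS_ORDER = {"UP1": ("1", "2<="), "UP2": ("1", "2<="),
               "UM2": ("<=2", "3<="), "LM1": ("2", "3"), "LM2": ("C", "2")}

CROWN_TRAITS = ("UI1_shovel", "UM1_carabelli", "UM2_cusp", "LM2_cusp")


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    n_tables_enumerated: int


@dataclass(frozen=True)
class LogisticFit:
    terms: tuple[str, ...]
    coef: np.ndarray           # log odds ratios (incl. intercept)
    se: np.ndarray
    wald_chi2: np.ndarray
    p: np.ndarray
    converged: bool
    separation_flag: bool      # any |coef| > 15: quasi-complete separation

    def term(self, name: str) -> dict:
        i = self.terms.index(name)
        return {"coef": float(self.coef[i]), "se": float(self.se[i]),
                "chi2": float(self.wald_chi2[i]), "p": float(self.p[i])}


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_approx: float
    n: int


# ------------------------------------------------------------- phenotypes


def dichotomize_root(tooth: str, left_code, right_code) -> str | None:
    """Collapse a left/right pair of root codes into the tooth's two-class
    phenotype; ``None`` marks a missing/excluded case (absent side, or a
    side combination outside the study's groupings).

    Codes: ``1``-``4`` root counts, ``m`` congenitally missing, ``C``
    C-shaped root; ``None``/``""``/``"absent"`` for a tooth lost to
    extraction or treatment.
    """
    if tooth not in ROOT_CLASSES:
        raise ValueError(f"unknown tooth {tooth!r}")
    sides = []
    for c in (left_code, right_code):
        if c is None or (isinstance(c, float) and np.isnan(c)):
            return None
        c = str(c)
        if c in ("", "absent"):
            return None
        if c not in ROOT_CODES:
            raise ValueError(f"invalid root code {c!r} for {tooth}")
        sides.append(c)
    pair = frozenset(sides)
    for cls, pairs in ROOT_CLASSES[tooth].items():
        if pair in pairs:
            return cls
    return None


def genotype_trait_table(cohort: pd.DataFrame, tooth: str) -> pd.DataFrame:
    """3 x 2 genotype-by-class counts (rows VV, VA, AA) over the cohort's
    non-missing records for one tooth."""
    cols = CLASS_ORDER[tooth]
    counts = pd.DataFrame(0, index=list(GENOTYPES), columns=list(cols))
    for _, row in cohort.iterrows():
        cls = dichotomize_root(tooth, row[f"{tooth}_L"], row[f"{tooth}_R"])
        if cls is not None:
            counts.loc[row["genotype"], cls] += 1
    return counts


def expand_counts(table) -> tuple[np.ndarray, np.ndarray]:
    """Individual-level (row_index, col_index) vectors for a count table."""
    t = np.asarray(table, int)
    xs, ys = [], []
    for (i, j), c in np.ndenumerate(t):
        xs.extend([i] * c)
        ys.extend([j] * c)
    return np.array(xs), np.array(ys)


# ------------------------------------------------------------ exact test


def _log_fact(n: int) -> float:
    return lgamma(n + 1)


def fisher_exact_rxc(table) -> FisherResult:
    """Freeman-Halton exact test for an r x c contingency table.

    Enumerates every table with the observed margins and sums the
    (multivariate hypergeometric) probabilities of those no more probable
    than the observed one — the probability-ordering two-sided criterion,
    with a 1e-12 relative tolerance for ties.  A zero row or column margin
    makes the table degenerate and returns P = 1.
    """
    t = np.asarray(table, int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    rows_nz = rows[rows > 0]
    cols_nz = cols[cols > 0]
    if len(rows_nz) < 2 or len(cols_nz) < 2:
        return FisherResult(1.0, 0)
    t = t[rows > 0][:, cols > 0]
    rows, cols = rows_nz, cols_nz
    n = int(t.sum())
    const = (sum(_log_fact(r) for r in rows)
             + sum(_log_fact(c) for c in cols) - _log_fact(n))

    def logp(flat) -> float:
        return const - sum(_log_fact(x) for x in flat)

    lp_obs = logp(t.ravel())
    r, c = t.shape
    total = 0.0
    count = 0

    def fill_rows(i: int, rem_cols: np.ndarray, acc: list[int]) -> None:
        nonlocal total, count
        if i == r - 1:
            count += 1
            lp = logp(acc + list(rem_cols))
            if lp <= lp_obs + 1e-12:
                total += exp(lp)
            return
        for row in _row_fills(rows[i], rem_cols):
            fill_rows(i + 1, rem_cols - row, acc + list(row))

    fill_rows(0, cols.copy(), [])
    return FisherResult(min(total, 1.0), count)


def _row_fills(row_sum: int, rem_cols: np.ndarray):
    """All ways to fill one row summing to ``row_sum`` within column
    remainders."""
    c = len(rem_cols)

    def rec(j: int, rem: int, acc: list[int]):
        if j == c - 1:
            if rem <= rem_cols[j]:
                yield np.array(acc + [rem])
            return
        hi = min(rem, rem_cols[j])
        lo = max(0, rem - int(rem_cols[j + 1:].sum()))
        for x in range(lo, hi + 1):
            yield from rec(j + 1, rem - x, acc + [x])

    yield from rec(0, int(row_sum), [])


# --------------------------------------------------------------- logistic


def logistic_fit(y, X, terms: tuple[str, ...] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression with an intercept.

    ``X`` columns are the explanatory variables (no constant column); Wald
    chi-square is ``(coef/se)^2`` with P from a 1-df chi-square.  Fitted by
    Newton's method (statsmodels) to gradient norm below 1e-8.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more observations than terms")
    if y.min() == y.max():
        raise ValueError("outcome is constant")
    import statsmodels.api as sm

    design = sm.add_constant(X, prepend=True)
    model = sm.Logit(y, design)
    try:
        fit = model.fit(method="newton", disp=False, tol=1e-8, maxiter=200)
    except np.linalg.LinAlgError:
        # singular Hessian: (quasi-)complete separation — refit with a
        # gradient method so coefficients are still reported, flagged below
        fit = model.fit(method="bfgs", disp=False, maxiter=500)
    coef = np.asarray(fit.params)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.asarray(fit.bse)
        chi2 = (coef / se) ** 2
    chi2 = np.where(np.isfinite(chi2), chi2, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    names = ("intercept",) + tuple(
        terms if terms is not None
        else (f"x{i}" for i in range(X.shape[1])))
    separated = bool(np.any(np.abs(coef) > 15)
                     or not np.all(np.isfinite(se)))
    return LogisticFit(names, coef, se, chi2, p,
                       converged=bool(fit.mle_retvals["converged"]),
                       separation_flag=separated)


# ---------------------------------------------------------------- spearman


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with mid-ranks for ties; P from the
    t-approximation ``t = rho*sqrt((n-2)/(1-rho^2))``."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.min() == x.max() or y.min() == y.max():
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), len(x))


def spearman_from_table(table, row_order=None, col_order=None) -> SpearmanResult:
    """Spearman's rho of a two-way count table's individual-level expansion,
    computed directly from the counts via mid-rank closed forms.

    ``row_order``/``col_order`` reorder the table's categories before
    ranking (ascending); by default rows/columns are used as given.
    """
    t = np.asarray(table, float)
    if isinstance(table, pd.DataFrame):
        if row_order is not None:
            table = table.loc[list(row_order)]
        if col_order is not None:
            table = table[list(col_order)]
        t = table.to_numpy(float)
    else:
        if row_order is not None:
            t = t[np.asarray(row_order)]
        if col_order is not None:
            t = t[:, np.asarray(col_order)]
    n = t.sum()
    if n < 3:
        raise ValueError("need at least 3 observations")
    rm = t.sum(axis=1)
    cm = t.sum(axis=0)
    if (rm > 0).sum() < 2 or (cm > 0).sum() < 2:
        raise ValueError("correlation undefined for a constant vector")

    def midranks(margin: np.ndarray) -> np.ndarray:
        cum = np.concatenate([[0.0], np.cumsum(margin)])
        return 0.5 * (cum[:-1] + cum[1:] + 1)

    rrow = midranks(rm)
    rcol = midranks(cm)
    mean = (n + 1) / 2
    cov = float(((rrow[:, None] - mean) * (rcol[None, :] - mean) * t).sum())
    var_r = float(((rrow - mean) ** 2 * rm).sum())
    var_c = float(((rcol - mean) ** 2 * cm).sum())
    rho = cov / np.sqrt(var_r * var_c)
    nn = int(n)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        tstat = rho * np.sqrt((nn - 2) / (1 - rho ** 2))
        p = 2 * stats.t.sf(abs(tstat), df=nn - 2)
    return SpearmanResult(float(rho), float(p), nn)


# ---------------------------------------------------------------- pipeline

#: teeth whose dichotomized phenotype is modelled by logistic regression,
#: with the class treated as outcome 1
LOGISTIC_OUTCOMES = {"UP1": "1", "LM1": "3", "LM2": "C"}

_GENOTYPE_DOSAGE = {"VV": 0, "VA": 1, "AA": 2}


def cohort_analysis(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Run the full association battery on an individual-level cohort.

    Returns three frames: ``"counts"`` (per-tooth genotype x class counts
    with the exact Freeman-Halton P), ``"logistic"`` (per-term log odds
    ratios, SE, Wald chi2 and P for the teeth with a modelled outcome,
    covariates age/sex/region/genotype dosage), and ``"spearman"``
    (genotype-vs-trait and trait-vs-trait rank correlations).
    """
    count_rows = []
    tables = {}
    for tooth in ROOT_TEETH:
        t = genotype_trait_table(cohort, tooth)
        tables[tooth] = t
        fr = fisher_exact_rxc(t.to_numpy())
        for cls in t.columns:
            count_rows.append({"tooth": tooth, "class": cls,
                               **{g: int(t.loc[g, cls]) for g in GENOTYPES},
                               "fisher_p": fr.p_two_sided})
    logit_rows = []
    dosage = cohort["genotype"].map(_GENOTYPE_DOSAGE)
    for tooth, test_class in LOGISTIC_OUTCOMES.items():
        cls = [dichotomize_root(tooth, l, r) for l, r in
               zip(cohort[f"{tooth}_L"], cohort[f"{tooth}_R"])]
        keep = [i for i, c in enumerate(cls) if c is not None]
        if len(keep) < 10:
            continue
        y = np.array([cls[i] == test_class for i in keep], float)
        X = np.column_stack([cohort["age"].iloc[keep],
                             cohort["sex"].iloc[keep],
                             cohort["region"].iloc[keep],
                             dosage.iloc[keep]])
        try:
            fit = logistic_fit(y, X, terms=("age", "sex", "region", "genotype"))
        except ValueError:
            continue
        for term in ("age", "sex", "region", "genotype"):
            logit_rows.append({"tooth": tooth, "test_class": test_class,
                               "term": term, **fit.term(term)})
    spear_rows = []
    ordinals = {"genotype": dosage}
    for tooth in ROOT_TEETH:
        order = CLASS_ORDER[tooth]
        vals = [dichotomize_root(tooth, l, r) for l, r in
                zip(cohort[f"{tooth}_L"], cohort[f"{tooth}_R"])]
        ordinals[f"{tooth}_roots"] = pd.Series(
            [order.index(v) if v is not None else np.nan for v in vals])
    for trait in CROWN_TRAITS:
        if trait in cohort:
            ordinals[trait] = cohort[trait].astype(float)
    names = list(ordinals)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pair = pd.DataFrame({"a": ordinals[a].to_numpy(float),
                                 "b": ordinals[b].to_numpy(float)}).dropna()
            if len(pair) < 3 or pair["a"].nunique() < 2 or pair["b"].nunique() < 2:
                continue
            sr = spearman(pair["a"], pair["b"])
            spear_rows.append({"var1": a, "var2": b, "rho": sr.rho,
                               "p": sr.p_approx, "n": sr.n})
    return {"counts": pd.DataFrame(count_rows),
            "logistic": pd.DataFrame(logit_rows),
            "spearman": pd.DataFrame(spear_rows)}
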