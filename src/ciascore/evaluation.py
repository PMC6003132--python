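"""Diagnostic-test evaluation: ROC cutoff selection, performance metrics,
and paired-test concordance statistics (Cohen's kappa, exact McNemar,
Fisher's exact test)."""

from __future__ import annotations


import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln


@dataclass
class LabeledScores:
    """Per-sample continuous score with a binary case/control label."""

    sample_ids: list[str]
    scores: np.ndarray
    is_case: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        if not (self.is_case.any() and (~self.is_case).any()):
            raise ValueError("need at least one case and one control")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, case_label: str = "case") -> "LabeledScores":
        return cls(
            list(df["sample_id"].astype(str)),
            df["score"].to_numpy(dtype=float),
            (df["label"].astype(str) == case_label).to_numpy(),
        )

    @classmethod
    def from_tsv(cls, path: str | Path, case_label: str = "case") -> "LabeledScores":
        return cls.from_frame(pd.read_csv(path, sep="\t"), case_label)


def _fmt_pct(x: float | None) -> str | None:
    return None if x is None else f"{100 * x:.1f}%"


@dataclass
class EvaluationReport:
    """Confusion counts and the derived diagnostic metrics.

    Metrics whose denominator is zero are ``None`` (absent), not 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float | None = None
    auc: float | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    def as_dict(self, percent: bool = False) -> dict:
        metrics = dict(
            sensitivity=self.sensitivity, specificity=self.specificity,
            accuracy=self.accuracy, npv=self.npv, ppv=self.ppv,
        )
        if percent:
            metrics = {k: _fmt_pct(v) for k, v in metrics.items()}
        return dict(
            tp=self.tp, fp=self.fp, tn=self.tn, fn=self.fn,
            cutoff=self.cutoff, auc=self.auc, **metrics,
        )


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> EvaluationReport:
    """Diagnostic metrics from confusion counts."""
    return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn)


def roc_points(scores: LabeledScores) -> pd.DataFrame:
    """ROC curve with one threshold per distinct score.

    At threshold t a sample is called positive iff its score is strictly
    greater than t; thresholds run from -inf (everything positive) through
    every distinct score (the maximum gives the (0, 0) corner).
    """
    thresholds = np.concatenate(([-np.inf], np.unique(scores.scores)))
    n_pos = int(scores.is_case.sum())
    n_neg = len(scores.scores) - n_pos
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = scores.scores > t
        tpr[i] = (pred & scores.is_case).sum() / n_pos
        fpr[i] = (pred & ~scores.is_case).sum() / n_neg
    return pd.DataFrame(dict(threshold=thresholds, fpr=fpr, tpr=tpr))


def auc_trapezoid(curve: pd.DataFrame) -> float:
    order = np.argsort(curve["fpr"].to_numpy(), kind="stable")
    fpr = curve["fpr"].to_numpy()[order]
    tpr = curve["tpr"].to_numpy()[order]
    # within equal-fpr runs, sort tpr so the trapezoid follows the curve
    df = pd.DataFrame(dict(fpr=fpr, tpr=tpr)).sort_values(["fpr", "tpr"])
    return float(np.trapezoid(df["tpr"], df["fpr"]))


def roc_and_cutoff(scores: LabeledScores) -> tuple[EvaluationReport, pd.DataFrame]:
    """ROC analysis with Youden-J cutoff selection.

    The chosen cutoff maximizes J = sensitivity + specificity - 1; ties are
    broken toward the larger cutoff (higher specificity).  The report's
    confusion counts use the strict-greater call rule at that cutoff.
    """
    curve = roc_points(scores)
    auc = auc_trapezoid(curve)
    finite = curve[np.isfinite(curve["threshold"])]
    j = finite["tpr"] - finite["fpr"]
    best = j.max()
    cutoff = float(finite["threshold"][np.isclose(j, best)].max())

    pred = scores.scores > cutoff
    tp = int((pred & scores.is_case).sum())
    fp = int((pred & ~scores.is_case).sum())
    fn = int((~pred & scores.is_case).sum())
    tn = int((~pred & ~scores.is_case).sum())
    report = EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn, cutoff=cutoff, auc=auc)
    return report, curve


@dataclass
class KappaResult:
    kappa: float | None
    observed_agreement: float
    p_value: float | None = None


def cohens_kappa(table: np.ndarray) -> KappaResult:
    """Cohen's kappa for a square agreement table.

    kappa = (po - pe) / (1 - pe) with po the diagonal fraction and pe the
    chance agreement from the marginals.  Degenerate marginals (pe = 1)
    yield kappa ``None``.  The p-value is the large-sample normal
    approximation for kappa = 0.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("agreement table must be square")
    if (t < 0).any():
        raise ValueError("cells must be non-negative")
    n = t.sum()
    if n <= 0:
        raise ValueError("table total must be positive")
    po = np.trace(t) / n
    rows, cols = t.sum(axis=1) / n, t.sum(axis=0) / n
    pe = float(rows @ cols)
    if math.isclose(pe, 1.0):
        return KappaResult(None, po)
    kappa = (po - pe) / (1 - pe)
    # normal approximation under H0: kappa = 0
    var0 = pe + pe**2 - float(sum(rows * cols * (rows + cols)))
    p = None
    if var0 > 0:
        se0 = math.sqrt(var0 / (n * (1 - pe) ** 2))
        p = 2 * stats.norm.sf(abs(kappa) / se0)
    return KappaResult(float(kappa), float(po), p)


def mcnemar_exact(discordant_b: int, discordant_c: int) -> float:
    """Two-sided exact McNemar p from the discordant pair counts.

    p = min(1, 2 * P(X <= min(b, c))) with X ~ Binomial(b + c, 1/2);
    p = 1 when there are no discordant pairs.
    """
    b, c = int(discordant_b), int(discordant_c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))


def _log_table_prob(t: np.ndarray, logfact_margin: float) -> float:
    return logfact_margin - float(gammaln(t + 1).sum())


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(rows), len(cols)

    def fill(row_idx: int, col_rem: np.ndarray, acc: list):
        if row_idx == r - 1:
            if (col_rem >= 0).all():
                yield np.vstack(acc + [col_rem])
            return
        total = rows[row_idx]
        for combo in _row_compositions(total, col_rem):
            yield from fill(row_idx + 1, col_rem - combo, acc + [combo])

    yield from fill(0, cols.copy(), [])


def _row_compositions(total: int, caps: np.ndarray):
    """All non-negative integer rows summing to ``total`` with per-cell caps."""
    c = len(caps)

    def rec(i: int, rem: int, acc: list):
        if i == c - 1:
            if rem <= caps[i]:
                yield np.array(acc + [rem], dtype=np.int64)
            return
        for v in range(min(rem, caps[i]) + 1):
            yield from rec(i + 1, rem - v, acc + [v])

    yield from rec(0, total, [])


def fisher_exact(table: np.ndarray, max_exact_total: int = 500,
                 n_monte_carlo: int = 100_000,
                 seed: int | None = 0) -> float:
    """Two-sided Fisher's exact test for an r x c table.

    2x2 tables use the hypergeometric point-probability rule.  Larger tables
    use Freeman-Halton enumeration over all margin-preserving tables, summing
    probabilities <= the observed table's; tables with total >
    ``max_exact_total`` fall back to seeded Monte Carlo over random tables
    with the observed margins.
    """
    t = np.asarray(table, dtype=np.int64)
    if (t < 0).any():
        raise ValueError("cells must be non-negative")
    n = int(t.sum())
    if n <= 0:
        raise ValueError("table total must be positive")
    if t.shape == (2, 2):
        return float(stats.fisher_exact(t)[1])

    rows, cols = t.sum(axis=1), t.sum(axis=0)
    logfact_margin = float(
        gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    )
    logp_obs = _log_table_prob(t, logfact_margin)
    tol = 1e-9 * abs(logp_obs)

    if n <= max_exact_total:
        p = 0.0
        for cand in _enumerate_tables(rows, cols):
            lp = _log_table_prob(cand, logfact_margin)
            if lp <= logp_obs + tol:
                p += math.exp(lp)
        return float(min(1.0, p))

    rng = np.random.default_rng(seed)
    sampler = stats.random_table(rows, cols, seed=rng)
    draws = sampler.rvs(n_monte_carlo)
    lps = logfact_margin - gammaln(draws + 1).sum(axis=(1, 2))
    hits = int((lps <= logp_obs + tol).sum())
    return (hits + 1) / (n_monte_carlo + 1)


def paired_concordance(both_neg: int, a_neg_b_pos: int, a_pos_b_neg: int,
                       both_pos: int) -> dict:
    """Agreement statistics for two binary tests on the same samples.

    Returns observed agreement, Cohen's kappa (with its approximate
    p-value) and the exact McNemar p for the discordant cells.
    """
    table = np.array([[both_neg, a_neg_b_pos], [a_pos_b_neg, both_pos]])
    kr = cohens_kappa(table)
    return dict(
        n=int(table.sum()),
        observed_agreement=kr.observed_agreement,
        kappa=kr.kappa,
        kappa_p_value=kr.p_value,
        mcnemar_p=mcnemar_exact(a_neg_b_pos, a_pos_b_neg),
    )
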