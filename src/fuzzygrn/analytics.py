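"""Network summary statistics, evidence-overlap analysis, and literature
curation-completeness estimation by first-order Hill saturation.

The completeness model: as articles are curated, the cumulative number of
distinct interactions n(a) saturates.  Fitting n(a) = nmax·a/(k + a) —
the first-order Hill (equivalently Michaelis–Menten) form, with nmax the
asymptotic number of discoverable interactions and k the half-saturation
article count — lets one extrapolate what fraction of the regulatory
network an annotation effort has already captured, and how many articles a
target completeness would cost.  Two useful closed forms follow directly:
doubling the article count moves model completeness c = a/(k+a) to
2c/(1+c), and the article count for target completeness c* is k·c*/(1−c*).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .curation import classify_confidence
from .model import Network

__all__ = [
    "SummaryTable",
    "OverlapReport",
    "CurationCurve",
    "HillFit",
    "HillSaturationModel",
    "anchor_fit",
    "summarize",
    "evidence_overlap",
    "curation_curve",
    "fit_hill",
    "completeness",
    "articles_for",
]

SUMMARY_COLUMNS = ("genes", "tfs", "interactions_high", "interactions_all",
                   "annotations", "articles")


@dataclass
class SummaryTable:
    """Per-process and total annotation counts (wrapping a DataFrame).

    Processes overlap in genes and TFs, so per-process counts need not sum
    to the totals; within every row interactions_high ≤ interactions_all.
    """

    table: pd.DataFrame  # index: process labels + "Total"

    @property
    def total(self) -> pd.Series:
        return self.table.loc["Total"]

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index_label="process")


def _row_counts(network: Network, tids) -> dict[str, int]:
    genes, tfs, articles = set(), set(), set()
    n_high = 0
    n_ann = 0
    for tid in tids:
        tr = network.transitions[tid]
        for out in tr.outputs:
            ent = network.entities.get(out.entity_id)
            if ent is not None and ent.etype == "gene":
                genes.add(out.entity_id)
        for inp in tr.tf_inputs():
            tfs.add(inp.entity_id)
        recs = network.evidence.get(tid, [])
        n_ann += len(recs)
        articles.update(r.article for r in recs)
        if recs and classify_confidence(recs).value == "high":
            n_high += 1
    return {
        "genes": len(genes),
        "tfs": len(tfs),
        "interactions_high": n_high,
        "interactions_all": len(tids),
        "annotations": n_ann,
        "articles": len(articles),
    }


def summarize(network: Network) -> SummaryTable:
    """Count targets, TFs, interactions (all/high-confidence), annotations
    and distinct articles, overall and per process label."""
    by_process: dict[str, list[str]] = {}
    for tid, tr in network.transitions.items():
        by_process.setdefault(tr.process, []).append(tid)
    rows = {}
    for proc in sorted(by_process):
        rows[proc] = _row_counts(network, by_process[proc])
    rows["Total"] = _row_counts(network, list(network.transitions))
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(SUMMARY_COLUMNS))
    return SummaryTable(table.astype(int))


@dataclass
class OverlapReport:
    """Pairwise overlap of two interaction-id sets.

    ``pct_a_in_b`` is the share of set A that is also in B, in percent;
    ``display`` rounds it to one decimal as printed in figure captions.
    """

    label_a: str
    label_b: str
    size_a: int
    size_b: int
    intersection: int
    pct_a_in_b: float

    @property
    def display(self) -> float:
        return round(self.pct_a_in_b, 1)

    def to_tsv(self) -> str:
        lines = [
            "label_a\tlabel_b\tsize_a\tsize_b\tintersection\tpct_a_in_b",
            f"{self.label_a}\t{self.label_b}\t{self.size_a}\t{self.size_b}"
            f"\t{self.intersection}\t{self.display:.1f}",
        ]
        return "\n".join(lines) + "\n"


def evidence_overlap(set_a, set_b, label_a: str = "A", label_b: str = "B") -> OverlapReport:
    """Overlap of two evidence sets, e.g. predicted vs binding-supported
    interactions: reports |A|, |B|, |A∩B| and 100·|A∩B|/|A|."""
    set_a, set_b = set(set_a), set(set_b)
    if not set_a:
        raise ValueError("set A is empty: percentage of A supported by B is undefined")
    inter = len(set_a & set_b)
    return OverlapReport(
        label_a=label_a,
        label_b=label_b,
        size_a=len(set_a),
        size_b=len(set_b),
        intersection=inter,
        pct_a_in_b=100.0 * inter / len(set_a),
    )


@dataclass
class CurationCurve:
    """Cumulative distinct-interaction counts vs articles curated.

    ``mean_n[i]`` is the average over ``replicates`` random article
    orderings of the number of distinct interactions annotated after
    ``articles[i]`` articles; rarefaction-style averaging removes the
    (unknowable) true curation order.
    """

    articles: np.ndarray  # 1..A
    mean_n: np.ndarray
    replicates: np.ndarray  # shape (n_orders, A)
    seed: int | None = None


def curation_curve(evidence, n_orders: int = 100, seed: int = 0) -> CurationCurve:
    """Rarefaction curve of distinct interactions vs number of articles.

    Articles are permuted ``n_orders`` times with a seeded generator; for
    each ordering the cumulative count of distinct transition ids is taken,
    and the pointwise mean over orderings is the curve used for fitting.
    """
    by_article: dict[str, set[str]] = {}
    for rec in evidence:
        by_article.setdefault(rec.article, set()).add(rec.transition_id)
    if not by_article:
        raise ValueError("no evidence records: cannot build a curation curve")
    articles = sorted(by_article)
    sets = [by_article[a] for a in articles]
    A = len(articles)
    rng = np.random.default_rng(seed)
    reps = np.zeros((n_orders, A), dtype=float)
    for m in range(n_orders):
        order = rng.permutation(A)
        seen: set[str] = set()
        for j, idx in enumerate(order):
            seen |= sets[idx]
            reps[m, j] = len(seen)
    return CurationCurve(
        articles=np.arange(1, A + 1),
        mean_n=reps.mean(axis=0),
        replicates=reps,
        seed=seed,
    )


@dataclass(frozen=True)
class HillFit:
    """Fitted saturation parameters with completeness accessors."""

    nmax: float
    k: float
    residual: float

    def predict(self, a):
        a = np.asarray(a, dtype=float)
        return self.nmax * a / (self.k + a)

    def model_completeness(self, a: float) -> float:
        return float(a / (self.k + a))


class HillSaturationModel(RegressorMixin, BaseEstimator):
    """First-order Hill saturation curve n(a) = nmax·a/(k + a).

    sklearn-style estimator: ``fit(a, n)`` estimates ``nmax_`` (asymptotic
    interaction count) and ``k_`` (half-saturation article count) by
    nonlinear least squares, seeded by a Lineweaver–Burk linearization
    (1/n against 1/a) and bounded to nmax ∈ [max(n), 100·max(n)], k > 0.

    Parameters
    ----------
    nmax_bound_factor : upper bound on nmax as a multiple of the largest
        observed count.  The lower bound is the largest observed count
        itself (the asymptote cannot undercut the data).
    """

    def __init__(self, nmax_bound_factor: float = 100.0):
        self.nmax_bound_factor = nmax_bound_factor

    def fit(self, a, n):
        a = np.asarray(a, dtype=float).ravel()
        n = np.asarray(n, dtype=float).ravel()
        if a.shape != n.shape:
            raise ValueError("a and n must have the same length")
        if len(np.unique(a)) < 3:
            raise ValueError("need at least 3 distinct article counts to fit")
        if np.ptp(n) == 0:
            raise ValueError("degenerate curve: constant interaction count")
        if np.any(a <= 0):
            raise ValueError("article counts must be positive")
        n_total = float(n.max())
        lo, hi = n_total, self.nmax_bound_factor * n_total

        # Lineweaver–Burk start: 1/n = 1/nmax + (k/nmax)·(1/a)
        mask = n > 0
        x, y = 1.0 / a[mask], 1.0 / n[mask]
        design = np.column_stack([np.ones_like(x), x])
        (icpt, slope), *_ = np.linalg.lstsq(design, y, rcond=None)
        nmax0 = 1.0 / icpt if icpt > 0 else 2.0 * n_total
        k0 = slope * nmax0 if slope * nmax0 > 0 else float(np.median(a))
        nmax0 = float(np.clip(nmax0, lo * (1 + 1e-9), hi * (1 - 1e-9)))

        def hill(a_, nmax, k):
            return nmax * a_ / (k + a_)

        popt, _ = curve_fit(
            hill, a, n, p0=[nmax0, k0], bounds=([lo, 1e-12], [hi, np.inf]), maxfev=20000
        )
        self.nmax_ = float(popt[0])
        self.k_ = float(popt[1])
        resid = n - hill(a, *popt)
        self.residual_ = float(np.sum(resid**2))
        return self

    def predict(self, a):
        return self.fit_result_().predict(np.asarray(a, dtype=float).ravel())

    def fit_result_(self) -> HillFit:
        if not hasattr(self, "nmax_"):
            raise AttributeError("model is not fitted")
        return HillFit(nmax=self.nmax_, k=self.k_, residual=self.residual_)


def anchor_fit(model_completeness: float, articles: float, nmax: float = 1.0) -> HillFit:
    """Hill fit constructed from a single completeness anchor.

    Inverting c = a/(k+a) gives k = a·(1−c)/c, which is all the doubling
    and articles-for extrapolations need; ``nmax`` only rescales predicted
    counts and defaults to 1.
    """
    if not 0 < model_completeness < 1:
        raise ValueError("anchor completeness must lie strictly between 0 and 1")
    if articles <= 0:
        raise ValueError("article count must be positive")
    c = model_completeness
    return HillFit(nmax=nmax, k=articles * (1.0 - c) / c, residual=float("nan"))


def fit_hill(curve: CurationCurve) -> HillFit:
    """Least-squares first-order Hill fit to a curation curve's mean."""
    return HillSaturationModel().fit(curve.articles, curve.mean_n).fit_result_()


def completeness(fit: HillFit, a: float, n_observed: float | None = None) -> float:
    """Fraction of the discoverable network already captured.

    With ``n_observed`` given, the network completeness n_observed/nmax
    (observed over asymptote); otherwise the model completeness a/(k+a) at
    article count ``a``.
    """
    if a <= 0:
        raise ValueError("article count must be positive")
    if n_observed is not None:
        if fit.nmax <= n_observed:
            warnings.warn(
                "observed count meets or exceeds the fitted asymptote; "
                "completeness clamped to 1.0",
                stacklevel=2,
            )
            return 1.0
        return float(n_observed / fit.nmax)
    return fit.model_completeness(a)


def articles_for(fit: HillFit, target_completeness: float) -> float:
    """Article count at which model completeness reaches the target:
    a = k·c/(1−c).  The asymptote (c = 1) is unreachable."""
    if not 0 < target_completeness < 1:
        raise ValueError("target completeness must lie strictly between 0 and 1")
    c = target_completeness
    return float(fit.k * c / (1.0 - c))
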