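"""Stage-wise functional enrichment of upregulated genes.

For every developmental stage, genes whose standardized (median-centered
log2) expression at that stage is at least 0.5 -- i.e. at least 0.5 log2
units above their own profile median -- form the upregulated set.  Each
annotation term is then tested for over/under-representation in that set
against the annotated-genome background with an exact two-sided ("two-way")
hypergeometric test; effect direction and size are reported as the log2 odds
of the stage frequency versus the genome frequency, and p-values are
Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import StandardizedExpression

__all__ = [
    "AnnotationSet",
    "select_upregulated",
    "hypergeometric_two_sided",
    "log_odds",
    "bh_adjust",
    "enrichment_scan",
    "read_annotations",
]

#: relative slack when deciding which outcomes are "at most as likely" as the
#: observed one; absorbs floating-point noise in exact ties (the convention of
#: R's fisher.test).
_REL_ERR = 1 + 1e-7


@dataclass
class AnnotationSet:
    """gene -> set of term ids, with the background universe.

    ``background`` defaults to the annotated genes (the standard enrichment
    universe); pass an explicit gene collection to test against the whole
    genome instead.  ``subset`` restricts the term universe (e.g. to the GO
    Plant subset) before any testing.
    """

    gene_terms: dict[str, set[str]]
    background: set[str] = field(default_factory=set)
    subset: set[str] | None = None

    def __post_init__(self) -> None:
        if self.subset is not None:
            self.gene_terms = {
                g: ts & self.subset for g, ts in self.gene_terms.items()
            }
            self.gene_terms = {g: ts for g, ts in self.gene_terms.items() if ts}
        if not self.background:
            self.background = set(self.gene_terms)

    @property
    def n_background(self) -> int:
        return len(self.background)

    def term_members(self) -> dict[str, set[str]]:
        members: dict[str, set[str]] = {}
        for g, ts in self.gene_terms.items():
            if g not in self.background:
                continue
            for t in ts:
                members.setdefault(t, set()).add(g)
        return members


def select_upregulated(
    std: StandardizedExpression, stage: str, threshold: float = 0.5
) -> set[str]:
    """Genes upregulated at a stage: standardized value >= threshold.

    Standardized 0 is the gene's own median, so the default picks genes at
    least 0.5 log2 units above their median profile ("at least" inclusive).
    """
    if stage not in std.values.columns:
        raise KeyError(f"stage {stage!r} not in standardized expression")
    col = std.values[stage]
    return set(col.index[col >= threshold])


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not max(0, n - (N - K)) <= k <= min(n, K):
        raise ValueError(f"k={k} outside hypergeometric support for K={K}, n={n}, N={N}")


def hypergeometric_two_sided(k: int, K: int, n: int, N: int, method: str = "minlike") -> float:
    """Exact two-sided hypergeometric p for observing k annotated genes.

    Drawing n genes from N of which K are annotated, the two-sided p is the
    sum of probabilities of every outcome at most as likely as the observed
    one (``method='minlike'``, the standard exact two-sided convention), or
    twice the smaller tail capped at 1 (``method='double'``).
    """
    _check_counts(k, K, n, N)
    lo = max(0, n - (N - K))
    hi = min(n, K)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    p_obs = pmf[k - lo]
    if method == "minlike":
        p = float(pmf[pmf <= p_obs * _REL_ERR].sum())
    elif method == "double":
        lower = float(pmf[: k - lo + 1].sum())
        upper = float(pmf[k - lo :].sum())
        p = 2 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def log_odds(k: int, n: int, K: int, N: int) -> float:
    """log2 of the stage frequency of a term over its genome frequency.

    Positive values mean the annotation is more frequent among the stage's
    upregulated genes than in the background.  When any of the four counts
    involved is zero the ratio is stabilized with Haldane-Anscombe 0.5
    pseudo-counts: log2(((k+0.5)/(n+0.5)) / ((K+0.5)/(N+0.5))).
    """
    if n == 0 or K == 0:
        raise ValueError("log odds undefined for n=0 or K=0")
    _check_counts(k, K, n, N)
    if k == 0:
        return float(np.log2(((k + 0.5) / (n + 0.5)) / ((K + 0.5) / (N + 0.5))))
    return float(np.log2((k / n) / (K / N)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _two_sided_vector(ks: np.ndarray, Ks: np.ndarray, n: int, N: int) -> np.ndarray:
    """Two-sided p for many terms sharing the same draw size n."""
    out = np.empty(ks.size)
    for i, (k, K) in enumerate(zip(ks, Ks)):
        out[i] = hypergeometric_two_sided(int(k), int(K), n, N)
    return out


def enrichment_scan(
    std: StandardizedExpression,
    annotations: AnnotationSet,
    stages: list[str] | None = None,
    threshold: float = 0.5,
    bh_scope: str = "stage",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every term in every stage's upregulated set.

    Returns one row per (stage, term) with counts k (upregulated and
    annotated), n (upregulated, within background), K (annotated in
    background), N (background), the log2 odds, raw and BH-adjusted p, and a
    significance flag at ``p_adj < alpha``.  ``bh_scope`` picks the BH family:
    per ``'stage'`` (default, matching per-stage reporting) or ``'global'``
    across all (stage, term) tests.
    """
    if bh_scope not in ("stage", "global"):
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    if not annotations.gene_terms:
        raise ValueError("empty annotation set")
    if stages is None:
        stages = list(std.stage_order)
    members = annotations.term_members()
    terms = sorted(members)
    N = annotations.n_background
    Ks = np.array([len(members[t]) for t in terms])

    frames = []
    for stage in stages:
        up = select_upregulated(std, stage, threshold) & annotations.background
        n = len(up)
        ks = np.array([len(members[t] & up) for t in terms])
        rows = pd.DataFrame(
            {"stage": stage, "term": terms, "k": ks, "n": n, "K": Ks, "N": N}
        )
        if n == 0:
            rows["log_odds"] = np.nan
            rows["p"] = np.nan
        else:
            rows["log_odds"] = [
                log_odds(int(k), n, int(K), N) for k, K in zip(ks, Ks)
            ]
            rows["p"] = _two_sided_vector(ks, Ks, n, N)
        frames.append(rows)
    result = pd.concat(frames, ignore_index=True)

    result["p_adj"] = np.nan
    tested = result["p"].notna()
    if bh_scope == "global":
        result.loc[tested, "p_adj"] = bh_adjust(result.loc[tested, "p"])
    else:
        for stage in stages:
            m = tested & (result["stage"] == stage)
            if m.any():
                result.loc[m, "p_adj"] = bh_adjust(result.loc[m, "p"])
    result["significant"] = result["p_adj"] < alpha
    return result


def read_annotations(
    path: str | Path,
    subset_path: str | Path | None = None,
    background: set[str] | None = None,
) -> AnnotationSet:
    """Read a two-column (gene, term) annotation TSV, optionally restricted to
    a one-term-per-line subset file."""
    df = pd.read_csv(path, sep="\t")
    gene_col, term_col = df.columns[:2]
    gene_terms: dict[str, set[str]] = {}
    for g, t in zip(df[gene_col].astype(str), df[term_col].astype(str)):
        gene_terms.setdefault(g, set()).add(t)
    subset = None
    if subset_path is not None:
        subset = {
            line.strip() for line in Path(subset_path).read_text().splitlines() if line.strip()
        }
    return AnnotationSet(gene_terms=gene_terms, background=background or set(), subset=subset)
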