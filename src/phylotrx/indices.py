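"""Expression-weighted evolutionary indices.

All four transcriptome indices share one form: for a developmental stage *s*
with normalized expression values :math:`e_{is}` and a per-gene evolutionary
weight :math:`w_i`,

.. math:: x_s = \\frac{\\sum_i w_i e_{is}}{\\sum_i e_{is}}

The weight picks the index: phylostratum (TAI, transcriptome age index),
nonsynonymous divergence dN (TdNI), synonymous divergence dS (TdSI), or the
effective number of codons ENC (TCBI; lower = stronger codon usage bias).
Each index uses only the genes carrying that weight, so the gene universe
(``n_genes_used``) differs per index.  The weighted-mean form makes every
profile invariant to rescaling any stage column by a positive constant and
bounded by the min/max of the weights used.

Also here: Wright's effective number of codons, per-phylostratum relative
expression, cumulative-phylostrata TAI, min-max profile normalization and
reciprocal-best-hit orthology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import StageExpression

__all__ = [
    "GeneEvolStats",
    "IndexProfile",
    "weighted_transcriptome_index",
    "tai",
    "tdni",
    "tdsi",
    "tcbi",
    "cumulative_tai",
    "min_max_normalize_profile",
    "relative_expression",
    "effective_number_of_codons",
    "reciprocal_best_hits",
    "read_divergence_table",
]

ENC_MIN, ENC_MAX = 20.0, 61.0


@dataclass
class GeneEvolStats:
    """Per-gene evolutionary attributes; any attribute may be missing (NaN).

    ``table`` is indexed by gene id with (a subset of) float columns ``ps``,
    ``dN``, ``dS``, ``enc``.  ENC values are capped into [20, 61] on
    construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        known = [c for c in ("ps", "dN", "dS", "enc") if c in self.table.columns]
        if not known:
            raise ValueError("GeneEvolStats needs at least one of ps/dN/dS/enc")
        self.table = self.table[known].astype(float)
        if "enc" in self.table:
            self.table["enc"] = self.table["enc"].clip(ENC_MIN, ENC_MAX)

    def weights(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"no {name!r} attribute available")
        return self.table[name].dropna()


@dataclass
class IndexProfile:
    """Per-stage index values with the gene count behind them."""

    values: pd.Series  # indexed by stage, in stage order
    n_genes_used: int
    weight_name: str

    def argmin_stage(self) -> str:
        return str(self.values.idxmin())

    def argmax_stage(self) -> str:
        return str(self.values.idxmax())

    def to_frame(self) -> pd.DataFrame:
        return self.values.rename("value").rename_axis("stage").reset_index()


def weighted_transcriptome_index(
    expr: StageExpression, weights: pd.Series, weight_name: str = "weight"
) -> IndexProfile:
    """Expression-weighted mean of a per-gene evolutionary weight, per stage.

    Genes missing a weight (or absent from the expression table) are excluded
    from both numerator and denominator; zero-expression genes contribute
    nothing either way.
    """
    weights = weights.dropna()
    common = expr.values.index.intersection(weights.index)
    if len(common) == 0:
        raise ValueError("no gene has both expression and a weight")
    e = expr.values.loc[common]
    w = weights.loc[common].to_numpy(dtype=float)
    denom = e.sum(axis=0)
    dead = denom.index[denom.to_numpy() == 0].tolist()
    if dead:
        raise ValueError(f"stages with zero total expression over weighted genes: {dead}")
    values = (e.mul(w, axis=0).sum(axis=0) / denom)[expr.stage_order]
    return IndexProfile(values=values, n_genes_used=len(common), weight_name=weight_name)


def tai(expr: StageExpression, evol: GeneEvolStats) -> IndexProfile:
    """Transcriptome age index: low = evolutionarily old transcriptome."""
    return weighted_transcriptome_index(expr, evol.weights("ps"), "ps")


def tdni(expr: StageExpression, evol: GeneEvolStats) -> IndexProfile:
    """Transcriptome nonsynonymous divergence index."""
    return weighted_transcriptome_index(expr, evol.weights("dN"), "dN")


def tdsi(expr: StageExpression, evol: GeneEvolStats) -> IndexProfile:
    """Transcriptome synonymous divergence index."""
    return weighted_transcriptome_index(expr, evol.weights("dS"), "dS")


def tcbi(expr: StageExpression, evol: GeneEvolStats) -> IndexProfile:
    """Transcriptome codon bias index (lower = stronger codon usage bias)."""
    return weighted_transcriptome_index(expr, evol.weights("enc"), "enc")


def cumulative_tai(expr: StageExpression, evol: GeneEvolStats, k: int) -> IndexProfile:
    """TAI restricted to genes of phylostrata 1..k.

    Sweeping k from 1 to P shows at which phylogenetic depth the profile
    shape (e.g. the mid-developmental minimum) becomes detectable; k = P
    reproduces the full TAI.
    """
    ps = evol.weights("ps")
    if not 1 <= k <= int(ps.max()):
        raise ValueError(f"k={k} outside 1..{int(ps.max())}")
    subset = ps[ps <= k]
    if subset.empty:
        raise ValueError(f"no genes with ps <= {k}")
    return weighted_transcriptome_index(expr, subset, "ps")


def min_max_normalize_profile(profile: IndexProfile) -> IndexProfile:
    """Rescale a profile to [0, 1] across stages: (x - min) / (max - min)."""
    x = profile.values
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("constant profile: min-max normalization undefined")
    return IndexProfile(
        values=(x - lo) / (hi - lo),
        n_genes_used=profile.n_genes_used,
        weight_name=profile.weight_name,
    )


def relative_expression(expr: StageExpression, evol: GeneEvolStats) -> pd.DataFrame:
    """Per-phylostratum relative expression RE(ps), min-max scaled over stages.

    For each phylostratum, the mean normalized expression of its genes is
    taken per stage and rescaled so that the stage with the lowest stratum
    mean reads 0 and the highest reads 1.
    """
    ps = evol.weights("ps").astype(int)
    common = expr.values.index.intersection(ps.index)
    if len(common) == 0:
        raise ValueError("no gene has both expression and a phylostratum")
    means = expr.values.loc[common].groupby(ps.loc[common]).mean()
    lo = means.min(axis=1)
    hi = means.max(axis=1)
    flat = means.index[(hi - lo) == 0].tolist()
    if flat:
        raise ValueError(f"phylostrata with constant mean expression: {flat}")
    re = means.sub(lo, axis=0).div(hi - lo, axis=0)
    re.index.name = "ps"
    return re[expr.stage_order]


# --- effective number of codons -------------------------------------------

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: amino acid -> synonymous-family degeneracy under the standard code
#: (Leu/Ser/Arg are six-fold families; Met/Trp are non-degenerate and do not
#: enter the estimator).
AA_DEGENERACY = {
    "F": 2, "Y": 2, "C": 2, "H": 2, "Q": 2, "N": 2, "K": 2, "D": 2, "E": 2,
    "I": 3,
    "V": 4, "P": 4, "T": 4, "A": 4, "G": 4,
    "L": 6, "S": 6, "R": 6,
}

#: number of amino-acid families per degeneracy class
_CLASS_SIZE = {2: 9, 3: 1, 4: 5, 6: 3}


def effective_number_of_codons(cds: str, on_bad_codon: str = "error") -> float:
    """Wright's Nc, the effective number of codons of a coding sequence.

    For each amino-acid family with n >= 2 observed codons and codon
    fractions p, the codon homozygosity is F = (n * sum(p^2) - 1) / (n - 1);
    F is averaged within each degeneracy class and

        Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

    (the 2 counts Met and Trp).  A sequence using a single codon per family
    gives Nc = 20 (maximal bias); uniform usage gives 61.  Classes with no
    computable family borrow the mean of the computable classes' averages;
    families with non-positive F are treated as uninformative.  The estimate
    is capped at 61 (short sequences can exceed the theoretical maximum).

    ``on_bad_codon='error'`` rejects internal stops and non-ACGT codons;
    ``'skip'`` drops them.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    counts: dict[str, dict[str, int]] = {}
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for pos, codon in enumerate(codons):
        aa = _CODON_TABLE.get(codon)
        is_stop = aa == "*" and pos < len(codons) - 1
        if aa is None or is_stop:
            if on_bad_codon == "skip":
                continue
            kind = "internal stop" if is_stop else "invalid codon"
            raise ValueError(f"{kind} {codon!r} at codon position {pos}")
        if aa in AA_DEGENERACY:
            counts.setdefault(aa, {})[codon] = counts.setdefault(aa, {}).get(codon, 0) + 1

    class_F: dict[int, list[float]] = {k: [] for k in _CLASS_SIZE}
    for aa, fam in counts.items():
        n = sum(fam.values())
        if n <= 1:
            continue
        p2 = sum((c / n) ** 2 for c in fam.values())
        F = (n * p2 - 1) / (n - 1)
        if F > 0:
            class_F[AA_DEGENERACY[aa]].append(F)

    avg = {k: float(np.mean(v)) for k, v in class_F.items() if v}
    if not avg:
        raise ValueError("no amino-acid family with >=2 codons: ENC undefined")
    fill = float(np.mean(list(avg.values())))
    nc = 2.0
    for k, size in _CLASS_SIZE.items():
        nc += size / avg.get(k, fill)
    return min(nc, ENC_MAX)


# --- orthology and divergence tables --------------------------------------

def _best_hits(hits: pd.DataFrame) -> pd.Series:
    """Per query, the best subject: highest bitscore, then lowest e-value,
    then lexicographically smallest subject id."""
    ordered = hits.sort_values(
        ["bitscore", "evalue", "subject"], ascending=[False, True, True], kind="stable"
    )
    return ordered.groupby("query", sort=False)["subject"].first()


def reciprocal_best_hits(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame, e_threshold: float = 1e-5
) -> pd.DataFrame:
    """Reciprocal-best-hit ortholog pairs between proteomes A and B.

    Both tables need columns ``query``, ``subject``, ``evalue``, ``bitscore``.
    A pair (a, b) is retained iff b is a's best hit in B and a is b's best
    hit in A, using only hits with e <= threshold.  Returns a DataFrame with
    columns ``gene_a``, ``gene_b`` sorted by ``gene_a``.
    """
    ab = hits_ab[hits_ab["evalue"] <= e_threshold]
    ba = hits_ba[hits_ba["evalue"] <= e_threshold]
    if ab.empty or ba.empty:
        return pd.DataFrame(columns=["gene_a", "gene_b"])
    best_ab = _best_hits(ab)
    best_ba = _best_hits(ba)
    pairs = [
        (a, b)
        for a, b in best_ab.items()
        if best_ba.get(b) == a
    ]
    return pd.DataFrame(sorted(pairs), columns=["gene_a", "gene_b"])


def read_divergence_table(path: str | Path) -> pd.DataFrame:
    """Read a per-gene divergence TSV (gene, dN, dS).

    Malformed rows are reported with their line numbers; duplicate gene rows
    are an error (silently keeping one would hide upstream join mistakes).
    """
    path = Path(path)
    rows = []
    errors = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise ValueError(f"{path}: expected 3 columns (gene, dN, dS)")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                errors.append(f"line {lineno}: {len(parts)} fields")
                continue
            try:
                rows.append((parts[0], float(parts[1]), float(parts[2])))
            except ValueError:
                errors.append(f"line {lineno}: non-numeric dN/dS")
    if errors:
        raise ValueError(f"{path}: malformed rows: " + "; ".join(errors[:10]))
    df = pd.DataFrame(rows, columns=["gene", "dN", "dS"]).set_index("gene")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate gene rows: {dup[:10]}")
    return df
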