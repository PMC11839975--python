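"""Synthetic developmental transcriptomes with known evolutionary ground truth.

Generates every input of the analysis pipeline -- counts with a design,
homology hit tables, coding sequences, divergence tables, GO labels -- from a
single seeded configuration, so that each downstream stage can be tested
against the truth that produced the data.

The defaults emulate the study system this package targets: 12 ordered
stages of somatic embryogenesis sampled in 3 replicates, genes stratified
over 18 phylostrata, negative-binomial counts, and an "hourglass" expression
program in which evolutionarily old genes (low phylostratum) peak at a
designated mid-developmental (phylotypic) stage while young genes peak at
the developmental extremes.  The hourglass is a single tunable effect:
per-gene log2 stage means are

    log2 mu_is = baseline_i + effect_size * [a_i * b_s + (1 - a_i) * (1 - b_s)]

where a_i in [0, 1] is the gene's "oldness" ((P - ps_i) / (P - 1)) and b_s a
Gaussian bump over the stage index centered on the phylotypic stage.  With
``effect_size = 0`` stage means are exchangeable and no stage is privileged.

Divergence (dN, dS) is gamma-distributed with scale increasing in
phylostratum (younger genes more diverged), and the target effective number
of codons increases with phylostratum (old genes more codon-biased), which
couples TAI, TdNI, TdSI and TCBI the way real developmental transcriptomes
couple them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expression import CountMatrix
from .indices import AA_DEGENERACY, _CODON_TABLE
from .phylostrata import LineageMap

__all__ = [
    "SimulationConfig",
    "GeneCatalog",
    "simulate_gene_catalog",
    "simulate_counts",
    "simulate_hit_table",
    "simulate_cds",
    "simulate_go_annotations",
    "lineage_for_catalog",
    "write_all_inputs",
]

#: default developmental series: early induction through juvenile plant
DEFAULT_STAGES = ["EI", "PG", "G1", "G2", "H", "T1", "T2", "C1", "C2", "S", "EP", "JP"]


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator.

    ``effect_size`` is the log2-scale expression boost of old genes at the
    phylotypic stage (and of young genes at the developmental extremes);
    0 removes any age-expression association.  ``dispersion`` is the
    negative-binomial size parameter (variance = mu + mu^2/dispersion);
    ``np.inf`` gives Poisson counts.
    """

    n_genes: int = 2000
    n_ps: int = 18
    stages: list[str] = field(default_factory=lambda: list(DEFAULT_STAGES))
    reps_per_stage: int = 3
    phylotypic_stage: str = "H"
    effect_size: float = 2.0
    dispersion: float = 5.0
    seed: int = 0
    bump_width: float = 1.5  # sd of the stage-index Gaussian bump, in stages
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    libsize_log_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_ps < 2:
            raise ValueError("n_ps must be >= 2")
        if self.reps_per_stage < 1:
            raise ValueError("reps_per_stage must be >= 1")
        if self.phylotypic_stage not in self.stages:
            raise ValueError(
                f"phylotypic_stage {self.phylotypic_stage!r} not in stages"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")


@dataclass
class GeneCatalog:
    """Ground-truth per-gene attributes backing every simulated input.

    One row per gene: true phylostratum, CDS length (a multiple of 3), true
    divergence values, the codon-bias target, and sparse GO labels.
    """

    table: pd.DataFrame  # gene_id index; true_ps, cds_length, dN, dS, target_enc
    go_terms: dict[str, set[str]]

    def __post_init__(self) -> None:
        t = self.table
        if (t["cds_length"] % 3 != 0).any():
            raise ValueError("cds_length must be divisible by 3")
        if not np.isfinite(t[["dN", "dS"]].to_numpy()).all():
            raise ValueError("dN/dS must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def n_ps(self) -> int:
        return int(self.table["true_ps"].max())


def simulate_gene_catalog(config: SimulationConfig) -> GeneCatalog:
    """Draw the gene catalog: ages, lengths, divergence, codon-bias targets.

    Phylostrata are sampled with geometrically decaying weights (most genes
    ancient, as in real phylostratigraphic maps) with every stratum forced
    non-empty.  dN and dS are gamma draws whose scale grows linearly with
    phylostratum, so expected divergence is non-decreasing in gene age rank
    (younger = more diverged).  The ENC target grows from 30 (old, strongly
    biased) to 57 (young, nearly uniform codon usage) with per-gene jitter.
    """
    rng = np.random.default_rng(config.seed)
    n, P = config.n_genes, config.n_ps
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene")

    weights = 0.85 ** np.arange(P)
    ps = rng.choice(np.arange(1, P + 1), size=n, p=weights / weights.sum())
    ps[rng.permutation(n)[:P]] = np.arange(1, P + 1)  # every stratum non-empty

    cds_codons = np.clip(rng.lognormal(np.log(400), 0.4, n).astype(int), 100, 2000)
    age = (ps - 1) / (P - 1)  # 0 = oldest, 1 = youngest
    dN = rng.gamma(shape=2.0, scale=(0.01 + 0.05 * age))
    dS = rng.gamma(shape=2.0, scale=(0.05 + 0.15 * age))
    target_enc = np.clip(30 + 27 * age + rng.normal(0, 2, n), 21, 60)

    table = pd.DataFrame(
        {
            "true_ps": ps.astype(int),
            "cds_length": cds_codons * 3,
            "dN": dN,
            "dS": dS,
            "target_enc": target_enc,
        },
        index=gene_ids,
    )
    go = simulate_go_annotations(gene_ids, rng)
    return GeneCatalog(table=table, go_terms=go)


def simulate_go_annotations(
    gene_ids: pd.Index, rng: np.random.Generator, n_terms: int = 50
) -> dict[str, set[str]]:
    """Sparse GO-like labels: per gene a Poisson(2) number of terms drawn
    from a skewed term-frequency distribution; some genes stay unannotated."""
    terms = np.array([f"GO:{7000000 + i}" for i in range(n_terms)])
    freq = 1.0 / np.arange(1, n_terms + 1)
    freq /= freq.sum()
    out: dict[str, set[str]] = {}
    n_per_gene = rng.poisson(2.0, len(gene_ids))
    for g, m in zip(gene_ids, n_per_gene):
        if m > 0:
            out[g] = set(rng.choice(terms, size=min(m, n_terms), replace=False, p=freq))
    return out


def _stage_bump(config: SimulationConfig) -> np.ndarray:
    """Gaussian bump over stage index, 1 at the phylotypic stage, ~0 at the
    extremes."""
    idx = np.arange(len(config.stages), dtype=float)
    center = config.stages.index(config.phylotypic_stage)
    return np.exp(-0.5 * ((idx - center) / config.bump_width) ** 2)


def true_stage_means(catalog: GeneCatalog, config: SimulationConfig) -> pd.DataFrame:
    """Noise-free per-gene per-stage expected expression (linear scale),
    excluding library-size factors."""
    rng = np.random.default_rng(config.seed + 1)
    n = len(catalog.genes)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    oldness = (config.n_ps - catalog.table["true_ps"].to_numpy()) / (config.n_ps - 1)
    bump = _stage_bump(config)
    log2mu = (
        baseline[:, None]
        + config.effect_size
        * (oldness[:, None] * bump[None, :] + (1 - oldness[:, None]) * (1 - bump[None, :]))
    )
    return pd.DataFrame(
        np.exp2(log2mu), index=catalog.genes, columns=config.stages
    )


def simulate_counts(
    catalog: GeneCatalog, config: SimulationConfig
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts around the hourglass stage means.

    Returns the CountMatrix (with design and gene lengths) and the
    ground-truth stage-mean table.  Library sizes are log-normal per sample;
    the same ``config.seed`` reproduces the matrix byte for byte.
    """
    if len(catalog.genes) != config.n_genes:
        raise ValueError("catalog and config disagree on n_genes")
    rng = np.random.default_rng(config.seed + 2)
    means = true_stage_means(catalog, config)
    samples, stages_of, reps_of = [], [], []
    for stage in config.stages:
        for r in range(1, config.reps_per_stage + 1):
            samples.append(f"{stage}_r{r}")
            stages_of.append(stage)
            reps_of.append(r)
    lib = np.exp(rng.normal(0.0, config.libsize_log_sd, len(samples)))
    mu = means[stages_of].to_numpy() * lib[None, :]
    if np.isinf(config.dispersion):
        counts = rng.poisson(mu)
    else:
        r_ = config.dispersion
        counts = rng.negative_binomial(r_, r_ / (r_ + mu))
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=catalog.genes, columns=samples),
        design=pd.DataFrame(
            {"stage": stages_of, "replicate": reps_of},
            index=pd.Index(samples, name="sample"),
        ),
        gene_lengths=catalog.table["cds_length"].astype(float),
        stage_order=list(config.stages),
    )
    return cm, means


def lineage_for_catalog(n_ps: int, taxa_per_ps: int = 1) -> LineageMap:
    """The lineage map matching the synthetic taxon naming scheme."""
    mapping = {
        f"ps{p}_taxon{t}": p
        for p in range(1, n_ps + 1)
        for t in range(1, taxa_per_ps + 1)
    }
    return LineageMap(n_ps=n_ps, taxon_to_ps=mapping)


def simulate_hit_table(
    catalog: GeneCatalog,
    taxa_per_ps: int = 1,
    noise: float = 0.0,
    seed: int = 0,
    e_max: float = 1e-4,
) -> pd.DataFrame:
    """Homology hits consistent with the true gene ages.

    Each gene gets one hit per taxon in every stratum from its true
    phylostratum up to the focal species, with e-values drawn log-uniformly
    below ``e_max`` (so assignment at any cutoff >= e_max recovers
    ``true_ps`` exactly when ``noise=0``).  With probability ``noise`` a gene
    additionally receives a spurious hit to a stratum-1 taxon, the
    worst-case false signal that drags the gene to the oldest stratum.
    """
    if not 0 <= noise <= 1:
        raise ValueError("noise must lie in [0, 1]")
    if taxa_per_ps < 1:
        raise ValueError("taxa_per_ps must be >= 1")
    rng = np.random.default_rng(seed)
    P = catalog.n_ps
    rows: list[tuple[str, str, float]] = []

    def evalue() -> float:
        return float(10 ** rng.uniform(-50, np.log10(e_max)))

    for gene, true_ps in catalog.table["true_ps"].items():
        for p in range(int(true_ps), P + 1):
            for t in range(1, taxa_per_ps + 1):
                rows.append((gene, f"ps{p}_taxon{t}", evalue()))
        if true_ps > 1 and rng.random() < noise:
            rows.append((gene, "ps1_taxon1", evalue()))
    return pd.DataFrame(rows, columns=["query", "taxon", "evalue"])


# --- coding sequences ------------------------------------------------------

_FAMILY_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.items():
    if _aa in AA_DEGENERACY:
        _FAMILY_CODONS.setdefault(_aa, []).append(_codon)
for _aa in _FAMILY_CODONS:
    _FAMILY_CODONS[_aa].sort()


def _sum_sq(bias: float, k: int) -> float:
    """Sum of squared codon probabilities in a degeneracy-k family under the
    preferred-codon mixture: the major codon has b + (1-b)/k, others (1-b)/k."""
    p_major = bias + (1 - bias) / k
    p_minor = (1 - bias) / k
    return p_major**2 + (k - 1) * p_minor**2


def _enc_at_bias(bias: float, fam_sizes: dict[str, int]) -> float:
    """ENC the estimator would report for given family sizes at a bias level.

    Mirrors the estimator's conventions: F = (n * sum(p^2) - 1) / (n - 1)
    with the family's realized size n, families with n <= 1 or F <= 0
    excluded, missing classes borrowing the mean of computable classes.
    This is what the finite-length bias solve has to invert: the estimator
    itself is upward-biased on short sequences, so targeting the asymptotic
    value would systematically overshoot.
    """
    class_F: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, n in fam_sizes.items():
        if n <= 1:
            continue
        k = AA_DEGENERACY[aa]
        F = (n * _sum_sq(bias, k) - 1) / (n - 1)
        if F > 0:
            class_F[k].append(F)
    avg = {k: float(np.mean(v)) for k, v in class_F.items() if v}
    fill = float(np.mean(list(avg.values())))
    nc = 2.0
    for k, size in ((2, 9), (3, 1), (4, 5), (6, 3)):
        nc += size / avg.get(k, fill)
    return nc


def _round_counts(n: int, probs: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding of n * probs to integer counts summing n."""
    raw = n * probs
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def simulate_cds(catalog: GeneCatalog, seed: int = 0) -> dict[str, str]:
    """Coding sequences whose measured ENC tracks each gene's target.

    Amino acids are drawn uniformly over the 18 degenerate families; the
    per-gene codon bias is then solved so that the ENC *estimator*, applied
    to this gene's realized family sizes, returns the target, and codon
    counts within each family are fixed by largest-remainder rounding (no
    multinomial noise).  Codon order is shuffled; no stop codons are emitted.
    For sequences of >= 300 codons the realized ENC sits within +/-2 of the
    target (the only residual error is integer rounding of codon counts).
    """
    rng = np.random.default_rng(seed)
    families = sorted(_FAMILY_CODONS)
    out: dict[str, str] = {}
    for gene, row in catalog.table.iterrows():
        target = float(row["target_enc"])
        n_codons = int(row["cds_length"]) // 3
        aas = rng.choice(families, size=n_codons)
        fam_sizes = dict(zip(*np.unique(aas, return_counts=True)))
        fam_sizes = {a: int(n) for a, n in fam_sizes.items()}
        lo, hi = _enc_at_bias(1.0, fam_sizes), _enc_at_bias(0.0, fam_sizes)
        if target <= lo:
            bias = 1.0
        elif target >= hi:
            bias = 0.0
        else:
            bias = float(
                brentq(lambda b: _enc_at_bias(b, fam_sizes) - target, 0.0, 1.0,
                       xtol=1e-10)
            )
        codons: list[str] = []
        for aa, n in fam_sizes.items():
            syn = _FAMILY_CODONS[aa]
            k = len(syn)
            probs = np.full(k, (1 - bias) / k)
            probs[0] += bias
            for codon, c in zip(syn, _round_counts(n, probs)):
                codons.extend([codon] * c)
        rng.shuffle(codons)
        out[str(gene)] = "".join(codons)
    return out


# --- writers ---------------------------------------------------------------

def write_all_inputs(
    catalog: GeneCatalog,
    config: SimulationConfig,
    outdir: str | Path,
    taxa_per_ps: int = 1,
    noise: float = 0.0,
    with_cds: bool = True,
) -> dict[str, Path]:
    """Write the full set of pipeline inputs as plain-text files.

    Produces counts.tsv, design.tsv, lengths.tsv, hits.tsv, lineage.tsv,
    divergence.tsv, annotations.tsv, truth.tsv and (optionally) cds.fasta
    under ``outdir``; returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, means = simulate_counts(catalog, config)
    paths = {
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "lengths": outdir / "lengths.tsv",
        "hits": outdir / "hits.tsv",
        "lineage": outdir / "lineage.tsv",
        "divergence": outdir / "divergence.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.tsv",
    }
    cm.counts.to_csv(paths["counts"], sep="\t", index_label="gene")
    cm.design.to_csv(paths["design"], sep="\t")
    cm.gene_lengths.rename("length").to_csv(paths["lengths"], sep="\t", index_label="gene")
    hits = simulate_hit_table(catalog, taxa_per_ps, noise, seed=config.seed + 3)
    hits.rename(columns={"taxon": "subject_taxon", "evalue": "e_value"}).to_csv(
        paths["hits"], sep="\t", index=False
    )
    lineage = lineage_for_catalog(config.n_ps, taxa_per_ps)
    pd.Series(lineage.taxon_to_ps, name="ps").rename_axis("taxon").to_csv(
        paths["lineage"], sep="\t"
    )
    catalog.table[["dN", "dS"]].to_csv(paths["divergence"], sep="\t", index_label="gene")
    with open(paths["annotations"], "w") as fh:
        fh.write("gene\tterm\n")
        for g in catalog.genes:
            for t in sorted(catalog.go_terms.get(g, ())):
                fh.write(f"{g}\t{t}\n")
    catalog.table.to_csv(paths["truth"], sep="\t", index_label="gene")
    if with_cds:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        cds = simulate_cds(catalog, seed=config.seed + 4)
        paths["cds"] = outdir / "cds.fasta"
        SeqIO.write(
            (SeqRecord(Seq(s), id=g, description="") for g, s in cds.items()),
            paths["cds"],
            "fasta",
        )
    return paths
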