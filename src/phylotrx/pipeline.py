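"""End-to-end pipeline: normalize -> phylostratigraphy -> indices -> flat-line
test -> enrichment, driven by one validated configuration.

Every artifact is a plain TSV or JSON file under a single run directory, and
a manifest records the package version, seed, and SHA-256 digests of inputs
and outputs so identical inputs plus the same seed give identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import enrichment_scan, read_annotations
from .expression import (
    collapse_replicates,
    normalize_fraction_of_transcripts,
    read_count_matrix,
    standardize_expression,
    write_stage_expression,
    write_standardized,
)
from .indices import (
    GeneEvolStats,
    min_max_normalize_profile,
    read_divergence_table,
    weighted_transcriptome_index,
)
from .phylostrata import (
    assign_phylostrata,
    evalue_sweep,
    read_hit_table,
    read_lineage_map,
    write_phylostratum_map,
)
from .significance import flat_line_test

log = logging.getLogger("phylotrx")

__all__ = ["RunConfig", "run_pipeline"]

_INDEX_WEIGHTS = {"tai": "ps", "tdni": "dN", "tdsi": "dS", "tcbi": "enc"}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    counts: str
    design: str
    out_dir: str
    stage_order: list[str]
    lengths: str | None = None
    hits: str | None = None
    lineage: str | None = None
    divergence: str | None = None
    cds: str | None = None
    annotations: str | None = None
    e_value: float = 1e-3
    sweep: list[float] = field(default_factory=list)
    indices: list[str] = field(default_factory=lambda: ["tai"])
    normalize_profiles: bool = True
    use_lengths: bool = True
    n_permutations: int = 1000
    seed: int = 0
    enrichment_threshold: float = 0.5
    bh_scope: str = "stage"

    def __post_init__(self) -> None:
        if not self.stage_order:
            raise ValueError("stage_order must be given")
        bad = [i for i in self.indices if i not in _INDEX_WEIGHTS]
        if bad:
            raise ValueError(f"unknown indices: {bad} (choose from {list(_INDEX_WEIGHTS)})")
        if "tai" in self.indices and (self.hits is None or self.lineage is None):
            raise ValueError("TAI requires hits and lineage inputs")
        if ({"tdni", "tdsi"} & set(self.indices)) and self.divergence is None:
            raise ValueError("TdNI/TdSI require a divergence table")
        if "tcbi" in self.indices and self.cds is None:
            raise ValueError("TCBI requires a CDS FASTA")
        if self.use_lengths and self.lengths is None:
            raise ValueError("use_lengths requires a lengths table")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _gene_enc_from_fasta(path: str | Path) -> pd.Series:
    from Bio import SeqIO

    from .indices import effective_number_of_codons

    values = {
        rec.id: effective_number_of_codons(str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    }
    return pd.Series(values, name="enc")


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {
        k: Path(getattr(config, k))
        for k in ("counts", "design", "lengths", "hits", "lineage",
                  "divergence", "cds", "annotations")
        if getattr(config, k) is not None
    }
    missing = {k: str(p) for k, p in inputs.items() if not p.exists()}
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
        "outputs": {},
        "stages": [],
    }

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def stage(name: str):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("normalize")
        cm = read_count_matrix(config.counts, config.design, config.lengths)
        cm.stage_order = list(config.stage_order)
        fractions = normalize_fraction_of_transcripts(cm, use_lengths=config.use_lengths)
        expr = collapse_replicates(fractions, cm)
        write_stage_expression(expr, out / "stage_expression.tsv")
        emit("stage_expression", out / "stage_expression.tsv")
        std = standardize_expression(expr)
        write_standardized(std, out / "standardized.tsv")
        emit("standardized", out / "standardized.tsv")
        emit("audit", out / "standardized.tsv.audit.json")

        evol_cols: dict[str, pd.Series] = {}
        if config.hits is not None:
            stage("phylostratigraphy")
            hits = read_hit_table(config.hits)
            lineage = read_lineage_map(config.lineage)
            pmap = assign_phylostrata(hits, lineage, config.e_value)
            write_phylostratum_map(pmap, out / "phylostrata.tsv")
            emit("phylostrata", out / "phylostrata.tsv")
            evol_cols["ps"] = pmap.to_series().astype(float)
            if config.sweep:
                maps, report = evalue_sweep(hits, lineage, config.sweep)
                long = pd.concat(
                    [m.to_series().rename_axis("gene").reset_index().assign(cutoff=c)
                     for c, m in maps.items()],
                    ignore_index=True,
                )
                long.to_csv(out / "sweep.tsv", sep="\t", index=False)
                emit("sweep", out / "sweep.tsv")
                if len(report):
                    log.warning("e-value sweep: %d monotonicity violations", len(report))
        if config.divergence is not None:
            stage("divergence")
            div = read_divergence_table(config.divergence)
            evol_cols["dN"] = div["dN"]
            evol_cols["dS"] = div["dS"]
        if config.cds is not None:
            stage("enc")
            evol_cols["enc"] = _gene_enc_from_fasta(config.cds)

        evol = GeneEvolStats(pd.DataFrame(evol_cols)) if evol_cols else None

        stage("indices")
        flat_results = {}
        for name in config.indices:
            wname = _INDEX_WEIGHTS[name]
            profile = weighted_transcriptome_index(expr, evol.weights(wname), wname)
            profile.to_frame().to_csv(out / f"{name}.tsv", sep="\t", index=False)
            emit(name, out / f"{name}.tsv")
            if config.normalize_profiles:
                norm = min_max_normalize_profile(profile)
                norm.to_frame().to_csv(out / f"{name}_norm.tsv", sep="\t", index=False)
                emit(f"{name}_norm", out / f"{name}_norm.tsv")
            stage(f"flatline:{name}")
            res = flat_line_test(
                expr, evol.weights(wname), n_perm=config.n_permutations, seed=config.seed
            )
            res.to_json(out / f"{name}_flatline.json")
            emit(f"{name}_flatline", out / f"{name}_flatline.json")
            res.null_band.to_csv(out / f"{name}_band.tsv", sep="\t")
            emit(f"{name}_band", out / f"{name}_band.tsv")
            flat_results[name] = res.p_value

        if config.annotations is not None:
            stage("enrichment")
            ann = read_annotations(config.annotations)
            table = enrichment_scan(
                std, ann, threshold=config.enrichment_threshold, bh_scope=config.bh_scope
            )
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            emit("enrichment", out / "enrichment.tsv")
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "config"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    manifest["flat_line_p"] = flat_results
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
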