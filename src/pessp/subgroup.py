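"""Clade-based substrate-specificity prediction (the PESSP core).

Given a bootstrap consensus tree over curated candidates, the predicted
subgroup is the minimal bipartition side spanning every reference enzyme
with the target defined function. Uncharacterized members of that side are
emitted as predicted to share the references' substrate specificity,
ranked by identity to the mining query; predictions are suppressed when the
clade's bootstrap support falls below a threshold.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import Alignment, DistanceMatrix, distance_matrix, progressive_msa
from .curation import attach_sequences, curate, load_reference_table
from .nj import bootstrap_trees, majority_consensus, neighbor_joining
from .records import CuratedSet, CurationConfig, ProteinRecord
from .tree import Tree


@dataclass
class SubgroupPrediction:
    """The minimal clade spanning all reference positives."""

    clade: frozenset[str]
    positives: frozenset[str]
    candidates: frozenset[str]
    support: float | None = None
    outside_references: frozenset[str] = frozenset()
    non_discriminating: bool = False
    valid: bool = True


def minimal_spanning_clade(tree: Tree, positive_ids) -> SubgroupPrediction:
    """Smallest bipartition side of the unrooted tree containing all positives.

    Falls back to the full leaf set — flagged ``non_discriminating`` — when
    the positives straddle every split. A complement of a single leaf
    ("everything except X") is not considered a designatable cluster, so
    scattered positives are flagged rather than swept into an n-1 clade.
    """
    positives = frozenset(positive_ids)
    if not positives:
        raise ValueError("need at least one positive reference id")
    leaves = frozenset(tree.leaf_names())
    unknown = positives - leaves
    if unknown:
        raise KeyError(f"positive ids not in tree: {sorted(unknown)}")

    n = len(leaves)
    sides: dict[frozenset[str], float | None] = {}
    for side, support in tree.bipartitions(include_trivial=True).items():
        sides.setdefault(side, support)
        sides.setdefault(leaves - side, support)
    for name in leaves:  # leaf splits may be absent when lengths/root merge them
        sides.setdefault(frozenset({name}), None)

    containing = [s for s in sides if positives <= s and len(s) < n - 1]
    if containing:
        clade = min(containing, key=lambda s: (len(s), sorted(s)))
        support = sides[clade]
        flag = False
    else:
        clade = leaves
        support = None
        flag = positives != leaves
    return SubgroupPrediction(
        clade=frozenset(clade),
        positives=positives,
        candidates=frozenset(clade) - positives,
        support=support,
        non_discriminating=flag,
    )


def predict_candidates(
    pred: SubgroupPrediction,
    annotations: dict[str, str],
    min_support: float = 50.0,
    identities: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Rank the clade's uncharacterized members as functional predictions.

    ``annotations`` maps leaf id -> defined function ('' when none). Any leaf
    sharing the positives' function but outside the clade invalidates the
    designation (reported, never silently dropped). Candidates are ranked by
    identity to the query (descending) when available, else alphabetically.
    An empty frame (plus a warning) is returned when clade support is below
    ``min_support``.
    """
    target_functions = {annotations.get(p, "") for p in pred.positives} - {""}
    outside = frozenset(
        leaf
        for leaf, fn in annotations.items()
        if fn and fn in target_functions and leaf not in pred.clade
    )
    pred.outside_references = outside
    pred.valid = not outside
    label = "; ".join(sorted(target_functions)) or "unknown"

    columns = ["accession", "predicted_label", "clade_support", "identity_pct", "rank"]
    if pred.non_discriminating:
        warnings.warn("positives span the whole tree; no discriminating clade")
        return pd.DataFrame(columns=columns)
    if pred.support is not None and pred.support < min_support:
        warnings.warn(
            f"clade support {pred.support:.1f}% below threshold {min_support:.1f}%; "
            "predictions suppressed"
        )
        return pd.DataFrame(columns=columns)

    identities = identities or {}
    ranked = sorted(
        pred.candidates,
        key=lambda c: (-(identities.get(c) if identities.get(c) is not None else -1.0), c),
    )
    rows = [
        {
            "accession": acc,
            "predicted_label": label,
            "clade_support": pred.support,
            "identity_pct": identities.get(acc),
            "rank": i + 1,
        }
        for i, acc in enumerate(ranked)
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class PipelineConfig:
    """Inputs and knobs for one full PESSP run."""

    table: str | Path
    fasta: str | Path
    target_function: str
    bootstrap_n: int = 1000
    seed: int = 0
    min_support: float = 50.0
    distance_model: str = "p-distance"
    curation: CurationConfig = field(default_factory=CurationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        cur = raw.pop("curation", None)
        cfg = cls(**raw)
        if cur == "passthrough":
            cfg.curation = CurationConfig.passthrough()
        elif isinstance(cur, dict):
            cfg.curation = CurationConfig(**cur)
        return cfg


@dataclass
class PesspReport:
    """Every artifact of a pipeline run, stage by stage."""

    curated: CuratedSet
    msa: Alignment
    distances: DistanceMatrix
    nj_tree: Tree
    bootstrap: list[Tree]
    consensus: Tree
    prediction: SubgroupPrediction
    candidates: pd.DataFrame
    manifest: dict


def run_pipeline(
    records: list[ProteinRecord],
    sequences: dict[str, str],
    *,
    target_function: str,
    bootstrap_n: int = 1000,
    seed: int = 0,
    min_support: float = 50.0,
    distance_model: str = "p-distance",
    curation_cfg: CurationConfig | None = None,
    outdir: str | Path | None = None,
) -> PesspReport:
    """Curate -> align -> distances -> NJ + bootstrap -> consensus -> predict."""

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"PESSP stage '{name}' failed: {exc}") from exc

        return _Ctx()

    with stage("curate"):
        recs = attach_sequences(records, sequences)
        curated = curate(recs, curation_cfg or CurationConfig())
        if len(curated) < 4:
            raise ValueError("fewer than 4 records survive curation")
        positives = frozenset(
            r.accession
            for r in curated.records
            if r.defined_function.strip().lower() == target_function.strip().lower()
        )
        if not positives:
            raise ValueError(f"no reference record has defined function {target_function!r}")
    with stage("align"):
        msa = progressive_msa([(r.accession, r.residues) for r in curated.records])
    with stage("distances"):
        dm = distance_matrix(msa, model=distance_model)
    with stage("tree"):
        nj_tree = neighbor_joining(dm)
        boots = bootstrap_trees(msa, n=bootstrap_n, seed=seed, model=distance_model)
        consensus = majority_consensus(boots)
    with stage("predict"):
        pred = minimal_spanning_clade(consensus, positives)
        annotations = {r.accession: r.defined_function for r in curated.records}
        identities = {
            r.accession: r.identity_to_query
            for r in curated.records
            if r.identity_to_query is not None
        }
        candidates = predict_candidates(pred, annotations, min_support, identities)

    manifest = {
        "target_function": target_function,
        "bootstrap_n": bootstrap_n,
        "seed": seed,
        "min_support": min_support,
        "distance_model": distance_model,
        "n_input": len(records),
        "n_curated": len(curated),
        "positives": sorted(positives),
        "clade_support": pred.support,
        "n_candidates": len(pred.candidates),
    }
    report = PesspReport(
        curated, msa, dm, nj_tree, boots, consensus, pred, candidates, manifest
    )
    if outdir is not None:
        _write_artifacts(report, Path(outdir))
    return report


def run_pessp(config: PipelineConfig, outdir: str | Path | None = None) -> PesspReport:
    """File-based entry point: reads the table and FASTA named by ``config``."""
    from Bio import SeqIO

    records = load_reference_table(config.table)
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(config.fasta), "fasta")
    }
    return run_pipeline(
        records,
        sequences,
        target_function=config.target_function,
        bootstrap_n=config.bootstrap_n,
        seed=config.seed,
        min_support=config.min_support,
        distance_model=config.distance_model,
        curation_cfg=config.curation,
        outdir=outdir,
    )


def _write_artifacts(report: PesspReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "accession": r.accession,
                "organism": r.organism,
                "defined_function": r.defined_function,
                "identity_pct": r.identity_to_query,
            }
            for r in report.curated.records
        ]
    ).to_csv(outdir / "curated.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(report.curated.audit.items()), columns=["accession", "removed_by"]
    ).to_csv(outdir / "audit.tsv", sep="\t", index=False)
    report.msa.to_fasta(outdir / "msa.afa")
    report.distances.to_tsv(outdir / "dist.tsv")
    report.nj_tree.write(outdir / "nj.nwk")
    with (outdir / "bootstrap.nwk").open("w", encoding="utf-8") as fh:
        for t in report.bootstrap:
            fh.write(t.to_newick() + "\n")
    report.consensus.write(outdir / "consensus.nwk")
    report.candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    manifest = dict(report.manifest)
    manifest["artifact_sha256"] = {
        name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        for name in ("msa.afa", "dist.tsv", "nj.nwk", "bootstrap.nwk", "consensus.nwk")
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
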