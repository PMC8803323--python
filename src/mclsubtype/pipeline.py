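"""End-to-end pipeline: simulate -> encode -> cluster -> markers ->
signatures -> clonal dynamics, with a manifest for reproducibility.

Every stage writes its outputs under the run directory before the next
stage starts; a rerun with ``resume=True`` skips stages whose outputs
already exist. The manifest records the package version, the global
seed, the config hash, and for each parameter whether the published
default or a user override was in effect.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, constants, io
from .clonal import call_cohort_evolution, count_events, temporal_order
from .clustering import associate_outcome, find_markers, nmf_consensus
from .signatures import compare_clusters, score_gene_sets
from .synthetic import default_cohort_spec, gene_sets_from_spec, generate_cohort, \
    generate_expression, generate_trajectories

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs; defaults are the published thresholds."""

    outdir: str = "mclsubtype_run"
    seed: int = 0
    n_samples: int = 134
    k_min: int = constants.K_MIN
    k_max: int = constants.K_MAX
    n_restarts: int = constants.N_RESTARTS
    marker_q: float = constants.MARKER_Q_CUTOFF
    clonal_ccf: float = constants.CLONAL_CCF_THRESHOLD
    evolution_none_below: float = constants.EVOLUTION_NONE_BELOW
    evolution_drastic_above: float = constants.EVOLUTION_DRASTIC_ABOVE
    trajectory_merge_threshold: float = constants.TRAJECTORY_MERGE_THRESHOLD
    wap_kernel_width: float = constants.WAP_KERNEL_WIDTH
    wap_n_perm: int = constants.WAP_N_PERM
    resume: bool = False

    def validate(self) -> None:
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if not 0 < self.marker_q < 1:
            raise ValueError("marker_q must be in (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def provenance(self) -> dict[str, str]:
        """'default' vs 'override' per parameter, for the manifest."""
        ref = RunConfig()
        return {
            k: ("default" if getattr(self, k) == getattr(ref, k) else "override")
            for k in self.__dataclass_fields__
        }


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage on a synthetic cohort; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def done(name: str) -> bool:
        return config.resume and (outdir / name).exists()

    spec = default_cohort_spec(seed=config.seed, n_samples=config.n_samples)

    # simulate
    matrix, ccf, metadata = generate_cohort(spec)
    trajectories = generate_trajectories(spec)
    if not done("lesion_matrix.tsv"):
        io.write_lesion_matrix(matrix, outdir / "lesion_matrix.tsv")
        io.write_ccf(ccf, outdir / "ccf.tsv")
        io.write_ccf(trajectories, outdir / "trajectories.tsv")
        metadata.to_csv(outdir / "metadata.tsv", sep="\t")

    # cluster + markers + outcome
    if not done("labels.tsv"):
        result = nmf_consensus(
            matrix,
            range(config.k_min, config.k_max + 1),
            n_restarts=config.n_restarts,
            seed=config.seed,
        )
        io.write_labels(result.labels, outdir / "labels.tsv")
        diag = {
            "chosen_k": result.chosen_k,
            "cophenetic": {str(k): v for k, v in result.cophenetic.items()},
            "silhouette": {str(k): v for k, v in result.silhouette.items()},
        }
        (outdir / "cluster_diagnostics.json").write_text(json.dumps(diag, indent=2) + "\n")
        markers = find_markers(matrix, result.labels, config.marker_q)
        markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
        km_table, logrank = associate_outcome(
            result.labels, metadata[["Time", "Event"]]
        )
        km_table.to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
        (outdir / "logrank.json").write_text(
            json.dumps({"statistic": float(logrank.test_statistic),
                        "p": float(logrank.p_value)}, indent=2) + "\n"
        )
        labels = result.labels
    else:
        labels = io.read_labels(outdir / "labels.tsv")

    # expression signatures
    if not done("signature_scores.tsv"):
        tpm = generate_expression(spec, metadata["TrueCluster"])
        io.write_tpm(tpm, outdir / "tpm.tsv")
        scores = score_gene_sets(tpm, gene_sets_from_spec(spec))
        scores.to_csv(outdir / "signature_scores.tsv", sep="\t", index_label="Sample")
        compare_clusters(scores, labels).to_csv(
            outdir / "signature_clusters.tsv", sep="\t", index=False
        )

    # clonal dynamics
    if not done("evolution.tsv"):
        per_lesion, per_sample = count_events(ccf)
        per_lesion.to_csv(outdir / "clonality_per_lesion.tsv", sep="\t")
        per_sample.to_csv(outdir / "clonal_drivers_per_sample.tsv", sep="\t",
                          index_label="Sample")
        graph = temporal_order(ccf)
        io.write_graph_json(graph, outdir / "temporal_order.json")
        io.write_graph_dot(graph, outdir / "temporal_order.dot")
        evolution = call_cohort_evolution(
            trajectories, config.trajectory_merge_threshold
        )
        evolution.to_csv(outdir / "evolution.tsv", sep="\t", index=False)

    manifest = {
        "package": "mclsubtype",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "parameter_provenance": config.provenance(),
        "stages": ["simulate", "cluster", "markers", "outcome", "signatures", "clonal"],
        "note": "trajectory clone grouping is a simplified agglomerative stand-in, "
                "not a phylogenetic posterior",
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
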