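"""Synthetic MCL-like cohort generator.

Emulates the statistical structure the downstream analyses assume: a
~134-sample cohort with ~35 recurrent lesions planted in 4 genetic
clusters, per-lesion cancer cell fractions with a clonal mode above 0.9
and a subclonal tail, multi-timepoint CCF trajectories under named
evolution scenarios, cluster-shifted expression for gene-set scoring, and
per-cluster exponential survival.

Reproducibility: one global integer seed is expanded into independent
per-stage child streams with ``numpy.random.SeedSequence(seed).spawn``
(PCG64 generators), so each stage is bit-identical across runs and
platforms for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants
from .encoding import LesionMatrix, score_cn, score_ighv, score_mutation

#: Evolution scenarios and the pattern label each is built to receive.
SCENARIO_PATTERNS = {
    "stable": "none",
    "drift": "modest",
    "sweep": "drastic",
    "emergent": "modest",
}


@dataclass
class LesionSpec:
    """One recurrent lesion: name, kind, per-cluster frequency, clonality."""

    name: str
    kind: str  # mutation | del | amp
    per_cluster_freq: tuple[float, ...]
    clonal_prob: float = 0.75

    def validate(self, n_clusters: int) -> None:
        if self.kind not in ("mutation", "del", "amp"):
            raise ValueError(f"lesion {self.name!r}: kind must be mutation/del/amp, got {self.kind!r}")
        if len(self.per_cluster_freq) != n_clusters:
            raise ValueError(
                f"lesion {self.name!r}: per_cluster_freq has length "
                f"{len(self.per_cluster_freq)}, expected {n_clusters}"
            )
        for p in self.per_cluster_freq:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"lesion {self.name!r}: frequency {p} outside [0,1]")
        if not 0.0 <= self.clonal_prob <= 1.0:
            raise ValueError(f"lesion {self.name!r}: clonal_prob {self.clonal_prob} outside [0,1]")


@dataclass
class ExpressionSetSpec:
    """A gene set whose log2 expression is shifted in designated clusters."""

    name: str
    genes: tuple[str, ...]
    shift_per_cluster: tuple[float, ...]
    noise_sd: float = 0.5
    base_log2_mean: float = 3.0


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults describe the reference conditions: 134 samples in 4 clusters
    with proportions 16/23/32/28 (normalised), marker lesions at 0.8
    frequency in their home cluster and 0.05 elsewhere, clonal CCFs from a
    Beta(2,1) rescaled into (0.9, 1], and subclonal CCFs uniform on
    (0.1, 0.9).
    """

    n_samples: int = 134
    n_clusters: int = 4
    lesions: list[LesionSpec] = field(default_factory=list)
    cluster_proportions: tuple[float, ...] | None = None
    ighv_mutated_prob_per_cluster: tuple[float, ...] = (0.9, 0.05, 0.05, 0.05)
    ccf_clonal_beta: tuple[float, float] = (2.0, 1.0)
    ccf_subclonal_range: tuple[float, float] = (0.1, 0.9)
    cn_high_level_prob: float = 0.2
    n_longitudinal_patients: int = 16
    timepoints_per_patient: int = 2
    trajectory_scenarios: tuple[str, ...] | None = None
    trajectory_noise_sd: float = 0.03
    lesions_per_clone: int = 5
    expression_sets: list[ExpressionSetSpec] = field(default_factory=list)
    n_background_genes: int = 200
    survival_hazard_per_cluster: tuple[float, ...] = (0.0010, 0.0095, 0.0120, 0.0325)
    followup_months: tuple[float, float] = (24.0, 120.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be positive")
        props = self.proportions()
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must sum to 1")
        if len(self.ighv_mutated_prob_per_cluster) != self.n_clusters:
            raise ValueError("ighv_mutated_prob_per_cluster length must equal n_clusters")
        for p in self.ighv_mutated_prob_per_cluster:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"ighv_mutated_prob_per_cluster entry {p} outside [0,1]")
        lo, hi = self.ccf_subclonal_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("ccf_subclonal_range must satisfy 0 <= lo < hi <= 1")
        a, b = self.ccf_clonal_beta
        if a <= 0 or b <= 0:
            raise ValueError("ccf_clonal_beta shape parameters must be positive")
        if len(self.survival_hazard_per_cluster) != self.n_clusters:
            raise ValueError("survival_hazard_per_cluster length must equal n_clusters")
        for h in self.survival_hazard_per_cluster:
            if h <= 0:
                raise ValueError(f"survival hazard {h} must be positive")
        if self.timepoints_per_patient < 2:
            raise ValueError("timepoints_per_patient must be >= 2")
        for les in self.lesions:
            les.validate(self.n_clusters)
        if self.trajectory_scenarios is not None:
            unknown = set(self.trajectory_scenarios) - set(SCENARIO_PATTERNS)
            if unknown:
                raise ValueError(f"unknown trajectory scenarios: {sorted(unknown)}")

    def proportions(self) -> tuple[float, ...]:
        if self.cluster_proportions is not None:
            return self.cluster_proportions
        if self.n_clusters == 4:
            raw = np.array([16.0, 23.0, 32.0, 28.0])
        else:
            raw = np.ones(self.n_clusters)
        return tuple(raw / raw.sum())

    def child_rng(self, stage: int) -> np.random.Generator:
        """Per-stage generator: stage i uses the i-th spawn of the root seed."""
        children = np.random.SeedSequence(self.seed).spawn(stage + 1)
        return np.random.default_rng(children[stage])


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Reference 134-sample / 35-lesion / 4-cluster cohort specification.

    34 somatic lesions (one marker cluster each, 0.8 in / 0.05 out) plus
    IGHV status. Copy-number lesions and ATM lean clonal (0.9); NSD2, PCLO
    and KMT2C lean subclonal (0.3); other mutations 0.75.
    """
    markers = {
        0: ["CCND1", "amp(11q13.3)", "HNRNPH1", "RYR2", "PCDH10", "FAT3", "LRP2", "SVEP1"],
        1: ["del(11q22.3)", "ATM", "del(1p21.1)", "amp(8q24)", "del(9q31)",
            "OBSCN", "TACC2", "ZFHX4", "MPDZ"],
        2: ["SP140", "NOTCH1", "NSD2", "KMT2D", "amp(13q31)", "del(6q25.3)",
            "KMT2C", "DCDC1", "PCLO"],
        3: ["TP53", "TRAF2", "del(17p13.3)", "del(13q14.2)", "del(9p21.3)",
            "del(8p23.3)", "del(12p13.31)", "SMARCA4"],
    }
    subclonal_leaning = {"NSD2", "PCLO", "KMT2C"}
    lesions = []
    for cluster, names in markers.items():
        for name in names:
            freq = tuple(0.8 if c == cluster else 0.05 for c in range(4))
            kind = "del" if name.startswith("del(") else "amp" if name.startswith("amp(") else "mutation"
            if kind != "mutation" or name == "ATM":
                clonal_prob = 0.9
            elif name in subclonal_leaning:
                clonal_prob = 0.3
            else:
                clonal_prob = 0.75
            lesions.append(LesionSpec(name=name, kind=kind, per_cluster_freq=freq,
                                      clonal_prob=clonal_prob))
    sets = [
        ExpressionSetSpec("BCR_SIGNALING", tuple(f"BCR_{i}" for i in range(20)),
                          (1.0, 0.0, -1.0, 0.0)),
        ExpressionSetSpec("TNFA_NFKB", tuple(f"NFKB_{i}" for i in range(20)),
                          (0.0, 1.0, -1.0, 0.0)),
        ExpressionSetSpec("MYC_TARGETS", tuple(f"MYC_{i}" for i in range(20)),
                          (0.0, 0.0, -1.0, 1.0)),
    ]
    spec = CohortSpec(lesions=lesions, expression_sets=sets, seed=seed)
    for k, v in overrides.items():
        setattr(spec, k, v)
    spec.validate()
    return spec


def _assign_clusters(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Deterministic largest-remainder cluster sizes, shuffled over samples."""
    props = np.asarray(spec.proportions())
    counts = np.floor(props * spec.n_samples).astype(int)
    frac = props * spec.n_samples - counts
    for i in np.argsort(-frac)[: spec.n_samples - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.arange(spec.n_clusters), counts)
    return labels[rng.permutation(spec.n_samples)]


def _draw_ccf(spec: CohortSpec, clonal_prob: float, rng: np.random.Generator) -> tuple[float, bool]:
    a, b = spec.ccf_clonal_beta
    if rng.random() < clonal_prob:
        # Beta draw rescaled into (0.9, 1] so the truth matches the 0.9 rule.
        return 0.9 + 0.1 * float(rng.beta(a, b)), True
    lo, hi = spec.ccf_subclonal_range
    return float(rng.uniform(lo, hi)), False


def generate_cohort(spec: CohortSpec) -> tuple[LesionMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw one cross-sectional cohort.

    Returns the scored lesion matrix, the per-lesion CCF table (Sample,
    Patient, Lesion, CCF, Timepoint, TrueClonal) and per-sample metadata
    (TrueCluster, IGHV, CN per lesion where applicable, survival Time /
    Event in months).
    """
    spec.validate()
    rng = spec.child_rng(0)
    sample_ids = [f"MCL{i + 1:03d}" for i in range(spec.n_samples)]
    clusters = _assign_clusters(spec, rng)

    score_cols: dict[str, np.ndarray] = {}
    meta_kinds: dict[str, str] = {}
    ccf_rows: list[tuple] = []

    for les in spec.lesions:
        freqs = np.asarray(les.per_cluster_freq)
        present = rng.random(spec.n_samples) < freqs[clusters]
        scores = np.zeros(spec.n_samples, dtype=int)
        for i in np.flatnonzero(present):
            if les.kind == "mutation":
                scores[i] = score_mutation(True)
            else:
                high = rng.random() < spec.cn_high_level_prob
                if les.kind == "del":
                    cn = rng.uniform(0.3, 0.99) if high else rng.uniform(1.0, 1.7)
                else:
                    cn = rng.uniform(3.71, 5.5) if high else rng.uniform(2.3, 3.7)
                scores[i] = score_cn(cn, les.kind)
            ccf, is_clonal = _draw_ccf(spec, les.clonal_prob, rng)
            ccf_rows.append((sample_ids[i], sample_ids[i], les.name, ccf, "T1", is_clonal))
        score_cols[les.name] = scores
        meta_kinds[les.name] = les.kind

    ighv_prob = np.asarray(spec.ighv_mutated_prob_per_cluster)
    ighv_mutated = rng.random(spec.n_samples) < ighv_prob[clusters]
    score_cols["IGHV"] = np.array(
        [score_ighv("mutated" if m else "unmutated") for m in ighv_mutated]
    )
    meta_kinds["IGHV"] = "IGHV"

    matrix = LesionMatrix(
        scores=pd.DataFrame(score_cols, index=pd.Index(sample_ids, name="Sample"), dtype=int),
        lesion_meta=meta_kinds,
    )
    ccf = pd.DataFrame(
        ccf_rows, columns=["Sample", "Patient", "Lesion", "CCF", "Timepoint", "TrueClonal"]
    )

    hazards = np.asarray(spec.survival_hazard_per_cluster)
    event_t = rng.exponential(1.0 / hazards[clusters])
    censor_t = rng.uniform(*spec.followup_months, size=spec.n_samples)
    metadata = pd.DataFrame(
        {
            "Sample": sample_ids,
            "Patient": sample_ids,
            "TrueCluster": clusters,
            "IGHV": np.where(ighv_mutated, "mutated", "unmutated"),
            "Time": np.minimum(event_t, censor_t),
            "Event": (event_t <= censor_t).astype(int),
        }
    ).set_index("Sample")
    return matrix, ccf, metadata


def _scenario_means(scenario: str, n_timepoints: int) -> dict[str, np.ndarray]:
    """Per-clone mean CCF trajectories; linear between endpoint values."""
    t = np.linspace(0.0, 1.0, n_timepoints)
    if scenario == "stable":
        ends = {"truncal": (1.0, 1.0), "cloneB": (0.45, 0.45), "cloneC": (0.30, 0.30)}
    elif scenario == "drift":
        ends = {"truncal": (1.0, 1.0), "cloneB": (0.45, 0.80), "cloneC": (0.30, 0.30)}
    elif scenario == "sweep":
        ends = {"truncal": (1.0, 1.0), "cloneB": (0.25, 0.95), "cloneC": (0.60, 0.05)}
    elif scenario == "emergent":
        ends = {"truncal": (1.0, 1.0), "cloneB": (0.45, 0.45), "cloneC": (0.0, 0.45)}
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return {clone: a + (b - a) * t for clone, (a, b) in ends.items()}


def generate_trajectories(spec: CohortSpec) -> pd.DataFrame:
    """Draw longitudinal CCF trajectories for each longitudinal patient.

    Each patient carries three lesion clones (truncal plus two subclones)
    whose mean CCFs follow the patient's scenario; per-lesion CCFs add
    Gaussian noise (sd ``trajectory_noise_sd``) and are clipped to [0, 1].
    The scenario and its built-in expected evolution pattern are stored as
    ground truth columns.
    """
    spec.validate()
    if spec.n_longitudinal_patients < 1:
        raise ValueError("n_longitudinal_patients must be >= 1")
    rng = spec.child_rng(1)
    if spec.trajectory_scenarios is not None:
        scenarios = [
            spec.trajectory_scenarios[i % len(spec.trajectory_scenarios)]
            for i in range(spec.n_longitudinal_patients)
        ]
    else:
        # Reference mix: 1 stable, 4 drift, 11 sweep per 16 patients.
        base = ["stable"] + ["drift"] * 4 + ["sweep"] * 11
        scenarios = [base[i % len(base)] for i in range(spec.n_longitudinal_patients)]

    rows = []
    for p in range(spec.n_longitudinal_patients):
        patient = f"LP{p + 1:03d}"
        scenario = scenarios[p]
        means = _scenario_means(scenario, spec.timepoints_per_patient)
        for clone, mean_traj in means.items():
            for j in range(spec.lesions_per_clone):
                lesion = f"{patient}_{clone}_les{j + 1}"
                noisy = np.clip(
                    mean_traj + rng.normal(0.0, spec.trajectory_noise_sd, mean_traj.size),
                    0.0, 1.0,
                )
                for ti, ccf in enumerate(noisy):
                    rows.append(
                        (patient, f"{patient}_T{ti + 1}", lesion, float(ccf), f"T{ti + 1}",
                         clone, scenario, SCENARIO_PATTERNS[scenario])
                    )
    return pd.DataFrame(
        rows,
        columns=["Patient", "Sample", "Lesion", "CCF", "Timepoint",
                 "TrueClone", "Scenario", "ExpectedPattern"],
    )


def generate_expression(spec: CohortSpec, labels: pd.Series) -> pd.DataFrame:
    """Draw a genes x samples TPM matrix with cluster-shifted gene sets.

    log2(TPM + 1) for a gene in set g of a sample in cluster c is
    ``base + shift_per_cluster[c] + Normal(0, sd)`` (noise lognormal on the
    TPM scale); values are floored at zero TPM. Background genes share the
    base mean with no shift.
    """
    spec.validate()
    labels = labels.astype(int)
    missing = labels.index[labels.isna()] if labels.isna().any() else []
    if len(missing):
        raise ValueError(f"labels missing for samples: {list(missing)[:5]}")
    rng = spec.child_rng(2)
    samples = list(labels.index)
    cl = labels.to_numpy()

    blocks = []
    names = []
    for gset in spec.expression_sets:
        if len(gset.shift_per_cluster) != spec.n_clusters:
            raise ValueError(f"gene set {gset.name!r}: shift_per_cluster length mismatch")
        shifts = np.asarray(gset.shift_per_cluster)[cl]
        for gene in gset.genes:
            log2v = gset.base_log2_mean + shifts + rng.normal(0, gset.noise_sd, len(samples))
            blocks.append(np.maximum(np.exp2(np.maximum(log2v, 0.0)) - 1.0, 0.0))
            names.append(gene)
    for i in range(spec.n_background_genes):
        log2v = 3.0 + rng.normal(0, 0.5, len(samples))
        blocks.append(np.maximum(np.exp2(np.maximum(log2v, 0.0)) - 1.0, 0.0))
        names.append(f"BG_{i}")
    return pd.DataFrame(np.vstack(blocks), index=pd.Index(names, name="Gene"), columns=samples)


def gene_sets_from_spec(spec: CohortSpec) -> dict[str, list[str]]:
    """Gene-set membership implied by the expression spec (GMT-shaped dict)."""
    return {g.name: list(g.genes) for g in spec.expression_sets}
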