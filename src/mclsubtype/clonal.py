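"""Clonality classification, temporal ordering, and clonal evolution calls.

Cancer cell fractions (CCFs) are the per-lesion fraction of tumor cells
carrying the alteration (the output of purity/ploidy deconvolution tools;
here they are inputs). A lesion is called clonal when CCF > 0.9 and
subclonal otherwise. Co-occurrence of a clonal with a subclonal lesion in
the same sample orders the clonal one earlier; edge support across the
cohort is reported at the >=3-sample (dashed) and >=5-sample (solid)
levels. Longitudinal CCF trajectories are grouped into clones by
agglomerative clustering, and each patient's evolution pattern is called
from the largest per-clone mean-CCF change between consecutive
timepoints: > 0.5 drastic, 0.2..0.5 (inclusive) modest, < 0.2 none when
the clone count is unchanged (and modest when it changed, since clone
gain or loss is itself evolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import constants


def classify_clonal(ccf: float) -> str:
    """'clonal' when CCF strictly exceeds 0.9, else 'subclonal'."""
    if not 0.0 <= ccf <= 1.0:
        raise ValueError(f"CCF must be in [0,1], got {ccf}")
    return "clonal" if ccf > constants.CLONAL_CCF_THRESHOLD else "subclonal"


def count_events(ccf_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Clonal/subclonal tallies per lesion, and clonal-driver counts per sample.

    ``ccf_table`` needs Sample, Lesion, CCF columns; duplicate
    (sample, lesion) rows are rejected.
    """
    if ccf_table.duplicated(subset=["Sample", "Lesion"]).any():
        dup = ccf_table[ccf_table.duplicated(subset=["Sample", "Lesion"])].iloc[0]
        raise ValueError(f"duplicate (sample, lesion) row: ({dup['Sample']}, {dup['Lesion']})")
    if ccf_table.empty:
        per_lesion = pd.DataFrame(columns=["Lesion", "Clonal", "Subclonal"]).set_index("Lesion")
        return per_lesion, pd.Series(dtype=int, name="ClonalDrivers")
    calls = ccf_table["CCF"].map(classify_clonal)
    tagged = ccf_table.assign(Call=calls)
    per_lesion = (
        tagged.pivot_table(index="Lesion", columns="Call", values="Sample",
                           aggfunc="count", fill_value=0)
        .reindex(columns=["clonal", "subclonal"], fill_value=0)
        .rename(columns={"clonal": "Clonal", "subclonal": "Subclonal"})
    )
    per_lesion.columns.name = None
    per_sample = (
        tagged[tagged["Call"] == "clonal"].groupby("Sample")["Lesion"].count()
        .reindex(tagged["Sample"].unique(), fill_value=0)
        .rename("ClonalDrivers")
    )
    return per_lesion, per_sample


def _earliest_timepoint(ccf_table: pd.DataFrame) -> pd.DataFrame:
    """Restrict to each patient's earliest timepoint (lexicographic T1 < T2 ...)."""
    if "Timepoint" not in ccf_table.columns:
        return ccf_table
    key = "Patient" if "Patient" in ccf_table.columns else "Sample"
    first = ccf_table.groupby(key)["Timepoint"].transform("min")
    return ccf_table[ccf_table["Timepoint"] == first]


def temporal_order(ccf_table: pd.DataFrame) -> nx.DiGraph:
    """Directed earlier->later lesion graph from clonal/subclonal pairs.

    Within each earliest-timepoint sample, every (clonal lesion c,
    subclonal lesion s) pair increments edge c->s by one sample of
    support. Edges carry ``support`` plus ``dashed`` (support >= 3) and
    ``solid`` (support >= 5) flags; the graph's ``points_of_departure``
    attribute lists nodes with outgoing reportable (dashed-or-better)
    edges and no incoming reportable edges.
    """
    graph = nx.DiGraph()
    table = _earliest_timepoint(ccf_table)
    for _, sub in table.groupby("Sample"):
        calls = sub["CCF"].map(classify_clonal)
        clonal = sub.loc[calls == "clonal", "Lesion"]
        subclonal = sub.loc[calls == "subclonal", "Lesion"]
        for c in clonal:
            for s in subclonal:
                if c == s:
                    continue
                if graph.has_edge(c, s):
                    graph[c][s]["support"] += 1
                else:
                    graph.add_edge(c, s, support=1)
    for _, _, data in graph.edges(data=True):
        data["dashed"] = data["support"] >= constants.EDGE_SUPPORT_DASHED
        data["solid"] = data["support"] >= constants.EDGE_SUPPORT_SOLID
    reportable = [(u, v) for u, v, d in graph.edges(data=True) if d["dashed"]]
    has_out = {u for u, _ in reportable}
    has_in = {v for _, v in reportable}
    graph.graph["points_of_departure"] = sorted(has_out - has_in)
    return graph


def cluster_trajectories(
    patient_table: pd.DataFrame,
    merge_threshold: float = constants.TRAJECTORY_MERGE_THRESHOLD,
) -> pd.DataFrame:
    """Group one patient's lesions into clones by their CCF trajectories.

    Lesions whose CCF vectors across timepoints sit within
    ``merge_threshold`` Euclidean distance merge under average linkage.
    Returns a clone x timepoint table of mean CCFs with a ``Lesions``
    column listing members. Deterministic: no randomness is involved.
    """
    wide = patient_table.pivot_table(index="Lesion", columns="Timepoint", values="CCF")
    if wide.shape[1] < 2:
        raise ValueError("trajectory clustering needs >= 2 timepoints")
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index[0]
        raise ValueError(f"lesion {missing!r} missing CCF at some timepoint")
    if len(wide) == 1:
        groups = np.array([1])
    else:
        Z = hierarchy.linkage(pdist(wide.to_numpy()), method="average")
        groups = hierarchy.fcluster(Z, t=merge_threshold, criterion="distance")
    out = wide.groupby(groups).mean()
    out.index = [f"clone{g}" for g in out.index]
    out.index.name = "Clone"
    members = pd.Series(wide.index, index=wide.index).groupby(groups).apply(list)
    out["Lesions"] = [members[g] for g in sorted(set(groups))]
    return out


@dataclass
class EvolutionCall:
    patient: str
    ccf_clusters: pd.DataFrame
    max_ccf_change: float
    n_clusters_per_timepoint: list[int]
    pattern: str  # none | modest | drastic


def classify_evolution(
    ccf_clusters: pd.DataFrame,
    patient: str = "",
    presence_ccf: float = constants.CLONE_PRESENCE_CCF,
) -> EvolutionCall:
    """Call the evolution pattern from clustered clone trajectories.

    ``ccf_clusters`` is the clone x timepoint mean-CCF table from
    :func:`cluster_trajectories`. The decisive statistic is the maximum
    absolute change of any clone's mean CCF between consecutive
    timepoints. A clone counts toward the per-timepoint clone number when
    its mean CCF is at least ``presence_ccf``.
    """
    values = ccf_clusters.drop(columns=["Lesions"], errors="ignore")
    if values.shape[1] < 2:
        raise ValueError("evolution classification needs >= 2 timepoints")
    if values.isna().any().any():
        raise ValueError("missing timepoint data in clone trajectories")
    arr = values.to_numpy(dtype=float)
    max_change = float(np.abs(np.diff(arr, axis=1)).max())
    n_per_tp = [int((arr[:, j] >= presence_ccf).sum()) for j in range(arr.shape[1])]

    if max_change > constants.EVOLUTION_DRASTIC_ABOVE:
        pattern = "drastic"
    elif max_change >= constants.EVOLUTION_NONE_BELOW:
        pattern = "modest"
    elif len(set(n_per_tp)) == 1:
        pattern = "none"
    else:
        # below the no-evolution change bound but the clone count moved:
        # clone emergence/loss is itself evolution
        pattern = "modest"
    return EvolutionCall(
        patient=patient,
        ccf_clusters=ccf_clusters,
        max_ccf_change=max_change,
        n_clusters_per_timepoint=n_per_tp,
        pattern=pattern,
    )


def call_cohort_evolution(
    longitudinal: pd.DataFrame,
    merge_threshold: float = constants.TRAJECTORY_MERGE_THRESHOLD,
) -> pd.DataFrame:
    """Cluster and classify every patient in a longitudinal CCF table."""
    rows = []
    for patient, sub in longitudinal.groupby("Patient"):
        clones = cluster_trajectories(sub, merge_threshold)
        call = classify_evolution(clones, patient=patient)
        rows.append(
            {
                "Patient": patient,
                "Pattern": call.pattern,
                "MaxCCFChange": call.max_ccf_change,
                "NClones": len(clones),
                "NClonesPerTimepoint": call.n_clusters_per_timepoint,
            }
        )
    return pd.DataFrame(rows)
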