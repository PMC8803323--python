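"""Readers and writers for the pipeline's tabular formats.

All tables are plain TSV. SEG coordinates are 1-based inclusive (a
single-base segment has Start == End; End < Start is rejected). Every
writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .encoding import LESION_KINDS, LesionMatrix

MAF_COLUMNS = ["Sample", "Gene", "Variant_Class", "Protein_Change"]
SEG_COLUMNS = ["Sample", "Chrom", "Start", "End", "AbsoluteCN"]
CCF_COLUMNS = ["Sample", "Lesion", "CCF", "Timepoint"]


def _require_columns(frame: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_maf(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(frame, ["Sample", "Gene", "Variant_Class"], path)
    return frame


def write_maf(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, SEG_COLUMNS, path)
    for line, (_, row) in enumerate(frame.iterrows(), start=2):
        if row["End"] < row["Start"]:
            raise ValueError(
                f"{path}:{line}: zero-length or inverted segment "
                f"(Start={row['Start']}, End={row['End']}; coordinates are 1-based inclusive)"
            )
        if row["AbsoluteCN"] < 0:
            raise ValueError(f"{path}:{line}: negative absolute CN {row['AbsoluteCN']}")
    return frame


def write_seg(frame: pd.DataFrame, path) -> None:
    frame[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ccf(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ["Sample", "Lesion", "CCF"], path)
    bad = frame[(frame["CCF"] < 0) | (frame["CCF"] > 1)]
    if not bad.empty:
        line = bad.index[0] + 2
        raise ValueError(f"{path}:{line}: CCF {bad['CCF'].iloc[0]} outside [0,1]")
    return frame


def write_ccf(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_lesion_matrix(path) -> LesionMatrix:
    """Lesion matrix TSV: first row '#kind' metadata, then integer scores."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        kind_line = fh.readline().rstrip("\n").split("\t")
    if not kind_line or kind_line[0] != "#kind":
        raise ValueError(f"{path}:2: expected '#kind' metadata row")
    lesions = header[1:]
    meta = dict(zip(lesions, kind_line[1:]))
    unknown = {k for k in meta.values() if k not in LESION_KINDS}
    if unknown:
        raise ValueError(f"{path}:2: unknown lesion kinds {sorted(unknown)}")
    frame = pd.read_csv(path, sep="\t", skiprows=[1], index_col=0)
    arr = frame.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        for i, row in enumerate(arr):
            for j, v in enumerate(row):
                if float(v) != int(v):
                    raise ValueError(
                        f"{path}:{i + 3}: non-integer score {v!r} for lesion "
                        f"{frame.columns[j]!r}"
                    )
        frame = frame.astype(int)
    frame.index.name = "Sample"
    return LesionMatrix(scores=frame, lesion_meta=meta)


def write_lesion_matrix(matrix: LesionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("Sample\t" + "\t".join(matrix.lesions) + "\n")
        kinds = [matrix.lesion_meta.get(l, "mutation") for l in matrix.lesions]
        fh.write("#kind\t" + "\t".join(kinds) + "\n")
        for sample, row in matrix.scores.iterrows():
            fh.write(str(sample) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_tpm(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if (frame.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative TPM values")
    frame.index.name = "Gene"
    return frame


def write_tpm(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="Gene")


def read_gmt(path) -> dict[str, dict]:
    """GMT: one set per line, tab-separated name, description, genes.

    Trailing empty fields (trailing tabs) are ignored. Returns
    {name: {"description": str, "genes": [..]}}.
    """
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: GMT lines need name, description "
                                 f"and >=1 gene")
            name, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g.strip()]
            if not genes:
                raise ValueError(f"{path}:{line_no}: gene set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"{path}:{line_no}: duplicate gene set {name!r}")
            sets[name] = {"description": description, "genes": genes}
    return sets


def write_gmt(sets: dict[str, dict], path) -> None:
    with open(path, "w") as fh:
        for name, entry in sets.items():
            fh.write("\t".join([name, entry.get("description", "")] + list(entry["genes"])) + "\n")


def gene_sets_only(sets: dict[str, dict]) -> dict[str, list[str]]:
    """Strip descriptions: {name: genes} as the scoring layer expects."""
    return {name: entry["genes"] for name, entry in sets.items()}


def read_labels(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.iloc[:, 0].rename("Cluster")


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("Cluster").to_csv(path, sep="\t", index_label="Sample")


def write_graph_json(graph: nx.DiGraph, path) -> None:
    payload = {
        "points_of_departure": graph.graph.get("points_of_departure", []),
        "edges": [
            {"from": u, "to": v, "support": d["support"],
             "dashed": bool(d["dashed"]), "solid": bool(d["solid"])}
            for u, v, d in graph.edges(data=True)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_graph_json(path) -> nx.DiGraph:
    payload = json.loads(Path(path).read_text())
    graph = nx.DiGraph()
    for e in payload["edges"]:
        graph.add_edge(e["from"], e["to"], support=e["support"],
                       dashed=e["dashed"], solid=e["solid"])
    graph.graph["points_of_departure"] = payload.get("points_of_departure", [])
    return graph


def write_graph_dot(graph: nx.DiGraph, path) -> None:
    """GraphViz DOT: solid edges for support >= 5, dashed for >= 3, dotted else."""
    lines = ["digraph temporal_order {"]
    for u, v, d in graph.edges(data=True):
        style = "solid" if d["solid"] else "dashed" if d["dashed"] else "dotted"
        lines.append(f'  "{u}" -> "{v}" [style={style}, label="{d["support"]}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
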