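"""3D mutation-proximity analysis on protein structures.

Measures whether the missense mutations observed in a cohort cluster
spatially in a protein structure. Each mutated residue carries a weight
equal to the number of patients mutated there; the weighted average
proximity (WAP) score sums, over all residue pairs, the product of
weights damped by a Gaussian kernel of the inter-residue distance:

    WAP = sum_{i<j} w_i * w_j * exp(-d_ij^2 / (2 t^2)),   t = 6 A default.

Significance comes from a permutation null that reassigns the observed
weight multiset to residues drawn uniformly without replacement among all
resolved residues. The contribution of each individual mutation is the
leave-one-out change in -log10(p) (delta-lp): one patient is removed from
a residue, the p-value is recomputed under the same permutation seed
schedule (common random numbers), and a positive delta-lp means removing
the mutation weakens the clustering signal, i.e. that mutation clusters
with the rest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants

logger = logging.getLogger(__name__)


@dataclass
class StructureMutationSet:
    """Residue coordinates plus per-residue mutation weights for one protein."""

    residues: pd.DataFrame  # index: residue id (author numbering); columns x,y,z
    weights: pd.Series  # residue id -> nonnegative patient count
    sample_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        coords = self.residues[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValueError("residue coordinates must be finite")
        self.weights = self.weights.astype(float)
        if (self.weights < 0).any():
            raise ValueError("mutation weights must be nonnegative")
        unknown = self.weights.index.difference(self.residues.index)
        if len(unknown):
            raise ValueError(f"weights refer to residues absent from the structure: "
                             f"{list(unknown)[:5]}")

    def mutated(self) -> pd.Series:
        """Residues with positive weight."""
        return self.weights[self.weights > 0]

    def with_weights(self, weights: pd.Series) -> "StructureMutationSet":
        return StructureMutationSet(self.residues, weights, self.sample_annotations)


@dataclass
class ClumpsResult:
    wap: float
    p_value: float
    lp: float
    per_mutation: pd.DataFrame = field(default=None)  # Residue, DeltaLp


def _pair_kernel(coords: np.ndarray, t: float) -> np.ndarray:
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * t * t))


def wap_score(mset: StructureMutationSet, t: float = constants.WAP_KERNEL_WIDTH) -> float:
    """Weighted average proximity of the mutated residues (see module docs)."""
    mut = mset.mutated()
    if mut.empty:
        raise ValueError("no mutated residues to score")
    coords = mset.residues.loc[mut.index, ["x", "y", "z"]].to_numpy(dtype=float)
    w = mut.to_numpy()
    K = _pair_kernel(coords, t)
    # sum over unordered pairs only
    return float(np.triu(np.outer(w, w) * K, k=1).sum())


def _wap_from_positions(coords_all: np.ndarray, idx: np.ndarray, w: np.ndarray,
                        t: float) -> float:
    K = _pair_kernel(coords_all[idx], t)
    return float(np.triu(np.outer(w, w) * K, k=1).sum())


def wap_pvalue(
    mset: StructureMutationSet,
    t: float = constants.WAP_KERNEL_WIDTH,
    n_perm: int = constants.WAP_N_PERM,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p-value for spatial clustering, and its -log10.

    The null keeps the observed weight multiset and scatters it uniformly
    without replacement over the resolved residues;
    p = (1 + #{WAP_null >= WAP_obs}) / (1 + n_perm).
    """
    mut = mset.mutated()
    n_res = len(mset.residues)
    n_mut = len(mut)
    if n_mut == 0:
        raise ValueError("no mutated residues")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-value resolution is coarse", stacklevel=2)
    if n_mut >= n_res:
        warnings.warn("every residue is mutated: permutation null is degenerate, p=1",
                      stacklevel=2)
        return 1.0, 0.0

    coords_all = mset.residues[["x", "y", "z"]].to_numpy(dtype=float)
    w = mut.to_numpy()
    obs = wap_score(mset, t)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.choice(n_res, size=n_mut, replace=False)
        if _wap_from_positions(coords_all, idx, w, t) >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return p, float(-np.log10(p))


def delta_lpvalue(
    mset: StructureMutationSet,
    t: float = constants.WAP_KERNEL_WIDTH,
    n_perm: int = constants.WAP_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-out attribution of the clustering signal per mutated residue.

    For each mutated residue, one patient is removed (the weight drops by
    1; the residue leaves the mutated set if the weight reaches 0) and the
    permutation p-value is recomputed with the same seed so full and
    reduced runs share random numbers. DeltaLp = lp_full - lp_reduced; a
    removal that leaves fewer than two mutated residues is undefined (NaN).
    """
    mut = mset.mutated()
    if len(mut) < 2:
        raise ValueError("delta-lp needs at least two mutated residues")
    _, lp_full = wap_pvalue(mset, t, n_perm, seed)
    rows = []
    for res in mut.index:
        reduced = mset.weights.copy()
        reduced[res] -= 1.0
        reduced_set = mset.with_weights(reduced)
        if len(reduced_set.mutated()) < 2:
            rows.append((res, np.nan))
            logger.info("removal at residue %s leaves <2 mutated residues; delta-lp undefined",
                        res)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, lp_red = wap_pvalue(reduced_set, t, n_perm, seed)
        rows.append((res, lp_full - lp_red))
    return pd.DataFrame(rows, columns=["Residue", "DeltaLp"])


def read_structure(pdb_file: str, chain: str) -> pd.DataFrame:
    """Representative 3D coordinate per residue of one chain of a PDB file.

    Uses the C-alpha atom; residues without one fall back to the centroid
    of their heavy atoms (logged). Author residue numbering is preserved
    so protein-change strings like p.R175H map directly to index 175.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    structure = pdb.PDBFile.read(pdb_file).get_structure(model=1)
    chains = sorted(set(structure.chain_id))
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not in structure; available chains: {chains}")
    sel = structure[(structure.chain_id == chain) & ~structure.hetero]
    sel = sel[sel.element != "H"]

    rows = []
    for res_id in np.unique(sel.res_id):
        res_atoms = sel[sel.res_id == res_id]
        ca = res_atoms[res_atoms.atom_name == "CA"]
        if len(ca):
            xyz = ca.coord[0]
        else:
            xyz = res_atoms.coord.mean(axis=0)
            logger.info("residue %d of chain %s lacks CA; heavy-atom centroid used",
                        int(res_id), chain)
        rows.append((int(res_id), float(xyz[0]), float(xyz[1]), float(xyz[2])))
    if not rows:
        raise ValueError(f"chain {chain!r} contains no polymer residues")
    frame = pd.DataFrame(rows, columns=["Residue", "x", "y", "z"]).set_index("Residue")
    return frame


def map_protein_changes(changes: pd.Series, residues: pd.DataFrame) -> pd.Series:
    """Per-residue patient counts from protein-change strings (p.R175H etc.).

    Counts one patient per row; changes at residues unresolved in the
    structure are dropped with a log message. Returns weights aligned to
    ``residues.index`` (zero where unmutated).
    """
    import re

    counts: dict[int, int] = {}
    dropped = 0
    for change in changes:
        m = re.match(r"^p\.[A-Za-z*]{1,3}(\d+)", str(change).strip())
        if not m:
            raise ValueError(f"unparseable protein change {change!r}")
        res = int(m.group(1))
        if res in residues.index:
            counts[res] = counts.get(res, 0) + 1
        else:
            dropped += 1
    if dropped:
        logger.info("%d protein changes at residues unresolved in the structure were dropped",
                    dropped)
    weights = pd.Series(0.0, index=residues.index)
    for res, n in counts.items():
        weights[res] = float(n)
    return weights
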